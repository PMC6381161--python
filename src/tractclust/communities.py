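"""Signed-modularity community detection with consensus clustering.

The quality index for a signed network splits the weights into a positive
layer w+ and a negative-magnitude layer w- and scores a partition as

    Q = (1/v+) * sum_ij (w+_ij - e+_ij) d_ij
        - (1/(v+ + v-)) * sum_ij (w-_ij - e-_ij) d_ij,

where v+- are the total layer weights (over ordered pairs), e+-_ij =
s+-_i s+-_j / v+- are the chance-expected within-module weights from each
node's layer strength, and d_ij = 1 iff i and j share a module.  Positive
within-module weight is rewarded relative to chance with full weight 1/v+;
negative within-module weight is penalized with the smaller weight
1/(v+ + v-), the asymmetry that makes the index well-behaved on correlation
networks.

Optimization is a two-phase Louvain heuristic (seeded local moves, then
aggregation) generalized to the signed index.  Because single runs are
stochastic, a consensus procedure re-clusters the run-by-run co-assignment
(agreement) matrix until every run returns the identical partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import AgglomerativeClustering
from sklearn.metrics import adjusted_rand_score, silhouette_score

from .prep import ResidualizedProfiles, tract_columns
from .similarity import SimilarityNetwork

DEFAULT_TAU = 0.5
DEFAULT_N_RUNS = 100
MAX_OUTER_ITERATIONS = 50
_EPS = 1e-12


@dataclass
class CommunityPartition:
    """Module labels (contiguous from 1) with the signed quality index."""

    ids: list[str]
    labels: np.ndarray
    q: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.ids):
            raise ValueError("labels must match ids")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.labels))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"participant_id": self.ids, "module": self.labels})


@dataclass
class ConsensusResult:
    partition: CommunityPartition
    agreement_matrix: np.ndarray
    n_outer_iterations: int
    run_q: np.ndarray = field(default_factory=lambda: np.empty(0))
    converged: bool = True


def _layers(W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    return np.where(W > 0, W, 0.0), np.where(W < 0, -W, 0.0)


def _signed_q(W: np.ndarray, labels: np.ndarray, resolution: float = 1.0) -> float:
    """Signed Q on a weight matrix (diagonal included if present)."""
    Wp, Wn = _layers(W)
    vp = Wp.sum()
    vn = Wn.sum()
    if vp <= 0:
        raise ValueError("network has no positive weights; Q undefined")
    delta = labels[:, None] == labels[None, :]
    sp = Wp.sum(axis=1)
    q = (Wp[delta].sum() - resolution * (np.outer(sp, sp)[delta]).sum() / vp) / vp
    if vn > 0:
        sn = Wn.sum(axis=1)
        q -= (Wn[delta].sum() - resolution * (np.outer(sn, sn)[delta]).sum() / vn) / (vp + vn)
    return float(q)


def signed_modularity(
    net: SimilarityNetwork, partition: CommunityPartition | np.ndarray,
    resolution: float = 1.0,
) -> float:
    """Evaluate the signed quality index of a partition on a network."""
    labels = partition.labels if isinstance(partition, CommunityPartition) else np.asarray(partition)
    if len(labels) != net.n:
        raise ValueError("partition does not cover the network's nodes")
    return _signed_q(net.weights, labels, resolution)


def _local_moves(W: np.ndarray, rng: np.random.Generator, resolution: float,
                 vp: float, vn: float) -> np.ndarray:
    """Phase 1 of Louvain: seeded sweeps of single-node moves.

    ``vp``/``vn`` are the layer totals of the ORIGINAL network (invariant
    under aggregation), so gains on an aggregated graph equal gains on the
    original.  Self-loops contribute to strengths but are constant across a
    node's community choices and are excluded from neighbour sums.
    """
    n = W.shape[0]
    Wp, Wn = _layers(W)
    Wp_off = Wp.copy()
    Wn_off = Wn.copy()
    np.fill_diagonal(Wp_off, 0.0)
    np.fill_diagonal(Wn_off, 0.0)
    sp = Wp.sum(axis=1)
    sn = Wn.sum(axis=1)
    labels = np.arange(n)
    Sp = sp.copy()
    Sn = sn.copy()
    neg_scale = 1.0 / (vp + vn) if vn > 0 else 0.0

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            c_old = labels[i]
            Sp[c_old] -= sp[i]
            Sn[c_old] -= sn[i]
            kp = np.bincount(labels, weights=Wp_off[i], minlength=n)
            gain = (kp - resolution * sp[i] * Sp / vp) / vp
            if neg_scale:
                kn = np.bincount(labels, weights=Wn_off[i], minlength=n)
                gain -= (kn - resolution * sn[i] * Sn / vn) * neg_scale
            best = int(np.argmax(gain))
            if gain[best] > gain[c_old] + _EPS:
                labels[i] = best
                improved = True
            else:
                labels[i] = c_old
            Sp[labels[i]] += sp[i]
            Sn[labels[i]] += sn[i]
    _, labels = np.unique(labels, return_inverse=True)
    return labels


def _aggregate(W: np.ndarray, labels: np.ndarray) -> np.ndarray:
    k = labels.max() + 1
    M = np.zeros((k, W.shape[0]))
    M[labels, np.arange(W.shape[0])] = 1.0
    return M @ W @ M.T  # diagonal carries within-community weight


def louvain_once(net: SimilarityNetwork, seed: int = 0,
                 resolution: float = 1.0) -> CommunityPartition:
    """One stochastic Louvain run maximizing the signed quality index.

    Starts from singletons, sweeps nodes in a seeded random order accepting
    the first-best strictly positive gain, aggregates, and repeats until no
    aggregation is possible.  Q never decreases across passes.
    """
    rng = np.random.default_rng(seed)
    W = net.weights
    Wp, Wn = _layers(W)
    vp = Wp.sum()
    vn = Wn.sum()
    if vp <= 0:
        raise ValueError("network has no positive weights")
    node_labels = np.arange(net.n)
    W_cur = W
    while True:
        part = _local_moves(W_cur, rng, resolution, vp, vn)
        node_labels = part[node_labels]
        if part.max() + 1 == W_cur.shape[0]:
            break
        W_cur = _aggregate(W_cur, part)
    labels = _canonical(node_labels)
    return CommunityPartition(ids=list(net.ids), labels=labels,
                              q=_signed_q(W, labels, resolution))


def _canonical(labels: np.ndarray) -> np.ndarray:
    """Relabel modules 1..k in order of first appearance."""
    out = np.empty_like(labels)
    mapping: dict[int, int] = {}
    for idx, lab in enumerate(labels):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        out[idx] = mapping[lab]
    return out


def consensus_cluster(net: SimilarityNetwork, n_runs: int = DEFAULT_N_RUNS,
                      tau: float = DEFAULT_TAU, seed: int = 0,
                      resolution: float = 1.0,
                      max_outer: int = MAX_OUTER_ITERATIONS) -> ConsensusResult:
    """Consensus community detection over repeated Louvain runs.

    Runs ``n_runs`` seeded Louvain instantiations, forms the agreement
    matrix of pairwise co-assignment proportions, thresholds it at ``tau``,
    and re-clusters the thresholded agreement network; this outer loop
    repeats until every run returns the identical partition.  Q of the
    returned partition is always evaluated on the original network.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    seeds = np.random.SeedSequence(seed).generate_state(max_outer * n_runs, dtype=np.uint32)
    current = net
    first_agreement = None
    run_q = None
    for outer in range(1, max_outer + 1):
        runs = [
            louvain_once(current, seed=int(seeds[(outer - 1) * n_runs + r]),
                         resolution=resolution)
            for r in range(n_runs)
        ]
        if run_q is None:
            run_q = np.array([p.q for p in runs])
        label_mat = np.stack([p.labels for p in runs])
        agreement = np.mean(
            label_mat[:, :, None] == label_mat[:, None, :], axis=0
        ).astype(float)
        np.fill_diagonal(agreement, 1.0)
        if first_agreement is None:
            first_agreement = agreement
        if all(np.array_equal(runs[0].labels, p.labels) for p in runs[1:]):
            labels = runs[0].labels
            q = _signed_q(net.weights, labels, resolution)
            part = CommunityPartition(ids=list(net.ids), labels=labels, q=q)
            return ConsensusResult(partition=part, agreement_matrix=first_agreement,
                                   n_outer_iterations=outer, run_q=run_q,
                                   converged=True)
        thresholded = np.where(agreement >= tau, agreement, 0.0)
        np.fill_diagonal(thresholded, 0.0)
        current = SimilarityNetwork(ids=list(net.ids), weights=thresholded)
    # report the modal (highest-Q) partition in the failure diagnostics
    best = max(runs, key=lambda p: p.q)
    raise RuntimeError(
        f"consensus did not converge in {max_outer} outer iterations; "
        f"best run had Q={best.q:.4f} with {best.n_modules} modules"
    )


def compare_partitions(a: CommunityPartition, b: CommunityPartition) -> dict:
    """Adjusted Rand index and disagreement count under optimal label matching."""
    if list(a.ids) != list(b.ids):
        raise ValueError("partitions cover different node sets")
    ari = float(adjusted_rand_score(a.labels, b.labels))
    la = np.unique(a.labels)
    lb = np.unique(b.labels)
    contingency = np.zeros((len(la), len(lb)))
    for i, x in enumerate(la):
        for j, y in enumerate(lb):
            contingency[i, j] = np.sum((a.labels == x) & (b.labels == y))
    rows, cols = linear_sum_assignment(-contingency)
    matched = contingency[rows, cols].sum()
    n_disagree = int(len(a.labels) - matched)
    return {"ari": ari, "n_disagreeing": n_disagree}


DEFAULT_LINKAGES = ("ward", "average", "complete", "single")


def silhouette_scan(
    profiles: ResidualizedProfiles | pd.DataFrame,
    k_range: range | list[int] = range(2, 7),
    linkage_set: tuple[str, ...] = DEFAULT_LINKAGES,
) -> pd.DataFrame:
    """Agglomerative-clustering comparison: mean silhouette by (k, linkage).

    Distance between participants is correlation distance 1 - r.  Ward
    linkage requires Euclidean geometry and therefore clusters the profile
    rows directly; the other linkages operate on the precomputed correlation
    distance.  Silhouettes are always scored on the correlation distance so
    linkages are comparable.  Returns a tidy frame with an ``is_best``
    column marking the argmax k within each linkage.
    """
    table = profiles.data if isinstance(profiles, ResidualizedProfiles) else profiles
    X = table[tract_columns(table)].to_numpy(dtype=float)
    n = X.shape[0]
    dist = 1.0 - np.corrcoef(X)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, 2.0)
    rows = []
    for linkage in linkage_set:
        for k in k_range:
            if not 2 <= k <= n - 1:
                raise ValueError(f"k={k} outside [2, n-1]")
            if linkage == "ward":
                model = AgglomerativeClustering(n_clusters=k, linkage="ward")
                labels = model.fit_predict(X)
            else:
                model = AgglomerativeClustering(
                    n_clusters=k, metric="precomputed", linkage=linkage
                )
                labels = model.fit_predict(dist)
            score = silhouette_score(dist, labels, metric="precomputed")
            rows.append({"linkage": linkage, "k": k, "silhouette": float(score)})
    out = pd.DataFrame(rows)
    out["is_best"] = False
    for linkage in linkage_set:
        sub = out[out["linkage"] == linkage]
        out.loc[sub["silhouette"].idxmax(), "is_best"] = True
    return out
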