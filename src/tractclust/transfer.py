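"""Transferring a discovery-sample grouping to independent cohorts.

Two assignment rules carry the discovery grouping to new participants:

* range rule — a new participant receives a group's label iff every marker
  tract value falls inside that group's empirical 5th-95th percentile range
  in the discovery sample (inside both ranges: nearer centroid wins; inside
  neither: unassigned, C0);
* correlation rule — the new participant's full tract profile is correlated
  with each group's mean profile and labelled by the stronger correlation,
  provided it clears a cutoff.

Behavioural predictiveness is scored by median-split accuracy: an assignment
is correct when the participant's group-implied side of the behavioural
median matches their actual side.  A tuning harness splits the sample into
equal train/test/validation thirds, tunes the cutoff (or percentile split)
train-to-test, and scores the frozen rule on validation, with significance
from label-shuffling permutations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .communities import CommunityPartition
from .prep import ResidualizedProfiles, tract_columns
from .similarity import SimilarityNetwork

UNASSIGNED = "C0"
PERCENTILE_BOUNDS = (5.0, 95.0)
DEFAULT_PERCENTILE_GRID = (50, 55, 60, 65, 70)


@dataclass
class GroupAssignment:
    table: pd.DataFrame           # participant_id, label in {C1, C2, C0}
    rule: str                     # "percentile-range" | "correlation"
    bounds: dict | None = None    # per group, per marker tract: (lo, hi)
    cutoff: float | None = None

    @property
    def labels(self) -> np.ndarray:
        return self.table["label"].to_numpy()

    def counts(self) -> dict[str, int]:
        return self.table["label"].value_counts().to_dict()


def _as_table(profiles) -> pd.DataFrame:
    return profiles.data if isinstance(profiles, ResidualizedProfiles) else profiles


def _group_masks(partition: CommunityPartition) -> dict[str, np.ndarray]:
    groups = np.unique(partition.labels)
    if len(groups) != 2:
        raise ValueError("discovery partition must have exactly 2 groups")
    return {f"C{i + 1}": partition.labels == g for i, g in enumerate(groups)}


def range_assign(discovery_profiles, discovery_partition: CommunityPartition,
                 new_profiles, marker_tracts: list[str]) -> GroupAssignment:
    """Assign by the discovery groups' empirical 5-95 percentile ranges on
    the marker tracts (all markers must fall in range; ties to the nearer
    group centroid)."""
    disc = _as_table(discovery_profiles)
    new = _as_table(new_profiles)
    for t in marker_tracts:
        if t not in disc.columns or t not in new.columns:
            raise KeyError(f"marker tract {t!r} missing")
    masks = _group_masks(discovery_partition)
    bounds: dict[str, dict[str, tuple[float, float]]] = {}
    centroids: dict[str, np.ndarray] = {}
    for name, mask in masks.items():
        vals = disc.loc[mask, marker_tracts].to_numpy(dtype=float)
        lo, hi = np.percentile(vals, PERCENTILE_BOUNDS, axis=0)
        bounds[name] = {t: (float(l), float(h))
                        for t, l, h in zip(marker_tracts, lo, hi)}
        centroids[name] = vals.mean(axis=0)

    newvals = new[marker_tracts].to_numpy(dtype=float)
    in_range = {}
    for name in masks:
        lo = np.array([bounds[name][t][0] for t in marker_tracts])
        hi = np.array([bounds[name][t][1] for t in marker_tracts])
        in_range[name] = np.all((newvals >= lo) & (newvals <= hi), axis=1)

    labels = np.full(len(new), UNASSIGNED, dtype=object)
    only1 = in_range["C1"] & ~in_range["C2"]
    only2 = in_range["C2"] & ~in_range["C1"]
    both = in_range["C1"] & in_range["C2"]
    labels[only1] = "C1"
    labels[only2] = "C2"
    if both.any():
        d1 = np.linalg.norm(newvals[both] - centroids["C1"], axis=1)
        d2 = np.linalg.norm(newvals[both] - centroids["C2"], axis=1)
        labels[both] = np.where(d1 <= d2, "C1", "C2")
    out = pd.DataFrame({"participant_id": new["participant_id"], "label": labels})
    return GroupAssignment(table=out, rule="percentile-range", bounds=bounds)


def correlation_assign(discovery_profiles, discovery_partition: CommunityPartition,
                       new_profiles, cutoff: float = 0.0) -> GroupAssignment:
    """Assign by Pearson correlation of the full profile with each discovery
    group's mean profile; below-cutoff correlations with both groups -> C0."""
    if not 0.0 <= cutoff < 1.0:
        raise ValueError("cutoff must be in [0, 1)")
    disc = _as_table(discovery_profiles)
    new = _as_table(new_profiles)
    tracts = [t for t in tract_columns(disc) if t in new.columns]
    if len(tracts) < 3:
        raise ValueError("need >= 3 shared tracts")
    masks = _group_masks(discovery_partition)
    centroids = {name: disc.loc[mask, tracts].to_numpy(dtype=float).mean(axis=0)
                 for name, mask in masks.items()}
    newvals = new[tracts].to_numpy(dtype=float)
    if np.any(newvals.std(axis=1) == 0):
        raise ValueError("zero-variance profile in new cohort")

    def corr_with(c):
        cz = (c - c.mean()) / c.std()
        vz = (newvals - newvals.mean(axis=1, keepdims=True)) \
            / newvals.std(axis=1, keepdims=True)
        return vz @ cz / len(tracts)

    r1 = corr_with(centroids["C1"])
    r2 = corr_with(centroids["C2"])
    best = np.where(r1 >= r2, "C1", "C2")
    rmax = np.maximum(r1, r2)
    labels = np.where(rmax >= cutoff, best, UNASSIGNED)
    out = pd.DataFrame({"participant_id": new["participant_id"], "label": labels})
    return GroupAssignment(table=out, rule="correlation", cutoff=cutoff)


# ---------------------------------------------------------------------------
# median-split prediction


def _median_side(values: np.ndarray, median: float) -> np.ndarray:
    """True = at-or-above the median (deterministic tie rule)."""
    return values >= median


def median_split_accuracy(labels: np.ndarray, behaviour: np.ndarray,
                          median: float, high_group: str) -> float:
    """Fraction of labelled (non-C0) participants whose group-implied side of
    the behavioural median is correct."""
    labels = np.asarray(labels)
    mask = labels != UNASSIGNED
    if not mask.any():
        return np.nan
    predicted_high = labels[mask] == high_group
    actual_high = _median_side(np.asarray(behaviour, dtype=float)[mask], median)
    return float(np.mean(predicted_high == actual_high))


@dataclass
class PredictionResult:
    measure: str
    rule: str
    tuned_value: float            # percentile cut-off or correlation cutoff
    train_accuracy: float
    test_accuracy: float
    validation_accuracy: float
    permutation_p: float
    n_permutations: int
    high_group: str


def tune_and_validate(profiles, behaviour: pd.DataFrame,
                      discovery_partition: CommunityPartition | None,
                      measure: str,
                      cutoff_grid=DEFAULT_PERCENTILE_GRID,
                      seed: int = 0,
                      marker_tracts: list[str] | None = None,
                      rule: str = "percentile",
                      discovery_profiles=None,
                      n_perm: int = 1000) -> PredictionResult:
    """Tune a group-assignment rule for out-of-sample behavioural prediction.

    The sample is split into equal train/test/validation thirds (seeded).
    For each candidate in ``cutoff_grid`` the assignment rule is built on the
    training third and scored on the test third; the best candidate is
    frozen and scored on the validation third.  The mapping from group label
    to median side is learned on the training third (group with the higher
    mean behaviour predicts "above median").  Percentile rule: participants
    above the q-th percentile of the training marker score form one group.
    Correlation rule: correlation_assign against the discovery centroids at
    each cutoff in the grid.
    """
    if len(cutoff_grid) == 0:
        raise ValueError("cutoff grid is empty")
    table = _as_table(profiles).reset_index(drop=True)
    n = len(table)
    if n < 30:
        raise ValueError("need >= 30 participants")
    beh = behaviour.set_index("participant_id").loc[
        table["participant_id"], measure
    ].to_numpy(dtype=float)
    median = float(np.median(beh))

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    third = n // 3
    idx_train = order[:third]
    idx_test = order[third: 2 * third]
    idx_val = order[2 * third: 3 * third]

    if marker_tracts is None:
        marker_tracts = tract_columns(table)[:2]
    marker_score = table[marker_tracts].to_numpy(dtype=float).mean(axis=1)

    def assign_percentile(q: float) -> np.ndarray:
        thr = np.percentile(marker_score[idx_train], q)
        return np.where(marker_score >= thr, "C1", "C2")

    def assign_correlation(cut: float) -> np.ndarray:
        ga = correlation_assign(discovery_profiles, discovery_partition,
                                table, cutoff=cut)
        return ga.labels

    assign = assign_percentile if rule == "percentile" else assign_correlation

    def learn_high_group(labels, idx):
        means = {}
        for g in ("C1", "C2"):
            m = (labels[idx] == g)
            if not m.any():
                raise ValueError(f"group {g} absent from training split")
            means[g] = beh[idx][m].mean()
        return max(means, key=means.get)

    best = None
    for cand in cutoff_grid:
        labels = assign(float(cand))
        high = learn_high_group(labels, idx_train)
        acc_train = median_split_accuracy(labels[idx_train], beh[idx_train],
                                          median, high)
        acc_test = median_split_accuracy(labels[idx_test], beh[idx_test],
                                         median, high)
        if best is None or acc_test > best[1]:
            best = (float(cand), acc_test, acc_train, labels, high)
    tuned, acc_test, acc_train, labels, high = best
    acc_val = median_split_accuracy(labels[idx_val], beh[idx_val], median, high)
    p = permutation_p(acc_val, labels[idx_val], beh[idx_val], median, high,
                      n_perm=n_perm, seed=int(rng.integers(2 ** 31)))
    return PredictionResult(
        measure=measure, rule=rule, tuned_value=tuned,
        train_accuracy=acc_train, test_accuracy=acc_test,
        validation_accuracy=acc_val, permutation_p=p,
        n_permutations=n_perm, high_group=high,
    )


def permutation_p(observed_accuracy: float, labels: np.ndarray,
                  behaviour: np.ndarray, median: float | None = None,
                  high_group: str = "C1", n_perm: int = 1000,
                  seed: int = 0) -> float:
    """Permutation p for a median-split accuracy: shuffle group labels and
    recompute; add-one estimator so p is never zero."""
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    behaviour = np.asarray(behaviour, dtype=float)
    if np.all(behaviour == behaviour[0]):
        raise ValueError("degenerate behaviour: all values equal")
    if median is None:
        median = float(np.median(behaviour))
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    mask = labels != UNASSIGNED
    pred_high = labels[mask] == high_group
    actual_high = _median_side(behaviour[mask], median)
    m = mask.sum()
    # shuffling the labels among labelled participants == permuting pred_high
    perm_idx = np.argsort(rng.random((n_perm, m)), axis=1)
    perm_pred = pred_high[perm_idx]
    perm_acc = np.mean(perm_pred == actual_high[None, :], axis=1)
    exceed = int(np.sum(perm_acc >= observed_accuracy - 1e-12))
    return (1 + exceed) / (1 + n_perm)


def cluster_fit(net: SimilarityNetwork, assignment: GroupAssignment,
                n_perm: int = 1000, seed: int = 0) -> dict:
    """Within- vs between-group connection strength of an assignment on a
    similarity network, with label-shuffling permutation p values.

    intra = sum of weights over pairs within labelled groups; inter = sum
    over pairs spanning the two groups; C0 participants are excluded from
    both the sums and the permutation null.  p_intra is one-sided high,
    p_inter one-sided low (add-one estimator).
    """
    labels = assignment.labels
    mask = labels != UNASSIGNED
    if mask.sum() == 0:
        raise ValueError("all participants unassigned")
    sub_labels = labels[mask]
    if len(np.unique(sub_labels)) < 2:
        raise ValueError("need >= 2 labelled groups")
    W = net.weights[np.ix_(mask, mask)]
    iu = np.triu_indices(W.shape[0], k=1)

    def strengths(lab):
        same = lab[iu[0]] == lab[iu[1]]
        w = W[iu]
        return float(w[same].sum()), float(w[~same].sum())

    intra, inter = strengths(sub_labels)
    rng = np.random.default_rng(seed)
    hits_intra = 0
    hits_inter = 0
    for _ in range(n_perm):
        perm = rng.permutation(sub_labels)
        pi, pe = strengths(perm)
        hits_intra += pi >= intra - 1e-12
        hits_inter += pe <= inter + 1e-12
    return {
        "intra_strength": intra,
        "inter_strength": inter,
        "p_intra": (1 + hits_intra) / (1 + n_perm),
        "p_inter": (1 + hits_inter) / (1 + n_perm),
        "n_permutations": n_perm,
    }
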