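"""Streamline-count connectome thresholding and cross-validated edge selection.

The fixed pipeline order is: absolute threshold (keep counts strictly above
a minimum streamline count) -> consensus mask (keep edges present in at
least a fixed proportion of the sample) -> log10 scaling -> cross-validated
group comparison.  Selection requires a significant Mann-Whitney difference
with a consistent direction in every one of four disjoint training folds
AND in the 20% hold-out test set; the conjunction is the multiplicity
control, so no per-test correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def _check_stack(stack: np.ndarray) -> np.ndarray:
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[1] != stack.shape[2]:
        raise ValueError("stack must be (n_participants, n_rois, n_rois)")
    return stack


def threshold_absolute(stack: np.ndarray, min_count: int = 5) -> np.ndarray:
    """Zero every entry at or below ``min_count`` (strictly-greater survives)."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    stack = _check_stack(stack)
    return np.where(stack > min_count, stack, 0)


def threshold_consensus(stack: np.ndarray, proportion: float = 0.6) -> np.ndarray:
    """Boolean edge mask: edge kept iff nonzero in >= ``proportion`` of
    participants (inclusive boundary)."""
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    stack = _check_stack(stack)
    if stack.shape[0] == 0:
        raise ValueError("empty stack")
    presence = (stack > 0).mean(axis=0)
    return presence >= proportion


def log_scale(stack: np.ndarray) -> np.ndarray:
    """log10 of nonzero counts; zeros stay zero.

    Safe after the absolute threshold: every surviving count is >= 6 so
    log10 > 0 and no collision with structural zeros occurs.
    """
    stack = _check_stack(stack)
    if np.any(stack < 0):
        raise ValueError("negative streamline count")
    out = np.zeros_like(stack, dtype=float)
    nz = stack > 0
    out[nz] = np.log10(stack[nz])
    return out


def _rank_mwu(values: np.ndarray, mask1: np.ndarray, mask2: np.ndarray
              ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Mann-Whitney over columns of ``values`` (rows = subjects).

    Tie-corrected normal approximation with continuity correction; returns
    (two-sided p, direction sign of group1 - group2 mean ranks).  Group
    sizes in this pipeline give n1*n2 well above the exact-enumeration
    regime, where the normal approximation is standard.
    """
    sub = np.concatenate([np.flatnonzero(mask1), np.flatnonzero(mask2)])
    v = values[sub]
    n1 = int(mask1.sum())
    n2 = int(mask2.sum())
    ranks = stats.rankdata(v, axis=0)
    r1 = ranks[:n1].sum(axis=0)
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    # tie correction per column
    tie_term = np.zeros(values.shape[1])
    for j in range(values.shape[1]):
        _, counts = np.unique(v[:, j], return_counts=True)
        tie_term[j] = np.sum(counts ** 3 - counts)
    sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    sigma = np.sqrt(np.maximum(sigma2, 1e-300))
    z = (u1 - mu - np.sign(u1 - mu) * 0.5) / sigma
    p = 2.0 * stats.norm.sf(np.abs(z))
    direction = np.sign(u1 - mu)
    return p, direction


@dataclass
class EdgeSelectionReport:
    edges: pd.DataFrame        # roi_i, roi_j, direction, per-fold p, test p
    mask: np.ndarray           # consensus edge mask used
    min_count: int
    consensus_proportion: float
    alpha: float
    seed: int
    n_train: int
    n_test: int


def select_edges_cv(stack: np.ndarray, labels: np.ndarray,
                    roi_names: list[str] | None = None,
                    train_frac: float = 0.8, n_folds: int = 4,
                    alpha: float = 0.05, seed: int = 0,
                    min_count: int = 5, consensus_proportion: float = 0.6
                    ) -> EdgeSelectionReport:
    """Select connectome edges that consistently differ between two groups.

    The sample is split (seeded) into a training fraction and a hold-out
    test set; the training set is divided into ``n_folds`` disjoint random
    subsets.  An edge is selected iff its Mann-Whitney p < alpha with the
    SAME direction in all folds, and the selection is confirmed (p < alpha,
    same direction) in the hold-out.  Direction -1 means lower counts in
    group 2.
    """
    stack = _check_stack(stack)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("need exactly 2 groups")
    n = stack.shape[0]
    r = stack.shape[1]
    if roi_names is None:
        roi_names = [f"roi_{i}" for i in range(r)]

    thresholded = threshold_absolute(stack, min_count)
    mask = threshold_consensus(thresholded, consensus_proportion)
    logged = log_scale(thresholded)
    iu = np.triu_indices(r, k=1)
    keep = mask[iu]
    edge_vals = logged[:, iu[0], iu[1]][:, keep]
    edge_i = iu[0][keep]
    edge_j = iu[1][keep]
    if edge_vals.shape[1] == 0:
        raise ValueError("no edges survive thresholding")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(round(train_frac * n))
    train_idx = order[:n_train]
    test_idx = order[n_train:]
    folds = np.array_split(rng.permutation(train_idx), n_folds)

    def fold_masks(idx):
        m1 = np.zeros(n, bool)
        m2 = np.zeros(n, bool)
        m1[idx] = labels[idx] == groups[0]
        m2[idx] = labels[idx] == groups[1]
        return m1, m2

    fold_p = []
    fold_dir = []
    for fold in folds:
        m1, m2 = fold_masks(fold)
        if m1.sum() < 8 or m2.sum() < 8:
            raise ValueError("a fold has fewer than 8 members in a group")
        p, d = _rank_mwu(edge_vals, m1, m2)
        fold_p.append(p)
        fold_dir.append(d)
    fold_p = np.stack(fold_p)
    fold_dir = np.stack(fold_dir)

    sig = np.all(fold_p < alpha, axis=0)
    consistent = np.all(fold_dir == fold_dir[0], axis=0) & (fold_dir[0] != 0)
    candidates = sig & consistent

    m1, m2 = fold_masks(test_idx)
    if m1.sum() < 2 or m2.sum() < 2:
        raise ValueError("hold-out test set lacks a group")
    test_p, test_dir = _rank_mwu(edge_vals, m1, m2)
    selected = candidates & (test_p < alpha) & (test_dir == fold_dir[0])

    rows = []
    for k in np.flatnonzero(selected):
        row = {
            "roi_i": roi_names[edge_i[k]],
            "roi_j": roi_names[edge_j[k]],
            "direction": int(fold_dir[0, k]),
            "test_p": float(test_p[k]),
        }
        for f in range(n_folds):
            row[f"fold{f + 1}_p"] = float(fold_p[f, k])
        rows.append(row)
    edges = pd.DataFrame(
        rows, columns=["roi_i", "roi_j", "direction", "test_p"]
        + [f"fold{f + 1}_p" for f in range(n_folds)]
    )
    return EdgeSelectionReport(
        edges=edges, mask=mask, min_count=min_count,
        consensus_proportion=consensus_proportion, alpha=alpha, seed=seed,
        n_train=n_train, n_test=n - n_train,
    )
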