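"""Subgroup characterization: tract-wise group differences and demographics.

Tract comparisons follow a normality-gated scheme: Shapiro-Wilk on each
group's values decides between a two-sample t-test and a Mann-Whitney U
test, with Bonferroni correction across tracts.  Demographic checks work
from summary statistics (pooled-variance t, Welch two-one-sided equivalence
test with margin delta, goodness-of-fit chi-square on assignment counts),
which makes printed group summaries directly checkable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .communities import CommunityPartition
from .prep import ResidualizedProfiles, tract_columns

SHAPIRO_ALPHA = 0.05
EXACT_U_LIMIT = 400  # exact enumeration when n1*n2 <= this


@dataclass
class GroupComparisonReport:
    per_tract: pd.DataFrame  # tract, test, statistic, p_raw, p_bonferroni, means/SEs
    n_tests: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        sig = self.per_tract[self.per_tract["p_bonferroni"] < alpha]
        return sig["tract"].tolist()


def mann_whitney_u(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U statistic of ``x`` (pairwise wins + half-ties) and two-sided p.

    Exact p by enumeration for small samples (n1*n2 <= 400), tie-corrected
    normal approximation otherwise — matching common statistical practice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    method = "exact" if (len(x) * len(y) <= EXACT_U_LIMIT and
                         len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)) \
        else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def compare_tracts(
    profiles: ResidualizedProfiles | pd.DataFrame,
    partition: CommunityPartition,
    raw_profiles: pd.DataFrame | None = None,
) -> GroupComparisonReport:
    """Per-tract two-group comparison with a Shapiro-Wilk normality gate.

    If either group's values deviate from normality (Shapiro-Wilk p < 0.05)
    the tract is tested with Mann-Whitney U, otherwise with a two-sample t
    test; p values are Bonferroni-corrected across tracts.  If
    ``raw_profiles`` is given, raw group means/SEs are reported alongside
    the residualized ones.
    """
    table = profiles.data if isinstance(profiles, ResidualizedProfiles) else profiles
    labels = np.asarray(partition.labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("compare_tracts requires exactly 2 groups")
    m1 = labels == groups[0]
    m2 = labels == groups[1]
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("each group needs at least 3 members")
    tracts = tract_columns(table)
    rows = []
    for tract in tracts:
        v = table[tract].to_numpy(dtype=float)
        g1, g2 = v[m1], v[m2]
        normal = (stats.shapiro(g1).pvalue >= SHAPIRO_ALPHA
                  and stats.shapiro(g2).pvalue >= SHAPIRO_ALPHA)
        if normal:
            res = stats.ttest_ind(g1, g2)
            test, statistic, p = "t", float(res.statistic), float(res.pvalue)
        else:
            statistic, p = mann_whitney_u(g1, g2)
            test = "mannwhitney"
        row = {
            "tract": tract, "test": test, "statistic": statistic, "p_raw": p,
            "mean_1": g1.mean(), "se_1": g1.std(ddof=1) / math.sqrt(len(g1)),
            "mean_2": g2.mean(), "se_2": g2.std(ddof=1) / math.sqrt(len(g2)),
        }
        if raw_profiles is not None:
            rv = raw_profiles[tract].to_numpy(dtype=float)
            row["raw_mean_1"] = rv[m1].mean()
            row["raw_mean_2"] = rv[m2].mean()
        rows.append(row)
    report = pd.DataFrame(rows)
    report["p_bonferroni"] = np.minimum(1.0, report["p_raw"] * len(tracts))
    return GroupComparisonReport(per_tract=report, n_tests=len(tracts))


def pooled_t(m1: float, se1: float, n1: int, m2: float, se2: float, n2: int
             ) -> tuple[float, int, float]:
    """Pooled-variance two-sample t from group summary statistics.

    SDs are recovered as se*sqrt(n); df = n1 + n2 - 2.  Returns
    (t, df, two-sided p).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    var1 = (se1 * math.sqrt(n1)) ** 2
    var2 = (se2 * math.sqrt(n2)) ** 2
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
    t = (m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def tost_equivalence(m1: float, se1: float, n1: int, m2: float, se2: float,
                     n2: int, delta: float) -> dict:
    """Welch two-one-sided equivalence test with margin ``delta``.

    t_lower tests H0: (m1-m2) <= -delta; t_upper tests H0: (m1-m2) >= +delta.
    Equivalence is claimed when both one-sided tests reject.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    if se1 <= 0 or se2 <= 0:
        raise ValueError("standard errors must be positive")
    se_diff = math.sqrt(se1 ** 2 + se2 ** 2)
    diff = m1 - m2
    t_lower = (diff + delta) / se_diff
    t_upper = (diff - delta) / se_diff
    df = (se1 ** 2 + se2 ** 2) ** 2 / (
        se1 ** 4 / (n1 - 1) + se2 ** 4 / (n2 - 1)
    )
    return {
        "t_lower": t_lower,
        "t_upper": t_upper,
        "welch_df": df,
        "p_lower": float(stats.t.sf(t_lower, df)),
        "p_upper": float(stats.t.cdf(t_upper, df)),
    }


def proportion_chisq(counts, expected_proportions=None) -> tuple[float, float]:
    """Pearson goodness-of-fit chi-square against stated proportions
    (equal by default)."""
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2 or np.any(counts < 0):
        raise ValueError("need >= 2 nonnegative cells")
    if expected_proportions is None:
        expected = np.full(counts.size, counts.sum() / counts.size)
    else:
        expected_proportions = np.asarray(expected_proportions, dtype=float)
        expected = counts.sum() * expected_proportions / expected_proportions.sum()
    if np.any(expected == 0):
        raise ValueError("zero expected cell")
    chi2, p = stats.chisquare(counts, expected)
    return float(chi2), float(p)
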