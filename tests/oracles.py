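"""Independent reference implementations used as oracles in the test suite.

Everything here is deliberately naive (double loops, exhaustive enumeration)
and shares no code with the package implementation paths it checks.
"""

import numpy as np


def brute_force_signed_q(W, labels):
    """Term-by-term evaluation of the signed quality index over ordered pairs."""
    n = W.shape[0]
    Wp = np.maximum(W, 0.0)
    Wn = np.maximum(-W, 0.0)
    vp = sum(Wp[i, j] for i in range(n) for j in range(n))
    vn = sum(Wn[i, j] for i in range(n) for j in range(n))
    sp = [sum(Wp[i, j] for j in range(n)) for i in range(n)]
    sn = [sum(Wn[i, j] for j in range(n)) for i in range(n)]
    q = 0.0
    for i in range(n):
        for j in range(n):
            if labels[i] == labels[j]:
                q += (Wp[i, j] - sp[i] * sp[j] / vp) / vp
                if vn > 0:
                    q -= (Wn[i, j] - sn[i] * sn[j] / vn) / (vp + vn)
    return q


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def partition_to_labels(partition, n):
    labels = np.empty(n, dtype=int)
    for k, block in enumerate(partition):
        for i in block:
            labels[i] = k
    return labels


def exhaustive_max_q(W):
    """Global maximum of the signed quality index over all partitions."""
    n = W.shape[0]
    best_q = -np.inf
    best_labels = None
    for part in set_partitions(list(range(n))):
        labels = partition_to_labels(part, n)
        q = brute_force_signed_q(W, labels)
        if q > best_q:
            best_q = q
            best_labels = labels
    return best_q, best_labels


def pairwise_win_u(x, y):
    """Mann-Whitney U of x as an explicit count of pairwise wins + half-ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def ari_closed_form(a, b):
    """Adjusted Rand index from the contingency-table closed form."""
    from math import comb

    a = np.asarray(a)
    b = np.asarray(b)
    n = len(a)
    sum_ij = sum(
        comb(int(np.sum((a == x) & (b == y))), 2)
        for x in np.unique(a) for y in np.unique(b)
    )
    sum_a = sum(comb(int(np.sum(a == x)), 2) for x in np.unique(a))
    sum_b = sum(comb(int(np.sum(b == y)), 2) for y in np.unique(b))
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    return (sum_ij - expected) / (max_index - expected)


def precision_partial_corr(data, i, j):
    """Partial correlation from the inverse covariance (precision) matrix."""
    P = np.linalg.inv(np.cov(data, rowvar=False))
    return -P[i, j] / np.sqrt(P[i, i] * P[j, j])
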