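"""Independent brute-force reference implementations used as test oracles.

Everything here is deliberately naive (explicit loops, textbook formulas)
and shares no code with the package, so agreement is informative.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_scalar(x, y):
    """Textbook Pearson r with two-sided t p-value, one pair at a time."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = len(x)
    xm, ym = x - x.mean(), y - y.mean()
    denom = math.sqrt((xm**2).sum() * (ym**2).sum())
    r = float((xm * ym).sum() / denom)
    if abs(r) >= 1.0:
        return max(-1.0, min(1.0, r)), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    return r, 2.0 * stats.t.sf(abs(t), n - 2)


def spearman_scalar(x, y):
    """Rank-transform then Pearson (average ranks), t-approximation p."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return pearson_scalar(rx, ry)


def naive_strong_filter(edges, r_min, p_max):
    """Loop-based strong-edge filter over a long-form edge table."""
    keep = []
    for row in edges.itertuples(index=False):
        if not (np.isnan(row.r) or np.isnan(row.p)):
            if abs(row.r) >= r_min and row.p <= p_max:
                keep.append((row.gene_a, row.gene_b))
    return sorted(keep)


def naive_complete_linkage_heights(d: np.ndarray) -> list[float]:
    """O(n^3) complete-linkage agglomeration; returns the merge heights."""
    n = d.shape[0]
    clusters = [[i] for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = (np.inf, None)
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                h = max(d[a, b] for a in clusters[i] for b in clusters[j])
                if h < best[0]:
                    best = (h, (i, j))
        h, (i, j) = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return heights


def naive_dunn_z(groups: list[np.ndarray], ref: int) -> list[float]:
    """Dunn's z vs a reference group, written from the definition."""
    pooled = np.concatenate(groups)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    # average ranks for ties, computed by hand
    sorted_vals = pooled[order]
    i = 0
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    n_tot = len(pooled)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    tie = sum(int(c) ** 3 - int(c) for c in counts) / (12.0 * (n_tot - 1))
    bounds = np.cumsum([0] + [len(g) for g in groups])
    mean_rank = [
        ranks[bounds[k] : bounds[k + 1]].mean() for k in range(len(groups))
    ]
    out = []
    for j in range(len(groups)):
        if j == ref:
            continue
        se = math.sqrt(
            (n_tot * (n_tot + 1) / 12.0 - tie)
            * (1.0 / len(groups[j]) + 1.0 / len(groups[ref]))
        )
        out.append((mean_rank[j] - mean_rank[ref]) / se)
    return out


def chi2_formula(table: np.ndarray) -> tuple[float, int]:
    """Pearson chi-squared statistic and dof from sum((O-E)^2 / E)."""
    table = np.asarray(table, float)
    total = table.sum()
    stat = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            e = table[i].sum() * table[:, j].sum() / total
            stat += (table[i, j] - e) ** 2 / e
    dof = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, dof


def ecdf_ks_statistic(s1: np.ndarray, s2: np.ndarray) -> float:
    """Two-sample KS D as the max ECDF gap over all observed points."""
    pts = np.concatenate([s1, s2])
    d = 0.0
    for p in pts:
        f1 = np.mean(s1 <= p)
        f2 = np.mean(s2 <= p)
        d = max(d, abs(f1 - f2))
    return d
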