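"""Cross-dataset correlation rewiring: per-pair delta-r and gene ranking.

Comparing the same gene pairs in two cohorts/datasets, delta = r_ref -
r_query measures how much a pair's co-expression changed; genes are ranked
by how many of their pairs changed strongly (|delta| above a threshold,
default 0.5).  The threshold applies to the absolute difference, but the
signed delta is retained — an edge flipping from +0.8 to -0.8 ("inverted")
is reported as delta = 1.6, not merely flagged.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .corrnet import CorrelationNetwork


def delta_network(
    ref: CorrelationNetwork, query: CorrelationNetwork
) -> pd.DataFrame:
    """Per-pair correlation difference over the genes shared by two networks.

    Returns one row per shared unordered pair: gene_a, gene_b, r_ref,
    r_query, delta (= r_ref - r_query, signed) and abs_delta.  Genes present
    in only one network are reported via a warning, never silently used.
    """
    shared = sorted(set(ref.genes) & set(query.genes))
    if len(shared) < 2:
        raise ValueError("networks share fewer than 2 genes")
    only_ref = sorted(set(ref.genes) - set(shared))
    only_query = sorted(set(query.genes) - set(shared))
    if only_ref or only_query:
        warnings.warn(
            f"genes not shared: {len(only_ref)} reference-only, "
            f"{len(only_query)} query-only; comparing {len(shared)} shared genes",
            stacklevel=2,
        )
    r1 = ref.r.loc[shared, shared].to_numpy()
    r2 = query.r.loc[shared, shared].to_numpy()
    ia, ib = np.triu_indices(len(shared), k=1)
    arr = np.asarray(shared, dtype=object)
    delta = r1[ia, ib] - r2[ia, ib]
    return pd.DataFrame(
        {
            "gene_a": arr[ia],
            "gene_b": arr[ib],
            "r_ref": r1[ia, ib],
            "r_query": r2[ia, ib],
            "delta": delta,
            "abs_delta": np.abs(delta),
        }
    )


def rank_by_delta(deltas: pd.DataFrame, threshold: float = 0.5) -> pd.DataFrame:
    """Per-gene count of incident pairs with abs_delta > threshold.

    Returns (gene, n_changed, mean_abs_delta) sorted by descending count,
    ties broken by gene symbol.  Every gene appearing in the delta table is
    listed (count 0 if none of its pairs changed).
    """
    genes = sorted(set(deltas["gene_a"]) | set(deltas["gene_b"]))
    changed = deltas[deltas["abs_delta"] > threshold]
    counts = {g: 0 for g in genes}
    sums = {g: [] for g in genes}
    for row in deltas.itertuples(index=False):
        sums[row.gene_a].append(row.abs_delta)
        sums[row.gene_b].append(row.abs_delta)
    for row in changed.itertuples(index=False):
        counts[row.gene_a] += 1
        counts[row.gene_b] += 1
    out = pd.DataFrame(
        {
            "gene": genes,
            "n_changed": [counts[g] for g in genes],
            "mean_abs_delta": [float(np.mean(sums[g])) if sums[g] else np.nan
                               for g in genes],
        }
    )
    return out.sort_values(
        ["n_changed", "gene"], ascending=[False, True]
    ).reset_index(drop=True)
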