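"""Per-gene cohort comparisons and clinical associations.

Covers the routine statistics around the network analysis: per-gene
medians and fold changes between cohorts, Kruskal-Wallis with Dunn's
post-hoc multiple comparisons against a reference cohort, overexpressed
target-gene counts, and chi-squared tests of clinical features across
patient subgroups.

Dunn's test is implemented directly (no dedicated post-hoc package in the
stack): all samples are rank-transformed jointly per gene; the z statistic
for cohorts i vs j is

    z = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) * (1/n_i + 1/n_j)),

with tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided p from the
normal tail, Bonferroni-adjusted within the per-gene family of comparisons
against the reference (no across-gene adjustment).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix, GeneSet


@dataclass
class CohortGeneSummary:
    """Per-gene medians, fold changes vs reference, and test results."""

    reference: str
    cohorts: list[str]
    medians: pd.DataFrame  # gene x cohort, log scale
    fold_change: pd.DataFrame  # gene x non-reference cohort, linear scale
    kruskal_p: pd.Series  # per gene
    dunn_z: pd.DataFrame  # gene x non-reference cohort
    dunn_p_raw: pd.DataFrame
    dunn_p_adj: pd.DataFrame  # Bonferroni within the per-gene family
    log_base: float


def dunn_statistics(
    groups: list[np.ndarray], reference_index: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Dunn's post-hoc z statistics of each group against a reference.

    Returns (z, p_raw) for every non-reference group, in group order.
    """
    ns = np.array([len(g) for g in groups])
    pooled = np.concatenate(groups)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    # tie correction over the pooled sample
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (12.0 * (n_total - 1))
    mean_ranks = []
    start = 0
    for n in ns:
        mean_ranks.append(ranks[start : start + n].mean())
        start += n
    mean_ranks = np.array(mean_ranks)
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    zs, ps = [], []
    for j in range(len(groups)):
        if j == reference_index:
            continue
        se = np.sqrt(var_base * (1.0 / ns[j] + 1.0 / ns[reference_index]))
        z = (mean_ranks[j] - mean_ranks[reference_index]) / se
        zs.append(z)
        ps.append(2.0 * stats.norm.sf(abs(z)))
    return np.array(zs), np.array(ps)


def cohort_summary(
    m: ExpressionMatrix,
    cohorts: list[str] | None = None,
    reference: str = "healthy",
) -> CohortGeneSummary:
    """Per-gene cohort comparison against a reference cohort.

    Kruskal-Wallis across all cohorts, Dunn's pairwise comparisons of each
    non-reference cohort vs the reference, and linear-scale fold changes
    computed by de-logging the median difference with the matrix's recorded
    log base (so the result is invariant to the base used at ingest).
    """
    if cohorts is None:
        cohorts = sorted(set(m.cohort_of.values()))
    if reference not in cohorts:
        raise ValueError(f"reference cohort {reference!r} not among {cohorts}")
    members = {c: m.samples_in(c) for c in cohorts}
    for c, ids in members.items():
        if len(ids) < 3:
            raise ValueError(f"cohort {c!r} has {len(ids)} samples; need >= 3")
    base = m.log_base if m.log_base is not None else 2.0
    others = [c for c in cohorts if c != reference]

    genes = m.gene_ids
    medians = pd.DataFrame(index=m.values.index, columns=cohorts, dtype=float)
    fold = pd.DataFrame(index=m.values.index, columns=others, dtype=float)
    kw_p = pd.Series(index=m.values.index, dtype=float)
    dz = pd.DataFrame(index=m.values.index, columns=others, dtype=float)
    dp = pd.DataFrame(index=m.values.index, columns=others, dtype=float)

    for gene in genes:
        row = m.values.loc[gene]
        groups = [row[members[c]].dropna().to_numpy() for c in cohorts]
        for c, g in zip(cohorts, groups):
            medians.loc[gene, c] = np.median(g) if len(g) else np.nan
        ref_med = medians.loc[gene, reference]
        for c in others:
            fold.loc[gene, c] = float(base ** (medians.loc[gene, c] - ref_med))
        if all(len(g) >= 3 for g in groups) and len(groups) >= 2:
            try:
                kw_p[gene] = stats.kruskal(*groups).pvalue
            except ValueError:  # all values identical
                kw_p[gene] = 1.0
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                dz.loc[gene, :] = 0.0
                dp.loc[gene, :] = 1.0
            else:
                z, p = dunn_statistics(groups, cohorts.index(reference))
                dz.loc[gene, others] = z
                dp.loc[gene, others] = p
    n_family = max(len(others), 1)
    dp_adj = (dp * n_family).clip(upper=1.0)
    return CohortGeneSummary(
        reference, cohorts, medians, fold, kw_p, dz, dp, dp_adj, float(base)
    )


def waterfall(summary: CohortGeneSummary, cohort: str) -> pd.DataFrame:
    """Genes ordered by signed log2 fold change vs reference (report artifact)."""
    lfc = np.log2(summary.fold_change[cohort].astype(float))
    out = pd.DataFrame(
        {
            "gene": summary.fold_change.index,
            "log2_fold_change": lfc.to_numpy(),
            "dunn_p_adj": summary.dunn_p_adj[cohort].to_numpy(),
        }
    )
    return out.sort_values("log2_fold_change", ascending=False).reset_index(drop=True)


def target_overexpression_count(
    summary: CohortGeneSummary,
    targets: GeneSet,
    fold_min: float = 2.0,
    p_max: float = 0.05,
) -> dict[str, int]:
    """Per cohort: number of target genes significantly overexpressed
    (fold change > fold_min and adjusted Dunn p <= p_max vs reference).

    Target genes missing from the summary are reported via a warning.
    """
    present = [g for g in targets.genes if g in summary.fold_change.index]
    missing = [g for g in targets.genes if g not in summary.fold_change.index]
    if missing:
        warnings.warn(
            f"{len(missing)} target gene(s) missing from summary: {missing[:10]}",
            stacklevel=2,
        )
    out: dict[str, int] = {}
    for c in summary.fold_change.columns:
        fc = summary.fold_change.loc[present, c]
        p = summary.dunn_p_adj.loc[present, c]
        out[c] = int(((fc > fold_min) & (p <= p_max)).sum())
    return out


@dataclass
class ClinicalAssociation:
    """Chi-squared association of a clinical feature with subgroup labels."""

    feature: str
    table: pd.DataFrame  # subgroup x feature level, counts
    statistic: float
    dof: int
    p: float
    low_expected: bool  # any expected cell < 5


def clinical_association(
    subgroup_of: dict[str, str],
    features: pd.DataFrame,
    feature_name: str,
) -> ClinicalAssociation:
    """Pearson chi-squared test of a categorical clinical feature across
    patient subgroups (samples with a missing value dropped)."""
    if feature_name not in features.columns:
        raise KeyError(f"feature {feature_name!r} not in the clinical table")
    rows = []
    for sample, group in subgroup_of.items():
        if sample in features.index:
            v = features.loc[sample, feature_name]
            if pd.notna(v):
                rows.append((group, str(v)))
    if not rows:
        raise ValueError("no samples with both a subgroup and a feature value")
    df = pd.DataFrame(rows, columns=["subgroup", feature_name])
    table = pd.crosstab(df["subgroup"], df[feature_name])
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {table.shape}; need >= 2 subgroups "
            "and >= 2 feature levels"
        )
    chi2, p, dof, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    low = bool((expected < 5).any())
    if low:
        warnings.warn(
            f"chi-squared on {feature_name!r}: some expected counts < 5",
            stacklevel=2,
        )
    return ClinicalAssociation(feature_name, table, float(chi2), int(dof), float(p), low)
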