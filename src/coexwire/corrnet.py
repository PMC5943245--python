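"""All-pairs gene-gene correlation networks and strong-edge statistics.

A :class:`CorrelationNetwork` holds the full C(G,2) set of pairwise
correlations (r, two-sided p, joint sample count n) for one set of samples.
The headline statistic throughout is the count of *strong* edges, i.e.
pairs passing ``|r| >= r_min`` and ``p <= p_max`` (defaults 0.5 and 0.001).
Because the two-sided p of a correlation is a monotone function of |r| at
fixed n, the strong-edge filter on complete data is equivalent to a single
|r| threshold ``max(r_min, r_crit(n, p_max))``; the fast scorer used by the
stratification search exploits this and is tested to agree with the full
edge-table route.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import ExpressionMatrix


@dataclass(frozen=True)
class StrongEdgeCriteria:
    """The strong-edge filter: keep pairs with |r| >= r_min and p <= p_max."""

    r_min: float = 0.5
    p_max: float = 0.001

    def __post_init__(self) -> None:
        if not (0 < self.r_min <= 1):
            raise ValueError("r_min must be in (0, 1]")
        if not (0 < self.p_max < 1):
            raise ValueError("p_max must be in (0, 1)")


@dataclass
class CorrelationNetwork:
    """All pairwise correlations of one gene set over one sample set."""

    genes: list[str]
    sample_ids: list[str]
    method: str
    r: pd.DataFrame  # gene x gene, NaN where a pair is missing
    p: pd.DataFrame
    n: pd.DataFrame  # joint non-missing sample counts
    excluded_genes: list[str] = field(default_factory=list)
    min_pair_n: int = 10

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_pairs(self) -> int:
        g = self.n_genes
        return g * (g - 1) // 2

    def edges(self) -> pd.DataFrame:
        """Long-form edge table: one row per unordered pair.

        Pairs are ordered so gene_a < gene_b lexicographically and rows are
        sorted lexicographically; pairs with too few joint observations have
        NaN r/p (marked missing, never fabricated).
        """
        genes = sorted(self.genes)
        ia, ib = np.triu_indices(len(genes), k=1)
        r = self.r.loc[genes, genes].to_numpy()
        p = self.p.loc[genes, genes].to_numpy()
        n = self.n.loc[genes, genes].to_numpy()
        return pd.DataFrame(
            {
                "gene_a": np.asarray(genes, dtype=object)[ia],
                "gene_b": np.asarray(genes, dtype=object)[ib],
                "r": r[ia, ib],
                "p": p[ia, ib],
                "n": n[ia, ib].astype(int),
            }
        )

    def r_values(self, drop_missing: bool = True) -> np.ndarray:
        """The C(G,2) off-diagonal r values (upper triangle, once per pair)."""
        arr = self.r.to_numpy()
        iu = np.triu_indices(len(self.genes), k=1)
        vals = arr[iu]
        return vals[~np.isnan(vals)] if drop_missing else vals


# ---------------------------------------------------------------------------
# Correlation computation
# ---------------------------------------------------------------------------

def pairwise_correlations(
    m: ExpressionMatrix,
    sample_ids: list[str] | None = None,
    method: str = "pearson",
    min_pair_n: int = 10,
) -> CorrelationNetwork:
    """Compute all pairwise gene-gene correlations with significance.

    Works on pairwise-complete observations.  Zero-variance genes over the
    selected samples are excluded with a warning (r is undefined for them).
    Pairs with fewer than ``min_pair_n`` joint observations keep their slot
    in the network with NaN r and p.  p-values use the standard two-sided
    t approximation with n-2 degrees of freedom; for Spearman, values are
    rank-transformed per gene first (average ranks).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    samples = m.sample_ids if sample_ids is None else list(sample_ids)
    if len(samples) < 3:
        raise ValueError("need at least 3 samples to correlate")
    df = m.values[samples]

    excluded = m.zero_variance_genes(samples)
    if excluded:
        warnings.warn(
            f"excluding {len(excluded)} zero-variance gene(s): {excluded[:10]}",
            stacklevel=2,
        )
        df = df.drop(index=excluded)
    if df.shape[0] < 2:
        raise ValueError("fewer than 2 genes with variance; nothing to correlate")

    if method == "spearman":
        df = df.rank(axis=1, method="average", na_option="keep")

    obs = df.notna().to_numpy()
    n_mat = obs.astype(np.float64) @ obs.astype(np.float64).T
    r_df = df.T.corr(method="pearson", min_periods=max(min_pair_n, 3))
    r = r_df.to_numpy(copy=True)
    np.clip(r, -1.0, 1.0, out=r)

    nn = n_mat.copy()
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((nn - 2) / (1.0 - r * r))
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(nn - 2, 1))
    p[np.abs(r) >= 1.0] = 0.0  # perfect correlation: t -> inf
    p[np.isnan(r)] = np.nan
    p[nn < 3] = np.nan

    genes = list(df.index)
    np.fill_diagonal(r, 1.0)
    idx = pd.Index(genes, name="gene")
    return CorrelationNetwork(
        genes=genes,
        sample_ids=samples,
        method=method,
        r=pd.DataFrame(r, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n_mat, index=idx, columns=idx),
        excluded_genes=excluded,
        min_pair_n=min_pair_n,
    )


def strong_edges(net: CorrelationNetwork, crit: StrongEdgeCriteria) -> pd.DataFrame:
    """Edges with |r| >= r_min and p <= p_max, lexicographic pair order."""
    e = net.edges()
    keep = (e["r"].abs() >= crit.r_min) & (e["p"] <= crit.p_max)
    return e[keep.fillna(False)].reset_index(drop=True)


def count_strong(net: CorrelationNetwork, crit: StrongEdgeCriteria) -> int:
    return len(strong_edges(net, crit))


# ---------------------------------------------------------------------------
# Fast scorer for complete (no-missing) matrices
# ---------------------------------------------------------------------------

def r_threshold(n_samples: int, crit: StrongEdgeCriteria) -> float:
    """The effective |r| cut implied by the joint (r_min, p_max) filter.

    At fixed n the two-sided p of the t approximation decreases
    monotonically in |r|, so ``p <= p_max`` is ``|r| >= r_crit(n)`` and the
    joint filter is a single threshold ``max(r_min, r_crit)``.
    """
    if n_samples < 3:
        return np.inf
    df = n_samples - 2
    t_crit = stats.t.isf(crit.p_max / 2.0, df)
    r_crit = t_crit / np.sqrt(t_crit * t_crit + df)
    return max(crit.r_min, float(r_crit))


def strong_count_complete(x: np.ndarray, crit: StrongEdgeCriteria) -> int:
    """Strong-edge count for a complete genes x samples value array.

    Equivalent to ``count_strong(pairwise_correlations(...), crit)`` on
    NaN-free data (zero-variance genes yield NaN correlations and are not
    counted, matching their exclusion in the full route).
    """
    thr = r_threshold(x.shape[1], crit)
    if not np.isfinite(thr):
        return 0
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(x)
    iu = np.triu_indices(x.shape[0], k=1)
    vals = np.abs(c[iu])
    return int(np.count_nonzero(vals >= thr))


# ---------------------------------------------------------------------------
# Histograms, null distributions, KS comparison, subsampling
# ---------------------------------------------------------------------------

@dataclass
class RHistogram:
    """A binned distribution of correlation coefficients on [-1, 1]."""

    bin_edges: np.ndarray
    frequencies: np.ndarray  # normalized (sums to 1) unless counts=True at build
    normalized: bool = True

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


def make_histogram(
    r_values: np.ndarray, bin_width: float = 0.05, normalized: bool = True
) -> RHistogram:
    """Histogram of r values with contiguous bins spanning [-1, 1].

    The default width 0.05 places bin edges exactly at +/-0.5, resolving
    the strong-edge cut.
    """
    n_bins = int(round(2.0 / bin_width))
    edges = np.linspace(-1.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(np.asarray(r_values), bins=edges)
    freq = counts.astype(float)
    if normalized and freq.sum() > 0:
        freq = freq / freq.sum()
    return RHistogram(edges, freq, normalized)


def random_geneset_null(
    m: ExpressionMatrix,
    sample_ids: list[str] | None,
    set_size: int,
    n_sets: int,
    crit: StrongEdgeCriteria,
    seed: int,
    exclude: list[str] | None = None,
    bin_width: float = 0.05,
    method: str = "pearson",
    min_pair_n: int = 10,
) -> tuple[RHistogram, np.ndarray]:
    """Null distribution over random gene sets.

    Draws ``n_sets`` gene sets of ``set_size`` (without replacement within a
    set) from the matrix genes minus ``exclude`` (typically the focal
    pathway set), computes each set's correlation distribution, and returns
    the bin-wise mean histogram together with the per-set strong-edge
    counts.  Reproducible under a fixed seed.
    """
    pool = [g for g in m.gene_ids if g not in set(exclude or [])]
    if set_size > len(pool):
        raise ValueError(
            f"set_size {set_size} exceeds the {len(pool)} genes available"
        )
    rng = np.random.default_rng(seed)
    hists = []
    counts = np.empty(n_sets, dtype=int)
    from .data_io import GeneSet, subset_genes

    for i in range(n_sets):
        chosen = list(rng.choice(pool, size=set_size, replace=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub = subset_genes(m, GeneSet(f"null_{i}", chosen))
            net = pairwise_correlations(sub, sample_ids, method, min_pair_n)
        hists.append(make_histogram(net.r_values(), bin_width).frequencies)
        counts[i] = count_strong(net, crit)
    edges = np.linspace(-1.0, 1.0, int(round(2.0 / bin_width)) + 1)
    mean_hist = RHistogram(edges, np.mean(hists, axis=0), True)
    return mean_hist, counts


def ks_compare(sample1: np.ndarray, sample2: np.ndarray) -> tuple[float, float]:
    """Two-sample two-sided Kolmogorov-Smirnov test on r-value samples."""
    s1, s2 = np.asarray(sample1), np.asarray(sample2)
    if s1.size == 0 or s2.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(s1, s2, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


@dataclass
class SubsampleSummary:
    """Strong-edge counts over repeated size-matched cohort subsamples."""

    n_subsamples: int
    subsample_size: int
    mean_strong: float
    sd_strong: float
    counts: np.ndarray
    sd_defined: bool = True


def subsample_strong_counts(
    m: ExpressionMatrix,
    cohort: list[str],
    subsample_size: int,
    n_subsamples: int,
    crit: StrongEdgeCriteria,
    seed: int,
    method: str = "pearson",
    min_pair_n: int = 10,
) -> SubsampleSummary:
    """Strong-edge counts over random subsamples drawn without replacement.

    Used to compare cohorts of unequal size on an equal footing (e.g. the
    large non-TNBC cohort subsampled to the TNBC size).
    """
    cohort = list(cohort)
    if subsample_size > len(cohort):
        raise ValueError("subsample_size exceeds the cohort size")
    rng = np.random.default_rng(seed)
    df = m.values[cohort]
    complete = not df.isna().any().any()
    counts = np.empty(n_subsamples, dtype=int)
    x = df.to_numpy()
    for i in range(n_subsamples):
        idx = rng.choice(len(cohort), size=subsample_size, replace=False)
        if complete and method == "pearson":
            counts[i] = strong_count_complete(x[:, idx], crit)
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = pairwise_correlations(
                    m, [cohort[j] for j in idx], method, min_pair_n
                )
            counts[i] = count_strong(net, crit)
    sd_defined = n_subsamples > 1
    sd = float(np.std(counts, ddof=1)) if sd_defined else 0.0
    return SubsampleSummary(
        n_subsamples, subsample_size, float(np.mean(counts)), sd, counts, sd_defined
    )


# ---------------------------------------------------------------------------
# Exports
# ---------------------------------------------------------------------------

def write_edge_table(
    net: CorrelationNetwork, crit: StrongEdgeCriteria, path, sep: str = "\t"
) -> None:
    """TSV of all edges with an is_strong flag.

    p-values are raw (the strong-edge filter applies no multiplicity
    adjustment); a note to that effect is written as a leading comment.
    """
    e = net.edges()
    e["is_strong"] = ((e["r"].abs() >= crit.r_min) & (e["p"] <= crit.p_max)).fillna(
        False
    )
    with open(path, "w") as fh:
        fh.write(
            "# p-values are raw two-sided t-approximation p-values; "
            "no multiple-testing adjustment is applied by the strong-edge filter\n"
        )
        e.to_csv(fh, sep=sep, index=False, na_rep="NA")


def write_sif(
    net: CorrelationNetwork, crit: StrongEdgeCriteria, path, relation: str = "corr"
) -> None:
    """SIF edge list of the strong edges (Cytoscape-compatible)."""
    e = strong_edges(net, crit)
    with open(path, "w") as fh:
        for _, row in e.iterrows():
            fh.write(f"{row.gene_a}\t{relation}\t{row.gene_b}\n")
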