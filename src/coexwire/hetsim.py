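"""Two-cell-type mixture simulation of heterogeneity-induced correlations.

Bulk tissue samples are mixtures of cell types.  If gene g is expressed
mainly in cell type A and gene h in cell type B, a cohort whose samples
vary in their A/B proportion will show a spurious g-h correlation driven
purely by composition.  This module quantifies how many strong edges such
mixing alone can fabricate.

Model: patient i has an A-cell fraction pi_i ~ Beta(mean, concentration)
(moment parameterization: alpha = mean*conc, beta = (1-mean)*conc; small
concentration gives near-bimodal cohorts where samples are close to pure A
or pure B).  Per gene g and cell type c, the patient's cell-type expression
is X_gci ~ N(mu_gc, sigma_gc) on the linear scale (clipped at 0).  By
default the bulk log-scale value is the proportion-weighted mixture of the
cell-type log levels,

    x_gi = pi_i * log2(X_gAi + 1) + (1 - pi_i) * log2(X_gBi + 1),

so x is exactly affine in pi when the sigmas vanish and composition
artifacts do not depend on where the mean composition sits — only on its
spread.  A ``mixing="linear"`` flag instead mixes linear-scale abundances
and re-logs the sum (physically, transcript abundances add); the log
curvature of that chain makes composition artifacts depend on the mean
proportion as well.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corrnet import (
    RHistogram,
    StrongEdgeCriteria,
    make_histogram,
    pairwise_correlations,
    count_strong,
)
from .data_io import ExpressionMatrix, GeneSet


@dataclass
class CellTypeProfile:
    """Per-gene linear-scale expression location/spread in cell types A/B."""

    table: pd.DataFrame  # index gene; columns mu_a, sigma_a, mu_b, sigma_b

    def __post_init__(self) -> None:
        need = {"mu_a", "sigma_a", "mu_b", "sigma_b"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"profile table needs columns {sorted(need)}")
        if (self.table[["sigma_a", "sigma_b"]] < 0).any().any():
            raise ValueError("sigmas must be >= 0")

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)


@dataclass
class MixtureSpec:
    """Configuration of one mixture-cohort simulation batch."""

    n_patients: int = 118
    proportion_mean: float = 0.5
    proportion_concentration: float = 10.0
    n_sims: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.proportion_mean < 1):
            raise ValueError("proportion_mean must be in (0, 1)")
        if self.proportion_concentration <= 0:
            raise ValueError("proportion_concentration must be > 0")
        if self.n_patients < 3 or self.n_sims < 1:
            raise ValueError("need n_patients >= 3 and n_sims >= 1")


def synthetic_tissue_panel(
    genes: list[str] | GeneSet, n_tissues: int = 53, seed: int = 0
) -> pd.DataFrame:
    """A synthetic per-tissue (median, SD) expression panel.

    Stands in for a public multi-tissue expression summary: per gene and
    tissue, a log-normal linear-scale median and an SD of 20-60% of it.
    Columns: gene, tissue, median, sd.
    """
    gene_list = list(genes.genes) if isinstance(genes, GeneSet) else list(genes)
    rng = np.random.default_rng(seed)
    rows = []
    for g in gene_list:
        meds = np.exp(rng.normal(3.0, 1.5, size=n_tissues))
        sds = meds * rng.uniform(0.2, 0.6, size=n_tissues)
        for t in range(n_tissues):
            rows.append((g, f"tissue_{t + 1:02d}", meds[t], sds[t]))
    return pd.DataFrame(rows, columns=["gene", "tissue", "median", "sd"])


def build_profile_from_panel(
    panel: pd.DataFrame, genes: list[str] | GeneSet, seed: int = 0
) -> CellTypeProfile:
    """Assign, per gene, two distinct random panel entries to cell types A/B."""
    gene_list = list(genes.genes) if isinstance(genes, GeneSet) else list(genes)
    rng = np.random.default_rng(seed)
    grouped = panel.groupby("gene")
    missing = [g for g in gene_list if g not in grouped.groups]
    if missing:
        raise ValueError(f"gene(s) absent from the panel: {missing}")
    rows = {}
    for g in gene_list:
        entries = grouped.get_group(g).reset_index(drop=True)
        if len(entries) < 2:
            raise ValueError(f"gene {g!r}: panel needs >= 2 tissues")
        ia, ib = rng.choice(len(entries), size=2, replace=False)
        rows[g] = {
            "mu_a": entries.loc[ia, "median"],
            "sigma_a": entries.loc[ia, "sd"],
            "mu_b": entries.loc[ib, "median"],
            "sigma_b": entries.loc[ib, "sd"],
        }
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "gene"
    return CellTypeProfile(table)


def simulate_mixture_cohort(
    profile: CellTypeProfile, spec: MixtureSpec, mixing: str = "log"
) -> ExpressionMatrix:
    """Simulate one bulk cohort of two-cell-type mixtures (seeded)."""
    if mixing not in ("linear", "log"):
        raise ValueError("mixing must be 'linear' or 'log'")
    rng = np.random.default_rng(spec.seed)
    n, genes = spec.n_patients, profile.genes
    a = spec.proportion_mean * spec.proportion_concentration
    b = (1 - spec.proportion_mean) * spec.proportion_concentration
    pi = rng.beta(a, b, size=n)

    t = profile.table
    mu_a = t["mu_a"].to_numpy()[:, None]
    mu_b = t["mu_b"].to_numpy()[:, None]
    s_a = t["sigma_a"].to_numpy()[:, None]
    s_b = t["sigma_b"].to_numpy()[:, None]
    xa = np.clip(mu_a + s_a * rng.standard_normal((len(genes), n)), 0, None)
    xb = np.clip(mu_b + s_b * rng.standard_normal((len(genes), n)), 0, None)
    if mixing == "linear":
        x = pi[None, :] * xa + (1 - pi[None, :]) * xb
        vals = np.log2(x + 1.0)
    else:
        vals = pi[None, :] * np.log2(xa + 1.0) + (1 - pi[None, :]) * np.log2(xb + 1.0)
    sample_ids = [f"P{i + 1:04d}" for i in range(n)]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=pd.Index(genes, name="gene"), columns=sample_ids),
        {s: "mixture" for s in sample_ids},
        scale_note=f"log2(x+1) of {mixing}-mixed two-cell-type model",
        log_base=2.0,
    )


@dataclass
class SweepPoint:
    value: float
    mean_histogram: RHistogram
    sd_per_bin: np.ndarray
    strong_counts: np.ndarray


@dataclass
class SweepResult:
    axis: str  # "mean" | "spread"
    points: list[SweepPoint] = field(default_factory=list)

    def mean_strong(self) -> np.ndarray:
        return np.array([p.strong_counts.mean() for p in self.points])


def heterogeneity_sweep(
    profile_or_panel: CellTypeProfile | pd.DataFrame,
    base_spec: MixtureSpec,
    axis: str,
    grid: list[float],
    crit: StrongEdgeCriteria,
    genes: list[str] | None = None,
    mixing: str = "log",
    bin_width: float = 0.05,
) -> SweepResult:
    """Sweep either the mean A-fraction (axis="mean") or its spread
    (axis="spread", grid of Beta concentrations; smaller = wider, with
    values << 1 giving near-bimodal cohorts).

    Per grid point, runs ``base_spec.n_sims`` cohort simulations and
    aggregates the per-simulation correlation histogram (bin-wise mean and
    SD) and strong-edge counts.  When a raw tissue panel is passed instead
    of a fixed profile, the A/B assignment is redrawn for every simulation
    (each simulation is then a fresh random two-cell-type world).

    Along the mean axis the Beta concentration is adjusted per grid point
    so that var(pi) stays at the base spec's value — the sweep varies the
    mean composition while keeping the heterogeneity *spread* constant.
    Simulation seeds are shared across grid points (common random numbers),
    so grid points differ only through the swept parameter.
    """
    if axis not in ("mean", "spread"):
        raise ValueError("axis must be 'mean' or 'spread'")
    if not grid:
        raise ValueError("grid must be non-empty")
    redraw = isinstance(profile_or_panel, pd.DataFrame)
    if redraw and genes is None:
        genes = sorted(profile_or_panel["gene"].unique())
    base_var = (
        base_spec.proportion_mean
        * (1 - base_spec.proportion_mean)
        / (1 + base_spec.proportion_concentration)
    )

    result = SweepResult(axis)
    for gvalue in grid:
        if axis == "mean":
            conc = max(gvalue * (1 - gvalue) / base_var - 1.0, 1e-6)
        else:
            conc = gvalue
        spec = MixtureSpec(
            n_patients=base_spec.n_patients,
            proportion_mean=gvalue if axis == "mean" else base_spec.proportion_mean,
            proportion_concentration=conc,
            n_sims=base_spec.n_sims,
            seed=base_spec.seed,
        )
        hists, counts = [], np.empty(spec.n_sims, dtype=int)
        for s in range(spec.n_sims):
            sim_seed = (spec.seed * 100003 + s * 193) % (2**31)
            if redraw:
                profile = build_profile_from_panel(
                    profile_or_panel, genes, seed=sim_seed + 1
                )
            else:
                profile = profile_or_panel
            sim_spec = MixtureSpec(
                spec.n_patients,
                spec.proportion_mean,
                spec.proportion_concentration,
                1,
                sim_seed,
            )
            cohort = simulate_mixture_cohort(profile, sim_spec, mixing)
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                net = pairwise_correlations(cohort, method="pearson")
            hists.append(make_histogram(net.r_values(), bin_width).frequencies)
            counts[s] = count_strong(net, crit)
        edges = np.linspace(-1.0, 1.0, int(round(2.0 / bin_width)) + 1)
        mean_h = RHistogram(edges, np.mean(hists, axis=0), True)
        result.points.append(
            SweepPoint(float(gvalue), mean_h, np.std(hists, axis=0, ddof=0), counts)
        )
    return result
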