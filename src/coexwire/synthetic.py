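"""Synthetic cohort generator with planted co-expression structure.

A latent-factor Gaussian model: gene g in sample i is

    x_gi = baseline_g + sign_g * loading_g * f_{w(g), i} + eps_gi

with factors f ~ N(0,1) per sample and noise eps ~ N(0, noise_sd^2).  Genes
sharing a factor form a co-expression cluster whose theoretical pairwise
correlation is

    r(g, h) = (l_g * l_h) / sqrt((l_g^2 + s^2) (l_h^2 + s^2))

(s = noise_sd), which makes every planted structure checkable in closed
form.  The model supports:

* an antagonistic cluster pair — two clusters sharing one factor with
  opposite signs, hence positive within- and negative between-cluster r;
* latent patient subgroups — per-subgroup loading scales and optional
  factor *rewiring* (genes reassigned to random factors), so that distinct
  subgroups carry distinct wiring that cancels out when they are mixed;
* ligand-driven target genes loading a cluster's factor directly;
* cancer-like decorrelation (:func:`cancerize`) — factor contributions are
  regenerated gene-wise independently for all clusters except a retained
  set, destroying co-expression while preserving marginal means and
  variances.

The generator operates directly on the log-expression scale the analysis
consumes (no read-count layer).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ExpressionMatrix


@dataclass
class ClusterSpec:
    """A planted co-expression cluster: genes sharing one latent factor."""

    name: str
    genes: list[str]
    factor: str
    loading: float | list[float] = 0.8
    sign: int = 1

    def loadings(self) -> np.ndarray:
        l = np.broadcast_to(np.asarray(self.loading, dtype=float), (len(self.genes),))
        if np.any((l < 0) | (l > 1)):
            raise ValueError(f"cluster {self.name!r}: loadings must be in [0, 1]")
        return np.array(l)


@dataclass
class SubgroupSpec:
    """A planted patient stratum with its own wiring.

    ``loading_scale`` rescales cluster loadings for this stratum (e.g. 0 to
    silence all structure in a noise stratum); ``rewire`` gives the stratum
    its own factor pool (``rewire_factors`` of them, default the base
    count) and reassigns each clustered gene to a random own factor with a
    random sign, so its strong pairs differ from — and partially invert —
    the base wiring, cancelling under superposition.
    """

    name: str
    n_samples: int
    loading_scale: dict[str, float] | float = 1.0
    rewire: bool = False
    rewire_factors: int | None = None

    def scale_for(self, cluster: str) -> float:
        if isinstance(self.loading_scale, dict):
            return float(self.loading_scale.get(cluster, 1.0))
        return float(self.loading_scale)


@dataclass
class TargetSpec:
    """A target gene driven by one cluster factor."""

    symbol: str
    factor: str
    loading: float = 0.8
    sign: int = 1


@dataclass
class SyntheticSpec:
    """Full description of a synthetic cohort."""

    n_samples: int
    gene_clusters: list[ClusterSpec]
    subgroups: list[SubgroupSpec] = field(default_factory=list)
    target_genes: list[TargetSpec] = field(default_factory=list)
    noise_sd: float = 1.0
    baseline_mean: float | dict[str, float] = 8.0
    cohort_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.subgroups:
            total = sum(s.n_samples for s in self.subgroups)
            if total != self.n_samples:
                raise ValueError(
                    f"subgroup sizes sum to {total}, expected n_samples="
                    f"{self.n_samples}"
                )
        genes = self.all_genes()
        if len(genes) != len(set(genes)):
            raise ValueError("duplicate gene symbols across clusters/targets")
        for c in self.gene_clusters:
            c.loadings()  # validates range
        for t in self.target_genes:
            if not (0 <= t.loading <= 1):
                raise ValueError(f"target {t.symbol!r}: loading must be in [0, 1]")

    def all_genes(self) -> list[str]:
        genes = [g for c in self.gene_clusters for g in c.genes]
        genes += [t.symbol for t in self.target_genes]
        return genes

    def factors(self) -> list[str]:
        seen: list[str] = []
        for c in self.gene_clusters:
            if c.factor not in seen:
                seen.append(c.factor)
        for t in self.target_genes:
            if t.factor not in seen:
                seen.append(t.factor)
        return seen


@dataclass
class SyntheticTruth:
    """Ground truth of a generated cohort, sufficient to rebuild it."""

    spec: SyntheticSpec
    subgroup_of: dict[str, str]
    cluster_of: dict[str, str]  # clustered genes only ("targets" excluded)
    factor_values: pd.DataFrame  # factor x sample
    baseline: pd.Series
    amplitude: pd.DataFrame  # |signed loading| per gene x sample
    contribution: pd.DataFrame  # realized factor term per gene x sample
    epsilon: pd.DataFrame

    def cluster_labels(self) -> dict[str, str]:
        return dict(self.cluster_of)


def theoretical_pair_r(l1: float, l2: float, noise_sd: float) -> float:
    """Closed-form correlation of two genes sharing a factor."""
    return (l1 * l2) / np.sqrt((l1**2 + noise_sd**2) * (l2**2 + noise_sd**2))


def generate_cohort(spec: SyntheticSpec) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Draw one cohort from a :class:`SyntheticSpec`; seeded and fully
    reproducible."""
    rng = np.random.default_rng(spec.seed)
    genes = spec.all_genes()
    factors = spec.factors()
    n, g, k = spec.n_samples, len(genes), len(factors)

    subgroups = spec.subgroups or [SubgroupSpec("all", spec.n_samples)]
    sample_ids: list[str] = []
    subgroup_of: dict[str, str] = {}
    i = 0
    for sg in subgroups:
        for _ in range(sg.n_samples):
            sid = f"S{i + 1:04d}"
            sample_ids.append(sid)
            subgroup_of[sid] = sg.name
            i += 1

    f = rng.standard_normal((k, n))

    # per-subgroup factor wiring for clustered genes
    cluster_of: dict[str, str] = {}
    base_factor: dict[str, str] = {}
    base_loading: dict[str, float] = {}
    base_sign: dict[str, int] = {}
    for c in spec.gene_clusters:
        for gene, l in zip(c.genes, c.loadings()):
            cluster_of[gene] = c.name
            base_factor[gene] = c.factor
            base_loading[gene] = float(l)
            base_sign[gene] = int(c.sign)
    for t in spec.target_genes:
        base_factor[t.symbol] = t.factor
        base_loading[t.symbol] = float(t.loading)
        base_sign[t.symbol] = int(t.sign)

    fidx = {name: j for j, name in enumerate(factors)}
    f_rows = {name: f[j] for name, j in fidx.items()}
    amplitude = np.zeros((g, n))
    contribution = np.zeros((g, n))
    col = 0
    for sg in subgroups:
        cols = slice(col, col + sg.n_samples)
        wiring = dict(base_factor)
        sign = dict(base_sign)
        if sg.rewire:
            # this stratum gets its own factor pool (fresh names AND fresh
            # values) and fresh random gene signs, so its strong pairs are
            # largely disjoint from the base wiring and partially inverted
            sub_rng = np.random.default_rng(
                (spec.seed * 9973 + zlib.crc32(sg.name.encode())) % (2**31)
            )
            kk = sg.rewire_factors or k
            own = []
            for j in range(kk):
                name = f"{sg.name}:F{j + 1}"
                f_rows[name] = sub_rng.standard_normal(n)
                own.append(name)
            clustered = [g for g in genes if g in cluster_of]
            if kk >= len(clustered):  # enough factors: one each, no collisions
                assign = sub_rng.permutation(kk)[: len(clustered)]
            else:
                assign = sub_rng.integers(kk, size=len(clustered))
            for gene, j in zip(clustered, assign):  # targets keep their driver
                wiring[gene] = own[int(j)]
                sign[gene] = 1 if sub_rng.integers(2) else -1
        for gi, gene in enumerate(genes):
            scale = sg.scale_for(cluster_of[gene]) if gene in cluster_of else 1.0
            a = sign[gene] * base_loading[gene] * scale
            amplitude[gi, cols] = abs(a)
            contribution[gi, cols] = a * f_rows[wiring[gene]][cols]
        col += sg.n_samples

    factor_values = pd.DataFrame(
        np.vstack(list(f_rows.values())), index=list(f_rows), columns=sample_ids
    )
    eps = rng.standard_normal((g, n)) * spec.noise_sd
    if isinstance(spec.baseline_mean, dict):
        baseline = np.array([spec.baseline_mean.get(gene, 0.0) for gene in genes])
    else:
        baseline = np.full(g, float(spec.baseline_mean))
    values = baseline[:, None] + contribution + eps

    gidx = pd.Index(genes, name="gene")
    m = ExpressionMatrix(
        pd.DataFrame(values, index=gidx, columns=sample_ids),
        {s: spec.cohort_label for s in sample_ids},
        scale_note="synthetic log2-scale",
        log_base=2.0,
    )
    truth = SyntheticTruth(
        spec,
        subgroup_of,
        cluster_of,
        factor_values,
        pd.Series(baseline, index=gidx),
        pd.DataFrame(amplitude, index=gidx, columns=sample_ids),
        pd.DataFrame(contribution, index=gidx, columns=sample_ids),
        pd.DataFrame(eps, index=gidx, columns=sample_ids),
    )
    return m, truth


def cancerize(
    m: ExpressionMatrix,
    truth: SyntheticTruth,
    retain_clusters: set[str],
    rewire_seed: int = 0,
) -> ExpressionMatrix:
    """Destroy planted co-expression except in ``retain_clusters``.

    For every gene outside the retained clusters (target genes included)
    the shared-factor contribution is replaced by an *independent* per-gene
    factor draw of the same amplitude, so marginal means and variances are
    preserved while within-cluster correlation collapses to the noise
    level.  Retained clusters keep their original shared-factor
    contribution; the original noise term is kept throughout.
    """
    known = {c.name for c in truth.spec.gene_clusters}
    unknown = set(retain_clusters) - known
    if unknown:
        raise ValueError(f"unknown cluster name(s): {sorted(unknown)}")
    if list(m.values.index) != list(truth.contribution.index) or list(
        m.values.columns
    ) != list(truth.contribution.columns):
        raise ValueError("matrix does not match the provided truth")
    rng = np.random.default_rng(rewire_seed)
    contrib = truth.contribution.to_numpy(copy=True)
    amp = truth.amplitude.to_numpy()
    genes = list(m.values.index)
    for gi, gene in enumerate(genes):
        cluster = truth.cluster_of.get(gene)
        if cluster in retain_clusters:
            continue
        contrib[gi] = amp[gi] * rng.standard_normal(contrib.shape[1])
    values = (
        truth.baseline.to_numpy()[:, None] + contrib + truth.epsilon.to_numpy()
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=m.values.index, columns=m.values.columns),
        dict(m.cohort_of),
        scale_note=m.scale_note + " (decorrelated)",
        log_base=m.log_base,
    )


# ---------------------------------------------------------------------------
# Ready-made specs at the scale of the motivating study
# ---------------------------------------------------------------------------

def healthy_spec(
    n_samples: int = 113,
    genes_per_cluster: int = 24,
    loading: float = 0.8,
    noise_sd: float = 1.0,
    n_target_genes: int = 0,
    target_loading: float = 0.8,
    seed: int = 0,
) -> SyntheticSpec:
    """A healthy-tissue-like cohort: four co-expression clusters, one
    antagonistic pair (clusters #1 and #4 share a factor with opposite
    signs), optional ligand-driven target genes split between the
    antagonistic factors."""
    clusters = []
    specs = [("#1", "F14", -1), ("#2", "F2", 1), ("#3", "F3", 1), ("#4", "F14", 1)]
    gi = 0
    for name, factor, sign in specs:
        genes = [f"GENE{gi + j + 1:03d}" for j in range(genes_per_cluster)]
        gi += genes_per_cluster
        clusters.append(ClusterSpec(name, genes, factor, loading, sign))
    targets = []
    for j in range(n_target_genes):
        sign = 1 if j % 2 == 0 else -1  # driven by cluster #4 or #1 side
        targets.append(TargetSpec(f"TGT{j + 1:03d}", "F14", target_loading, sign))
    return SyntheticSpec(
        n_samples=n_samples,
        gene_clusters=clusters,
        target_genes=targets,
        noise_sd=noise_sd,
        seed=seed,
        cohort_label="healthy",
    )


def tumor_spec(
    n_subgroup_a: int = 40,
    n_subgroup_b: int = 40,
    n_noise: int = 38,
    genes_per_cluster: int = 24,
    loading_range: tuple[float, float] = (0.55, 0.95),
    noise_sd: float = 0.45,
    seed: int = 0,
) -> SyntheticSpec:
    """A tumor-like cohort hiding two patient subgroups with distinct
    wiring plus a decorrelated remainder.

    Subgroup A carries the base four-cluster wiring, subgroup B the same
    clusters rewired to random factors, and the noise stratum no structure
    at all, so the mixed cohort shows few strong edges while each subgroup
    alone shows many.  Per-gene loadings are graded across
    ``loading_range`` so planted correlations span a band around the
    strong-edge cut instead of sitting at a single value.
    """
    clusters = []
    specs = [("#1", "F14", -1), ("#2", "F2", 1), ("#3", "F3", 1), ("#4", "F14", 1)]
    lo, hi = loading_range
    gi = 0
    for name, factor, sign in specs:
        genes = [f"GENE{gi + j + 1:03d}" for j in range(genes_per_cluster)]
        loadings = list(np.linspace(lo, hi, genes_per_cluster))
        gi += genes_per_cluster
        clusters.append(ClusterSpec(name, genes, factor, loadings, sign))
    n_genes = 4 * genes_per_cluster
    subgroups = [
        SubgroupSpec("A", n_subgroup_a),
        # 8 private factors: B's wiring shares only a few percent of its
        # strong pairs with A's (random-partition coincidence halved by the
        # random signs), so the two wirings superpose destructively
        SubgroupSpec("B", n_subgroup_b, rewire=True, rewire_factors=8),
        # one private factor per gene: fully decorrelated but with the same
        # per-gene marginal variance as the structured strata
        SubgroupSpec("NOISE", n_noise, rewire=True, rewire_factors=n_genes),
    ]
    return SyntheticSpec(
        n_samples=n_subgroup_a + n_subgroup_b + n_noise,
        gene_clusters=clusters,
        subgroups=subgroups,
        noise_sd=noise_sd,
        seed=seed,
        cohort_label="tumor",
    )


def noise_spec(
    n_samples: int = 113, n_genes: int = 100, seed: int = 0
) -> SyntheticSpec:
    """Pure i.i.d. noise: one cluster with loading 0 (no shared signal)."""
    genes = [f"GENE{j + 1:03d}" for j in range(n_genes)]
    return SyntheticSpec(
        n_samples=n_samples,
        gene_clusters=[ClusterSpec("null", genes, "F1", 0.0)],
        noise_sd=1.0,
        seed=seed,
        cohort_label="noise",
    )
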