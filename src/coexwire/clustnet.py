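"""Hierarchical clustering of correlation networks and cross-cohort
cluster preservation.

Genes are clustered on the signed correlation distance d = 1 - r, so a
perfectly anticorrelated pair sits at the maximal distance 2.  The signed
form (rather than 1 - |r|) keeps antagonistic gene groups — clusters whose
members correlate positively within and negatively between groups — as
separate clusters, which is exactly the structure of interest here.
Agglomeration uses complete (maximum) linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .corrnet import (
    CorrelationNetwork,
    StrongEdgeCriteria,
    pairwise_correlations,
    strong_edges,
)
from .data_io import ExpressionMatrix, GeneSet


def correlation_distance(net: CorrelationNetwork) -> pd.DataFrame:
    """Distance matrix d(a,b) = 1 - r(a,b) over the network's genes.

    Genes are put in lexicographic order so downstream clustering is
    invariant to the input gene order.  A missing edge is an error: only
    the complete sub-network can be clustered.
    """
    genes = sorted(net.genes)
    r = net.r.loc[genes, genes].to_numpy(copy=True)
    iu = np.triu_indices(len(genes), k=1)
    if np.isnan(r[iu]).any():
        ia = iu[0][np.isnan(r[iu])][:5]
        ib = iu[1][np.isnan(r[iu])][:5]
        pairs = [(genes[a], genes[b]) for a, b in zip(ia, ib)]
        raise ValueError(f"missing correlation edges, e.g. {pairs}; "
                         "cluster only the complete sub-network")
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    idx = pd.Index(genes, name="gene")
    return pd.DataFrame(d, index=idx, columns=idx)


@dataclass
class GeneClustering:
    """A flat cut of a complete-linkage dendrogram into k clusters."""

    labels: dict[str, int]  # gene -> 1..k
    k: int
    linkage_matrix: np.ndarray  # scipy (n-1) x 4 merge table
    genes: list[str]  # lexicographic order used for the linkage

    def members(self, label: int) -> list[str]:
        return [g for g in self.genes if self.labels[g] == label]

    @property
    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.genes[i] for i in order]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "cluster": [self.labels[g] for g in self.genes]}
        )

    def newick(self) -> str:
        """Dendrogram in Newick text form (branch lengths from merge heights)."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.genes[node.id]}:{length:g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:g}"

        return render(tree, tree.dist) + ";"


def complete_linkage_clusters(
    d: pd.DataFrame, k: int | None = None, height: float | None = None
) -> GeneClustering:
    """Complete-linkage agglomerative clustering of a dissimilarity matrix.

    Cut either to exactly ``k`` clusters (default) or at a merge ``height``.
    Cluster labels 1..k are assigned deterministically by first appearance
    in lexicographic gene order.
    """
    if k is None and height is None:
        raise ValueError("provide k or height")
    genes = sorted(d.index)
    if k is not None and (k < 1 or k > len(genes)):
        raise ValueError(f"k must be in 1..{len(genes)}")
    dm = d.loc[genes, genes].to_numpy()
    condensed = squareform(dm, checks=False)
    z = hierarchy.linkage(condensed, method="complete")
    if k is not None:
        raw = hierarchy.fcluster(z, t=k, criterion="maxclust")
    else:
        raw = hierarchy.fcluster(z, t=height, criterion="distance")
    # relabel deterministically: 1..k by first appearance in gene order
    mapping: dict[int, int] = {}
    labels: dict[str, int] = {}
    for g, lab in zip(genes, raw):
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
        labels[g] = mapping[lab]
    return GeneClustering(labels, len(mapping), z, genes)


@dataclass
class PreservationReport:
    """Within-cluster strong-edge retention of a reference clustering in a
    query cohort, plus the signed antagonism between a designated cluster
    pair."""

    per_cluster: pd.DataFrame  # cluster, n_genes, ref_strong, query_strong, retained
    antagonism_ref: float | None = None  # mean signed r between the named pair, ref
    antagonism_query: float | None = None
    antagonism_pair: tuple[int, int] | None = None


def cluster_preservation(
    ref: GeneClustering,
    ref_net: CorrelationNetwork,
    query_net: CorrelationNetwork,
    crit: StrongEdgeCriteria,
    antagonism_pair: tuple[int, int] | None = None,
) -> PreservationReport:
    """How much of each reference cluster's internal wiring survives in a
    query cohort.

    For every reference cluster, counts within-cluster strong edges in the
    reference and the query networks and reports the retained fraction
    (query/ref; NaN when the reference cluster has no strong edges).  If
    ``antagonism_pair`` names two cluster labels, the mean signed r between
    their genes is reported for both networks.
    """
    clustered = set(ref.genes)
    for name, net in (("reference", ref_net), ("query", query_net)):
        missing = clustered - set(net.genes)
        if missing:
            raise ValueError(f"{name} network lacks clustered genes: {sorted(missing)}")

    rows = []
    for lab in range(1, ref.k + 1):
        members = set(ref.members(lab))
        ref_cnt = _within_strong(ref_net, members, crit)
        qry_cnt = _within_strong(query_net, members, crit)
        retained = qry_cnt / ref_cnt if ref_cnt > 0 else np.nan
        rows.append(
            {
                "cluster": lab,
                "n_genes": len(members),
                "ref_strong": ref_cnt,
                "query_strong": qry_cnt,
                "retained": retained,
            }
        )
    report = PreservationReport(pd.DataFrame(rows))
    if antagonism_pair is not None:
        a, b = antagonism_pair
        ga, gb = ref.members(a), ref.members(b)
        report.antagonism_ref = float(ref_net.r.loc[ga, gb].to_numpy().mean())
        report.antagonism_query = float(query_net.r.loc[ga, gb].to_numpy().mean())
        report.antagonism_pair = antagonism_pair
    return report


def _within_strong(
    net: CorrelationNetwork, members: set[str], crit: StrongEdgeCriteria
) -> int:
    e = strong_edges(net, crit)
    return int((e["gene_a"].isin(members) & e["gene_b"].isin(members)).sum())


# ---------------------------------------------------------------------------
# Ligand -> target bipartite network
# ---------------------------------------------------------------------------

@dataclass
class BipartiteTargetNet:
    """Strong cross-side edges between a ligand gene set and a target set."""

    edges: pd.DataFrame  # ligand, target, r, p, n
    ligands: list[str]
    targets: list[str]
    shared_excluded: list[str] = field(default_factory=list)


def bipartite_target_network(
    m: ExpressionMatrix,
    samples: list[str] | None,
    ligands: GeneSet,
    targets: GeneSet,
    crit: StrongEdgeCriteria,
    method: str = "pearson",
    min_pair_n: int = 10,
) -> BipartiteTargetNet:
    """Bipartite network of strong ligand-target correlations.

    Symbols appearing on both sides (pathway components that are themselves
    targets) are excluded from the target side, with the exclusion
    reported.  Only cross-side edges passing the strong-edge criteria are
    kept.
    """
    lig = [g for g in ligands.genes if g in m.values.index]
    shared = [g for g in targets.genes if g in set(ligands.genes)]
    tgt = [g for g in targets.genes if g not in set(ligands.genes) and g in m.values.index]
    if shared:
        warnings.warn(
            f"excluding {len(shared)} symbol(s) present on both sides from the "
            f"target side: {shared}",
            stacklevel=2,
        )
    if not lig or not tgt:
        raise ValueError("a bipartite side is empty after exclusions")

    sub = ExpressionMatrix(
        m.values.loc[lig + tgt].copy(), dict(m.cohort_of), m.scale_note, m.log_base
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        net = pairwise_correlations(sub, samples, method, min_pair_n)
    e = strong_edges(net, crit)
    lig_set, tgt_set = set(lig) & set(net.genes), set(tgt) & set(net.genes)
    cross = e[
        (e["gene_a"].isin(lig_set) & e["gene_b"].isin(tgt_set))
        | (e["gene_a"].isin(tgt_set) & e["gene_b"].isin(lig_set))
    ].copy()
    swap = cross["gene_a"].isin(tgt_set)
    cross.loc[swap, ["gene_a", "gene_b"]] = cross.loc[swap, ["gene_b", "gene_a"]].values
    cross = cross.rename(columns={"gene_a": "ligand", "gene_b": "target"})
    cross = cross.sort_values(["ligand", "target"]).reset_index(drop=True)
    return BipartiteTargetNet(cross, sorted(lig_set), sorted(tgt_set), shared)


def annotate_targets_by_cluster(
    bnet: BipartiteTargetNet, clustering: GeneClustering
) -> pd.DataFrame:
    """Per target gene: strong-edge counts to each ligand cluster and the
    dominant cluster (the one providing most of its edges)."""
    e = bnet.edges.copy()
    e["ligand_cluster"] = e["ligand"].map(clustering.labels)
    counts = (
        e.groupby(["target", "ligand_cluster"]).size().unstack(fill_value=0)
    )
    counts.columns = [f"cluster_{c}" for c in counts.columns]
    counts["dominant_cluster"] = (
        e.groupby("target")["ligand_cluster"]
        .agg(lambda s: s.value_counts().sort_index().idxmax())
    )
    return counts.reset_index()


def heatmap_matrix(net: CorrelationNetwork, clustering: GeneClustering) -> pd.DataFrame:
    """r matrix with genes in dendrogram leaf order (heatmap-ready)."""
    order = clustering.leaf_order
    return net.r.loc[order, order]
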