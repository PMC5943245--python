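"""Cluster the healthy correlation network and measure what survives in
the cancer-like cohort.

Complete-linkage clustering on d = 1 - r at k = 4, per-cluster strong-edge
retention in the decorrelated cohort, and the antagonism between the
opposed cluster pair.  Writes cluster labels, the dendrogram (Newick), a
heatmap-ready r matrix, and the preservation report under
results/clustering/.
"""

import warnings
from pathlib import Path

from coexwire import clustnet, corrnet, data_io

warnings.simplefilter("ignore")
ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "clustering"
OUT.mkdir(parents=True, exist_ok=True)
CRIT = corrnet.StrongEdgeCriteria()

healthy = data_io.read_expression_table(ROOT / "cohorts" / "healthy.tsv")
pathway = data_io.GeneSet(
    "pathway", [g for g in healthy.gene_ids if g.startswith("GENE")]
)
cancer = data_io.read_expression_table(ROOT / "cohorts" / "cancer.tsv")

ref_net = corrnet.pairwise_correlations(data_io.subset_genes(healthy, pathway))
qry_net = corrnet.pairwise_correlations(data_io.subset_genes(cancer, pathway))

d = clustnet.correlation_distance(ref_net)
clustering = clustnet.complete_linkage_clusters(d, k=4)
clustering.to_frame().to_csv(OUT / "healthy_clusters.tsv", sep="\t", index=False)
(OUT / "healthy_dendrogram.nwk").write_text(clustering.newick() + "\n")
clustnet.heatmap_matrix(ref_net, clustering).to_csv(
    OUT / "healthy_r_leaf_order.tsv", sep="\t", float_format="%.4f"
)

# the planted antagonistic pair ends up as two clusters; report the pair
# with the most negative mean inter-cluster r
pairs = [(a, b) for a in range(1, 5) for b in range(a + 1, 5)]
antag = min(
    pairs,
    key=lambda p: ref_net.r.loc[clustering.members(p[0]),
                                clustering.members(p[1])].to_numpy().mean(),
)
rep = clustnet.cluster_preservation(clustering, ref_net, qry_net, CRIT,
                                    antagonism_pair=antag)
rep.per_cluster.to_csv(OUT / "preservation.tsv", sep="\t", index=False)

print(rep.per_cluster.to_string(index=False))
print(f"antagonistic pair {antag}: mean r = {rep.antagonism_ref:.2f} (healthy), "
      f"{rep.antagonism_query:.2f} (cancer-like)")
kept = rep.per_cluster[rep.per_cluster["retained"] > 0.5]["cluster"].tolist()
print(f"clusters retaining >50% of their wiring in the cancer-like cohort: {kept}")
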