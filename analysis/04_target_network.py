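"""Ligand -> target bipartite network in the healthy cohort.

Strong cross-correlations between the pathway components and the target
genes, with each target annotated by the ligand cluster that drives it.
Writes the edge list and per-target annotation under results/targets/.
"""

import warnings
from pathlib import Path

from coexwire import clustnet, corrnet, data_io

warnings.simplefilter("ignore")
ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "targets"
OUT.mkdir(parents=True, exist_ok=True)
CRIT = corrnet.StrongEdgeCriteria()

healthy = data_io.read_expression_table(ROOT / "cohorts" / "healthy.tsv")
ligands = data_io.GeneSet(
    "components", [g for g in healthy.gene_ids if g.startswith("GENE")]
)
targets = data_io.GeneSet(
    "targets", [g for g in healthy.gene_ids if g.startswith("TGT")]
)

bnet = clustnet.bipartite_target_network(healthy, None, ligands, targets, CRIT)
bnet.edges.to_csv(OUT / "ligand_target_edges.tsv", sep="\t", index=False)

ref_net = corrnet.pairwise_correlations(data_io.subset_genes(healthy, ligands))
clustering = clustnet.complete_linkage_clusters(
    clustnet.correlation_distance(ref_net), k=4
)
annotation = clustnet.annotate_targets_by_cluster(bnet, clustering)
annotation.to_csv(OUT / "target_annotation.tsv", sep="\t", index=False)

print(f"{len(bnet.edges)} strong ligand-target edges "
      f"({len(set(bnet.edges['target']))} of {len(targets)} targets connected)")
print("targets per dominant ligand cluster:")
print(annotation["dominant_cluster"].value_counts().to_string())
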