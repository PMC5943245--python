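"""Generate the synthetic study cohorts used by the downstream analyses.

Three cohorts at the scale of a public breast-tissue study:
  * healthy  — 113 samples, four coherent co-expression clusters of Wnt-like
    pathway genes (one antagonistic cluster pair) plus 20 target genes;
  * cancer   — the same cohort decorrelated except for cluster #2
    (cancer-like loss of co-expression coherence);
  * tumor    — 118 samples hiding two 40-patient subgroups with distinct
    wiring plus 38 decorrelated patients.

Writes expression tables and ground-truth labels under results/cohorts/.
"""

import warnings
from pathlib import Path

import pandas as pd

from coexwire import data_io, synthetic

warnings.simplefilter("ignore")
OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

healthy_spec = synthetic.healthy_spec(noise_sd=0.5, n_target_genes=20, seed=SEED)
healthy, truth = synthetic.generate_cohort(healthy_spec)
data_io.write_expression_table(healthy, OUT / "healthy.tsv")
pd.DataFrame(
    {"gene": list(truth.cluster_of), "cluster": list(truth.cluster_of.values())}
).to_csv(OUT / "healthy_gene_clusters.tsv", sep="\t", index=False)

cancer = synthetic.cancerize(healthy, truth, {"#2"}, rewire_seed=SEED + 1)
data_io.write_expression_table(cancer, OUT / "cancer.tsv")

tumor_spec = synthetic.tumor_spec(seed=SEED + 2)
tumor, tumor_truth = synthetic.generate_cohort(tumor_spec)
data_io.write_expression_table(tumor, OUT / "tumor.tsv")
pd.DataFrame(
    {
        "sample_id": tumor.sample_ids,
        "subgroup": [tumor_truth.subgroup_of[s] for s in tumor.sample_ids],
    }
).to_csv(OUT / "tumor_subgroups.tsv", sep="\t", index=False)

print(f"healthy: {healthy.shape[0]} genes x {healthy.shape[1]} samples")
print(f"cancer:  decorrelated copy retaining cluster #2")
print(f"tumor:   {tumor.shape[1]} samples "
      f"(40 subgroup A + 40 subgroup B + 38 decorrelated)")
print(f"written to {OUT}")
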