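"""Quantify the loss of co-expression coherence between cohorts.

For the healthy and cancer-like cohorts: all pairwise correlations of the
pathway genes, the strong-edge count (|r| >= 0.5, p <= 0.001), the null
distribution over random gene sets, a KS comparison of the r
distributions, and size-matched subsampling of the larger cohort.

Writes edge tables (TSV + SIF) and summary numbers under results/networks/.
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from coexwire import corrnet, data_io

warnings.simplefilter("ignore")
ROOT = Path(__file__).resolve().parent.parent / "results"
OUT = ROOT / "networks"
OUT.mkdir(parents=True, exist_ok=True)
CRIT = corrnet.StrongEdgeCriteria()
SEED = 1

pathway = [g for g in data_io.read_expression_table(ROOT / "cohorts" / "healthy.tsv").gene_ids
           if g.startswith("GENE")]

rows = []
nets = {}
for name in ("healthy", "cancer"):
    m = data_io.read_expression_table(ROOT / "cohorts" / f"{name}.tsv")
    sub = data_io.subset_genes(m, data_io.GeneSet("pathway", pathway))
    net = corrnet.pairwise_correlations(sub)
    nets[name] = net
    n_strong = corrnet.count_strong(net, CRIT)
    corrnet.write_edge_table(net, CRIT, OUT / f"{name}_edges.tsv")
    corrnet.write_sif(net, CRIT, OUT / f"{name}_strong.sif")
    # null: same-size random gene sets drawn from the target-gene background
    null_hist, null_counts = corrnet.random_geneset_null(
        m, None, set_size=20, n_sets=100, crit=CRIT, seed=SEED, exclude=pathway
    )
    rows.append(
        {
            "cohort": name,
            "n_samples": len(net.sample_ids),
            "n_pairs": net.n_pairs,
            "strong_edges": n_strong,
            "strong_fraction": n_strong / net.n_pairs,
            "null_mean_strong_20genes": float(null_counts.mean()),
        }
    )
    print(f"{name}: {n_strong} strong edges of {net.n_pairs} pairs "
          f"({100 * n_strong / net.n_pairs:.1f}%)")

d_stat, p_val = corrnet.ks_compare(
    nets["healthy"].r_values(), nets["cancer"].r_values()
)
print(f"KS healthy vs cancer r-distributions: D = {d_stat:.3f}, p = {p_val:.3g}")

# size-matched subsampling of the healthy cohort to 60 samples
m = data_io.read_expression_table(ROOT / "cohorts" / "healthy.tsv")
sub = data_io.subset_genes(m, data_io.GeneSet("pathway", pathway))
summary = corrnet.subsample_strong_counts(
    sub, sub.sample_ids, subsample_size=60, n_subsamples=500, crit=CRIT, seed=SEED
)
print(f"healthy subsampled to 60: {summary.mean_strong:.0f} +/- "
      f"{summary.sd_strong:.0f} strong edges (mean +/- SD, 500 subsamples)")

pd.DataFrame(rows).to_csv(OUT / "strong_edge_summary.tsv", sep="\t", index=False)
pd.DataFrame(
    {"ks_D": [d_stat], "ks_p": [p_val],
     "subsample60_mean": [summary.mean_strong],
     "subsample60_sd": [summary.sd_strong]}
).to_csv(OUT / "comparison_summary.tsv", sep="\t", index=False)
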