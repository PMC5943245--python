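# coexwire

Differential co-expression network analysis of signaling-pathway genes
across patient cohorts.

## The problem

In healthy tissue, genes that operate in one signaling pathway (here the
Wnt pathway: ligands, FZD receptors, transducers, G-protein subunits) tend
to be produced in a coordinated way — their expression levels correlate
strongly across individuals.  In breast tumors this coordination largely
collapses, even when the individual genes' expression levels barely
change.  That observation suggests analyzing the *correlation network*
rather than per-gene expression: which gene pairs stay wired together,
which clusters of components survive, whether a tumor cohort hides
subgroups of patients with distinct internal wiring, and whether the
correlations could be an artifact of tissue composition rather than real
co-regulation.

`coexwire` implements that analysis end to end, for anyone who has a
gene × sample log-expression matrix and cohort labels:

* **corrnet** — all C(G,2) pairwise correlations with significance; the
  *strong edge* filter |r| ≥ 0.5 and p ≤ 0.001; random-gene-set null
  distributions; Kolmogorov–Smirnov comparison of r distributions;
  size-matched cohort subsampling.
* **clustnet** — complete-linkage clustering of genes on the signed
  correlation distance d = 1 − r; cross-cohort cluster preservation;
  ligand → target bipartite networks.
* **stratify** — the greedy block search for maximally-correlated patient
  subgroups: patients are shuffled into blocks of 5, all 5-block
  combinations are scored by strong-edge count, the most frequent blocks
  among the top 100 combinations seed a group that is then pruned and
  extended two patients at a time; acceptance of each subgroup is
  calibrated against the same search run on permuted data.
* **delta_r** — per-pair correlation differences between two datasets and
  a per-gene ranking by the number of strongly changed (|Δr| > 0.5) pairs.
* **hetsim** — a two-cell-type stochastic mixture model quantifying how
  many strong correlations sample heterogeneity alone can fabricate.
* **cohort_stats** — per-gene medians, fold changes, Kruskal–Wallis with
  Dunn's multiple comparisons, and chi-squared clinical associations.
* **synthetic** — a latent-factor Gaussian generator that plants
  co-expression clusters (including an antagonistic pair), cancer-like
  decorrelation, patient subgroups with distinct wiring, and ligand-driven
  target genes, so every stage is testable at desk scale with closed-form
  expectations.

## The statistics at the core

For genes g, h over n samples, the edge statistic is the Pearson (or
Spearman) correlation r with the two-sided p-value from
t = r √((n−2)/(1−r²)).  An edge is **strong** when |r| ≥ 0.5 and
p ≤ 0.001.  Since p is monotone in |r| at fixed n, the joint filter equals
a single cut |r| ≥ max(0.5, r_crit(n)); the stratification search exploits
this for fast scoring while remaining exactly equivalent to the full
filter.

The synthetic generator writes x_gi = baseline_g + s_g·l_g·f_{w(g),i} +
ε_gi with factors f ~ N(0,1) and noise ε ~ N(0, σ²), giving the
closed-form pair correlation r = l_g l_h / √((l_g²+σ²)(l_h²+σ²)) used as
an oracle throughout the tests.

## Worked example

Running the numbered analyses over the bundled synthetic study
(`python analysis/01_generate_cohorts.py` … `08_heterogeneity_model.py`)
prints, among other things:

```
healthy: 1680 strong edges of 4560 pairs (36.8%)
cancer:  276 strong edges of 4560 pairs (6.1%)
clusters retaining >50% of their wiring in the cancer-like cohort: [2]
antagonistic pair (1, 4): mean r = -0.64 (healthy), -0.00 (cancer-like)

mixed cohort (118 patients): 66 strong edges
subgroup 1: 35 patients, 1669 strong edges (25.3x the mixed cohort)
subgroup 2: 37 patients, 585 strong edges (8.9x the mixed cohort)
residual: 46 patients, 6 strong edges
decorrelated patients in residual: 38/38

mean-composition sweep (fixed spread): fold range 1.17
spread sweep: strong counts 356 -> 4 as the composition spread narrows
```

Read: the healthy cohort is densely wired (36.8% of all pairs strong);
decorrelation collapses the network except the one retained cluster; the
tumor cohort looks weakly wired (66 edges) only because two subgroups with
opposite wiring are superposed — the greedy search separates them, each
an order of magnitude more coherent than the mixture, and correctly
leaves the genuinely decorrelated patients unassigned.  The mixture model
shows that realistic levels of tissue heterogeneity cannot fabricate such
edges (only implausible near-bimodal cohorts can), so strong correlations
reflect real co-regulation.

A thin CLI covers the main stages:

```bash
coexwire correlate --matrix cohort.tsv --genes wnt.txt --rmin 0.5 --pmax 0.001 --out edges.tsv
coexwire cluster   --matrix cohort.tsv --k 4 --out clusters.tsv --newick tree.nwk
coexwire stratify  --matrix cohort.tsv --block-size 5 --top-n 100 --seed 7 --out strata/
coexwire hetsim    --panel panel.tsv --axis spread --grid 0.1,0.5,2,10 --out sweep.tsv
coexwire synth     --spec spec.yaml --out cohort.tsv --truth truth.tsv
```

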