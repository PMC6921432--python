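# sialonet

Pathway-driven stratification and key driver analysis for salivary-gland
transcriptomes.

Minor salivary gland biopsies from patients with Sjögren's syndrome show
heterogeneous molecular profiles: merged case/control microarray cohorts
must be normalized and batch-corrected, differentially expressed genes
(DEGs) identified with small per-group sample sizes, their protein-protein
interaction structure summarized (hubs, largest connected component),
pathway activity scored per patient, patients stratified into molecular
subgroups on those pathway profiles, and upstream regulators of the
disease module pinpointed on a directed gene network. `sialonet`
implements this workflow end to end as a tested, reusable library + CLI,
together with a synthetic-data generator that plants every piece of
structure the analysis is supposed to find — so the whole pipeline is
verifiable against ground truth without any external download.

## The statistics at the core

* **Moderated t** (two-group limma-style empirical Bayes): per gene g the
  pooled residual variance s_g² (df d_g) is shrunk toward a prior s₀²
  with prior df d₀ estimated by method of moments on log s_g²;
  s̃_g² = (d₀s₀² + d_g s_g²)/(d₀ + d_g) and
  t̃_g = (x̄₁ − x̄₀)/√(s̃_g²(1/n₁ + 1/n₀)) with d₀ + d_g df.
  P-values are Benjamini–Hochberg adjusted; DEGs pass adjusted p < 0.01.
* **ComBat batch correction**: parametric empirical-Bayes location–scale
  adjustment of per-batch per-gene effects, with the case/control factor
  protected in the standardization design (verified numerically identical
  to `sva::ComBat`).
* **Hub molecules**: genes in the shared top 10 % of degree, harmonic
  closeness, and Brandes betweenness ranks of the DEG-induced interactome
  subgraph.
* **GSEA / ssGSEA**: the weighted Kolmogorov–Smirnov-like running sum
  ES = max deviation of P_hit − P_miss over a ranked list (gene-set
  permutation p, leading-edge genes); per-sample scores are the summed
  difference between the weighted in-set and uniform out-of-set empirical
  CDFs of that sample's expression ranking.
* **Subgrouping**: agglomerative clustering (Euclidean, average linkage)
  of patients on z-scored pathway scores; the cluster number over
  k = 2…5 is chosen by the gap statistic, Gap(k) = E*[log W_k] − log W_k
  with uniform PCA-aligned reference sets, cross-checked by silhouette;
  a Gaussian naive Bayes classifier over the pathway panel (10-fold CV)
  assigns subgroups to new samples.
* **Key driver analysis (KDA)**: on a directed acyclic gene network, for
  every candidate g near the target set G the h-layer downstream
  neighborhood HLN(g,h) is tested for enrichment in G by one-sided
  Fisher's exact test for h = 1…H; ES_h* = max_h(−log₁₀ p) with
  Bonferroni-corrected p < 0.01. Parent-free candidates (roots) are
  *global* drivers, the rest *local*.

## Worked example

Run the full pipeline on the default synthetic study (17,479 genes,
30 case / 23 control samples across 4 batches, 26 pathways):

```bash
sialonet run --outdir out --seed 1
```

```
INFO sialonet.pipeline: 363 up / 208 down DEGs at adjusted p < 0.01
done: 363 up-DEGs, LCC 12, 10 hubs, k = 2, CV accuracy 1.000, 4 key drivers
```

What the numbers mean: the moderated-t stage recovers the planted
upregulated genes (plus pathway-shifted subgroup genes) at adjusted
p < 0.01; projecting them onto the interactome yields a largest connected
component of 12 genes containing the planted 10-gene dense module, whose
members are exactly the 10 hub molecules; the gap statistic picks k = 2
subgroups from the ssGSEA pathway profiles (matching the planted case
subgroups, adjusted Rand index 1.0), which the naive Bayes classifier
reproduces at CV accuracy 1.0; and KDA flags 4 key drivers — the 3
planted roots as *global* drivers and the module's internal head node as
a *local* driver:

```
  gene  h_star        es  p_bonferroni  scope  overlap  neighborhood_size
G02517       2 16.328959  4.219715e-15 global       10                 10
G10202       2 16.328959  4.219715e-15 global       10                 10
G12654       2 16.328959  4.219715e-15 global       10                 10
G13909       1  7.292723  4.586898e-06  local        5                  5
```

Every intermediate artifact (normalized matrix, DEG table, centralities,
ssGSEA scores, cluster labels, classifier model, KDA candidates) is
written to `out/` alongside `run_manifest.json` with parameters and
SHA-256 checksums; reruns with the same seed are byte-identical.

Each stage is also available standalone (`sialonet synth | preprocess |
dge | netcore | enrich | cluster | classify | kda`) on user-supplied
TSV/GMT files — see `sialonet <verb> --help`.

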