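# Methods

This note documents the models and procedures `sialonet` implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Scope and data model

The pipeline starts from gene-level log2 expression matrices (genes ×
samples) with a sample annotation (batch = source dataset, group =
case/control, optional grade/response/timepoint). Probe-level processing
(RMA of CEL files) is upstream of this package and out of scope, as are
calls to hosted enrichment services, xCell's trained signatures and
spillover model (cell-type scoring is handled as ssGSEA over user-supplied
signature GMTs), and learning the directed network's structure from
expression data (the directed network is an input).

## Normalization and batch correction

`quantile_normalize` equalizes sample distributions by rank-wise
substitution of the mean sorted profile; tied values within a column share
the mean reference value over their rank span. With tie-free input the
transform is exactly idempotent and all column distributions are
identical; with ties both properties hold only approximately (the tie rule
trades them for monotonicity and determinism).

`combat_adjust` implements parametric empirical-Bayes location–scale batch
adjustment: per-gene standardization against a design of full batch
indicators plus the protected group factor; per-batch location γ̂ and scale
δ̂² estimates; a normal prior on γ and an inverse-gamma prior on δ²
(moments matched across genes); joint iterative posterior solution per
batch (convergence 1e-4, as in the reference implementation — our output
matches `sva::ComBat` to ~1e-13 on shared inputs). The group factor is
protected inside the standardization so case/control signal is not
absorbed; whether the original analysis did the same is not documented,
and we treat protection as the safer default. `mode="mean-only"` removes
the **raw** per-batch locations (no EB shrinkage, δ²* ≡ 1): shrunk
locations necessarily leave a residual batch mean, and the mean-only
contract here is exact per-gene batch-mean equalization. Degenerate
(near-constant) genes have variances floored at 1e-8 with a logged
warning.

Note a practical caveat the tests make visible: moderated-t inference on
ComBat-cleaned data is mildly anti-conservative when batch effects are
strong (the correction spends degrees of freedom the downstream model
does not know about). The DEG-recovery simulations therefore evaluate the
differential-expression stage on its own two-group sampling model; the
end-to-end run reports recall against the planted truth.

## Differential expression

Two-group linear model per gene (the only contrast the workflow uses):
logFC = mean(case) − mean(control), pooled residual variance s_g², df
d_g = n − 2. The variance prior (d₀, s₀²) is estimated by the method of
moments on e_g = log s_g² − ψ(d_g/2) + log(d_g/2): the excess of
Var(e_g) over trigamma(d_g/2) identifies trigamma(d₀/2), solved by Newton
iteration; non-positive excess dispersion gives d₀ = ∞ (complete
pooling). Moderated t uses the posterior variance and d₀ + d_g degrees of
freedom (a huge-df t stands in for the normal when d₀ = ∞). This matches
R `limma` (lmFit/eBayes) to ~1e-14 on shared inputs, which the test suite
asserts via `Rscript`. BH adjustment delegates to statsmodels. DEG
selection: adjusted p < α (default 0.01) split by sign of logFC, sorted by
adjusted p then gene id.

## Network core

The DEG list is projected onto the undirected interactome as an induced
subgraph; genes with no induced edge (including genes absent from the
interactome) are reported as isolated. Centralities: degree, harmonic
closeness (sum of reciprocal distances — well defined on the disconnected
induced graphs this stage actually sees), and unnormalized Brandes
betweenness. Hubs are the intersection of the top-⌈fraction·n⌉ positions
of the three average-rank tables (default fraction 0.10); a tie straddling
the cutoff admits all tied nodes. `select_hubs` operates on whatever
graph's centrality table it is given; the *pipeline* feeds it the
interacting genes only, because on the full induced subgraph the giant
zero-centrality tie group would degenerately admit every isolated gene.
The largest connected component (ties broken by smallest member id) is the
target set for KDA downstream.

## Enrichment

* ORA: one-sided Fisher's exact (hypergeometric tail) of query × set
  overlap against the expression universe; Haldane 0.5 odds-ratio
  correction when a cell is zero; BH across sets.
* GSEA: weighted running sum with hit increments |r|^p / N_R (default
  exponent p = 1; p = 0 reduces to the rank KS statistic) and uniform miss
  increments; ES is the signed extreme deviation, the leading edge the set
  members at/before the peak (positive ES) or at/after it (negative ES).
  Significance by **gene-set permutation** (random same-size sets,
  p = (1 + #{|ES*| ≥ |ES|})/(B + 1)): phenotype permutation is not
  meaningful at the small per-subgroup sample sizes this workflow targets.
* ssGSEA: per sample, genes ranked by decreasing expression (average
  ranks, ties then ordered by gene id); score = Σᵢ [P_W(i) − P_NW(i)]
  where P_W weights set members by (rank value)^α (default α = 0.25,
  α = 0 → rank-only) and P_NW is the uniform ECDF of non-members. Scores
  are raw sums by default; min–max normalization is an option, not the
  default, since the variant used originally is not documented.
* Enrichment map: gene-set graph with edges where Jaccard > 0.25,
  strictly — exactly 0.25 does not connect.

## Subgrouping and classification

Case samples are clustered on pathway × sample ssGSEA scores, transposed
and z-scored per pathway (so no pathway dominates by scale; the original
scaling is undocumented). Agglomerative clustering with Euclidean
distance and average (UPGMA) linkage — Ward is available by flag since the
source description names both. Cluster number: gap statistic over
k = 2…5, W_k = Σ_r D_r/(2n_r) on squared distances, B uniform reference
draws in the PCA-aligned bounding box (Tibshirani's variant b),
s_k = sd·√(1 + 1/B), chosen k = smallest with Gap(k) ≥ Gap(k+1) − s_{k+1}
(last k if never); mean silhouette per k is reported alongside. t-SNE
(scikit-learn, perplexity adapted to small n) is provided for visual
confirmation only.

The subgroup classifier is Gaussian naive Bayes over the pathway panel:
class priors from training frequencies, per-class per-feature means and
variances, variances floored at 1e-9 × the feature's global variance
(avoids degenerate likelihood spikes from within-class constant
features). Validated by stratified 10-fold cross-validation
(deterministic under seed; falls back to plain folds with a warning when
a class has fewer members than folds). Matches scikit-learn's GaussianNB
posteriors on shared inputs (asserted in tests).

## Key driver analysis

Candidates are all nodes within H layers (both edge orientations) of the
target set G. For each candidate g and h = 1…H, the downstream h-layer
neighborhood (BFS over child edges, g excluded) is tested for enrichment
in G \ {g} against a background of all network nodes except g, by
one-sided Fisher's exact test; ES_{h,g} = −log₁₀ p and ES_h* = max over
h, keeping the smallest h on ties. The enrichment statistic's functional
form is our choice (the maximum-ES and Fisher-significance structure is
fixed; −log₁₀ p makes maximizing ES coincide with minimizing p).
Bonferroni correction uses m = number of tested candidates; key drivers
have corrected p < α (default 0.01). Roots (no parents) are global
drivers, others local. Defaults: H = 3 (configurable 1–6), downstream
neighborhoods (an undirected mode exists since "layers away" is
directionally ambiguous in the source description).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
at the merged-study design scale: 30 case / 23 control samples, 17,479
genes, 4 source batches, 26 pathways (all defaults; every piece is
configurable). One global seed fans out to independent per-component RNG
streams, so regenerating one artifact never shifts another's draw.

* Expression: per-gene baseline ~ N(7, 1) on log2 scale; additive
  per-(gene, batch) shifts ~ N(0, batch_shift_sd); planted DE genes carry
  sign·de_effect in cases (half up, half down); the two case subgroups
  carry +cluster_shift on the member genes of their (disjoint) active
  pathway sets; i.i.d. N(0, noise_sd) noise. Defaults de_effect = 1.5,
  cluster_shift = 1.0, noise_sd = 0.5, batch_shift_sd = 0.5 — effect
  magnitudes are not documented for any real contrast, so these are
  chosen once as plausible microarray log2 scales that leave recovery
  non-trivial (signal ≈ 2–4 × the per-gene sampling noise at the default
  n), and are not tuned thereafter.
* Gene sets: 26 pathways with sizes uniform in (15, 40), sampled without
  replacement within a set; 2 × 6 disjoint active pathways define the two
  subgroups.
* Interactome: preferential-attachment backbone (m = 2 edges per new
  node; m = 1 gives a tree) over the whole gene universe, plus a planted
  10-gene clique over upregulated DE genes — the dense disease module.
* Directed network: a 200-node DAG. All module-internal edges follow one
  global module order (a heap-like branching with `driver_fanout`
  children per node), so each planted driver root wired to the first
  `driver_fanout` module genes covers the whole module within 3 layers
  and acyclicity holds by construction. Filler nodes get 0–2 forward
  edges among themselves and, with probability 0.08, a single edge onto a
  *leaf* module member — enough to be tested as candidates without
  accumulating target overlap through cascades. Module members reached
  early in the order legitimately regulate the rest of the module, so
  they can (correctly) surface as local drivers; driver-recovery metrics
  therefore count false positives among tested nodes that are neither
  planted drivers nor module members.

What the generator does **not** emulate: RNA-seq count distributions,
probe-level artifacts, correlated gene-gene noise, realistic interactome
topology beyond scale-freeness, dropout/missingness, or time-course
kinetics. Passing tests demonstrate the pipeline recovers structure under
its own idealized sampling assumptions; they do not certify performance
on real cohort data.

## Numerical choices and degenerate inputs

Variance floors: 1e-8 (ComBat pooled variance), 1e-12 (moderated-t
posterior variance), 1e-9 × global feature variance (naive Bayes).
P-values are floored at 1e-300 before −log₁₀. Hierarchical merges and
hub/driver orderings break ties deterministically (smallest index /
lexicographic gene id). Quantile normalization requires ≥ 2 samples; PCA
QC ≥ 3 samples and a non-constant matrix; silhouette ≥ 2 clusters; gap
statistic ≥ 10 reference draws; GSEA permutation ≥ 100 permutations;
single-batch input passes through ComBat unchanged with a warning.

## Problem sizes used in tests

Unit and acceptance tests run the generator at reduced scale (typically
400–2,000 genes, 8–16 samples per group, 6–14 pathways) and the
end-to-end determinism check at 1,000 genes — the same planted structure
at sizes where the full suite stays fast; the acceptance script runs the
complete pipeline once at the default 17,479-gene scale. Recovery
simulations use 20–50 independent seeds.

## Known limitations

* The two-group moderated t omits limma's array weights, variance trend,
  and multi-factor designs — only the case/control contrast is needed.
* ComBat is parametric-EB only (no nonparametric variant, no missing
  values, no cross-platform probe mapping).
* KDA treats the directed network as given; conditional probabilities on
  edges are never estimated.
* ssGSEA scores are raw sums; comparing absolute score magnitudes across
  collections of very different set sizes requires the optional
  normalization.
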