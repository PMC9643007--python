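# Methods

This note documents the statistical model behind `netpert`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Interaction-perturbation representation

Expression is reduced to within-sample ranks over the genes shared between
the measured matrix and the background network (restricting to network
genes makes the features independent of off-network probes; ranking over
all measured genes is available via `restrict_to_network=False`). Ranks are
ascending (1 = lowest) with average ties. For a canonical edge (a, b),
a < b lexicographically, the delta rank is `rank(a) − rank(b)`; the
canonical orientation is fixed so results do not depend on how the edge
list was written.

The benchmark is the normal-tissue reference against which perturbation is
measured. Two conventions are implemented:

* `mean_expression` (default): rank the per-gene mean expression over
  normal samples as one pseudo-sample and take its delta ranks;
* `mean_delta_rank`: average the normals' per-sample delta-rank columns.

The two agree whenever the normals are homogeneous. They differ in one
important property: only the rank-space average is *exactly* invariant
under arbitrary strictly increasing per-sample transforms of the input
(the mean of transformed profiles can re-order even though each sample's
ranks are unchanged). The delta-rank matrix itself is always bit-invariant
under such transforms; the invariance test of the perturbation matrix is
therefore run in `mean_delta_rank` mode. With either convention the
perturbation of sample *s* on edge (a, b) is the sample's delta rank minus
the benchmark value, bounded by ±2(G−1) for G ranked genes.

Normal samples enter the benchmark and the matrix; with identical normal
profiles their perturbation columns are exactly zero.

### Dispersion comparison

Tumor-vs-normal dispersion per edge supports `cv` (sd/|mean|, the
conventional wording) and `sd`. Because perturbations are centred near
zero *by construction* — normals define the benchmark — the CV denominator
for normal groups is frequently in the guard regime (|mean| < 1e-8 is
replaced by 1e-8 and logged), which makes normal CVs explode and the CV
fraction uninformative on well-centred synthetic data. The `sd` measure is
the meaningful one in that regime and is what the acceptance script
reports alongside the CV value. A paired Wilcoxon signed-rank across edges
summarises the comparison.

## Edge selection

An edge is representative when it (i) separates tumor from normal
perturbation values and (ii) stays variable within tumors. Because each
latent subtype perturbs its own edge set, a truly perturbed edge shows a
*mixture* alternative in the pooled tumor group: most tumors sit at the
benchmark and one subtype sits far away. A pure rank-sum test has a hard
power ceiling against such mixtures (with K balanced subtypes,
P(tumor > normal) ≤ 1/2 + 1/(2K) no matter how large the displacement), so
the default test combines a location component (two-sided Wilcoxon
rank-sum) with a scale component (Brown–Forsythe) through a Bonferroni
combination `p = min(1, 2·min(p_loc, p_scale))`; `wilcoxon` and `levene`
are selectable alone. P-values are BH-adjusted across edges (default
q ≤ 0.05).

Variability is the tumor-group sd (ddof = 1; scaled MAD also reported).
The cutoff is the `variability_quantile` (default 0.5) of the
*significant-edge* sd distribution, following the two-criterion rule;
because that reference set changes with the q threshold, selection is
monotone in the quantile at fixed q but not jointly — an absolute
`variability_cutoff` override restores joint monotonicity when needed.
The reduced network is re-checked for a scale-free degree distribution
(least-squares fit of log10 frequency vs log10 degree; Pearson r is the
diagnostic, with zero-count degrees omitted).

## Consensus subtyping

For each K in a sweep (default 2–8), `n_reps` subsampled runs
(default fraction 0.8 without replacement) of a base clusterer are
accumulated into a consensus matrix: entry (i, j) = times co-clustered /
times co-sampled. The base method is k-means with a **single** k-means++
start per rep (`n_init=1`). This is deliberate: consensus clustering
measures the *stability of the data partition under resampling and
initialisation*; with multi-restart k-means every rep converges to the
same optimum and even wrong K values produce binary consensus matrices,
collapsing PAC's ability to discriminate. Average-linkage and a plain
k-medoids base are also available.

PAC = CDF(u₂) − CDF(u₁) (default window 0.1–0.9) over the off-diagonal
upper-triangle consensus entries; the selected K minimises PAC with ties
broken toward the smaller K. Final labels are a deterministic
average-linkage hierarchical cut of 1 − consensus, so the labelling is a
function of the consensus matrix alone. Silhouette widths on the
1 − consensus distance define the core set (s(i) > 0 by default); members
of singleton clusters get s(i) = 0 by convention.

Runs are bit-reproducible given a seed; the per-K seeds in a sweep are
spawned from one root seed.

## Classifiers

**SAM screen.** One-vs-rest statistic d = (mean_in − mean_rest)/(s + s0)
per gene and subtype, with s the two-sample pooled sd and s0 the median of
the per-gene s vector for that contrast. The null is pooled over all genes
across label permutations; p-values are add-one smoothed and BH-adjusted,
and genes with q ≤ fdr are kept per subtype.

**Nearest shrunken centroid (PAM).** Standardised centroid deviations
d_ik = (x̄_ik − x̄_i)/(m_k(s_i + s0)), m_k = √(1/n_k − 1/n),
s0 = median(s_i), soft-thresholded by Δ; genes with all-zero shrunken
deviations leave the model, and survivor count is non-increasing in Δ. Δ
is chosen on a 30-point grid by stratified cross-validation minimising
misclassification, ties toward the larger Δ (sparser panel); fold count is
reduced (and logged) when the smallest class is smaller than the requested
folds.

**DQDA.** Per class: empirical prior, per-gene mean and variance
(ddof = 1, needs ≥ 2 samples per class), variances floored at
1e-6 × pooled variance so the discriminant stays finite. Assignment is the
argmax of δ_k with deterministic ties to the lowest class index;
posteriors are the softmax of δ_k.

**Cross-cohort assignment.** The new cohort's rows are median-centred
within the cohort, absorbing per-gene platform offsets; the model's
centroids are centred the same way (the training feature medians are
stored at fit time). `centroid_correlation` assigns by the highest Pearson
correlation to the class centroids — shift- and scale-free, the robust
choice across platforms — flagging calls whose top-two correlations differ
by less than the margin (default 0.05); `dqda` applies the discriminant in
the centred space.

**Reduced-panel chain.** Paired one-vs-rest Wilcoxon DE (p < 0.01) →
bootstrap univariable logistic screen (stratified resamples; a gene is
robust when its slope is significant at p < 0.05 in ≥ 95% of iterations;
the per-gene fits use a vectorised Newton solver, and quasi-separated fits
where the Wald statistic degenerates are flagged and counted as
significant) → multinomial LASSO over a 20-point C grid with stratified CV
deviance and the one-standard-error rule (strongest penalty within one SE
of the deviance minimum; an empty 1-SE panel falls back to the minimum,
logged) → seeded random forest on the panel, developed on a stratified
70% split and evaluated on the held-out 30% with accuracy and one-vs-rest
precision/recall/F1/specificity from the confusion matrix.

## Sample-set enrichment (SSEA)

For a pathway and subtype, genes are split by point-biserial correlation
with the subtype indicator (BH q ≤ 0.05; constant genes excluded), the
integrated score is mean(positive genes) − mean(negative genes) per
sample, and samples are ranked by decreasing score (ties broken by sample
id). The running sum increments by |score|^w / Σ|score|^w at member
samples and decrements by 1/(N − N_set) elsewhere; ES is the signed
maximal deviation. Default weight w = 1 (score-weighted, the classic
convention); w = 0 gives the unweighted Kolmogorov–Smirnov form used by
the analytic tests, under which ES is invariant to any strictly increasing
transform of the scores and set/complement ES have opposite signs. The
p-value is the add-one smoothed fraction of random same-size sample sets
with |ES| at least as large (default 1000, seeded, bit-reproducible).

## Synthetic cohorts

The generator emulates the structure the method assumes, with ground truth
for every stage:

* **Network**: preferential attachment (Barabási–Albert, default 1000
  genes, m = 2), which reproduces the scale-free log-log degree profile
  (fit r < −0.8).
* **Expression scale**: per-gene baselines μ_g ~ N(8, 3) on a
  log2-intensity-like scale (typical microarray dynamic range ~0–16) plus
  independent N(0, noise_sd²) noise, default noise 1.
* **Subtypes**: K = 6 subtypes (default 300 tumors, 60 normals, 40 edges
  per subtype) on endpoint-disjoint edge sets. Each planted edge is
  perturbed by *swapping* its two endpoint baselines, choosing edges whose
  baseline gap lies between `shift_magnitude` (3) and
  `max_shift_magnitude` (7) noise units. The swap flips the pair's rank
  order with a margin of at least 3 noise units per endpoint (robust to
  the sampling noise), while the template's value multiset equals the
  baseline's, so the ranks of all unswapped genes are exactly unchanged —
  no spurious cohort-wide rank drift. The planted edge, whose endpoints
  move in opposite directions, carries exactly twice the delta-rank
  displacement of the other edges incident to a swapped gene; those
  incident edges are genuinely (more weakly) perturbed, which recovery
  analyses must account for when defining false positives. Swapped genes
  are the per-subtype marker ("informative") genes for the classifier
  chain; `resample_cohort` draws fresh cohorts from the same templates and
  `add_batch_effects` adds constant per-gene offsets for cross-platform
  tests.

What the generator does **not** emulate: gene–gene correlation structure
within pathways, batch/platform structure beyond constant per-gene
offsets, probe-level effects, survival outcomes, or tumor purity
gradients. Passing recovery tests therefore show that the pipeline's
statistics behave as designed under the assumed data model, not that real
cohorts will cluster as cleanly; in real data the dispersion contrast is
weaker and subtype boundaries are fuzzier.

## Problem sizes and numerical choices

Tests and the acceptance script run the default cohort (1000 genes, 360
samples) for the perturbation/selection/subtyping stages, a 10-seed sweep
at 100 consensus reps per K for the subtype-number check, and a
300-gene/300-tumor cohort with 2 planted edges per subtype for the
reduced-panel chain (200 bootstrap iterations) — sizes at which every
recovery statistic is already stable. Other conventions: average-tie
ranks; lexicographic edge orientation with `rank(min) − rank(max)`;
CV guard at 1e-8; variance floor 1e-6 × pooled; deterministic tie-breaks
(smaller K, larger Δ, lowest class index); add-one smoothing of all
permutation p-values; all randomness flows from explicit seeds through
`numpy.random.SeedSequence` spawning.

## Known limitations

* The benchmark assumes an adequately sized, homogeneous normal reference;
  with very few normals the benchmark itself is noisy and normal
  perturbation columns are mildly shrunk toward zero (they contribute to
  their own reference).
* The CV dispersion measure is unstable near zero means (see above).
* The combined location/scale edge test controls FDR across edges but
  inherits the usual caveats of Levene-type tests under heavy-tailed
  within-group distributions.
* PAC-based K selection assumes the consensus matrix can become near-binary
  at the true K; overlapping subtypes yield flat PAC curves, and the
  smaller-K tie-break is then conservative.
* The bootstrap logistic screen's Wald p-values are asymptotic; the
  quasi-separation guard replaces degenerate fits rather than applying a
  bias-corrected (Firth) likelihood.
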