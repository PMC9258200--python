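# Methods

## Model and procedure

The pipeline treats each gene independently. Inputs are a binary patient ×
variant carrier matrix (zygosity-blind: any alternate allele makes a
carrier), a binary phenotype (1 = case) and a variant→gene map in which
every variant belongs to exactly one gene.

**Association statistic.** For variants A, B and phenotype class k,
JCS(A,B|X=k) is the Jaccard similarity of the two carrier sets restricted to
patients of class k; an empty union yields 0 (a pair never seen in a class
carries no co-occurrence evidence). The level of association is the smoothed
log-ratio LOA = log((JCS₁+ε)/(JCS₀+ε)). This form is symmetric in (A,B),
zero when the class-conditional similarities are equal, and exactly negates
when the phenotype labels are swapped. The per-gene matrix of pairwise LOA
values, with zero diagonal (self-association is uninformative), is the
gene's association network; its elementwise exponential supplies strictly
positive weights for NMF and for walk transitions.

**Embedding backends.**

- *lcw_sg*: from every node, 10 random walks of length 10; each step picks
  among the other nodes with probability proportional to exp(LOA), so the
  walk prefers strongly associated neighbours and avoids negatively
  associated ones. The walks are sentences for a SkipGram
  (negative-sampling) model implemented in-package: fixed symmetric window
  (5), no token pruning or subsampling, 5 negatives from the unigram^0.75
  distribution, mini-batch SGD (batch 128) with a linearly decaying
  learning rate (0.025 → 1e-4), 5 epochs, default dimension 8. Batches must
  stay small relative to the vocabulary: each node accumulates roughly
  batch/vocab pair-gradients per update, and large batches inflate the
  effective step until all vectors collapse onto one direction.
- *gmf_pca*: rows of the LOA matrix, columns centred, projected on the top
  principal components (default 2). Component signs are fixed by making the
  largest-magnitude loading positive, so results are identical across runs
  and platforms. Genes with fewer than dim+1 variants are zero-padded with
  a warning.
- *gmf_nmf*: NMF of the exponentiated matrix (default 2 components),
  NNDSVDa initialisation with the multiplicative-update solver. This
  initialisation is data-derived and deterministic, and — unlike a
  position-tied random initialisation — keeps the factorization equivariant
  under permutations of the variant order, which is the property the test
  suite asserts for both global backends. Non-convergence within `max_iter`
  (default 500) logs a warning and keeps the best iterate.

**Module discovery.** Per gene, agglomerative clustering (Ward linkage,
Euclidean distance) of the embedding at every k in [2, min(20, n−1)]; the k
with the highest mean silhouette wins, ties to the smaller k (parsimony).
Genes with fewer than three variants, or degenerate all-identical
embeddings, yield one whole-gene candidate, keeping candidate counts
comparable to the gene-level control. Controls: ctrl_gla (one candidate per
gene) and ctrl_inv (one singleton candidate per variant).

**Scoring.** MAL(p,m) = carried fraction of the module's variants;
thr(m) = cohort-mean MAL; activation is the strict comparison MAL > thr
(consequence: if every patient has the same MAL, nobody activates).
ctrl_inv candidates are scored on carrier status directly, which for a
singleton equals MAL > 0. FEP is the upper-tail hypergeometric probability
P(X ≥ a) of the activated-case cell with margins fixed (a positive one-sided
test: only case-ward enrichment counts); FER is (a·d)/(b·c), reported as
+inf when b·c = 0 with a·d > 0 and as NaN (undefined) when both products
vanish; an optional Haldane–Anscombe +0.5 correction is off by default. Raw
p-values are thresholded at α = 0.05 with no multiple-testing correction (a
Benjamini–Hochberg step would be a trivial extension but is not part of the
benchmark).

**Benchmark.** One stratified split (per class, floor(fraction·n) patients
to train, remainder to test — at fraction 0.5 the odd patient lands in
test); discovery on the training half only, using the training-observed
gene map (variants carried by no training patient are dropped, genes left
empty are skipped); acceptance = FEP < α on train; reproduction = FEP < α
on test among accepted. The activation threshold is recomputed within
whichever split is being scored, since it is defined as a cohort mean; an
alternative reading (freeze the training threshold) is possible but not
used. Rates are ratios of raw counts; rounding (4 decimals) happens only in
the tabular report, and rate ratios between approaches are computed from
unrounded counts. Zero denominators give an undefined sentinel (`None`/NA),
never 0.

## Smoothing constant ε

ε trades variance against bias. The estimate of a Jaccard similarity in a
phenotype class has resolution ≈ 1/(union count): for rare variants
(carrier frequency q ≈ 0.02) in a class of ~200 patients, the union holds
~8 patients, so a single chance co-carrier jumps JCS from 0 to ~0.125. With
ε far below that scale (e.g. 1e-3), such flukes produce spurious edges of
magnitude |log(JCS/ε)| ≈ 2–5 that dwarf genuine module signals (~0.5), and
no backend can recover planted structure (0/12 seeds in every configuration
tried). The default ε = 0.2 sits just above the fluke scale, keeping a
single-count artefact within log(1.6) ≈ 0.5 of zero while preserving the
ordering of real contrasts. The default is calibrated to cohorts of a few
thousand patients with a rare phenotype class; much larger cohorts with
rarer variants resolve smaller similarities and should lower ε (it is a
parameter of every network-building entry point and of the CLI).

## Synthetic cohorts

The generator emulates the structure of a large case/control variant
cohort: binary carrier calls grouped into genes, a rare phenotype (default
10% cases), and planted modules. Planting uses a latent-activation model:
per patient and module, a hidden activation is drawn (probability
p_active_case or p_active_control by phenotype); given activation each
module variant is carried with q_carrier_active, otherwise with the
background rate. This single latent cause produces both co-occurrence among
module variants and phenotype-conditional enrichment — exactly the two
signals LOA is built to detect. Defaults: background carrier frequency
0.02 (rare variants), exact case counts (round(n·case_fraction)), and a
hierarchical random stream (one child per gene) so extending a
configuration with new genes never perturbs existing genes' draws.

What the generator does **not** emulate: linkage-disequilibrium haplotype
structure, realistic allele-frequency spectra, population stratification,
covariates, or genotyping error. Passing tests therefore demonstrate that
the pipeline recovers co-occurrence structure of the planted kind, not that
it is robust to confounding present in real cohorts.

**Study scenarios frozen in the tests and acceptance script.**

- *Strong planted module*: p_active_case 0.6, p_active_control 0.05,
  q_carrier_active 0.9, q_background 0.02, 2,000 patients, 10% cases; one
  12-variant gene with an 8-variant planted module. A sensitivity scan over
  layouts showed recovery degrades as the background share grows: rare
  background variants are mutually near-independent, so "background" is not
  a compact cluster, and single-co-carrier noise attaches stray background
  variants to the module. The 8+4 layout keeps the planted partition
  detectable by the global backends while remaining a realistic
  domain-sized module.
- *Null calibration*: 100 genes × 8 variants, no planted modules, 2,000
  patients, 10% cases, background carrier frequency 0.20. Common variants
  are used deliberately: Fisher's exact test is conservative by
  discreteness, and at rare-variant margins (expected activated-case count
  ~10) its achieved size is ~0.027, which would test discreteness rather
  than calibration; at frequency 0.2 the expected activated-case count is
  ~20 and the achieved size approaches the nominal 0.05.

## Numerical choices and edge cases

- Exact test via the hypergeometric survival function; verified against a
  rational-arithmetic enumeration for every table with n ≤ 40.
- Silhouette of a degenerate (all-identical) embedding is treated as
  unusable and the gene falls back to a single candidate.
- Seeds: every stochastic step (simulation, splitting, walks, SkipGram)
  takes an explicit seed; the benchmark derives per-approach, per-gene
  seeds from its one config seed, so reports are byte-identical across
  runs. SkipGram is single-threaded by design; multi-threading would void
  bitwise reproducibility.
- Problem sizes in the shipped tests and acceptance script (2,000-patient
  cohorts, ≤100 genes, 20 simulation replicates) are chosen so the whole
  verification surface runs in a few minutes on one CPU while leaving the
  binomial error of the measured rates well inside the asserted bands.

## Known limitations

- **The walk-based backend does not recover planted modules at the strong
  scenario's effect size.** With smoothing at the noise floor the
  within-module LOA contrast is ~0.4, and after the softmax over exp(LOA)
  a background node sends ~77% of its transition mass into an 8-variant
  module versus ~72% for a module node: the per-node walk distributions
  differ by total variation ≈ 0.15 while within-group variation is ≈ 0.12.
  A 10×10-walk corpus — or even a 50× larger diagnostic corpus — carries
  essentially no partition signal, so SkipGram embeds noise (ARI ≈ 0).
  This is a property of walk statistics at this effect size, not of the
  trainer: the same backend recovers an ideal two-block network exactly.
  The corresponding recovery test is expected to fail for `lcw_sg` and
  passes for both global-factorization backends, mirroring the benchmark
  ordering in which the walk-based approach is the weakest.
- LOA is undefined without smoothing whenever a pair is absent in one
  class; all reported values depend (smoothly) on ε.
- Cross-module LOA between two independently planted case-enriched modules
  can exceed within-module LOA (their co-occurrence is almost entirely
  case-specific), so multi-module genes are harder than single-module ones.
- The evaluation protocol shares one split across approaches and does not
  cross-validate; reproduction rates on small candidate sets are coarse.
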