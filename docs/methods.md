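# Methods

## Activity quantification

A barcode-level count table holds one row per (element, barcode, replicate)
with DNA and RNA read counts. Within each replicate and modality, counts are
scaled to counts-per-million (CPM) of that replicate's total. Element
activity in a replicate is the sum-then-ratio statistic

    activity = log2( (Σ_b rnaCPM_b + pc·scaleRNA) / (Σ_b dnaCPM_b + pc·scaleDNA) )

where `scale` terms are the CPM equivalents of one raw read and the
pseudocount `pc = 1` raw read keeps zero-RNA elements finite. Aggregating
counts before taking the ratio (rather than averaging per-barcode ratios)
weights barcodes by their abundance and is robust to shallow barcodes. A
barcode contributes to the support count only if its DNA count is positive
— a barcode never observed in DNA carries no integration evidence — and
elements with fewer than 10 supported barcodes in a replicate are censored
there. Replicates are combined by subtracting each replicate's median
activity over retained elements and averaging whatever replicates remain
per element. CPM makes activities invariant to rescaling any one
replicate/modality up to a pseudocount effect below 0.01 log2 units once an
element has ≥50 raw DNA reads.

`barcode_sd`, the SD of per-barcode log2 CPM ratios, is reported for QC.
Note that the per-barcode SD itself does not shrink with barcode support
(at fixed per-barcode depth it is support-independent; at fixed element
depth, fewer barcodes are individually deeper and less noisy). What
improves with support is the precision of the element score, i.e. the
standard error `barcode_sd / sqrt(n_barcodes)`; the test suite asserts that
quantity.

### Identifiability: the composition offset

Sequencing is compositional: totals are fixed by the machine, so any
per-replicate normalization determines activities only up to an additive
constant `C = log2(Σ_b w_b 2^{g_b} / Σ_b w_b)` set by the library's
expression composition (w are barcode abundances, g true log2 activities).
Correlations, slopes, rank statistics, active calls against internal
negative controls, ESS and all downstream contrasts are unaffected; only
the absolute zero point is not identified. The count simulator therefore
records its exact composition offset in
`counts.attrs["composition_offset"]`, and calibration checks comparing
estimated to true activities align the scales with it. Shuffled negatives
estimate at `−C` relative to the library, exactly as real negative controls
sit below an actively-composed library's median.

## Active-element calling

Foreground scores (each tested orientation is its own entry) are converted
to empirical p-values against pooled shuffled-negative scores with +1
smoothing, ties counting toward the negatives:
`p = (1 + #{neg ≥ s}) / (1 + #neg)`. Benjamini–Hochberg over the foreground
yields q-values; `active ⇔ q ≤ 0.05` by default. An element tested in both
orientations is reported active overall if either orientation passes, with
per-orientation calls retained. With N negatives the smallest achievable p
is 1/(N+1); below 100 negatives a warning flags the granularity. Category
shifts use the one-sided Wilcoxon rank-sum test (exact enumeration for
tie-free combined n ≤ 50, tie-corrected normal approximation otherwise)
with Bonferroni adjustment. The downsampling power curve re-quantifies and
re-calls after keeping ⌈p·B⌉ barcodes per element and replicate; for
proportions at which ⌈p·B⌉ falls below the support filter, the analysis is
run with the filter relaxed (`min_barcodes=1`), since the object of study
is the degradation of the scores themselves.

## Orientation and cell-type specificity

Orientation dependence is summarized two ways: (1) Pearson correlations for
every replicate pairing, labelled same-orientation (FvF, RvR) versus
opposite (FvR, RvF) — orientation-dependent elements depress the opposite
pairings; (2) strand asymmetry `|fwd − rev|` per element, compared between
promoters and potential enhancers by the one-sided rank-sum test.

Element specificity scores z-score each cell type's activities (sample SD,
over the elements measured in every cell type) and subtract each element's
across-cell-type mean; rows sum to 0 exactly and the score is invariant to
per-cell-type constant shifts. The PCA of the (column-centered)
element × cell-type matrix treats cell types as variables; component 1
carries the shared activity signal and is excluded from biplots, with signs
fixed so each component's largest-magnitude loading is positive. A rank-1
matrix (all cell types identical) is legal and simply yields zero variance
beyond component 1. Per-category, per-cell-type enrichment uses the
one-sided Wilcoxon signed-rank test for median ESS > 0 (exact for n ≤ 25).

## Binding-site grammar

PWMs hold per-position base probabilities (floored at 1e-4 before logs)
with a 0-order background (uniform by default). Scanning computes the
log-odds score `Σ log2(p_base / bg_base)` at every offset on both strands;
ambiguous bases contribute 0. Scores are discretized per position to
1e-3-bit bins and the null distribution of the binned score under the
background model is computed exactly by dynamic-programming convolution
across positions, so a hit (exact null p ≤ 0.001, matching the text-mode
`--thresh` convention of FIMO-style scanners) is reproducible without an
external tool. Overlapping hits all count. Per element and TF, hits are
summarized as a site count and the sum of natural-log match probabilities
over hits ("log-likelihood"; 0 when there are no hits).

Homotypic dosage: among elements with zero sites for every other top TF,
elements are grouped by site count 0–5 (groups under 10 elements dropped).
Least squares of activity on dose in log2 space gives the multiplicative
(log-additive) expectation; least squares of `2^activity` on dose, re-drawn
in log2, gives the additive expectation; observed medians per dose sit
alongside both lines.

Heterotypic interactions: for a TF pair, eligible elements carry 0/1 sites
of each pair member and none of the other top TFs. Activities are first
residualized on the log-likelihood columns of every scanned TF outside the
pair — removing variance attributable to other factors' binding — and the
residuals are fit by OLS to `b0 + b1·I1 + b2·I2 + b_int·I1·I2`, all four
cells requiring n ≥ 10. `b_int > 0` is super-multiplicative (cooperative),
`b_int < 0` sub-multiplicative (saturating). The two-stage adjustment is
exact when confounder variation is spread beyond the pair indicators; the
test suite demonstrates both the bias without adjustment and its removal.

## Feature models and variant effects

The biochemical lasso z-scores features (so coefficients are comparable),
assigns each element to one of 10 folds by a seeded hash of its id (stable
across runs and cell types), and picks λ by mean CV MSE on a 100-point
log-spaced grid whose largest value provably zeroes all coefficients
(λ_max = max|Xᵀ(y−ȳ)|/n). Ten per-fold models supply held-out Pearson r and
an ensemble; final coefficients come from a full-data fit at the chosen λ.
λ is chosen at the CV minimum (not the 1-SE rule). An identically-zero
response returns the trivial zero model with undefined per-fold r.

ISM evaluates a deterministic scorer on every single-nucleotide substitution
(600 deltas for a 200-nt input; reference cells are absent). Variant effects
over a scorer ensemble report the mean delta and a two-sided one-sample
t-test of the deltas against 0 as the uncertainty p — a pragmatic stand-in
isolated in one function; identical nonzero deltas (zero variance) are
flagged and given p = 0, all-zero deltas p = 1. ASV concordance excludes
variants with ASV FDR > 0.05 or uncertainty p > 0.05, crosses predicted and
observed effect signs in a 2×2 table, and reports OR = (n₊₊·n₋₋)/(n₊₋·n₋₊)
(Haldane 0.5 correction, flagged, when a cell is empty — an all-concordant
table is reported as degenerate with an unbounded OR rather than a number)
with Fisher's exact p.

## Representative selection

Similarity between element feature vectors is the Pearson correlation
mapped to [0, 1] via (r+1)/2 (the alternative max(r, 0) is available); the
facility-location objective `f(A) = Σ_v max_{a∈A} φ(v,a)` is maximized by a
lazy greedy optimizer — cached marginal gains in a max-heap, re-evaluated
when they surface, valid because submodularity makes gains non-increasing.
Ties break by ascending element id, and cached/fresh gains are compared as
exact floats (recomputation is deterministic), which makes the lazy
optimizer provably identical to naive greedy; an exhaustive optimizer
(≤10⁶ subsets) serves as the test oracle, and the greedy solution always
satisfies f ≥ (1 − 1/e)·OPT. Self-similarity is included in the ground-set
sum (standard facility location). The similarity matrix is dense; the CLI
refuses ground sets beyond 20,000 elements unless the cap is raised
explicitly. The stratified sampler bins scores into equal-width bins over
[min, max], draws equal quotas per bin and redistributes deficits from
sparse bins to the fullest ones; a degenerate score range collapses to one
bin with a warning.

## Synthetic libraries

The generator encodes the study conditions. Defaults: a promoter:enhancer
ratio of about 1:3.5 with a few hundred shuffled negatives and a small
positive-control set; 3 replicates; barcode support drawn from a clipped
lognormal with median 50 over 20–250; 2×10⁶ reads per replicate and
modality; gamma-Poisson counts with dispersion 0.1 (Var = μ + 0.1μ², the
Poisson limit at 0) around lognormal (sd 0.5) barcode abundances shared
across replicates, with ±20% library-size jitter.

True activities follow the linear bookkeeping
`baseline + 0.4·(sites) + Σγ·(co-occurrence) + deviation`: promoter
baselines are a bimodal normal mixture (inactive near 0, active near 3
log2), enhancer baselines a right-skewed Gamma(2, 0.75), shuffled negatives
exactly 0, positive controls near 4. Enhancers get an origin cell type
whose deviation is N(specificity_shift, specificity_sd) at home and
N(0, specificity_sd) elsewhere — the mean shift (default 1 log2) is what
makes "cell-type-specific enhancers" a planted, recoverable signal.
Orientation offsets are N(0, σ) with promoters given 2σ, reflecting their
stronger strand dependence.

Sequences are uniform-random backgrounds **rejection-cleaned until no PWM
scores above the scan threshold**, after which consensus sites (argmax base
per column) are planted at non-overlapping positions via random gap
allocation; flanking windows that would scan as spurious hits are locally
repaired by redrawing only background bases. The emitted sequence therefore
scans back to exactly the planted counts — ground truth is exact by
construction, which is the point of a generator: at FIMO-style p ≤ 1e-3
thresholds an unconstrained 200-bp background yields on the order of 0.1
chance hits per element and TF, which would contaminate every recovery
analysis. Shuffled negatives are dinucleotide shuffles (Eulerian-path
algorithm: uniform random last-edge arborescence plus uniform edge
orderings, preserving exact dinucleotide counts and both terminal bases) of
motif-free backgrounds, re-shuffled if a spurious hit appears.

What the generator does **not** emulate: PCR/UMI duplication structure,
barcode sequencing errors and collisions, integration-site position
effects, GC-dependent coverage bias, correlated (non-independent) feature
noise, and real motif information content (planted sites are consensus,
i.e. maximally clean). Passing recovery tests therefore demonstrates the
correctness of the estimators under the stated noise model, not robustness
to every artefact of real sequencing data.

## Numerical and design choices

- All randomness flows through `numpy.random.default_rng([seed, stream])`
  with fixed stream ids per stage; equal seeds give byte-identical outputs.
- PWM probabilities floored at 1e-4; scan scores discretized to 1e-3-bit
  bins (the DP null and the scanner share the same per-position binning, so
  threshold comparisons are exact, verified against full 4^w enumeration).
- Empirical-p ties count toward negatives (conservative); BH is applied
  over the full foreground.
- Negatives are pooled across orientations when both are tested.
- Z-scores use the sample (n−1) SD throughout.
- ESS is computed on the intersection of elements measured in all cell
  types.
- Problem sizes in the test suite and acceptance script (for example 1,000
  elements × 50 barcodes × 3 replicates for quantification recovery, 200
  random 10×10 instances for the optimizer, 10 generator seeds for
  Monte-Carlo recoveries) are chosen as the smallest sizes at which the
  checked properties are statistically unambiguous.

## Known limitations

- The CPM + pseudocount normalization dialect is one reasonable reading of
  "normalized counts"; it is isolated in `element_activity` so an
  alternative dialect is a one-function change.
- The negative-binomial/lognormal noise family is a modelling choice; real
  barcode-count noise families are not printed anywhere authoritative.
- The variant-effect uncertainty p (ensemble t-test) is one defensible
  definition of prediction uncertainty, not the only one; it lives behind
  `predict_variant_effect` only, so swapping it is a one-function change.
- The interaction adjustment is two-stage (residualize, then fit); it is
  exact under confounder variation orthogonal to the pair design and
  slightly conservative otherwise.
- Facility location materializes a dense n×n matrix: memory grows
  quadratically and very large ground sets need the streaming/approximate
  optimizers that are out of scope here.
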