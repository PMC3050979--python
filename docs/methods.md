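# Methods

This note documents the models behind `cllmir`, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and
the numerical decisions a maintainer would want spelled out. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Normalization: the mock array

Bead-array median fluorescence intensities are floored at 1 (values near
zero are noise) and log2-transformed. Features on a configurable
exclusion list — by default `hsa-miR-146b-5p`, the probe with abnormal
background bead signal on the original platform — are dropped *before*
anything else, so background artifacts never contaminate the reference.
The mock array is the per-feature arithmetic mean of the remaining log2
values across all samples. Each sample *x* is then corrected by
ordinary least squares: fit `mock = a + b·x` over features and replace
the sample with `a + b·x`.

Decisions where the procedure was under-determined:

- **Scale.** The correction is fitted on the log2 scale (recorded in
  the provenance sidecar). Downstream scores and fold-change language
  are all log-scale, and an affine map on log2 intensities corresponds
  to the multiplicative-plus-exponent distortions bead labeling
  chemistry actually produces.
- **Regression direction.** Fitting `mock ~ sample` and reporting the
  fitted values maps every sample into the common mock frame; a sample
  that is an affine distortion of the cohort profile is restored
  exactly (tested to 1e-9), and correcting the mock against itself is
  the identity.
- **Idempotence.** Projection onto a *fixed* mock is exactly idempotent
  (OLS fitted values re-project to themselves); re-running the whole
  pipeline recomputes the mock from corrected samples, which moves
  values again (the iteration contracts but is not a one-pass fixed
  point). Only one pass is ever applied.
- Exclusion-id matching is species-prefix tolerant
  (`hsa-miR-146b-5p` matches `miR-146b-5p`), since panels mix both
  conventions; requested exclusions absent from the panel warn rather
  than fail.

## Marker statistics

The two-class ranking metric is the signal-to-noise style score
`(µ₁ − µ₂)/√(s₁² + s₂²)` with sample (n−1) standard deviations — the
paper-era marker-selection score; a positive value means higher
expression in class 1 (the caller designates class 1; resting control
B cells by convention in the comparisons shipped here). Per-feature
significance is a Welch two-sample *t*-test. If both classes have zero
variance the score is 0 for equal means and signed infinity (with a
warning) otherwise; Welch *t* on such degenerate ties reports p = 1 (no
evidence, rather than an error, so one flat feature cannot abort a
panel-wide scan).

Multiple testing uses Benjamini–Hochberg throughout (backed by
`statsmodels`, cross-checked in the tests against an O(m²) brute-force
step-up). The activation signature takes features with BH-adjusted
Welch p < α (default 0.05) between resting and CpG-activated B cells,
assigned to the up or down set by the sign of the mean difference;
α ≥ 1 disables the threshold and assigns every feature by sign. An
empty result is a warning, not an error.

One consequence worth knowing: when a dozen features pass at p ≈ 0, the
BH step-up threshold for an additional discovery is ≈ 13·α/m, so on a
large panel an occasional *extra* null member is admitted by design —
that is the controlled false-discovery rate at work, not a defect. The
exact-recovery tests therefore run the derivation on a panel consisting
of the planted signature itself, which isolates the machinery
(direction assignment, adjustment, thresholding) from BH's designed
false-inclusion rate.

Clinical associations: continuous expression against a binary covariate
uses the Wilcoxon rank-sum test (exact when both groups are ≤ 25 and
untied, midrank normal approximation otherwise); dichotomized
expression (median split unless a cut-point is supplied) uses Fisher's
exact test; covariates with ≥ 3 categories use Kruskal–Wallis. BH
q-values are computed across the features tested.

## Set enrichment

A from-scratch GSEA running sum: walking the ranked list, the sum
increases at set members by `|metric|^w / Σ_hits |metric|^w` and
decreases at non-members by `1/(N − N_hits)`; ES is the signed maximum
deviation. `w = 0` is the classic Kolmogorov–Smirnov form (running sum
ends exactly at zero, ES invariant to monotone metric transforms); the
default is `w = 1`, the weighted form of the canonical method. Ties in
the ranking metric break by feature id so permutation nulls are
reproducible.

Significance is by phenotype-label permutation with a signed-null
convention: the nominal p compares |ES| against null ES of the observed
sign only, and NES = ES / mean(|null ES| of that sign). This treats
up- and down-regulated sets independently, which is why the two halves
of the signature are tested separately. All distinct label assignments
are enumerated when there are at most `n_perm` of them (e.g. all 20 for
a 3-vs-3 design); otherwise `n_perm` distinct assignments are sampled
without replacement from the given seed. The add-one pseudocount keeps
p in (0, 1]. A gene-set (random same-size set) permutation mode is
available behind `permutation="feature"` for designs with too few
samples to permute. The leading edge is the set members at or before
the running-sum peak (ES > 0) or at or after the trough (ES < 0).

## ΔΔCt quantification

Replicate Ct values are aggregated by arithmetic mean per
(sample, target); ΔCt = mean Ct(target) − mean Ct(reference), with
snoRNA RNU44 as the default reference. The calibrator is a sample or a
group (the resting control-B group by convention; a group calibrates
against the mean of its per-sample ΔCt). Fold = 2^(−ΔΔCt): perfect
doubling per cycle, no efficiency correction — plain ΔΔCt. Replicate
scatter is propagated in cycles as √(sd_target² + sd_ref²), never in
folds. Ct values outside (0, 50) are rejected; a sample with target
rows but no reference rows is an error naming the sample.

## Survival screen

Kaplan–Meier estimation is product-limit (lifelines-backed), ties
processed events-first. The log-rank statistic is the standard
observed-minus-expected form with hypergeometric variance, implemented
in-package as a batched routine because the cut-point search evaluates
it at every candidate split for every feature and permutation;
agreement with lifelines is pinned in the tests to 1e-9.

For each miRNA individually the candidate cut-points are the midpoints
between consecutive sorted unique expression values; samples *at or
below* the cut form the low group ("at 11.82 or lower" convention).
Candidates keeping at least `max(⌈0.2·n⌉, 5)` samples on both sides are
scored; the maximizing cut is reported, ties resolved to the lower cut
(with a 1e-9 tolerance so exact ties are not decided by float noise).
The split criterion is log-rank χ² maximization — the transparent,
directly testable surrogate for survival-tree deviance splitting; the
two agree on where strong changepoints lie, and χ² is what the screen
reports anyway. Constant expression, or no admissible candidate, yields
a no-split record rather than an exception.

The naive p at the chosen split is *not* adjusted for the optimization
over cut-points and is flagged as such. The screen's
`adjust="permutation"` mode re-runs the entire search on permutations
of the expression vector (candidate values and leaf admissibility are
permutation-invariant, so only the group masks are rebuilt — this is
what makes 1000 permutations × 50 features tractable) and reports the
add-one fraction of permutations whose best χ² reaches the observed
best. BH q-values across screened features; q ≤ 0.10 is the reporting
criterion. Expected behavior under FDR control: with two true
prognostic features discovered, a screening run admits ≥ 1 false
co-discovery with probability ≈ 1 − (1 − 3·0.1/m)^(m−2) ≈ 0.2–0.25 —
again the designed FDR, so specificity claims are evaluated per
feature across replicate cohorts, not as exact hit-sets per cohort.

## Hierarchical ordering

Heatmap ordering uses average-linkage agglomerative clustering with
distance 1 − Pearson correlation, rows and columns independently
(linkage and metric are recorded in the pipeline manifest; the original
analysis software's defaults vary by version). Constant rows fall back
to zero correlation (distance 1 to everything). Inputs are sorted by id
before clustering so tie-breaking is deterministic.

## Synthetic cohorts

The generator emulates the study design: by default 38 CLL, 9 resting
control B and 5 CpG-activated B samples on a 50-miRNA panel (the
12-member activation signature plus the CLL-signature miRNAs and panel
filler). Log2 intensity = baseline (8.0) + group effect + N(0, 0.5²);
raw intensity = 2^log2. Planted effects apply to the CLL *and*
activated groups relative to control: +log2(50) for miR-155, −log2(100)
for miR-181a/b — the magnitudes the profiling reports — and ±2 log2
units for the other signature members. One high-background feature
(miR-146b-5p) receives an additive raw-scale offset of 10× the
baseline-median intensity in every sample, to exercise the exclusion
path.

The two prognostic miRNAs (miR-29c, miR-223; hazard coefficient −1.0
each) share a latent per-sample aggressiveness factor giving their
noise terms a pairwise correlation of 0.7 while keeping each feature's
marginal SD at `noise_sd_log2`. This reflects that the prognostic
miRNAs co-vary with the same clinical axis rather than acting as
independent hazards; under independence, each feature's marginal
association carries the other's full effect as frailty, which is an
artifact of the independence assumption rather than a feature of the
design being emulated. ZAP70 and IgVH-unmutated status are assigned by
thresholding the same latent score (worst 14/38 each by default), so
clinical-association tests have planted signal.

Survival: time to first therapy is exponential with log-hazard linear
in the standardized log2 expression of the prognostic features
(negative coefficient ⇒ low expression, shorter time); the baseline
mean is 1500 days. Censoring is uniform on [0, m], with m solved
numerically so the expected censoring fraction over the realized
per-subject hazards matches `censor_rate` (default 0.3); `censor_rate`
0 and 1 are exact no-censoring / all-censored edges. Ct tables are
built from the noiseless latent abundances: Ct(target) = 30 − (latent −
baseline) + N(0, replicate_sd), Ct(RNU44) = 25 + noise, three
replicates, so ΔCt falls one cycle per planted two-fold increase and a
noiseless table reproduces planted folds exactly.

What the simulator does **not** emulate: bead chemistry and
cross-hybridization, intensity-dependent (nonlinear) distortions,
heavy-tailed or feature-correlated noise beyond the prognostic pair,
informative censoring, and patient heterogeneity in effect magnitude
(every CLL sample carries the full planted effect). Passing recovery
tests therefore demonstrates that the analysis chain finds what its own
statistical model plants at realistic sizes and noise — not that it is
robust to real-platform artifacts outside that model.

## Test and experiment sizes

Problem sizes were chosen so each check has clear resolution:

- Oracle-equivalence suites run 1000 random instances at n ≤ 12 against
  naive brute-force implementations (enumeration, closed forms,
  lifelines).
- Null calibrations use 1000 feature-tests (Welch t), 200 replicates
  (log-rank), and 200 runs (GSEA nominal p, 16-sample cohorts with 199
  permutations), each judged against the binomial 95% interval around
  0.05.
- Signature recovery: 20 cohorts, 9 control vs 5 activated samples,
  ±2 log2 effects, noise 0.3, panel = the planted signature (see the
  BH note above).
- Cut-point recovery: 20 cohorts of n = 200 with a 3× hazard below the
  planted threshold, expression quantized to a 0.25-log2 grid (~10
  patients per level), so "recovered within one candidate step" tests
  whether the search localizes the changepoint to one expression level.
  At fine grids the same check would measure the changepoint
  estimator's intrinsic few-sample jitter, which no search can remove.
- Screen recovery: 20 default cohorts, permutation-adjusted mode with
  1000 permutations, evaluated per feature across seeds (each planted
  prognostic miRNA flagged at q ≤ 0.10 in ≥ 80% of seeds; no other
  feature flagged that consistently), for the FDR reason above.

## Known limitations

- The OLS correction assumes most features are non-differential or
  balanced between groups; panels dominated by large one-sided effects
  tilt the per-sample slope and can leak small systematic shifts into
  null features. On the default cohort this occasionally nudges a null
  feature past the signature threshold (the BH leniency above makes
  the final step permissive once many features are certain).
- Exact Wilcoxon p-values fall back to the midrank normal approximation
  in the presence of ties.
- The permutation-adjusted screen p has resolution 1/(n_perm + 1);
  detecting q ≤ 0.10 across m features needs n_perm ≳ m/(rank·0.1)
  permutations for the top hits.
- `NES` is undefined (NaN) when no null ES of the observed sign exists;
  with enumeration this only occurs for ES = 0 edge cases.
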