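# Methods

This note records the models, conventions and numerical choices behind
`tbimir`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Synthetic cohorts (`simdata`)

The generator exists so that every downstream stage can be exercised and
validated without access to the original sequencing data. It emulates
four kinds of measurement.

**Count matrices.** Counts are negative binomial. The expected count of
miRNA *i* in sample *s* of group *g* is

    mu_is = exp(baseline_log_mean + eps_i) * depth_s * 2^effect[i][g]

where `eps_i ~ N(0, mirna_log_sd)` spreads per-miRNA baseline abundances
(default SD 1.2 on the natural-log scale, giving a realistically
heavy-tailed abundance distribution), `depth_s` is the sample's library
size drawn uniformly from `library_size_range` and divided by the range
midpoint (so depths act as relative factors), and the effect table holds
per-group log2 fold effects. Counts are NB with size parameter *k*
(`dispersion`; variance mu + mu²/k), with the Poisson limit at k = ∞.
Recorded per-sample miRNA-mapped totals are the realized column sums.

Defaults mirror the rat study design: the sequencing subset is
naïve/sham/mTBI/sTBI = 4/5/5/5 animals, the whole cohort 5/8/10/8, with
748 miRNA species. The default planted effects for the three validated
markers are the whole-cohort relative RT-qPCR fold changes (mTBI vs
naïve 14.8 / 4.3 / 7.1 for miR-9a-3p / miR-136-3p / miR-434-3p, with the
corresponding sham and sTBI effects), because the default simulated
designs are that cohort. The dispersion default k = 10 puts the
biological coefficient of variation near 0.3, deliberately consistent
with the log-scale SD 0.3 used for copy numbers (below); both are free
parameters of the generator, configurable per design.

**Cq tables.** Cq = assay baseline − (log2 relative abundance) +
Gaussian noise, so a +1 log2 effect lowers Cq by one cycle. The table
always carries the endogenous reference (miR-28-3p) and the hemolysis
indicator pair: samples flagged hemolyzed in the metadata get a planted
ΔCq(miR-23a − miR-451) drawn from (5.5, 8) cycles, clean samples from
(1, 4), so the ΔCq > 5 rule recovers the planted flags exactly.

**ddPCR wells.** With *c* template copies among *d* droplets the
positive-droplet count is Binomial(d, 1 − e^(−c/d)). Droplet
fluorescence comes from two Gaussian clusters (defaults 4000 and
14000 AU, SD 900) clipped to the correct side of the calling threshold
(default 10000 AU), reflecting assays with clear cluster separation
where the threshold is set manually; automatic thresholding is out of
scope. Positive counts are drawn before amplitudes so the counts-only
and amplitude-emitting modes agree under one seed.

**Copy numbers and the human cohort.** Per-animal copies/well are
log-normal around group geometric means with log-scale SD 0.3 — the
between-animal variability is not reported anywhere, so 0.3 is a free
parameter chosen once (it makes a 4.2-fold group separation ≈ 4.8 SDs,
consistent with the perfect mTBI/naïve separability the workflow is
designed to detect) and is configurable. The human generator plants the
cohort structure the clinical analysis expects: control n = 14, mTBI
n = 15 with elevated subpopulations (7/15 for miR-9-3p at 4x the bulk
geometric mean, 5/15 for miR-136-3p, nested), sTBI n = 2, and an S100B
covariate with 11/15 mTBI patients above the 0.1 µg/L clinical cutoff.

**What the generator does not emulate**: read-level artifacts (UMIs,
adapter trimming, mapping ambiguity — the pipeline starts at the count
matrix), correlation between miRNAs (counts are independent given the
design, while real miRNAs co-vary), batch effects, and the dependence of
hemolysis on the measured counts. Passing tests therefore demonstrate
the correctness and calibration of the algorithms under the stated
generative model, not performance on real cohorts.

## Quality control (`qc`)

Two independent hemolysis checks: the 414-nm absorbance hemolysis
coefficient (flag strictly above 0.25; the coefficient itself is an
opaque input — its spectrophotometric definition is instrument-specific)
and ΔCq(miR-23a − miR-451) strictly above 5 cycles. Boundary values pass
in both cases. The checks assess different material (plasma vs extracted
RNA) and may disagree; both flags are carried and nothing is excluded by
default — downstream exclusion is a configuration choice. Samples
missing a pair member are unassessable, not flagged. Cq range checks are
inclusive on both ends and fail on missing values.

## Normalization (`normalize`)

- **CPM**: counts / per-sample miRNA-mapped total × 10⁶. Totals may
  exceed in-matrix column sums (the matrix may be pre-filtered); when
  they are the column sums, columns sum to 10⁶ exactly.
- **Prevalence filter**: keep miRNAs with count ≥ 1 in at least
  ⌈0.8 · n⌉ samples (both knobs configurable); idempotent, order-
  preserving, totals untouched.
- **2^−ΔCt**: relative expression vs miR-28-3p per sample; samples
  without a reference Cq are skipped with a warning.
- **Reference stability**: for ranking candidate reference assays the
  per-assay variation is decomposed into pooled within-group variance
  and the between-group variance of group means, the latter
  bias-corrected by the expected sampling contribution of the
  within-group noise (floored at 0); stability = sqrt(intra + inter),
  lower = more stable. This follows the intra/inter-group decomposition
  idea of model-based reference selection but deliberately skips the
  per-sample centering step of the full scheme, so that an assay that is
  constant across samples scores exactly 0 — the property the ranking
  should have. By default the decomposition runs on log2(count + 1),
  where noise is approximately additive; raw-scale mode is available.
- **Small-RNA input normalization**: dilution factor = concentration /
  target (target must not exceed the smallest concentration); CV% =
  100 · sample SD / mean, reported before and after.
- **EDA**: PCA on log2(CPM + 1) with feature centering (the transform is
  a choice; raw CPM PCA is dominated by the most abundant miRNAs);
  sample–sample Spearman ρ; complete-linkage clustering on 1 − ρ
  (undefined correlations from constant samples become maximal distance
  and are reported); per-group detection counts with "detected" = raw
  count > 0 in ≥ 1 sample of the group.

## Differential expression (`de`)

An intentionally transparent NB Wald pipeline. Size factors are median
of ratios to per-miRNA geometric means (all-positive miRNAs; positive-
subset fallback with a warning for sparse matrices). Dispersion is a
pooled within-group moment estimate on normalized counts,
α = (var − mean)/mean² weighted by group degrees of freedom, floored at
10⁻⁸. The Wald statistic is log₂(μ̂_A/μ̂_B) over a delta-method standard
error under variance μ + αμ²; p-values are two-sided normal, BH-adjusted
per contrast, significant at FDR < 0.05. A zero group mean is replaced
by half a normalized count (keeping the statistic finite and the
contrast antisymmetric); miRNAs all-zero in both groups are excluded and
listed. There is no dispersion shrinkage toward a trend, no fold-change
shrinkage and no independent filtering: equivalence with heavier DE
machinery is not claimed, and the validated contract is calibration
(type-I error ≈ 5% at nominal 0.05 in null simulations with n = 50 per
group) and sign/power on planted effects. The median-of-ratios step
assumes most miRNAs are non-differential; planting an effect in every
simulated miRNA would be absorbed into the size factors by design.

## Nested-CV feature selection (`mlselect`)

Outer loop: leave-one-out (unbiased for tiny cohorts). Inner loop:
stratified 3-fold (an inner LOO on ~9 training samples makes the inner
AUC degenerate; the fold count is configurable), pooling inner held-out
scores into a single AUC per hyperparameter combination. The grid spans
regularization strength C ∈ {0.01, 0.1, 1, 10}, selected-feature count
∈ {1, 2, 5, 10, 20}, selection method ∈ {RFE step 1, F-score filter},
penalty ∈ {L1, L2} by default — all configurable, and a single-
combination grid skips the inner search. Within each outer training set,
zero-variance features are dropped and the rest standardized with
training statistics only; the invariant is testable: replacing a
held-out sample's features with constants leaves its fold's fitted
coefficients unchanged. The held-out score is the class-1 probability;
CV AUC uses the rank (Mann–Whitney) formulation with mid-rank ties.
Feature importance is the outer-fold average of |coefficients| (zeros
for eliminated features), normalized to sum to one, ordered descending
with lexicographic tie-breaks. The permutation p-value uses the add-one
estimator (1 + #{AUC\* ≥ AUC})/(B + 1), which cannot return zero;
B defaults to 1000. Candidate selection takes the top-k (default 5)
importance features and flags their intersection with the DE hits as the
validation-priority set. Comparisons are binary; merged groups (injured
= mTBI + sTBI vs uninjured = naïve + sham) are handled by label mapping.

## ddPCR quantification (`quant`)

copies/well = −ln(1 − p) · n over the analyzed droplets, where p is the
positive fraction and droplets at or exactly on the amplitude threshold
count as positive. This per-analyzed-droplet convention matches the
magnitude of reported copy numbers; a per-reaction-volume mode
(λ · 20 µL / droplet volume) is available but off by default, since
which convention an instrument reports depends on its partial-analysis
accounting. A fully positive well is saturated and raises rather than
returning an infinite estimate. Replicate wells of one (sample, assay)
are summarized by the arithmetic mean. Group contrasts are ratios of
arithmetic group means, reported with half-up rounding to one decimal
(the convention under which 5.05 prints as 5.1); CV% uses the sample SD.

## ROC, cutpoints and flags (`rocstats`)

Group comparisons: Kruskal–Wallis with tie correction, then pairwise
two-sided Mann–Whitney U (exact for combined n ≤ 20 without ties, normal
approximation with tie correction otherwise); singleton groups are
excluded with a warning. AUC = U/(n₁n₂) with mid-rank ties, its p-value
from the same U test; AUC(pos, neg) + AUC(neg, pos) = 1 holds exactly.
Cutpoint candidates are midpoints between adjacent distinct observed
values plus sentinels beyond the range; the cutoff maximizes
sensitivity + specificity with "value ≥ cutoff ⇒ positive" (elevated-
marker direction); ties break toward higher specificity, then the
smaller cutoff. If every observation is identical the best achievable
sum is 100 and the result is flagged degenerate. Elevation flags use
value > mean + k·SD of the reference group (strict inequality, sample
SD with n − 1); the optional covariate flag (e.g. S100B > 0.1 µg/L) is
cross-tabulated against the elevation flag, with missing covariates
reported as unknown rather than imputed.

## Pipeline (`pipeline`, `cli`)

Stages run sequentially from one YAML config whose defaults encode the
analysis profile above (0.25 and 5 for hemolysis, 1/80% prevalence,
FDR 0.05, amplitude thresholds 10000/6000, k = 1 SD, S100B 0.1 µg/L).
Every artifact is written to the output directory and recorded with a
SHA-256 checksum in `manifest.json`; a stage failure records partial
completion and the failing stage. A mandatory seed drives a single RNG
from which all stage seeds derive, so identical configs produce
byte-identical numeric outputs.

## Problem sizes used in validation

The test suite validates calibration and recovery at sizes chosen to
make Monte-Carlo intervals tight while keeping the suite quick:
2000 null miRNAs at n = 50/50 for DE type-I error; 200 repetitions of a
19-permutation test (12 samples, 8 features) for permutation-p
calibration; 120 random instances against exhaustive-scan and
pair-enumeration oracles for cutpoint/AUC; 20 seeded whole-cohort runs
(3 planted markers among 300 noise miRNAs, mTBI n = 10 vs naïve n = 5)
for top-5 importance recovery; 500 wells at 19.2 copies / 15000 droplets
for ddPCR round-trip recovery. The acceptance script uses the n = 15
rat cohort directly.

## Known limitations

- The DE pipeline's moment dispersion is noisy for very small groups
  (n ≤ 4 per group); calibration is validated at larger n.
- RFE with step 1 from hundreds of features is expensive inside a
  nested grid search; the F-score filter is the practical default for
  wide matrices.
- The reference-stability ranking is a simplified decomposition (see
  above); its absolute values are not comparable to other software's
  stability scores, only its ranking contract is tested.
- Exact Mann–Whitney p-values switch to the normal approximation in the
  presence of ties at any sample size.
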