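# Methods

## The clock model

An epigenetic clock here is a sparse linear map from array beta values to
age in years: `DNAm age = β₀ + Σ_i x_i β_i` over a selected set of CpGs.
Training minimizes the elastic-net objective

    (1/2n) Σ_j (y_j − β₀ − x_jᵀβ)² + λ [ α‖β‖₁ + (1−α)/2 ‖β‖₂² ]

with predictors standardized to unit population variance (divisor n) and
the response centered; reported coefficients are de-standardized back to
the raw beta scale, so a trained `ClockModel` applies to raw betas with
no preprocessing beyond the probe selection itself. Defaults follow the
adult-blood-clock protocol: α = 0.5, λ chosen at minimum mean CV MSE
over a 10-fold split.

### Solver numerics

Cyclic coordinate descent with soft-thresholding; residuals are updated
in place and columns are walked in Fortran (column-major) order. A sweep
converges when the largest coefficient change is below `tol = 1e-7`
(hard cap `max_iter = 1e5` sweeps; hitting it raises with the last
iterate attached). Between full passes the solver iterates only the
current active set, and the penalty path is warm-started from the
previous λ. Solutions are verified in the test suite by a
solver-independent KKT oracle: for nonzero β_i,
|(1/n)x_iᵀr − (1−α)λβ_i − αλ·sign β_i| ≈ 0, and |(1/n)x_iᵀr| ≤ αλ
otherwise.

The λ grid is log-spaced from λ_max = max_j |x_jᵀ(y−ȳ)|/(nα) (the
smallest penalty with an all-zero solution; multiplied by 1 + 1e-10 so
the null model is exact under floating-point rounding) down to
λ_max·`min_ratio`, 100 values by default. `min_ratio` defaults
adaptively — 1e-4 when n > p, 1e-2 when p ≥ n — mirroring the common
convention of the reference penalized-regression solvers: in the
overparameterized regime the sub-1e-2 tail of the path is pure
overfitting and multiplies solver time by an order of magnitude without
ever being selected. Any explicit `min_ratio` is honored.

Cross-validation uses simple random, unstratified, near-equal folds
(seeded); per-fold standardization is recomputed from the training folds
only, and held-out MSE is averaged across folds. Ties in the CV curve
break toward the larger (sparser) λ; because the grid is descending,
`argmin` implements this directly. Missing betas at training time are
imputed with train-set probe means (stored in model provenance and
reusable at prediction time via `missing_policy="impute_stored_means"`);
all-missing probes are dropped with a warning.

Training on the day scale (`age_unit="days"`) multiplies the response by
365.25. Elastic net is not scale-equivariant in the response — the ridge
term scales with the cube of the response scale while the rest scales
with the square — so day-trained coefficients are a genuinely different
(more ridge-shrunk at matched path position) fit rather than exactly
365.25× the year-trained ones. The unit is recorded in provenance.

## Synthetic cohorts

The generator emulates the statistical structure adult blood clocks
assume. Ages are uniform on 18–88 y by default, or a two-component
mixture (U(min, 46) w.p. 0.75, U(46, max) w.p. 0.25) mimicking a
pregnancy cohort with an older extension. Each probe has a logit-scale
baseline μ_i ~ N(0, 1.5²) — spreading baseline methylation over roughly
(0.05, 0.95) as on real arrays — and a minority of "causal"
(age-informative) probes gain a slope b_i ~ N(0, effect_sd²) in logits
per standardized-age unit. Observed betas are Beta-distributed around
the logistic mean with concentration φ (default 50, i.e. sd ≈ 0.07 at
mid-range — array-like noise); the logit-linear construction keeps every
beta inside (0, 1) by design. Probe annotations (EPIC-only fraction
0.45, sex-chromosome 2.5%, cross-hybridizing 3%, SNP-proximal 2%, design
type I/II 15/85) approximate EPIC manifest proportions; causal probes
are always autosomal and unflagged so the QC cascade cannot silently
delete the planted signal. Optional per-(batch, probe) logit offsets add
batch structure, and the detection-p grid draws each cell above the 0.01
threshold with probability `detection_fail_rate`.

A subgroup age-acceleration shift of s years is implemented exactly as
"being s years older on the causal axis": each causal probe's logit mean
gains b_i·s/sd(age) for subgroup members, so any consistent clock reads
the subgroup as ≈ s years accelerated. The calibration constant
s/sd(age) and the causal-id/slope sidecar are stored in
`provenance` (`ground_truth`), which training code never reads.

What the generator does **not** emulate: cell-composition heterogeneity,
probe-chemistry (type I vs II) intensity differences, spatially
correlated CpG blocks, genotype-driven methylation, or non-linear age
trajectories. Passing tests therefore demonstrate correctness of the
pipeline's algorithms and their statistical behavior under the stated
generative model — not clock performance on real cohorts.

With the default effect_sd = 0.4 a causal probe correlates with age at
|r| ≈ 0.8 — a strong-signal regime in which a clock saturates with a few
dozen training samples. That is the right regime for parameter-recovery
checks, but not for learning-curve experiments; the platform-comparison
conditions below use effect_sd = 0.1 (per-probe |r| ≈ 0.3, typical of
real age-associated CpGs), where precision genuinely grows with training
size.

## Probe and sample QC

The exclusion cascade removes probes on sex chromosomes (SC),
cross-hybridizing probes (CH), SNP-proximal probes (SNP), and probes
failing detection (DP): a probe fails DP when the fraction of samples
with detection p > 0.01 strictly exceeds `detection_sample_fraction`
(default 0 — the strictest reading: any failing cell removes the probe;
fractional rules are configurable). All thresholds are strict
inequalities. Criteria are evaluated independently on the full input, so
the surviving set is order-independent, and per-criterion counts may sum
to more than the number removed. Per-batch exclusion lists are combined
by set union — a probe excluded in any batch is removed everywhere.
`restrict_to_common` keeps exactly the autosomal probes present on both
450K and EPIC. Sample-level QC implements only the objective rule
|linear EAA| > 15 years; "low-quality" and PCA-outlier removal are not
algorithmically specifiable and are out of scope.

## Evaluation and EAA

Precision is Pearson r between DNAm age and chronological age; its CI is
a percentile bootstrap on the Fisher-Z scale (z values capped at
arctanh(1 − 1e-12) so perfectly collinear resamples stay finite;
degenerate constant resamples are redrawn). Accuracy is MAD — the median
absolute prediction error in years, the epigenetic-clock literature's
usage, not the dispersion-around-median statistic.

EAA is the residual of DNAm age regressed on chronological age. Three
calibrations: ordinary least squares (EAA then has mean 0 and exactly
zero Pearson correlation with age); a truncated-power cubic with one
knot (default 70 y, continuous second derivative); and a cubic smoothing
spline with smoothness chosen by generalized cross-validation. The
regression direction is DNAm age on chronological age, per the EAA
definition; the reverse direction is available behind
`direction="reverse"` for the alternative recalibration convention.

Diagnosing residual age dependence needs care: in-sample OLS residuals
are Pearson-orthogonal to age *by construction*, even under gross
non-linear bias. `EAAResult` therefore reports both the Pearson
diagnostic (a construction check for the linear method) and a Spearman
rank diagnostic; the tests compare calibrations where the bias actually
lives — the correlation between EAA and age within the old stratum
(above the flattening point), which the spline calibrations shrink
dramatically while the linear calibration cannot.

Group comparisons of EAA use Welch's unequal-variance two-sample t-test
with its confidence interval; the difference is reported as
comparison − reference.

## The sample-size × probe-set experiment

Training sizes follow the geometric rule
`size_k = round(n_min · (n_full/n_min)^(k/n_steps))`, k = 0…n_steps−1
(nearest-integer, half away from zero) — denser at the small end, and
reproducing the canonical 14-value sequence 100…1784 at
(100, 2227, 14). For each (size, replicate) cell a subject subset is
drawn with a seed derived deterministically from (base_seed, size,
replicate) via `SeedSequence` spawn keys, making cells reproducible in
any execution order; the identical subset trains one clock per probe set
(all-EPIC vs autosomal 450K∩EPIC), so per-cell metric differences
isolate the probe-set effect. Both clocks are scored on one fixed test
set.

Learning curves are summarized by GCV smoothing splines — of Fisher-Z
transformed r on size (curve and ±1.96·SE bands back-transformed through
tanh, hence always inside (−1, 1)) and of MAD on size untransformed.
Replicated sizes are collapsed to weighted means for the fit (the spline
routine needs strictly increasing x); the band half-width uses the
residual sd divided by √(replicates per size), a normal approximation
that collapses to zero as residual variance vanishes. Fewer than five
distinct sizes fall back to a straight-line fit with a warning.

## Study conditions used by the tests and acceptance script

- Parameter recovery: n = 600, p = 3000, 150 causal CpGs, effect_sd 0.4,
  φ = 50, 80/20 split, α = 0.5, 10-fold CV.
- Platform equivalence: n = 900 (600 train / 300 test), p = 2000, 200
  causal CpGs all in the common set, effect_sd 0.1, sizes
  geometric(50 → 600, 6 steps), 5 replicates, `n_lambda = 50` for the 60
  repeated fits (a coarser path is ample at these sizes).
- Group shift: n = 1600 (half train, half test), shift 0.5 y, ~400 per
  group in the test half.

These sizes keep the full suite within a few minutes on one CPU while
leaving the statistical conclusions stable across seeds.

## Known limitations

- The solver handles dense matrices only; at real array scale
  (p ≈ 8·10⁵) training is memory-bound (~10 GB at n ≈ 2000 in float64)
  and would benefit from screening rules not implemented here.
- GCV smoothing of heavily tied x values relies on the weighted-mean
  collapse; alternative penalized-regression-spline bases (e.g. REML
  smoothing) are not provided.
- The spline CI bands are a normal approximation ignoring smoothing
  bias; they match the constant-fit limit exactly but are approximate in
  curved regions.
- The coefficient-file dialect (CSV, `CpG,Coefficient`, `(Intercept)`
  token) is the conventional penalized-regression export; other layouts
  must be converted before loading.
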