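# Methods

This note documents the statistical machinery implemented in `eventconn`,
the assumptions behind each stage, the design decisions taken where the
procedure was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Event boundaries and transition vectors

Observer annotations (key presses while watching the movie) are clustered by
single linkage: sorted onsets chain into one candidate whenever successive
onsets are within `merge_tolerance_s` (default one TR, 2.47 s). A candidate
is a consensus boundary when the number of *distinct* observers contributing
is at least `ceil(threshold * n_observers)` — with the default 50% of 16
observers, 8 marks keep a candidate and 7 do not. The kept onset is the
cluster mean. The procedure is invariant to record order and observer
relabelling; repeated marks by one observer count once.

Each onset `t` defines a pre-shift transition window
`[t − w·TR, t + w·TR]` with half-width `w = 2` TRs; the applied window adds
a hemodynamic-lag shift of `+2` TRs (~5 s at TR = 2.47 s). A volume is
coded 1 when its acquisition time `i·TR` lies in the **half-open** applied
window `[start, end)`. The half-open convention makes the window arithmetic
exactly representable and independent of evaluation order; one consequence
is that an unclipped window of length `2w·TR` always contains exactly `2w`
volumes. Windows are clipped to the scan; overlapping windows are unioned.

## Nuisance regression and high-pass filtering

The confound design holds exactly 32 columns: the 6 motion parameters plus
mean WM and CSF signals; their backward-difference temporal derivatives
(leading element 0, SPM convention — the differencing scheme is a package
choice); their element-wise squares; and the squared derivatives. High-pass
filtering at `cutoff_hz` (default 0.008 Hz) enters the same GLM as a
discrete-cosine basis with `K = floor(2·n_vols·TR·cutoff)` unit-normalized
columns (K = 7 for 193 volumes at TR = 2.47 s); the constant is excluded
because the GLM carries its own intercept. Cleaning is a single
least-squares projection against `[intercept | confounds | DCT]`, so
filtering and nuisance regression happen simultaneously and the operation
is idempotent. Rank-deficient designs fall back to the minimum-norm
solution with a warning; the residual is unaffected.

## Autocorrelation model and prewhitening

Residual autocorrelation is modelled as a stationary autocovariance

    acov(lag) = sigma2_white * [lag = 0]  +  sum_h w_h * 0.5^(lag / h)

over the fixed half-life grid h ∈ {0.5, 1, 2, 4, 8, 16, 32, 64} TRs. The
white-noise component corresponds to the model's `residual_variance`; it is
what lets already-white input map to an (approximately) identity whitening
transform. Weights are estimated by nonnegative least squares on the
empirical autocovariance at lags 0..min(n_vols − 1, 128) (biased
estimator), pooled across ROIs into one model per subject (per-ROI fitting
is available by flag). NNLS was chosen over maximum likelihood for
robustness and convexity; the estimator is a package choice.

Whitening works in correlation units (the model autocovariance is
normalized by its lag-0 value, so marginal variance is preserved), adds a
ridge of `1e-6 · acov(0)` at lag 0, and applies the Levinson–Durbin
innovations ("staircase") filter: the output at volume `t` is the
normalized one-step prediction error of the order-`min(t, 128)` linear
predictor. This is exactly multiplication by the inverse Cholesky factor of
the implied Toeplitz covariance (with the AR extension beyond lag 128),
costs O(n·p) instead of O(n³), and is invertible by construction. On
simulated AR(1) input with coefficient 0.5 and 10 000 volumes, whitened
lag-1 autocorrelation is within ±0.03 of zero (see the acceptance suite).

## Boundary metrics

The univariate boundary response defaults to the window-mean contrast:
mean signal over transition volumes minus mean over within-event volumes,
computed on the whitened series. An HRF-based alternative (OLS beta on the
indicator convolved with a canonical double-gamma HRF) is selectable, since
the literature names the quantity but not the estimator. Note that
confound regression and prewhitening attenuate a boxcar-injected amplitude;
generator round-trip guarantees (recovering the injected 0.5) hold for the
metric applied to unprocessed series.

Pairwise coactivation is the interaction coefficient of the logistic model
`transition ~ 1 + z1 + z2 + z1·z2` with both ROI series z-scored before the
product is formed (making the statistic invariant to additive shifts and
symmetric in its arguments). On detected separation or non-convergence the
model is refit with an L2 penalty of 1.0 on the non-intercept coefficients;
the reported SE then comes from the *unpenalized* observed information at
the penalized estimate, and the result is flagged. All R(R−1)/2 pairs are
fit once and mirrored into a symmetric matrix with NaN diagonal.

ROI definition by coactivation uses exhaustive subset search (≤ 20
candidate parcels): the largest candidate subset whose group-mean pairwise
coactivations are all positive among themselves and with the hippocampus,
ties broken toward the larger coactivation sum. Spatial contiguity is *not*
enforced — ROI-level inputs carry no geometry — which is a documented
limitation relative to atlas-based practice. Merged super-regions are
unweighted means of member series.

## Genotype × age models

Genotypes collapse to a two-level factor: ε3/ε4 and ε4/ε4 → "e4+"; ε3/ε3 is
the reference; ε2 carriers are dropped (count logged). Outliers per
dependent variable are residuals from OLS on `[1, age, age²]` falling
strictly outside `[Q1 − 1.5·IQR, Q3 + 1.5·IQR]`; with zero IQR the fences
collapse and nothing is flagged.

The model is OLS of y on

    [1, z(age), z(z(age)^2), group, group·z(age), group·z(z(age)^2)]

with `group` coded 0/1 and all age regressors z-scored on the analysed
(post-outlier) sample. The quadratic term is the square of z-scored age,
itself re-z-scored — not orthogonalized against the linear term — following
the most literal reading of "all regressors z-scored"; an
orthogonal-polynomial variant would change individual term estimates but
not the full-model fit. Per-term inference is a two-tailed t-test with
residual df; p-values are reported uncorrected. Per-group quadratic age
fits are retained for reporting and plotting.

### Bayes factors

Each term's BF₀₁ (evidence for the term-absent model) uses the
Jeffreys–Zellner–Siow setup: a Cauchy prior with scale r = √2/2 on the
standardized effect, equivalently a scaled inverse-gamma mixture of
g-priors. The marginal likelihood is computed from the term's t statistic
and residual df by adaptive quadrature over g. The prior scale is the
package's default, stated prominently because reasonable alternatives
(r = 1, r = √2) shift BF magnitudes; it can be changed per model. A seeded
random-walk Metropolis Savage–Dickey estimator (noncentral-t likelihood,
Gaussian KDE at zero) is available as `method="savage_dickey"` for users
who want an MCMC route; it agrees with the quadrature to sampling error.
Using the marginal t statistic per term is the standard single-coefficient
approximation; it does not integrate over uncertainty in the other terms
jointly.

## Classification

Features are the lower triangle of each subject's coactivation matrix
(row-major, diagonal excluded; column order stable and documented in the
header). The classifier is a linear-kernel SVM (C = 1, scikit-learn)
scored by balanced accuracy — the mean of per-class recalls — on
predictions pooled over stratified k-fold CV (default k = 5); features are
standardized with training-fold statistics only. Kernel, C, scaling and
fold count are package choices where the emulated analysis reports only
"SVM, balanced accuracy, stratified CV". Significance re-runs the entire
CV loop per permuted label vector: p = (1 + #{null ≥ observed}) /
(1 + n_perm), which can never be zero; the default n_perm is 5000.
Balanced accuracy takes discrete values, so the permutation p-value is
mildly conservative when ties with the observed statistic occur; larger
samples make the grid finer.

## System segregation

After global signal regression (per-ROI residual against the mean-over-ROIs
series and an intercept), whole-scan Pearson correlations feed

    SyS = (mean_within − mean_between) / mean_within

where means are over unordered same-network / cross-network ROI pairs. Raw
correlations are averaged, negatives retained; Fisher-z averaging and
negative clipping are exposed as toggles since the canonical computation
leaves these details open. When `mean_within ≤ 0` the ratio is undefined
and the result is flagged rather than fabricated. Note GSR forces the
average pairwise correlation toward a negative value; with few ROIs and no
modular structure, undefined SyS is the *expected* outcome, so segregation
analyses on synthetic data should use a partition plus a positive
`within_rho_gap` (see below) and enough ROIs.

## Synthetic-data generator

`SimConfig` defaults encode the emulated design: 425 subjects, ages uniform
on [18, 88] (uniform keeps leverage for the quadratic term stable across
the range), genotype frequencies 291:126:8:74 over ε3/ε3, ε3/ε4, ε4/ε4 and
ε2 carriers (the ε2 fraction exercises the exclusion path), 193 volumes at
TR = 2.47 s, 12 boundary onsets spread over the scan, and 16 annotating
observers. Per subject, the ROI signal is

* a boundary-locked boxcar over the lag-shifted transition window (HRF
  convolution optional) with amplitude
  `boundary_amplitude + age_slope_linear·z_age + age_slope_quadratic·z_age² + genotype_effect·[ε4+]`
  — defaults 0.5, −0.1, −0.05, 0 in units of the noise SD;
* AR(1) noise (coefficient 0.3 by default) whose innovations are
  cross-ROI correlated: `boundary_coact_rho` (0.3) inside transition
  windows, `baseline_rho` (0.1) elsewhere, optionally with a
  `within_rho_gap` added for same-network pairs to create modular
  structure;
* small random linear combinations of 8 smoothed random-walk confound
  sources (6 "motion" + "WM" + "CSF"), weights within ±0.3 noise SD, so
  confound cleaning is measurable but not dominant.

Where the emulated study reports no numeric value (noise level, effect
sizes, boundary spacing), defaults are one-time choices of plausible
magnitudes, not calibrations to real data. The generator does **not**
emulate voxel-space structure, scanner drift beyond AR(1)+confounds,
HRF variability, annotator reaction-time bias, or genotype-age frequency
dependence; passing tests therefore demonstrate statistical correctness of
the pipeline, not performance on real acquisitions. Determinism: a fixed
`SimConfig.seed` drives cohort, annotations and per-subject child seeds, so
identical configurations are bit-identical.

Note the AR(1) filter is applied after the state-dependent cross-ROI
mixing, so the instantaneous correlation contrast between transition and
within-event volumes is slightly smeared across neighbouring volumes; with
the default coefficient 0.3 the injected coactivation contrast remains
recoverable (see the round-trip tests).

## Problem sizes in the test suite

Monte-Carlo checks run at sizes chosen to balance statistical resolution
against a single-CPU run: type-I calibration uses 1000 null replicates at
n = 400; permutation uniformity uses 500 replicates of 199 permutations
with 100 subjects × 6 features and 3 folds (3 folds rather than 5 keeps the
SVM count tractable; 100 subjects keeps the balanced-accuracy grid fine
enough that tie-induced conservativeness stays small); the end-to-end null
check runs 20 pipeline replicates at n = 400 with the genotype effect at
zero. All are seeded and deterministic.

## Known limitations

* Single-coefficient JZS BFs from marginal t statistics, not joint
  model-comparison BFs over all terms.
* No spatial information anywhere: contiguity cannot be enforced in ROI
  selection, and nothing voxel-level is modelled.
* The whitening filter assumes stationarity and truncates the
  autocovariance at 128 lags (AR-extended beyond).
* The pipeline's segregation stage is only meaningful when the simulated
  correlation structure is modular; with the default 4-ROI configuration
  SyS after GSR is usually undefined and is flagged as such.
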