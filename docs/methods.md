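# Methods

This note records the statistical model, the numerical choices, and the
limits of what the synthetic experiments demonstrate.

## Observation model

Daily fire counts are log-transformed (optionally with a +1 offset when
zero-count days occur, e.g. for sparse anthrome groups) and modelled as

Y_t = M_t + X_t, with mean function
M_t = a0 + a1·t + Σᵢ [cᵢ cos(ωᵢ t) + dᵢ sin(ωᵢ t)], i = 1..6,
and X_t a zero-mean stationary Gaussian AR(7) process.

The six angular frequencies are the annual cycle 2π/365 with its first
three harmonics (6-, 4- and 3-month cycles, reflecting hemispheric fire
seasons) and the 7-day and 3.5-day cycles (the anthropogenic weekly
signal and its first harmonic).  The time index is 1-based with t = 1 the
first Monday of the week-trimmed series; weekdays are numbered 1 = Monday
… 7 = Sunday from the proleptic Gregorian calendar.  The period basis is
365 days: leap days stay in the series and the resulting phase drift
(≈2.5 days over a decade) is accepted.

## Spectral identification

The periodogram I(ω_j) = |Σ_t (y_t − ȳ) e^(−i t ω_j)|²/n is evaluated at
the Fourier frequencies ω_j = 2πj/n, j = 1..⌊(n−1)/2⌋, and satisfies the
Parseval identity 2ΣI = Σ(y−ȳ)² (Nyquist counted once for even n; checked
to 1e−6 relative in the tests).

Fisher's g-test rejects white noise when g = max I / Σ I is large; the
exact null p-value Σ_j (−1)^(j−1) C(m,j)(1−jg)^(m−1) is evaluated in
log-gamma space so it remains usable at m ≈ 1800 ordinates.  Deep in the
non-significant regime (g within a small multiple of its minimum 1/m) the
alternating series is numerically unstable; there the p-value is 1 to
working precision and is returned as such.  Whittle's test is implemented
as sequential Fisher testing: the r-th largest ordinate is tested with
the r−1 larger ones removed and m reduced accordingly, stopping at the
first non-significant rank.  Ordinate ties (to one part in 1e9) are
broken toward the lower frequency so the procedure is invariant to the
order of equal-amplitude peaks.

`detect_cycles` alternates sequential testing with harmonic
de-seasonalization at everything detected so far (two rounds by
default).  Detections within one Fourier bin (2π/n) of a nominal
frequency are snapped to it for reporting, while the regression always
uses the exact nominal frequencies; nominal frequencies such as 2π/365
are not Fourier frequencies of n = 3675, so their power leaks into
neighbouring bins, and snapping plus de-seasonalization at the exact
frequency removes the leakage in the next round.  The default detection
level is α = 0.01.  Because the Fisher null is white noise, an
autocorrelated series produces spuriously significant low-frequency
ordinates; these extra detections are harmless for the weekly-cycle
question (the tests verify that the 7-day bin's false-positive rate on
pure AR(7) noise stays at the nominal level) but users should not
over-interpret isolated low-frequency detections.

## Inference

The fit is empirical-Bayes rather than fully Bayesian: conditional on AR
parameters (φ, σ_Z), the fixed-effect posterior is the exact conjugate
Gaussian posterior computed on the AR-whitened response and design, with
prior precision 0.001 on every coefficient and a flat prior on a0
(per-coefficient overrides are available).  Whitening uses the
conditional likelihood — the first p rows are dropped — which at n = 3675
differs negligibly from the exact initial-state likelihood.  The AR
parameters are Burg plug-in estimates refitted on the posterior-mean
residuals, iterated to a fixed point (tolerance 1e−4 on the
coefficients, then one final posterior update so the reported posterior
and AR parameters are mutually consistent).  Burg estimates are
stationary by construction.  σ_Z is a plug-in with no inverse-gamma
layer, so posterior spreads are slightly optimistic; the coverage
simulations quantify this (harmonic-coefficient interval coverage ≈
0.93–0.95 at nominal 0.95, and the band's revalidated joint coverage sits
in [0.94, 0.96]).

AR order selection minimizes AIC over Burg fits of order 0..14.  AIC's
asymptotic overfitting probability (~0.3 with several surplus candidate
orders) means the selected order for a true AR(7) is exactly 7 in about
60 % of replicates and within ±1 in about 70 %; this is a property of
AIC, not of the implementation, and order 7 is the modal choice.

## Simultaneous band and weekday comparison

The posterior of M_t on the report window (default the first 364 days —
one year of whole weeks, justified because the trend is negligible and
M_t is cyclic) is multivariate normal with mean D β̂ and covariance
S = D Σ Dᵀ (rank ≤ 14).  Monte-Carlo draws use an eigenvalue factor of S
with negative eigenvalues beyond −1e−8·scale rejected and null
directions dropped, which handles the rank deficiency exactly and makes
a 10⁵-sample band search run in about a second.  One common set of
standardized maxima serves every candidate z, so the estimated coverage
is monotone in z and bisection between the pointwise multiplier
Φ⁻¹(1−α/2) and the Bonferroni multiplier Φ⁻¹(1−α/(2d)) is guaranteed to
bracket; the search stops when the estimated coverage is within 0.002 of
1−α.  The band used for weekday comparison is built on the full
364-component window and then partitioned; this is why Sunday's own
membership probability exceeds 1−α.  A per-weekday (52-component) band
can be requested instead by building the band on a weekday sub-posterior.

Membership and exceedance probabilities are plain seeded Monte Carlo
(default 10⁵ samples) with the binomial standard error reported;
zero-variance components are resolved deterministically from the mean,
and exact ties in the exceedance event count as "not above"
(measure-zero under the Gaussian posterior).  In dimensions ≤ 3 the
estimates are cross-checked against quadrature in the test suite.

One structural property worth knowing: the comparison aligns weekday i's
value in week w with Sunday's band in the same week, i.e. at a time up to
6 days later.  The annual harmonics change across those days, so even
with no weekly effect at all the membership probability decays with the
distance from Sunday (Monday lowest, Saturday highest).  The published
global table shows the same gradient.  Null behaviour should therefore be
judged by the identity of the minimum weekday (uniform over the seven
days under the null — verified by a chi-square test over 70 replicates),
not by flat membership tables.

The strongest-cycle window sharpens a qualitative rule: per week w,
count the non-Sunday weekdays whose estimated mean exceeds Sunday's upper
band; report the longest run of consecutive weeks with at least
`threshold_days` (default 1) such weekdays, ties to the earliest run,
together with the full weekly profile so stricter readings can be
applied.

## Synthetic data

The generator realizes exactly the model above: linear trend +
six-harmonic mean, optional additive weekday offsets (Monday..Sunday, log
scale), stationary AR(7) noise drawn with a 500-sample burn-in from a
seeded stream, and counts as either rint(exp y) ("round-lognormal") or
Poisson(exp y).  Weekly structure can be planted two ways — through the
weekly harmonics (as the fitted model represents it) or through weekday
offsets (as the scientific claim is stated); both are exercised in the
tests.  Note that a pure Sunday offset is a 7-periodic pattern needing
three weekly harmonics, while the model carries two, so roughly 5/7 of a
planted Sunday deficit appears in the fitted mean function and the
remainder is absorbed by the AR noise (visible as a lag-7 component in
the fitted φ).

`global_fire_preset` ships the published posterior means of the global
fit as generator truth (intercept 9.3405, trend −2.37e−5, the twelve
harmonic coefficients).  The AR coefficients and innovation sd were never
published; the preset uses φ = (0.55, 0.08, 0.04, 0.02, 0.01, 0.005,
0.05) and σ_Z = 0.10 — moderate synoptic-scale persistence (lag-1
autocorrelation ≈ 0.65), a mild lag-7 residual component large enough for
AR-order identification, and a marginal residual spread σ_X ≈ 0.13 on
the log scale — chosen once as a realistic noise process for a global
daily aggregate and clearly non-published values.

Fire-record sets place each group's daily counts uniformly at random
inside the group's raster cells, with cosmetic satellite/overpass-time
fields.  The generator does not emulate spatial clustering of fires,
overpass gaps or cloud obscuration, detection-confidence structure, or
non-stationary fire regimes; passing tests therefore demonstrate the
correctness and calibration of the statistical machinery under the
model's own assumptions, not robustness to the real product's artefacts.

## Problem sizes

The simulation studies use the study-scale series length n = 3675
(525 weeks) with 50 replicates for coefficient coverage, 20 for the
end-to-end Sunday-deficit detection (band and table Monte Carlo at
5×10⁴ samples there, 10⁵ elsewhere), 70 for null minimum-weekday
uniformity, 200 for the weekly-bin false-positive rate, and 500
white-noise series for the test-size check — sizes at which every check
runs in seconds while keeping Monte-Carlo error well below the margins
being asserted.

## Known limitations

* Plug-in (φ, σ_Z) understates posterior spread slightly; fully Bayesian
  AR treatment (e.g. penalised-complexity priors on partial
  autocorrelations) is an extension point.
* Fisher/Whittle assume a white null; on strongly autocorrelated series
  the sequential procedure yields extra low-frequency detections.
* Day boundaries are taken from the record acquisition date as written
  (UTC); no local-solar-time correction is applied.
* The false-alarm screening of the real product is not reproducible from
  the published description; `screen_records` exposes the standard
  type/confidence filters instead.
* Real-archive headline numbers (the fixed-effects table and the global
  probability tables) depend on the 43.4-million-record archive and are
  not reproducible at desk scale; the package accepts real files for
  users who obtain them.
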