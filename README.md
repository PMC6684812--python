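# firecycles

Detection of weekly cycles in daily vegetation-fire counts.

Seven-day periodicities in environmental time series are very unlikely to
arise from natural forcing, so a weekly cycle in global fire activity is a
fingerprint of human agency (days of rest imposed by labour law and
religion).  `firecycles` implements the full statistical pipeline for
testing this hypothesis on daily active-fire detection counts, stratified
by anthropogenic biome ("anthrome": Settlements, Villages, Croplands,
Rangelands, Seminatural, Wildlands), together with a synthetic-data module
that makes every stage testable without the multi-gigabyte satellite
archive.

It is intended for fire scientists and statisticians who want to (a) run
the analysis on real MCD14ML-style active-fire files and an anthrome class
raster, or (b) study the behaviour of the method itself under controlled
synthetic conditions.

## The model

The log of the daily fire count is modelled as

```
Y_t = M_t + X_t,                       t = 1, ..., n
M_t = a0 + a1 t + Σ_{i=1}^{6} [c_i cos(ω_i t) + d_i sin(ω_i t)]
X_t = Σ_{i=1}^{7} φ_i X_{t−i} + Z_t,   Z_t ~ N(0, σ_Z²)
```

with angular frequencies ω_i for the annual cycle and its first three
harmonics plus the 7-day and 3.5-day cycles.  The candidate frequencies
are identified from the periodogram with Fisher's exact g-test and
Whittle's sequential extension, alternating with harmonic
de-seasonalization.  The fixed effects carry independent N(0, precision
0.001) priors (flat on a0); the AR(7) noise parameters are plugged in by
Burg estimation, giving an exact conjugate multivariate-normal posterior
for the coefficient vector and hence for the mean function M_t.

Weekday comparison follows the simultaneous-band construction: pointwise
HPD intervals `M̂_t ± z √S_tt` with z tuned by Monte Carlo so the joint
probability that the whole mean-function vector lies inside is 1−α
(default 0.95).  The posterior of M_t over the first 52 weeks is
partitioned into the seven interleaved weekday sub-series t_i = i, i+7, …
(1 = Monday, 7 = Sunday), and two tables are computed per series:

* **membership** — P(LB_Sunday ≤ M_{t_i} ≤ UB_Sunday), the probability
  that weekday i's mean function lies inside Sunday's band, and
* **exceedance** — P(M_{t_i} > M̂_Sunday componentwise).

Small membership and large exceedance probabilities for Monday–Saturday
are evidence that Sunday is the weekly minimum of fire activity.

## Worked example

Simulate ten years of daily counts from the shipped preset (coefficients
mirroring the published global fit) with a planted Sunday deficit of
−0.10 log units (≈ 9.5 % fewer fires on Sundays), fit the model, and test
for the Sunday minimum:

```python
import firecycles as fc

spec = fc.global_fire_preset(seed=11, weekday_offsets=(0.0,)*6 + (-0.10,))
counts = fc.simulate_count_series(spec)
logs = fc.log_transform(counts)

fit = fc.fit_bayes_harmonic_ar(logs)
mfp = fc.mean_function_posterior(fit)                  # first 52 weeks
band = fc.simultaneous_band(mfp, alpha=0.05, seed=5)
part = fc.partition_by_weekday(mfp, band)
membership = fc.membership_table(part, seed=7)

print(f"z = {band.z:.3f}, gamma = {band.gamma:.5f}")
print(membership.table.round(4))
```

Output:

```
z = 3.118, gamma = 0.00182
           estimate  mc_error
Monday       0.0000    0.0000
Tuesday      0.0000    0.0000
Wednesday    0.0000    0.0000
Thursday     0.0000    0.0000
Friday       0.0000    0.0000
Saturday     0.0001    0.0000
Sunday       0.9693    0.0005
```

The half-width multiplier z = 3.118 makes the 364 pointwise intervals a
joint 95 % band (each pointwise interval is at level 1−γ ≈ 99.8 %).
Monday–Saturday have essentially zero probability of lying inside
Sunday's band — their mean functions sit above it — while Sunday's own
sub-vector is inside with probability 0.97 (slightly above 0.95, as a
sub-vector of the jointly covered full vector must be).  That is the
signature of a weekly cycle with a Sunday minimum.

The same pipeline runs from the shell:

```sh
firecycles simulate --seed 3 --out sim --sunday-offset=-0.1
firecycles run --fires sim/fires.txt --anthrome-grid sim/anthromes.asc --out results
```

which writes the share table, the fixed-effects summary, the global and
per-anthrome membership/exceedance tables, the band, the strongest-cycle
window and a run manifest as CSV/JSON.

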