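"""Simultaneous credible bands and rectangle/exceedance probabilities for
Gaussian mean-function posteriors.

A simultaneous band at joint level 1−α is the hyper-rectangle of pointwise
HPD intervals M̂_t ± z·√S_tt whose common multiplier z is tuned until the
joint probability that the whole vector lies inside is 1−α; for Gaussian
marginals the pointwise level is 1−γ with γ = 2(1−Φ(z)).  Probabilities
are plain Monte-Carlo estimates over a low-rank factor of the posterior
covariance, with the binomial standard error reported alongside; common
random numbers across the z search make the estimated coverage monotone
in z, so bisection between the pointwise and Bonferroni multipliers is
guaranteed to bracket the solution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import MeanFunctionPosterior

__all__ = [
    "CredibleBand",
    "ProbabilityEstimate",
    "exceedance_probability",
    "interval_probability",
    "simultaneous_band",
]

_MC_CHUNK = 20_000


@dataclass(frozen=True)
class ProbabilityEstimate:
    """A Monte-Carlo probability with its binomial standard error."""

    estimate: float
    se: float
    n_mc: int
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.estimate <= 1.0):
            raise ValueError("estimate must lie in [0, 1]")


@dataclass(frozen=True)
class CredibleBand:
    """A simultaneous credible band LB_t .. UB_t at joint level 1−alpha."""

    alpha: float
    gamma: float
    z: float
    lower: np.ndarray
    upper: np.ndarray
    n_mc: int
    seed: int | None
    coverage: float  # achieved Monte-Carlo joint coverage at z

    def __post_init__(self) -> None:
        object.__setattr__(self, "lower", np.asarray(self.lower, dtype=float))
        object.__setattr__(self, "upper", np.asarray(self.upper, dtype=float))
        if np.any(self.lower > self.upper):
            raise ValueError("lower band above upper band")

    def to_frame(self, mfp: MeanFunctionPosterior) -> pd.DataFrame:
        dates = mfp.dates()
        return pd.DataFrame(
            {
                "t": mfp.t,
                "date": dates.strftime("%Y-%m-%d") if dates is not None else "",
                "mean": mfp.mean,
                "lower": self.lower,
                "upper": self.upper,
            }
        )


def _psd_factor(cov: np.ndarray) -> np.ndarray:
    """Factor F with F F' = cov for a PSD matrix, dropping null directions.

    Small negative eigenvalues from finite precision are clipped; genuinely
    negative eigenvalues (beyond jitter scale) are an error.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    vals, vecs = np.linalg.eigh((cov + cov.T) / 2)
    scale = max(float(vals.max(initial=0.0)), 1.0)
    if vals.min(initial=0.0) < -1e-8 * scale - 1e-10:
        raise ValueError("covariance matrix is not positive semi-definite")
    keep = vals > 1e-12 * scale
    return vecs[:, keep] * np.sqrt(vals[keep])


def _max_abs_standardized(
    cov: np.ndarray, sd: np.ndarray, n_mc: int, rng: np.random.Generator
) -> np.ndarray:
    """Per-sample max_t |X_t|/sd_t for X ~ N(0, cov), over components with sd > 0."""
    F = _psd_factor(cov)
    pos = sd > 0
    Fp = F[pos] / sd[pos, None]
    out = np.empty(n_mc)
    done = 0
    while done < n_mc:
        c = min(_MC_CHUNK, n_mc - done)
        Z = rng.standard_normal((c, F.shape[1]))
        out[done : done + c] = np.abs(Z @ Fp.T).max(axis=1)
        done += c
    return out


def simultaneous_band(
    mfp: MeanFunctionPosterior,
    alpha: float = 0.05,
    n_mc: int = 100_000,
    seed: int | None = None,
    tol: float = 0.002,
) -> CredibleBand:
    """Tune the half-width multiplier z so the joint coverage of M̂ ± z·√S_tt is 1−α.

    Uses one set of Monte-Carlo draws for every candidate z (common random
    numbers), and bisects z between the pointwise multiplier Φ⁻¹(1−α/2) and
    the Bonferroni multiplier Φ⁻¹(1−α/(2d)).
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    sd = np.sqrt(np.clip(np.diag(mfp.cov), 0.0, None))
    d = int(np.count_nonzero(sd > 0))
    target = 1.0 - alpha
    z_lo = float(norm.ppf(1 - alpha / 2))
    if d == 0:
        return CredibleBand(alpha, alpha, z_lo, mfp.mean, mfp.mean, 0, seed, 1.0)

    rng = np.random.default_rng(seed)
    m = _max_abs_standardized(mfp.cov, sd, n_mc, rng)

    def coverage(z: float) -> float:
        return float(np.mean(m <= z))

    z_hi = float(norm.ppf(1 - alpha / (2 * d)))
    if coverage(z_lo) >= target:
        z = z_lo
    elif coverage(z_hi) <= target:
        z = z_hi
    else:
        lo, hi = z_lo, z_hi
        z = (lo + hi) / 2
        for _ in range(200):
            z = (lo + hi) / 2
            c = coverage(z)
            if abs(c - target) <= tol or hi - lo < 1e-9:
                break
            if c < target:
                lo = z
            else:
                hi = z
    cov_z = coverage(z)
    gamma = float(2 * (1 - norm.cdf(z)))
    return CredibleBand(
        alpha=alpha,
        gamma=gamma,
        z=float(z),
        lower=mfp.mean - z * sd,
        upper=mfp.mean + z * sd,
        n_mc=n_mc,
        seed=seed,
        coverage=cov_z,
    )


def _mc_event_probability(
    mean: np.ndarray,
    cov: np.ndarray,
    event,
    deterministic_ok: bool,
    n_mc: int,
    seed: int | None,
) -> ProbabilityEstimate:
    if not deterministic_ok:
        return ProbabilityEstimate(0.0, 0.0, n_mc, seed)
    F = _psd_factor(cov)
    if F.shape[1] == 0:
        # fully degenerate posterior: the event is decided by the mean alone
        return ProbabilityEstimate(1.0, 0.0, n_mc, seed)
    rng = np.random.default_rng(seed)
    hits = 0
    done = 0
    while done < n_mc:
        c = min(_MC_CHUNK, n_mc - done)
        X = mean + rng.standard_normal((c, F.shape[1])) @ F.T
        hits += int(event(X).sum())
        done += c
    p = hits / n_mc
    se = float(np.sqrt(p * (1 - p) / n_mc))
    return ProbabilityEstimate(float(p), se, n_mc, seed)


def interval_probability(
    mean: np.ndarray,
    cov: np.ndarray,
    lower: np.ndarray,
    upper: np.ndarray,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> ProbabilityEstimate:
    """Monte-Carlo estimate of P(lower <= X <= upper componentwise), X ~ MVN(mean, cov).

    Zero-variance components are resolved deterministically from the mean."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if not (mean.shape == lower.shape == upper.shape) or cov.shape != (len(mean), len(mean)):
        raise ValueError("dimension mismatch between mean, covariance and bounds")
    if np.any(lower > upper):
        raise ValueError("lower bound exceeds upper bound")
    var = np.clip(np.diag(cov), 0.0, None)
    fixed = var <= 0
    ok = bool(np.all((mean[fixed] >= lower[fixed]) & (mean[fixed] <= upper[fixed])))
    free = ~fixed
    if not np.any(free):
        return ProbabilityEstimate(1.0 if ok else 0.0, 0.0, n_mc, seed)
    sub = np.ix_(free, free)
    lo, up = lower[free], upper[free]
    return _mc_event_probability(
        mean[free],
        cov[sub],
        lambda X: np.all((X >= lo) & (X <= up), axis=1),
        ok,
        n_mc,
        seed,
    )


def exceedance_probability(
    mean: np.ndarray,
    cov: np.ndarray,
    threshold: np.ndarray,
    n_mc: int = 100_000,
    seed: int | None = None,
) -> ProbabilityEstimate:
    """Monte-Carlo estimate of P(X_t > threshold_t for all t), X ~ MVN(mean, cov).

    The inequality is strict: an exact tie counts as not above."""
    mean = np.asarray(mean, dtype=float)
    cov = np.asarray(cov, dtype=float)
    threshold = np.asarray(threshold, dtype=float)
    if mean.shape != threshold.shape or cov.shape != (len(mean), len(mean)):
        raise ValueError("dimension mismatch between mean, covariance and threshold")
    var = np.clip(np.diag(cov), 0.0, None)
    fixed = var <= 0
    ok = bool(np.all(mean[fixed] > threshold[fixed]))
    free = ~fixed
    if not np.any(free):
        return ProbabilityEstimate(1.0 if ok else 0.0, 0.0, n_mc, seed)
    sub = np.ix_(free, free)
    thr = threshold[free]
    return _mc_event_probability(
        mean[free],
        cov[sub],
        lambda X: np.all(X > thr, axis=1),
        ok,
        n_mc,
        seed,
    )
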