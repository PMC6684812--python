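"""Bayesian harmonic regression with autoregressive errors.

The observation model for the log count series is

    Y_t = M_t + X_t,
    M_t = a0 + a1 t + sum_i [c_i cos(w_i t) + d_i sin(w_i t)],
    X_t = sum_{i=1}^{p} phi_i X_{t-i} + Z_t,

with Z_t Gaussian white noise.  The fixed effects carry independent
zero-mean normal priors (precision 0.001 by default) and a flat prior on
the intercept.  Inference is empirical-Bayes: Burg plug-in estimates of
the AR parameters alternate with the exact conjugate Gaussian posterior of
the fixed effects computed on the AR-whitened response and design
(conditional likelihood: the first p rows are dropped).  The quantity the
downstream analysis consumes is the multivariate-normal posterior of the
mean function M_t, which this construction yields exactly conditional on
the plug-in AR parameters.
"""

from __future__ import annotations

import datetime as dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import norm
from statsmodels.regression.linear_model import burg as _burg

from .spectral import FrequencySet, LogCountSeries, _harmonic_design

__all__ = [
    "ARParams",
    "CoefficientPosterior",
    "MeanFunctionPosterior",
    "ModelFit",
    "PriorSpec",
    "build_design",
    "fit_ar",
    "fit_bayes_harmonic_ar",
    "mean_function_posterior",
    "select_ar_order",
    "summarize_fixed_effects",
]


@dataclass(frozen=True)
class ARParams:
    """Stationary AR(p) noise parameters, p <= 7."""

    coefficients: tuple[float, ...]
    innovation_sd: float

    def __post_init__(self) -> None:
        if self.innovation_sd <= 0:
            raise ValueError("innovation_sd must be positive")
        phi = np.asarray(self.coefficients, dtype=float)
        if phi.size and phi.any():
            roots = np.roots(np.r_[1.0, -phi])
            if np.any(np.abs(roots) >= 1.0):
                raise ValueError("AR coefficients are non-stationary")

    @property
    def order(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class PriorSpec:
    """Independent normal priors on the fixed effects.

    ``precision`` applies to every coefficient except the intercept when
    ``intercept_flat``; ``precision_overrides`` maps coefficient names
    (``a0``, ``a1``, ``c1`` ...) to individual precisions.
    """

    precision: float = 0.001
    intercept_flat: bool = True
    precision_overrides: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValueError("precision must be >= 0")

    def precision_vector(self, names: Sequence[str]) -> np.ndarray:
        overrides = dict(self.precision_overrides)
        prec = np.full(len(names), self.precision, dtype=float)
        if self.intercept_flat and "a0" not in overrides:
            prec[list(names).index("a0")] = 0.0
        for name, value in overrides.items():
            prec[list(names).index(name)] = value
        return prec


@dataclass(frozen=True)
class CoefficientPosterior:
    """Gaussian posterior of the fixed effects (a0, a1, c_1, d_1, ..., c_k, d_k)."""

    names: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if cov.shape != (len(mean), len(mean)) or len(self.names) != len(mean):
            raise ValueError("dimension mismatch in coefficient posterior")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("posterior covariance must be symmetric")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", (cov + cov.T) / 2)


@dataclass(frozen=True)
class MeanFunctionPosterior:
    """Multivariate-normal posterior of the mean function on a time window."""

    t: np.ndarray
    mean: np.ndarray
    cov: np.ndarray
    start_date: dt.date | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t, dtype=int)
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.cov, dtype=float)
        if len(t) != len(mean) or cov.shape != (len(t), len(t)):
            raise ValueError("dimension mismatch in mean-function posterior")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "cov", (cov + cov.T) / 2)

    def __len__(self) -> int:
        return len(self.t)

    def dates(self) -> pd.DatetimeIndex | None:
        if self.start_date is None:
            return None
        base = pd.Timestamp(self.start_date)
        return base + pd.to_timedelta(self.t - 1, unit="D")


@dataclass(frozen=True)
class ModelFit:
    """Result of the empirical-Bayes harmonic-AR fit."""

    posterior: CoefficientPosterior
    ar: ARParams
    residuals: np.ndarray
    freqs: FrequencySet
    n: int
    converged: bool
    n_iter: int
    start_date: dt.date | None = None
    label: str = ""
    gram_condition: float = float("nan")


def coefficient_names(k: int) -> tuple[str, ...]:
    names = ["a0", "a1"]
    for i in range(1, k + 1):
        names += [f"c{i}", f"d{i}"]
    return tuple(names)


def build_design(n: int, freqs: FrequencySet) -> np.ndarray:
    """Design matrix with columns (1, t, cos w_1 t, sin w_1 t, ...), t = 1..n."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return _harmonic_design(n, list(freqs))


def design_at(t: np.ndarray, freqs: FrequencySet) -> np.ndarray:
    """Design rows evaluated at arbitrary (1-based) time indices."""
    t = np.asarray(t, dtype=float)
    cols = [np.ones_like(t), t]
    for w in freqs:
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    return np.column_stack(cols)


def fit_ar(residuals: np.ndarray, order: int) -> ARParams:
    """Burg-method AR fit; the innovation sd comes from the final prediction-error
    variance.  Burg estimates are stationary by construction."""
    residuals = np.asarray(residuals, dtype=float)
    if order < 0:
        raise ValueError("order must be >= 0")
    if np.var(residuals) <= 0:
        raise ValueError("residuals have zero variance; AR fit is degenerate")
    if order == 0:
        return ARParams(coefficients=(), innovation_sd=float(np.std(residuals)))
    if len(residuals) <= 10 * order:
        raise ValueError("need more than 10*order residuals for a stable AR fit")
    phi, sigma2 = _burg(residuals, order=order, demean=True)
    return ARParams(coefficients=tuple(float(p) for p in phi), innovation_sd=float(np.sqrt(sigma2)))


def select_ar_order(residuals: np.ndarray, max_order: int = 14) -> int:
    """AR order minimizing AIC over 0..max_order using Burg fits."""
    residuals = np.asarray(residuals, dtype=float)
    n = len(residuals)
    best_order, best_aic = 0, n * np.log(np.var(residuals)) + 2.0
    for p in range(1, max_order + 1):
        if n <= 10 * p:
            break
        _, sigma2 = _burg(residuals, order=p, demean=True)
        aic = n * np.log(sigma2) + 2.0 * (p + 1)
        if aic < best_aic:
            best_order, best_aic = p, aic
    return best_order


def _whiten(y: np.ndarray, X: np.ndarray, ar: ARParams) -> tuple[np.ndarray, np.ndarray]:
    p = ar.order
    if p == 0:
        return y, X
    phi = np.asarray(ar.coefficients)
    n = len(y)
    yw = y[p:].copy()
    Xw = X[p:].copy()
    for i, f in enumerate(phi, start=1):
        yw -= f * y[p - i : n - i]
        Xw -= f * X[p - i : n - i]
    return yw, Xw


def fit_bayes_harmonic_ar(
    series: LogCountSeries,
    freqs: FrequencySet | None = None,
    ar_order: int = 7,
    priors: PriorSpec | None = None,
    max_iter: int = 20,
    tol: float = 1e-4,
) -> ModelFit:
    """Fit the harmonic regression with AR errors by empirical-Bayes iteration.

    Alternates (1) the conjugate Gaussian posterior of the fixed effects
    under the current AR parameters (whitened conditional likelihood) and
    (2) a Burg refit of the AR parameters on the posterior-mean residuals,
    until the AR coefficients move less than ``tol``.  Non-convergence
    returns the current state with a warning and ``converged=False``.
    """
    freqs = FrequencySet.default() if freqs is None else freqs
    priors = PriorSpec() if priors is None else priors
    n = len(series)
    k = len(freqs)
    n_coef = 2 + 2 * k
    if n <= n_coef + ar_order + 10:
        raise ValueError("series too short for the requested model")

    y = series.values
    X = build_design(n, freqs)
    names = coefficient_names(k)
    prec = priors.precision_vector(names)

    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    ar = fit_ar(y - X @ coef, ar_order)
    mean = coef
    cov = np.eye(n_coef)
    converged = False
    n_iter = 0
    cond = float("nan")
    for n_iter in range(1, max_iter + 1):
        yw, Xw = _whiten(y, X, ar)
        sigma2 = ar.innovation_sd**2
        gram = Xw.T @ Xw
        cond = float(np.linalg.cond(gram))
        A = gram / sigma2 + np.diag(prec)
        c, low = cho_factor(A)
        cov = cho_solve((c, low), np.eye(n_coef))
        mean = cho_solve((c, low), Xw.T @ yw / sigma2)
        new_ar = fit_ar(y - X @ mean, ar_order)
        delta = (
            max(abs(a - b) for a, b in zip(new_ar.coefficients, ar.coefficients))
            if ar_order
            else 0.0
        )
        ar = new_ar
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"AR coefficients did not converge within {max_iter} iterations", RuntimeWarning
        )

    # final posterior update so the reported posterior matches the reported AR params
    yw, Xw = _whiten(y, X, ar)
    sigma2 = ar.innovation_sd**2
    gram = Xw.T @ Xw
    cond = float(np.linalg.cond(gram))
    A = gram / sigma2 + np.diag(prec)
    c, low = cho_factor(A)
    cov = cho_solve((c, low), np.eye(n_coef))
    mean = cho_solve((c, low), Xw.T @ yw / sigma2)

    posterior = CoefficientPosterior(names=names, mean=mean, cov=(cov + cov.T) / 2)
    return ModelFit(
        posterior=posterior,
        ar=ar,
        residuals=y - X @ mean,
        freqs=freqs,
        n=n,
        converged=converged,
        n_iter=n_iter,
        start_date=series.start_date,
        label=series.label,
        gram_condition=cond,
    )


def summarize_fixed_effects(fit: ModelFit) -> pd.DataFrame:
    """Gaussian marginal summaries of the fixed effects.

    Columns match the conventional posterior-summary layout (mean, sd,
    0.025/0.5/0.975 quantiles, mode); for Gaussian marginals the mode and
    median equal the mean.  A coefficient is significant when 0 lies
    outside its central 95% interval.
    """
    mean = fit.posterior.mean
    sd = np.sqrt(np.clip(np.diag(fit.posterior.cov), 0.0, None))
    z = norm.ppf(0.975)
    lo, hi = mean - z * sd, mean + z * sd
    return pd.DataFrame(
        {
            "mean": mean,
            "sd": sd,
            "0.025quant": lo,
            "0.5quant": mean,
            "0.975quant": hi,
            "mode": mean,
            "significant": (lo > 0) | (hi < 0),
        },
        index=list(fit.posterior.names),
    )


def mean_function_posterior(
    fit: ModelFit, window: np.ndarray | range | None = None
) -> MeanFunctionPosterior:
    """Posterior of M_t on a window of time indices (default the first 364 days).

    mean = D beta_hat, S = D Sigma D' with D the design rows of the window;
    S is symmetrized.  Windows beyond the fitted range extrapolate with a
    warning.
    """
    t = np.arange(1, 365) if window is None else np.asarray(list(window), dtype=int)
    if t.min() < 1:
        raise ValueError("window indices must be >= 1")
    if t.max() > fit.n:
        warnings.warn("window extends beyond the fitted series: extrapolating", RuntimeWarning)
    D = design_at(t, fit.freqs)
    mean = D @ fit.posterior.mean
    S = D @ fit.posterior.cov @ D.T
    return MeanFunctionPosterior(t=t, mean=mean, cov=S, start_date=fit.start_date)


def save_model_fit(fit: ModelFit, path: str | Path) -> None:
    """Serialize a fit as a flat JSON document."""
    doc = {
        "names": list(fit.posterior.names),
        "mean": fit.posterior.mean.tolist(),
        "cov": fit.posterior.cov.tolist(),
        "ar_coefficients": list(fit.ar.coefficients),
        "innovation_sd": fit.ar.innovation_sd,
        "omegas": list(fit.freqs.omegas),
        "n": fit.n,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "start_date": fit.start_date.isoformat() if fit.start_date else None,
        "label": fit.label,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def load_model_fit(path: str | Path) -> ModelFit:
    doc = json.loads(Path(path).read_text())
    return ModelFit(
        posterior=CoefficientPosterior(
            names=tuple(doc["names"]),
            mean=np.asarray(doc["mean"]),
            cov=np.asarray(doc["cov"]),
        ),
        ar=ARParams(tuple(doc["ar_coefficients"]), doc["innovation_sd"]),
        residuals=np.array([]),
        freqs=FrequencySet(tuple(doc["omegas"])),
        n=doc["n"],
        converged=doc["converged"],
        n_iter=doc["n_iter"],
        start_date=dt.date.fromisoformat(doc["start_date"]) if doc["start_date"] else None,
        label=doc.get("label", ""),
    )
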