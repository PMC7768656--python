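"""Parametric machinery for the six-family distribution panel.

Families: Normal and Cauchy (symmetric), Lognormal, Gamma and Pareto
(right-skewed, positive support), plus a two-component-Gaussian Bimodal label
and an Unknown fallback handled upstream.  This module provides the
estimators, closed-form CDFs, the exact Kolmogorov-Smirnov statistic and
seeded samplers; the classification logic lives in :mod:`exprshape.classify`.

Conventions (these matter for reproducibility):

* Gamma is parameterized by (shape k, rate beta); Pareto by (minimum x_m,
  tail index alpha); Lognormal by (log-mean, log-sd); Cauchy by (location,
  scale).
* Sample quantiles use linear interpolation at plotting positions
  (k-1)/(n-1) — numpy's default — because the Cauchy fit, and hence the
  classification of small samples, depends on the convention.
* The Cauchy scale defaults to IQR/2 (the quartiles of a Cauchy sit at
  x0 +/- gamma, so IQR = 2*gamma); ``mode="iqr"`` sets scale = IQR instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import special, stats

__all__ = [
    "Family",
    "FitParams",
    "fit_normal",
    "fit_lognormal",
    "fit_gamma_mle",
    "fit_pareto_mle",
    "fit_cauchy_quantile",
    "family_cdf",
    "ks_statistic",
    "sample_family",
]


class Family(Enum):
    NORMAL = "normal"
    LOGNORMAL = "lognormal"
    CAUCHY = "cauchy"
    GAMMA = "gamma"
    PARETO = "pareto"
    BIMODAL = "bimodal"
    UNKNOWN = "unknown"


#: families whose support is the positive reals (testable only on all-positive data)
POSITIVE_FAMILIES = (Family.LOGNORMAL, Family.GAMMA, Family.PARETO)
#: families with a parametric CDF in this module
FITTABLE_FAMILIES = (
    Family.NORMAL,
    Family.LOGNORMAL,
    Family.CAUCHY,
    Family.GAMMA,
    Family.PARETO,
)


@dataclass(frozen=True)
class FitParams:
    """A fitted family with its ordered parameter tuple."""

    family: Family
    params: tuple[float, ...]

    def __post_init__(self) -> None:
        fam, p = self.family, self.params
        if fam not in FITTABLE_FAMILIES:
            raise ValueError(f"{fam} carries no fit parameters")
        if len(p) != 2:
            raise ValueError(f"{fam.value} takes exactly 2 parameters, got {len(p)}")
        if fam in (Family.NORMAL, Family.LOGNORMAL, Family.CAUCHY) and p[1] <= 0:
            raise ValueError(f"{fam.value} scale/sd must be positive")
        if fam in (Family.GAMMA, Family.PARETO) and (p[0] <= 0 or p[1] <= 0):
            raise ValueError(f"{fam.value} parameters must both be positive")

    def to_dict(self) -> dict:
        return {"family": self.family.value, "params": list(self.params)}


def _as_sample(x, min_n: int) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} observations, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("sample contains non-finite values")
    return x


def fit_normal(x) -> FitParams:
    """Gaussian MLE: sample mean and (population) standard deviation."""
    x = _as_sample(x, 2)
    sd = float(np.std(x))
    if sd == 0:
        raise ValueError("zero variance: normal scale undefined")
    return FitParams(Family.NORMAL, (float(np.mean(x)), sd))


def fit_lognormal(x) -> FitParams:
    """Lognormal MLE: mean and sd of log(x); requires positive data."""
    x = _as_sample(x, 2)
    if np.any(x <= 0):
        raise ValueError("lognormal requires strictly positive data")
    lx = np.log(x)
    sd = float(np.std(lx))
    if sd == 0:
        raise ValueError("zero variance on the log scale")
    return FitParams(Family.LOGNORMAL, (float(np.mean(lx)), sd))


def _gamma_newton(
    mean_x: np.ndarray, var_x: np.ndarray, mean_log_x: np.ndarray
) -> np.ndarray:
    """Newton iteration for the Gamma shape on s = ln(mean) - mean(ln x).

    Initialized at the method-of-moments shape mean^2/var; vectorized over
    independent samples; converges to relative tolerance 1e-10 or stops
    after 100 iterations.
    """
    s = np.log(mean_x) - mean_log_x
    k = np.clip(mean_x**2 / np.clip(var_x, 1e-300, None), 1e-8, 1e12)
    for _ in range(100):
        f = np.log(k) - special.digamma(k) - s
        fprime = 1.0 / k - special.polygamma(1, k)
        step = f / fprime
        new_k = np.clip(k - step, 1e-12, None)
        done = np.abs(new_k - k) <= 1e-10 * np.abs(new_k)
        k = new_k
        if np.all(done):
            break
    return k


def fit_gamma_mle(x) -> FitParams:
    """Gamma MLE (shape k, rate beta) via Newton on the digamma equation."""
    x = _as_sample(x, 3)
    if np.any(x <= 0):
        raise ValueError("gamma requires strictly positive data")
    if np.all(x == x[0]):
        raise ValueError("all values equal: gamma shape diverges")
    k = float(
        _gamma_newton(
            np.array(np.mean(x)), np.array(np.var(x)), np.array(np.mean(np.log(x)))
        )
    )
    return FitParams(Family.GAMMA, (k, k / float(np.mean(x))))


def fit_pareto_mle(x) -> FitParams:
    """Closed-form Pareto MLE: x_m = min(x), alpha = n / sum(ln(x_i/x_m))."""
    x = _as_sample(x, 2)
    if np.any(x <= 0):
        raise ValueError("pareto requires strictly positive data")
    xm = float(np.min(x))
    denom = float(np.sum(np.log(x / xm)))
    if denom == 0:
        raise ValueError("all values equal: pareto index undefined")
    return FitParams(Family.PARETO, (xm, x.size / denom))


def fit_cauchy_quantile(x, mode: str = "half-iqr") -> FitParams:
    """Cauchy fit from robust quantiles: location = median, scale from the IQR."""
    x = _as_sample(x, 4)
    q25, q50, q75 = np.quantile(x, (0.25, 0.5, 0.75))
    iqr = float(q75 - q25)
    if iqr == 0:
        raise ValueError("zero interquartile range: cauchy scale degenerate")
    if mode == "half-iqr":
        scale = iqr / 2.0
    elif mode == "iqr":
        scale = iqr
    else:
        raise ValueError("mode must be 'half-iqr' or 'iqr'")
    return FitParams(Family.CAUCHY, (float(q50), scale))


# ---------------------------------------------------------------------------
# CDFs, KS statistic, samplers.  Closed forms are used so the bootstrap can
# evaluate whole (B x n) matrices at once.
# ---------------------------------------------------------------------------

def _cdf(family: Family, p0, p1, x):
    """CDF with broadcastable parameters (p0/p1 may be column vectors)."""
    if family is Family.NORMAL:
        return special.ndtr((x - p0) / p1)
    if family is Family.LOGNORMAL:
        out = np.zeros(np.broadcast_shapes(np.shape(x), np.shape(p0)))
        pos = x > 0
        lx = np.log(np.where(pos, x, 1.0))
        return np.where(pos, special.ndtr((lx - p0) / p1), out)
    if family is Family.CAUCHY:
        return 0.5 + np.arctan((x - p0) / p1) / np.pi
    if family is Family.GAMMA:
        return special.gammainc(p0, p1 * np.clip(x, 0, None))
    if family is Family.PARETO:
        ratio = np.clip(p0 / np.clip(x, 1e-300, None), None, 1.0)
        return np.where(x >= p0, 1.0 - ratio ** p1, 0.0)
    raise ValueError(f"{family} has no parametric CDF")


def family_cdf(fit: FitParams, x) -> np.ndarray:
    """Evaluate the fitted family's CDF at x."""
    return _cdf(fit.family, fit.params[0], fit.params[1], np.asarray(x, dtype=float))


def ks_statistic(x, fit: FitParams) -> float:
    """Exact two-sided KS statistic sup |F_n - F| for a fitted family.

    Computed over the order statistics as the larger of the two one-sided
    discrepancies at each data point.
    """
    x = np.sort(_as_sample(x, 1))
    n = x.size
    f = family_cdf(fit, x)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f)
    d_minus = np.max(f - (i - 1) / n)
    return float(max(d_plus, d_minus))


def _ks_rows(family: Family, p0: np.ndarray, p1: np.ndarray, samples: np.ndarray) -> np.ndarray:
    """KS statistic per row of `samples` against per-row parameters."""
    b, n = samples.shape
    xs = np.sort(samples, axis=1)
    f = _cdf(family, p0[:, None], p1[:, None], xs)
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - f, axis=1)
    d_minus = np.max(f - (i - 1) / n, axis=1)
    return np.maximum(d_plus, d_minus)


def sample_family(fit: FitParams, n: int, seed) -> np.ndarray:
    """n i.i.d. draws from the fitted law; identical seed -> identical draws."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return _sample_rows(fit.family, np.array([fit.params[0]]), np.array([fit.params[1]]), n, rng)[0]


def _sample_rows(
    family: Family, p0: np.ndarray, p1: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """(len(p0) x n) matrix of draws, row b from parameters (p0[b], p1[b])."""
    b = p0.size
    if family is Family.NORMAL:
        return p0[:, None] + p1[:, None] * rng.standard_normal((b, n))
    if family is Family.LOGNORMAL:
        return np.exp(p0[:, None] + p1[:, None] * rng.standard_normal((b, n)))
    if family is Family.CAUCHY:
        return p0[:, None] + p1[:, None] * rng.standard_cauchy((b, n))
    if family is Family.GAMMA:
        return rng.gamma(np.broadcast_to(p0[:, None], (b, n)), 1.0) / p1[:, None]
    if family is Family.PARETO:
        u = rng.random((b, n))
        return p0[:, None] * (1.0 - u) ** (-1.0 / p1[:, None])
    raise ValueError(f"cannot sample from {family}")


def _fit_rows(family: Family, samples: np.ndarray, cauchy_mode: str = "half-iqr"):
    """Re-estimate parameters on each row; used by the parametric bootstrap."""
    if family is Family.CAUCHY:
        q25, q50, q75 = np.quantile(samples, (0.25, 0.5, 0.75), axis=1)
        iqr = q75 - q25
        scale = iqr / 2.0 if cauchy_mode == "half-iqr" else iqr
        return q50, np.clip(scale, 1e-300, None)
    if family is Family.GAMMA:
        mean_x = samples.mean(axis=1)
        var_x = samples.var(axis=1)
        mean_log = np.log(samples).mean(axis=1)
        k = _gamma_newton(mean_x, var_x, mean_log)
        return k, k / mean_x
    if family is Family.PARETO:
        xm = samples.min(axis=1)
        denom = np.clip(np.sum(np.log(samples / xm[:, None]), axis=1), 1e-300, None)
        return xm, samples.shape[1] / denom
    raise ValueError(f"row-wise refit not needed for {family}")
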