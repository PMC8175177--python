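"""Weibull-Frechet (WFr) lifetime distribution.

The four-parameter Weibull-Frechet law WFr(a, b, alpha, beta) compounds a
Weibull generator with a Frechet baseline.  With ``x = (alpha/y)**beta`` its
survival (reliability) function is

    r(y) = exp(-a * (exp(x) - 1)**(-b)),        y > 0,

so the distribution has support on the positive half line; ``alpha`` is a
scale parameter (same units as time) and ``a``, ``b``, ``beta`` are shapes.
Fixing parameters recovers several classical sub-models (e.g. beta = 1 gives
the Weibull inverse-exponential law).

All functions here evaluate the ``exp((alpha/y)**beta)`` terms in log space:
``log(exp(x) - 1)`` is computed as ``x + log1p(-exp(-x))`` for large ``x``
and as ``log(expm1(x))`` for small ``x``, so densities stay finite even when
``(alpha/y)**beta`` reaches several hundred.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "WFrParams",
    "pdf",
    "logpdf",
    "cdf",
    "reliability",
    "log_reliability",
    "hazard",
    "quantile",
    "sample",
]


@dataclass(frozen=True)
class WFrParams:
    """Parameter 4-tuple (a, b, alpha, beta) of the WFr distribution.

    All four entries must be strictly positive: ``a``, ``b`` and ``beta``
    are shape parameters and ``alpha`` is the scale (time units).
    """

    a: float
    b: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "alpha", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(
                    f"WFr parameter {name!r} must be a positive finite real, got {v!r}"
                )

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.alpha, self.beta], dtype=float)

    @classmethod
    def from_array(cls, theta) -> "WFrParams":
        a, b, alpha, beta = np.asarray(theta, dtype=float)
        return cls(a, b, alpha, beta)


def _check_times(y, name: str = "y") -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError(f"{name} must be nonempty")
    if not np.all(np.isfinite(y)) or np.any(y <= 0):
        raise ValueError(f"{name} must contain strictly positive finite values")
    return y


def _frechet_exponent(y: np.ndarray, params: WFrParams) -> np.ndarray:
    """x = (alpha/y)**beta, the Frechet exponent of the baseline."""
    return (params.alpha / y) ** params.beta


def _log_expm1(x: np.ndarray) -> np.ndarray:
    """log(exp(x) - 1), stable for both tails of x > 0."""
    x = np.asarray(x, dtype=float)
    small = x < 0.6931471805599453  # below log 2 expm1 keeps full precision
    return np.where(
        small,
        np.log(np.expm1(np.where(small, x, 1.0))),
        x + np.log1p(-np.exp(-np.where(small, 1.0, x))),
    )


def _gee(x: np.ndarray, b: float) -> np.ndarray:
    """G(x) = (exp(x) - 1)**(-b), evaluated via the log of expm1."""
    return np.exp(-b * _log_expm1(x))


def logpdf(y, params: WFrParams):
    """Natural log of the WFr density, finite for any y > 0."""
    y = _check_times(y)
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    x = _frechet_exponent(y, params)
    lx = _log_expm1(x)
    out = (
        np.log(a)
        + np.log(b)
        + np.log(beta)
        + beta * np.log(alpha)
        - (beta + 1.0) * np.log(y)
        - b * x
        - (b + 1.0) * (lx - x)  # log(1 - exp(-x)) = log(expm1(x)) - x
        - a * np.exp(-b * lx)
    )
    return out if out.ndim else float(out)


def pdf(y, params: WFrParams):
    """WFr probability density f(y)."""
    out = np.exp(logpdf(y, params))
    return out if np.ndim(out) else float(out)


def log_reliability(t, params: WFrParams):
    """log r(t) = -a * (exp((alpha/t)**beta) - 1)**(-b)."""
    t = _check_times(t, "t")
    out = -params.a * _gee(_frechet_exponent(t, params), params.b)
    return out if out.ndim else float(out)


def reliability(t, params: WFrParams):
    """Survival probability r(t) = P(Y > t); strictly decreasing in t."""
    out = np.exp(log_reliability(t, params))
    return out if np.ndim(out) else float(out)


def cdf(y, params: WFrParams):
    """Distribution function F(y) = 1 - r(y), computed via expm1."""
    out = -np.expm1(log_reliability(y, params))
    return out if np.ndim(out) else float(out)


def hazard(t, params: WFrParams):
    """Hazard rate h(t) = f(t) / r(t), evaluated directly in log space."""
    t = _check_times(t, "t")
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    x = _frechet_exponent(t, params)
    lx = _log_expm1(x)
    logh = (
        np.log(a)
        + np.log(b)
        + np.log(beta)
        + beta * np.log(alpha)
        - (beta + 1.0) * np.log(t)
        - b * x
        - (b + 1.0) * (lx - x)
    )
    out = np.exp(logh)
    return out if out.ndim else float(out)


def quantile(u, params: WFrParams):
    """Inverse CDF by closed-form inversion of the survival function.

    Solving r(y) = 1 - u for y gives
    ``y = alpha * [log1p((-log1p(-u)/a)**(-1/b))]**(-1/beta)``.
    """
    u = np.asarray(u, dtype=float)
    if np.any(u <= 0) or np.any(u >= 1) or not np.all(np.isfinite(u)):
        raise ValueError("quantile argument must lie strictly inside (0, 1)")
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    w = -np.log1p(-u) / a          # a * (e^x - 1)^(-b) = w
    x = np.log1p(w ** (-1.0 / b))  # invert (e^x - 1)^(-b) = w / a... in one step
    out = alpha * x ** (-1.0 / beta)
    return out if out.ndim else float(out)


def sample(count: int, params: WFrParams, rng: np.random.Generator) -> np.ndarray:
    """Draw ``count`` iid WFr variates by inverse-transform sampling."""
    if count < 1:
        raise ValueError("count must be a positive integer")
    u = rng.random(int(count))
    # guard against an exact 0 from the generator (prob ~2^-53)
    u = np.clip(u, np.nextafter(0.0, 1.0), None)
    return np.asarray(quantile(u, params), dtype=float)
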