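"""Maximum-likelihood inference for WFr progressive type-II censored data.

The censored log-likelihood (up to the scheme's additive constant) is

    l = sum_k [ log f(y_k) + R_k * log r(y_k) ],

where f and r are the WFr density and reliability.  The parameter ``a``
enters the likelihood linearly through ``a * sum_k (R_k+1) * S_k`` with
``S_k = (exp((alpha/y_k)**beta) - 1)**(-b)``, so its score equation solves
in closed form (``profile_a``); maximisation therefore runs over
``(b, alpha, beta)`` only, on the log scale to keep parameters positive,
followed by Newton polish on the natural scale using the analytic score.

The observed information is obtained by central differences of the analytic
score (one source of truth for derivatives), and confidence intervals for
the reliability r(t) and hazard h(t) use the delta method with analytic
gradients.  Intervals are reported untruncated: with small samples the
normal approximation routinely produces negative lower bounds for positive
parameters, and we keep them as such.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .censoring import CensoredSample
from .distribution import (
    WFrParams,
    _frechet_exponent,
    _log_expm1,
    hazard,
    log_reliability,
    logpdf,
    reliability,
)

__all__ = [
    "FitResult",
    "IntervalSet",
    "log_likelihood",
    "score",
    "profile_a",
    "observed_information",
    "fit_mle",
    "asymptotic_ci",
    "delta_ci",
    "reliability_gradient",
    "hazard_gradient",
]


@dataclass
class FitResult:
    """MLE output: point estimates, curvature, and convergence diagnostics."""

    estimates: WFrParams
    loglik: float
    vcov: np.ndarray
    converged: bool
    iterations: int
    score_norm: float

    def se(self) -> np.ndarray:
        """Asymptotic standard errors in order (a, b, alpha, beta)."""
        d = np.diag(self.vcov)
        return np.sqrt(np.where(d > 0, d, np.nan))


@dataclass
class IntervalSet:
    """Normal-theory confidence bounds for (a, b, alpha, beta, r(t), h(t))."""

    level: float
    t_eval: float
    bounds: dict = field(default_factory=dict)  # name -> (lower, upper)

    def __getitem__(self, key: str):
        return self.bounds[key]


def log_likelihood(params: WFrParams, sample: CensoredSample) -> float:
    """Censored log-likelihood, omitting the scheme's additive constant."""
    y, r = sample.y, sample.removals
    return float(np.sum(logpdf(y, params) + r * log_reliability(y, params)))


def _pieces(params: WFrParams, sample: CensoredSample):
    y = sample.y
    x = _frechet_exponent(y, params)
    lx = _log_expm1(x)
    s = np.exp(-params.b * lx)
    return y, sample.removals, x, lx, s


def score(params: WFrParams, sample: CensoredSample) -> np.ndarray:
    """Analytic gradient of the log-likelihood in order (a, b, alpha, beta)."""
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    y, r, x, lx, s = _pieces(params, sample)
    m = y.size
    w = r + 1.0
    da = m / a - np.sum(w * s)
    db = m / b + a * np.sum(w * s * lx) - np.sum(lx)
    # dl/dx_k, shared by the alpha and beta chain rules
    dldx = -b + a * b * w * np.exp(x - (b + 1.0) * lx) - (b + 1.0) * np.exp(-lx)
    dalpha = m * beta / alpha + np.sum(dldx * beta * x / alpha)
    lr = np.log(alpha / y)
    dbeta = m / beta + m * np.log(alpha) - np.sum(np.log(y)) + np.sum(dldx * x * lr)
    return np.array([da, db, dalpha, dbeta])


def profile_a(
    b: float, alpha: float, beta: float, sample: CensoredSample
) -> float:
    """Closed-form conditional MLE of ``a`` given the other three parameters.

    a_hat = m / sum_k (R_k + 1) * (exp((alpha/y_k)**beta) - 1)**(-b).
    """
    if b <= 0 or alpha <= 0 or beta <= 0:
        raise ValueError("b, alpha, beta must be positive")
    y, rem = sample.y, sample.removals
    x = (alpha / y) ** beta
    s = np.exp(-b * _log_expm1(x))
    denom = np.sum((rem + 1.0) * s)
    if not np.isfinite(denom) or denom <= 0:
        raise ValueError("profile estimate of a is degenerate for these inputs")
    return float(y.size / denom)


def observed_information(
    params: WFrParams, sample: CensoredSample, step: float = 1e-5
) -> np.ndarray:
    """Negative Hessian of the log-likelihood at ``params``.

    Computed by central differences of the analytic score with per-parameter
    step ``step * max(1, |theta_i|)`` and explicitly symmetrised.
    """
    theta = params.as_array()
    hmat = np.empty((4, 4))
    for i in range(4):
        h = step * max(1.0, abs(theta[i]))
        up, dn = theta.copy(), theta.copy()
        up[i] += h
        dn[i] = max(dn[i] - h, 1e-12)
        g1 = score(WFrParams.from_array(up), sample)
        g0 = score(WFrParams.from_array(dn), sample)
        hmat[i] = (g1 - g0) / (up[i] - dn[i])
    hess = 0.5 * (hmat + hmat.T)
    return -hess


def _profiled_negloglik(phi: np.ndarray, sample: CensoredSample) -> float:
    with np.errstate(over="ignore", invalid="ignore"):
        b, alpha, beta = np.exp(phi)
        try:
            a = profile_a(b, alpha, beta, sample)
            ll = log_likelihood(WFrParams(a, b, alpha, beta), sample)
        except (ValueError, OverflowError, FloatingPointError):
            return np.inf
    return -ll if np.isfinite(ll) else np.inf


def _pll_and_grad(phi: np.ndarray, sample: CensoredSample):
    """Profiled log-likelihood and its gradient w.r.t. log(b, alpha, beta).

    By the envelope theorem the profiled gradient equals the (b, alpha,
    beta) components of the full score evaluated at the profiled a.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        b, alpha, beta = np.exp(phi)
        try:
            a = profile_a(b, alpha, beta, sample)
            p = WFrParams(a, b, alpha, beta)
            ll = log_likelihood(p, sample)
            g = score(p, sample)[1:] * np.exp(phi)
        except (ValueError, OverflowError, FloatingPointError):
            return -np.inf, None
    if not (np.isfinite(ll) and np.all(np.isfinite(g))):
        return -np.inf, None
    return ll, g


def _profiled_hessian(phi: np.ndarray, sample: CensoredSample):
    hmat = np.empty((3, 3))
    for i in range(3):
        h = 1e-6 * max(1.0, abs(phi[i]))
        up, dn = phi.copy(), phi.copy()
        up[i] += h
        dn[i] -= h
        _, gu = _pll_and_grad(up, sample)
        _, gd = _pll_and_grad(dn, sample)
        if gu is None or gd is None:
            return None
        hmat[i] = (gu - gd) / (2.0 * h)
    return 0.5 * (hmat + hmat.T)


def _newton_ascent(
    phi: np.ndarray,
    sample: CensoredSample,
    gtol: float,
    maxiter: int,
    box: float = 12.0,
):
    """Damped Newton ascent of the profiled log-likelihood.

    When the Hessian is not negative definite the step uses an eigenvalue
    shift (Levenberg-style), so saddle regions of the flat 4-parameter
    surface are traversed instead of stalling.  Iterates leaving the box
    |log theta| > box are treated as escapes towards a degenerate boundary
    spike, where no maximum-likelihood estimate exists.
    """
    ll, g = _pll_and_grad(phi, sample)
    if g is None:
        return phi, ll, np.inf, 0, "bad-start"
    status = "maxiter"
    it = 0
    for it in range(1, maxiter + 1):
        if np.max(np.abs(g)) < gtol:
            status = "converged"
            break
        if np.max(np.abs(phi)) > box:
            status = "escaped"
            break
        hess = _profiled_hessian(phi, sample)
        if hess is None:
            status = "hessian-failed"
            break
        ev = np.linalg.eigvalsh(hess)
        tau = 0.0
        if ev.max() >= -1e-8:  # not safely negative definite: shift
            tau = ev.max() + 1e-4 * max(1.0, np.abs(ev).max())
        step = np.linalg.solve(hess - tau * np.eye(3), -g)
        lam, ok = 1.0, False
        for _ in range(40):
            cand = phi + lam * step
            ll_new, g_new = _pll_and_grad(cand, sample)
            if g_new is not None and (
                ll_new > ll + 1e-13
                or (
                    abs(ll_new - ll) <= 1e-13
                    and np.max(np.abs(g_new)) < np.max(np.abs(g))
                )
            ):
                phi, ll, g, ok = cand, ll_new, g_new, True
                break
            lam *= 0.5
        if not ok:
            status = "stalled"
            break
    return phi, ll, float(np.max(np.abs(g))), it, status


def _default_grid(sample: CensoredSample):
    med = float(np.median(sample.y))
    best, best_val = None, np.inf
    for b0 in (0.5, 1.0, 2.0, 3.0):
        for al0 in (0.25 * med, 0.5 * med, med, 2.0 * med):
            for be0 in (0.5, 1.0, 2.0, 3.0):
                v = _profiled_negloglik(np.log([b0, al0, be0]), sample)
                if v < best_val:
                    best, best_val = (b0, al0, be0), v
    if best is None:
        raise RuntimeError("no finite likelihood found on the starting grid")
    return np.log(best)


def fit_mle(
    sample: CensoredSample,
    init: WFrParams | None = None,
    gtol: float = 1e-8,
    nm_maxiter: int = 150,
    max_polish: int = 200,
) -> FitResult:
    """Local maximum-likelihood fit of all four WFr parameters.

    ``a`` is profiled out in closed form at every step; the remaining three
    parameters are maximised on the log scale by damped Newton ascent with
    eigenvalue-shifted steps, seeded by ``init`` or by a coarse data-driven
    grid refined with a short Nelder-Mead run.  The estimator is the local
    interior maximiser reached by ascent: like other threshold-type
    lifetime models, the four-parameter WFr likelihood is unbounded along a
    boundary spike (alpha just below the smallest observation with beta
    large), so iterates escaping towards that spike are reported as
    non-converged rather than followed.  Non-convergence is reported in the
    result, never raised.
    """
    starts = []
    if init is not None:
        starts.append(np.log([init.b, init.alpha, init.beta]))
    else:
        phi_grid = _default_grid(sample)
        starts.append(phi_grid)
        # short simplex refinement of the grid point as a second start;
        # usable only if the gradient is finite there (a spike iterate is not)
        res = optimize.minimize(
            _profiled_negloglik,
            phi_grid,
            args=(sample,),
            method="Nelder-Mead",
            options={"maxiter": nm_maxiter, "xatol": 1e-8, "fatol": 1e-10},
        )
        if np.isfinite(res.fun) and np.max(np.abs(res.x)) < 8.0:
            if _pll_and_grad(res.x, sample)[1] is not None:
                starts.append(res.x)

    best = None
    iterations = 0
    for phi0 in starts:
        phi_c, ll_c, g_c, it_c, st_c = _newton_ascent(
            phi0, sample, gtol=gtol, maxiter=max_polish
        )
        iterations += it_c
        key = (st_c == "converged", ll_c if np.isfinite(ll_c) else -np.inf)
        if best is None or key > best[0]:
            best = (key, phi_c, ll_c, st_c)
        if st_c == "converged":
            break
    _, phi, ll, status = best
    if init is not None and status != "converged":
        # retry once from the data-driven grid
        phi_alt, ll_alt, _, it_alt, st_alt = _newton_ascent(
            _default_grid(sample), sample, gtol=gtol, maxiter=max_polish
        )
        iterations += it_alt
        if st_alt == "converged" or (
            status != "converged" and ll_alt > ll
        ):
            phi, ll, status = phi_alt, ll_alt, st_alt

    b, alpha, beta = np.exp(phi)
    with np.errstate(over="ignore", invalid="ignore"):
        try:
            a = profile_a(b, alpha, beta, sample)
            params = WFrParams(a, b, alpha, beta)
            g = score(params, sample)
            score_norm = float(np.max(np.abs(g)))
            info = observed_information(params, sample)
            try:
                vcov = np.linalg.inv(info)
            except np.linalg.LinAlgError:
                vcov = np.linalg.pinv(info)
        except (ValueError, OverflowError, FloatingPointError):
            # the ascent ended in unusable territory; report diagnostics
            params = WFrParams(1.0, max(b, 1e-8), max(alpha, 1e-8),
                               max(beta, 1e-8)) if np.all(
                np.isfinite([b, alpha, beta])) else WFrParams(1, 1, 1, 1)
            score_norm = np.inf
            vcov = np.full((4, 4), np.nan)
            status = "degenerate"
    converged = bool(status == "converged" and np.isfinite(ll))
    return FitResult(
        estimates=params,
        loglik=float(ll),
        vcov=vcov,
        converged=converged,
        iterations=iterations,
        score_norm=score_norm,
    )


def reliability_gradient(t: float, params: WFrParams) -> np.ndarray:
    """Gradient of r(t) in (a, b, alpha, beta), for the delta method."""
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    x = _frechet_exponent(np.asarray(t, dtype=float), params)
    lx = _log_expm1(x)
    g = np.exp(-b * lx)
    r = float(reliability(t, params))
    core = a * b * np.exp(x - (b + 1.0) * lx)
    return np.array(
        [
            -g * r,
            a * g * lx * r,
            core * (beta * x / alpha) * r,
            core * x * np.log(alpha / t) * r,
        ],
        dtype=float,
    )


def hazard_gradient(t: float, params: WFrParams) -> np.ndarray:
    """Gradient of h(t) in (a, b, alpha, beta), for the delta method."""
    a, b, alpha, beta = params.a, params.b, params.alpha, params.beta
    x = float(_frechet_exponent(np.asarray(t, dtype=float), params))
    lx = float(_log_expm1(x))
    h = float(hazard(t, params))
    dlogx = -b - (b + 1.0) * np.exp(-lx)  # d log h / d x
    return h * np.array(
        [
            1.0 / a,
            1.0 / b - lx,
            beta / alpha + dlogx * beta * x / alpha,
            1.0 / beta + np.log(alpha) - np.log(t) + dlogx * x * np.log(alpha / t),
        ]
    )


def delta_ci(fit: FitResult, t: float, level: float = 0.95):
    """Delta-method intervals for r(t) and h(t) at confidence ``level``.

    Variances are the quadratic forms B' V B with B the analytic gradients
    of r and h; bounds are left untruncated (the upper r(t) bound can exceed
    one in small samples).
    """
    if not fit.converged:
        raise ValueError("delta intervals require a converged fit")
    z = stats.norm.ppf(0.5 + level / 2.0)
    p = fit.estimates
    r_hat, h_hat = reliability(t, p), hazard(t, p)
    b1, b2 = reliability_gradient(t, p), hazard_gradient(t, p)
    var_r = float(b1 @ fit.vcov @ b1)
    var_h = float(b2 @ fit.vcov @ b2)
    sr, sh = np.sqrt(max(var_r, 0.0)), np.sqrt(max(var_h, 0.0))
    return (r_hat - z * sr, r_hat + z * sr), (h_hat - z * sh, h_hat + z * sh)


def asymptotic_ci(
    fit: FitResult, level: float = 0.95, t_eval: float = 0.5
) -> IntervalSet:
    """Normal-theory intervals for all six quantities.

    Parameters use estimate +/- z * sqrt(var) from the inverse observed
    information; r(t) and h(t) use the delta method.  Lower bounds are not
    truncated at zero.
    """
    if not fit.converged:
        raise ValueError("asymptotic intervals require a converged fit")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    theta = fit.estimates.as_array()
    se = np.sqrt(np.clip(np.diag(fit.vcov), 0.0, None))
    out = IntervalSet(level=level, t_eval=t_eval)
    for name, est, s in zip(("a", "b", "alpha", "beta"), theta, se):
        out.bounds[name] = (float(est - z * s), float(est + z * s))
    (rlo, rhi), (hlo, hhi) = delta_ci(fit, t_eval, level)
    out.bounds["r"] = (float(rlo), float(rhi))
    out.bounds["h"] = (float(hlo), float(hhi))
    return out
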