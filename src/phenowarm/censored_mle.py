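"""Stage 1: intercept-only interval-censored normal MLE per replicate.

Each observation contributes P(L < Y <= U) under Y ~ N(mu, sigma^2); the
replicate (treatment x species x subsite x year, within a phenophase) gets
the maximizing (mu, sigma), the standard error of mu from the inverse
observed information, and a fallback (average midpoint, borrowed SE) when
all intervals in a replicate are identical and the likelihood carries no
scale information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import log_ndtr

logger = logging.getLogger(__name__)

REPLICATE_KEY = ["phenophase", "species", "site", "subsite", "year", "treatment"]

_HESSIAN_STEP = 1e-5


def _log_phi_diff(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """log(Phi(b) - Phi(a)) for a < b, stable in both tails.

    Uses log Phi differences on whichever side keeps the arguments in the
    lower tail (Phi(b) - Phi(a) = Phi(-a) - Phi(-b)), then log1p(-exp(.)).
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    flip = a + b > 0
    a_, b_ = np.where(flip, -b, a), np.where(flip, -a, b)
    la, lb = log_ndtr(a_), log_ndtr(b_)
    with np.errstate(divide="ignore"):
        return lb + np.log1p(-np.exp(np.minimum(la - lb, -1e-300)))


def loglik_interval_normal(
    mu: float, log_sigma: float, lower: np.ndarray, upper: np.ndarray
) -> float:
    """Sum of log P(L_i < Y <= U_i) with Y ~ N(mu, exp(log_sigma)^2)."""
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if np.any(lower >= upper):
        raise ValueError("every interval must satisfy lower < upper")
    sigma = np.exp(log_sigma)
    a = (lower - mu) / sigma
    b = (upper - mu) / sigma
    return float(np.sum(_log_phi_diff(a, b)))


@dataclass(frozen=True)
class IntervalFit:
    mu: float
    sigma: float
    se_mu: float
    loglik: float
    converged: bool


def _hessian_from_grad(grad, x: np.ndarray, h: float = _HESSIAN_STEP) -> np.ndarray:
    """Central differences of the (analytic) gradient; symmetrized."""
    n = len(x)
    H = np.empty((n, n))
    for i in range(n):
        e = np.zeros(n)
        e[i] = h
        H[:, i] = (grad(x + e) - grad(x - e)) / (2 * h)
    return 0.5 * (H + H.T)


def fit_interval_censored(
    lower: np.ndarray, upper: np.ndarray, n_starts: int = 3
) -> IntervalFit:
    """Maximize the interval-censored normal likelihood in (mu, log sigma).

    Quasi-Newton (L-BFGS-B) from multistart points seeded by the midpoint
    mean/SD; the SE of mu comes from the inverse observed information
    (central-difference Hessian at the optimum).
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if len(lower) < 2:
        raise ValueError("need at least two intervals")
    if np.any(lower >= upper):
        raise ValueError("every interval must satisfy lower < upper")

    mid = (lower + upper) / 2.0
    width = float(np.mean(upper - lower))
    s0 = max(float(np.std(mid, ddof=1)), width / 4.0, 1e-3)
    m0 = float(np.mean(mid))
    starts = [
        (m0, np.log(s0)),
        (m0, np.log(2.0 * s0)),
        (m0 + 0.5 * s0, np.log(max(0.5 * s0, 1e-3))),
    ][:n_starts]

    log_sqrt_2pi = 0.5 * np.log(2 * np.pi)

    def neg(x: np.ndarray) -> tuple[float, np.ndarray]:
        mu, log_sigma = x
        sigma = np.exp(log_sigma)
        a = (lower - mu) / sigma
        b = (upper - mu) / sigma
        log_p = _log_phi_diff(a, b)
        # phi(x)/P computed in log space to stay finite in the tails; the
        # exponent is clamped so an underflowing P yields a large (not inf)
        # gradient during line searches
        ra = np.exp(np.minimum(-0.5 * a * a - log_sqrt_2pi - log_p, 500.0))
        rb = np.exp(np.minimum(-0.5 * b * b - log_sqrt_2pi - log_p, 500.0))
        g_mu = -np.sum(ra - rb) / sigma
        g_ls = -np.sum(a * ra - b * rb)
        return -float(np.sum(log_p)), np.array([g_mu, g_ls])

    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            neg,
            np.array(x0),
            method="L-BFGS-B",
            jac=True,
            bounds=[(None, None), (-20.0, 20.0)],
            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9},
        )
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res

    # Newton polish: quasi-Newton stops at line-search tolerance; a couple of
    # exact Newton steps on the analytic gradient reach machine precision
    x = best.x.copy()
    f, g = neg(x)
    for _ in range(3):
        if np.max(np.abs(g)) < 1e-12 * max(1.0, abs(f)):
            break
        H = _hessian_from_grad(lambda z: neg(z)[1], x)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            break
        f_new, g_new = neg(x - step)
        if not np.isfinite(f_new) or f_new > f + 1e-9:
            break
        x, f, g = x - step, f_new, g_new
    best_x, best_f = x, f

    mu, log_sigma = best_x
    sigma = float(np.exp(log_sigma))
    # a flat line-search termination at the optimum still counts as converged
    grad_norm = float(np.max(np.abs(g)))
    any_ok = any_ok or grad_norm < 1e-5 * max(1.0, abs(best_f))

    H = _hessian_from_grad(lambda z: neg(z)[1], best_x)
    se_mu = np.nan
    converged = bool(any_ok)
    try:
        cov = np.linalg.inv(H)
        var_mu = cov[0, 0]
        if var_mu > 0:
            se_mu = float(np.sqrt(var_mu))
        else:
            converged = False
    except np.linalg.LinAlgError:
        converged = False
    if not np.isfinite(se_mu):
        converged = False
    return IntervalFit(
        mu=float(mu),
        sigma=sigma,
        se_mu=se_mu,
        loglik=-float(best_f),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# replicate-level estimation
# ---------------------------------------------------------------------------


def estimate_replicates(standardized: pd.DataFrame) -> pd.DataFrame:
    """Fit every replicate; apply the midpoint/borrowed-SE fallback.

    A replicate is degenerate when all its intervals share a common point
    (identical bounds being the extreme case): the likelihood is then
    maximized on the sigma -> 0 boundary and carries no usable information
    about scale.  Such replicates — and replicates whose fit fails — get the average
    midpoint as the mean and, as the SE, the mean SE of successfully fitted
    replicates of the same species x subsite x treatment across years, falling
    back to the phenophase-level mean SE when the stratum has none.

    Returns one row per replicate: key columns + mu, se, sigma, n_obs,
    method ('mle' | 'midpoint_fallback'), converged.
    """
    out_cols = REPLICATE_KEY + ["mu", "se", "sigma", "n_obs", "method", "converged"]
    if len(standardized) == 0:
        return pd.DataFrame(columns=out_cols)
    rows = []
    for key, g in standardized.groupby(REPLICATE_KEY, observed=True, sort=True):
        lo = g["lower_std"].to_numpy()
        hi = g["upper_std"].to_numpy()
        n = len(g)
        # Degenerate whenever all intervals share a common point — identical
        # bounds are the extreme case, and intervals merely touching at one
        # census date count too: the likelihood is then maximized on the
        # sigma -> 0 boundary and the observed information carries no
        # usable SE.
        degenerate = bool(lo.max() <= hi.min())
        mu = se = sigma = np.nan
        method = "midpoint_fallback"
        converged = False
        if not degenerate and n >= 2:
            fit = fit_interval_censored(lo, hi)
            if fit.converged:
                mu, se, sigma = fit.mu, fit.se_mu, fit.sigma
                # census-resolution floor: an event located only to a
                # width-w interval carries at least w/sqrt(12) timing
                # uncertainty, so the SE of the mean cannot fall below the
                # rounding-error limit; guards against sigma-collapse when
                # coarse intervals nearly share a common point
                floor = float(np.sqrt(np.mean((hi - lo) ** 2) / 12.0 / n))
                se = max(se, floor)
                method = "mle"
                converged = True
        if method == "midpoint_fallback":
            mu = float(np.mean((lo + hi) / 2.0))
        rows.append(dict(zip(REPLICATE_KEY, key), mu=mu, se=se, sigma=sigma,
                         n_obs=n, method=method, converged=converged))
    est = pd.DataFrame(rows)
    if est.empty:
        return est

    # borrowed SEs for fallback replicates
    fitted = est[est["method"] == "mle"]
    stratum_cols = ["phenophase", "species", "subsite", "treatment"]
    stratum_se = fitted.groupby(stratum_cols, observed=True)["se"].mean()
    phase_se = fitted.groupby("phenophase", observed=True)["se"].mean()
    need = est["method"] == "midpoint_fallback"
    for i in est.index[need]:
        key = tuple(est.loc[i, c] for c in stratum_cols)
        se = stratum_se.get(key, np.nan)
        if np.isnan(se):
            se = phase_se.get(est.loc[i, "phenophase"], np.nan)
            if np.isnan(se):
                logger.warning(
                    "no fitted SE available anywhere for phenophase %r; "
                    "fallback replicate keeps NaN SE",
                    est.loc[i, "phenophase"],
                )
            else:
                logger.info(
                    "fallback SE for %s taken at phenophase level", key
                )
        est.loc[i, "se"] = se
    return est
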