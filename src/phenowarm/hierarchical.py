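"""Stage 2: Bayesian hierarchical measurement-error models of warming effects.

The model for replicate-level means (standardized scale) is

    mu_r ~ N( alpha + a_s + a_k + a_y + a_j
              + (beta + b_s + b_k + b_y + b_j) * Trt_r
              [+ beta_st * St_r + beta_trt_x_st * Trt_r * St_r],
              sigma_obs,r )

with correlated (intercept, slope) deviations per grouping factor (species
s, site k, site:year y, site:subsite j), each pair multivariate normal with
SDs S_group and correlation rho_group, and per-replicate observation SD
combining the residual scale sigma_r with the known stage-1 standard error
(quadrature by default; the literal sum is available as a sensitivity
switch).

Priors: effectively-flat Normal(0, 100^2) on all fixed effects,
half-Student-t(df 3, scale 10) on every SD, and uniform correlations on
(-1, 1) (the 2x2 LKJ(1) prior).

Sampling exploits the linear-Gaussian structure: group deviations and fixed
effects are integrated out analytically (low-rank Woodbury form), the
remaining variance/correlation hyperparameters are sampled with an
affine-invariant ensemble MCMC (differential-evolution moves), and all
coefficients are then drawn from their exact Gaussian conditionals for each
retained hyperparameter draw.  Two independent ensembles play the role of
the two chains for split-R-hat diagnostics.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import emcee
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize

from .prep import ScalingRecord

logger = logging.getLogger(__name__)

FACTORS = ("species", "site", "site_year", "site_subsite")

_LOG_SD_MIN, _LOG_SD_MAX = -15.0, 8.0
_Z_RHO_MAX = 12.0


@dataclass(frozen=True)
class ModelSpec:
    """Sampler and prior settings for one stage-2 fit.

    ``iterations`` counts posterior-density evaluations per chain (the
    ensemble runs iterations/walkers steps), so the default 2 chains x
    10,000 iterations with 5,000 warmup matches the conventional MCMC
    budget for this model family.
    """

    phenophase: str | None = None
    chains: int = 2
    iterations: int = 10_000
    warmup: int = 5_000
    walkers: int = 32
    seed: int = 0
    se_combination: str = "quadrature"  # or "sum"
    fixed_prior_sd: float = 100.0
    sd_prior_df: float = 3.0
    sd_prior_scale: float = 10.0
    rhat_threshold: float = 1.1

    def __post_init__(self) -> None:
        if self.chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("require 0 < warmup < iterations")
        if self.se_combination not in ("quadrature", "sum"):
            raise ValueError("se_combination must be 'quadrature' or 'sum'")

    @property
    def steps(self) -> int:
        return max(int(math.ceil(self.iterations / self.walkers)), 20)

    @property
    def burn_steps(self) -> int:
        b = int(round(self.steps * self.warmup / self.iterations))
        return min(max(b, 5), self.steps - 10)


# ---------------------------------------------------------------------------
# ETI and Gelman-Rubin
# ---------------------------------------------------------------------------


def compute_eti(draws: np.ndarray, level: float) -> tuple[float, float]:
    """Equal-tailed credible interval: symmetric empirical quantiles."""
    if level not in (0.90, 0.95):
        if not 0 < level < 1:
            raise ValueError("level must be in (0, 1)")
    draws = np.asarray(draws).ravel()
    if draws.size < 2:
        raise ValueError("need at least two draws")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def gelman_rubin(chain_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (classic split R-hat).

    ``chain_draws`` has shape (chains, draws); each chain is split in half
    before computing the between/within variance ratio.
    """
    x = np.asarray(chain_draws, float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need a (chains, draws) array with >= 2 chains")
    n = x.shape[1] // 2
    if n < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([x[:, :n], x[:, n : 2 * n]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B_over_n = halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _Design:
    y: np.ndarray
    se: np.ndarray
    W: np.ndarray  # [X | Z] column-stacked
    fixed_names: list[str]
    factor_offsets: dict[str, int]
    factor_levels: dict[str, list]

    @property
    def p(self) -> int:
        return len(self.fixed_names)


def _build_design(df: pd.DataFrame, st_cols: list[str]) -> _Design:
    df = df.sort_values(
        ["species", "site", "subsite", "year", "treatment"], kind="mergesort"
    ).reset_index(drop=True)
    y = df["mu"].to_numpy(float)
    se = df["se"].to_numpy(float)
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("replicate estimates must have finite mu and positive se")
    trt = (df["treatment"] == "otc").to_numpy(float)
    n = len(df)

    cols = [np.ones(n), trt]
    names = ["alpha", "beta_trt"]
    for c in st_cols:
        v = df[c].to_numpy(float)
        cols.append(v)
        names.append(f"beta_{c}")
        cols.append(v * trt)
        names.append(f"beta_trt_x_{c}")
    X = np.column_stack(cols)

    df = df.assign(
        site_year=df["site"].astype(str) + ":" + df["year"].astype(str),
        site_subsite=df["site"].astype(str) + ":" + df["subsite"].astype(str),
    )
    blocks = [X]
    offsets: dict[str, int] = {}
    levels: dict[str, list] = {}
    off = X.shape[1]
    for fac in FACTORS:
        lv = sorted(df[fac].unique())
        codes = df[fac].map({l: i for i, l in enumerate(lv)}).to_numpy()
        Z = np.zeros((n, 2 * len(lv)))
        Z[np.arange(n), 2 * codes] = 1.0
        Z[np.arange(n), 2 * codes + 1] = trt
        blocks.append(Z)
        offsets[fac] = off
        levels[fac] = lv
        off += 2 * len(lv)
    W = np.column_stack(blocks)
    return _Design(y=y, se=se, W=W, fixed_names=names,
                   factor_offsets=offsets, factor_levels=levels)


# ---------------------------------------------------------------------------
# marginal log-posterior over variance parameters
# ---------------------------------------------------------------------------


class _MarginalPosterior:
    """log p(theta | y) with coefficients integrated out.

    theta = [log sd_int, log sd_slope, atanh(rho)] per factor + [log sigma_r].
    """

    def __init__(self, design: _Design, spec: ModelSpec):
        self.d = design
        self.spec = spec
        self.ndim = 3 * len(FACTORS) + 1
        df, s = spec.sd_prior_df, spec.sd_prior_scale
        self._t_const = (
            math.lgamma((df + 1) / 2)
            - math.lgamma(df / 2)
            - 0.5 * math.log(df * math.pi)
            - math.log(s)
        )
        self._half_t = lambda x: self._t_const + math.log(2.0) - (
            (df + 1) / 2
        ) * math.log1p((x / s) ** 2 / df)

    # -- parameter unpacking ------------------------------------------------
    def unpack(self, theta: np.ndarray):
        sds = np.exp(theta[:-1].reshape(-1, 3)[:, :2])  # (4, 2)
        rhos = np.tanh(theta[2::3][: len(FACTORS)])
        sigma_r = math.exp(theta[-1])
        return sds, rhos, sigma_r

    def _obs_sd2(self, sigma_r: float) -> np.ndarray:
        if self.spec.se_combination == "quadrature":
            return sigma_r**2 + self.d.se**2
        return (sigma_r + self.d.se) ** 2

    def _precision_and_logdet(self, theta: np.ndarray):
        """Posterior precision A of all coefficients, plus pieces of the
        marginal likelihood; returns (cho, u, logdet_sigma, d2)."""
        sds, rhos, sigma_r = self.unpack(theta)
        d2 = self._obs_sd2(sigma_r)
        W = self.d.W
        inv_d = 1.0 / d2
        A = W.T @ (W * inv_d[:, None])
        u = W.T @ (self.d.y * inv_d)

        p = self.d.p
        tau2 = self.spec.fixed_prior_sd**2
        idx = np.arange(p)
        A[idx, idx] += 1.0 / tau2
        logdet_sigma = p * math.log(tau2)
        for f_i, fac in enumerate(FACTORS):
            si, sj = sds[f_i]
            rho = rhos[f_i]
            L = len(self.d.factor_levels[fac])
            o = self.d.factor_offsets[fac]
            om = 1.0 - rho**2
            det = (si * sj) ** 2 * om
            logdet_sigma += L * math.log(det)
            inv00 = sj**2 / det
            inv11 = si**2 / det
            inv01 = -rho * si * sj / det
            i0 = o + 2 * np.arange(L)
            i1 = i0 + 1
            A[i0, i0] += inv00
            A[i1, i1] += inv11
            A[i0, i1] += inv01
            A[i1, i0] += inv01
        cho = cho_factor(A, lower=True, check_finite=False)
        return cho, u, logdet_sigma, d2

    def log_posterior(self, theta: np.ndarray) -> float:
        if (
            np.any(theta[:-1].reshape(-1, 3)[:, :2] < _LOG_SD_MIN)
            or np.any(theta[:-1].reshape(-1, 3)[:, :2] > _LOG_SD_MAX)
            or theta[-1] < _LOG_SD_MIN
            or theta[-1] > _LOG_SD_MAX
            or np.any(np.abs(theta[2::3][: len(FACTORS)]) > _Z_RHO_MAX)
        ):
            return -np.inf
        try:
            cho, u, logdet_sigma, d2 = self._precision_and_logdet(theta)
        except np.linalg.LinAlgError:
            return -np.inf
        y = self.d.y
        n = len(y)
        quad = float(y @ (y / d2) - u @ cho_solve(cho, u, check_finite=False))
        logdet_A = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ll = -0.5 * (
            n * math.log(2 * math.pi)
            + float(np.sum(np.log(d2)))
            + logdet_sigma
            + logdet_A
            + quad
        )

        sds, rhos, sigma_r = self.unpack(theta)
        lp = 0.0
        for f_i in range(len(FACTORS)):
            si, sj = sds[f_i]
            lp += self._half_t(si) + math.log(si)  # + Jacobian d sd / d log sd
            lp += self._half_t(sj) + math.log(sj)
            lp += math.log1p(-rhos[f_i] ** 2)  # uniform rho, atanh Jacobian
        lp += self._half_t(sigma_r) + math.log(sigma_r)
        return ll + lp

    # -- conditional coefficient draw --------------------------------------
    def draw_coefficients(
        self, theta: np.ndarray, rng: np.random.Generator
    ) -> np.ndarray:
        cho, u, _, _ = self._precision_and_logdet(theta)
        mean = cho_solve(cho, u, check_finite=False)
        z = rng.standard_normal(len(u))
        # A = L L^T  =>  cov = A^{-1}; solve L^T x = z gives x ~ N(0, A^{-1})
        from scipy.linalg import solve_triangular

        x = solve_triangular(cho[0], z, trans="T", lower=True, check_finite=False)
        return mean + x


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------


@dataclass
class PosteriorFit:
    """Draws, diagnostics and scaling for one fitted phenophase model."""

    phenophase: str | None
    spec: ModelSpec
    param_draws: dict[str, np.ndarray]  # name -> (chains, draws)
    group_draws: dict[str, np.ndarray]  # factor -> (chains, draws, levels, 2)
    group_levels: dict[str, list]
    rhat: dict[str, float]
    scaling: ScalingRecord | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return next(iter(self.param_draws.values())).size

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < self.spec.rhat_threshold

    def draws(self, name: str) -> np.ndarray:
        """Flattened draws for one parameter (standardized scale)."""
        return self.param_draws[name].ravel()

    def eti(self, name: str, level: float) -> tuple[float, float]:
        return compute_eti(self.draws(name), level)

    def draws_days(self, name: str) -> np.ndarray:
        if self.scaling is None:
            raise ValueError("no scaling record attached to this fit")
        return self.scaling.to_days(self.draws(name))

    def to_frame(self) -> pd.DataFrame:
        """Long draw table (parameter, chain, draw, value)."""
        rows = []
        for name, arr in self.param_draws.items():
            c, n = arr.shape
            rows.append(
                pd.DataFrame(
                    {
                        "parameter": name,
                        "chain": np.repeat(np.arange(c), n),
                        "draw": np.tile(np.arange(n), c),
                        "value": arr.ravel(),
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _map_start(post: _MarginalPosterior, rng: np.random.Generator) -> np.ndarray:
    y = post.d.y
    s_resid = max(float(np.std(y, ddof=1)) * 0.5, 1e-3)
    base = []
    for _ in FACTORS:
        base += [math.log(0.3 * max(s_resid, 0.1)), math.log(0.15 * max(s_resid, 0.1)), 0.0]
    base.append(math.log(s_resid))
    base = np.array(base)

    def neg(t):
        v = post.log_posterior(t)
        return -v if np.isfinite(v) else 1e12

    best = None
    for k in range(3):
        x0 = base + (0.3 * rng.standard_normal(post.ndim) if k else 0.0)
        res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 200})
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def _laplace_scale(post: _MarginalPosterior, theta_map: np.ndarray) -> np.ndarray:
    """Cholesky factor of the MAP-Hessian inverse, for posterior-shaped
    walker initialization; falls back to 0.1 * I when not positive definite."""
    h = 1e-4
    n = post.ndim
    H = np.empty((n, n))
    f0 = post.log_posterior(theta_map)
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = h
            ej[j] = h
            H[i, j] = H[j, i] = -(
                post.log_posterior(theta_map + ei + ej)
                - post.log_posterior(theta_map + ei - ej)
                - post.log_posterior(theta_map - ei + ej)
                + post.log_posterior(theta_map - ei - ej)
            ) / (4 * h * h)
    if not np.isfinite(H).all() or not np.isfinite(f0):
        return 0.1 * np.eye(n)
    try:
        Hc = np.linalg.cholesky(H + 1e-8 * np.eye(n))
        # L with cov = H^{-1}: solve Hc^T L = I
        L = np.linalg.inv(Hc).T
        # cap the scatter so walkers stay in a sane region
        norms = np.linalg.norm(L, axis=1)
        L[norms > 2.0] *= (2.0 / norms[norms > 2.0])[:, None]
        return L
    except np.linalg.LinAlgError:
        return 0.1 * np.eye(n)


def _run_chains(post: _MarginalPosterior, spec: ModelSpec):
    ss = np.random.SeedSequence(spec.seed)
    child = ss.spawn(spec.chains + 1)
    rng0 = np.random.default_rng(child[-1])
    theta_map = _map_start(post, rng0)
    scale = _laplace_scale(post, theta_map)

    nw = max(spec.walkers, 2 * post.ndim + 2)
    nw += nw % 2
    moves = [(emcee.moves.DEMove(), 0.8), (emcee.moves.DESnookerMove(), 0.2)]
    chain_thetas = []
    for c in range(spec.chains):
        rng = np.random.default_rng(child[c])
        init = theta_map + rng.standard_normal((nw, post.ndim)) @ scale.T
        sampler = emcee.EnsembleSampler(nw, post.ndim, post.log_posterior, moves=moves)
        sampler.random_state = np.random.RandomState(
            int(rng.integers(2**31 - 1))
        ).get_state()
        sampler.run_mcmc(init, spec.steps, progress=False, skip_initial_state_check=True)
        chain = sampler.get_chain(discard=spec.burn_steps)  # (steps, nw, ndim)
        chain_thetas.append(chain.reshape(-1, post.ndim))
    return chain_thetas, [np.random.default_rng(child[c].spawn(1)[0]) for c in range(spec.chains)]


def _fit(df: pd.DataFrame, st_cols: list[str], spec: ModelSpec,
         scaling: ScalingRecord | None) -> PosteriorFit:
    design = _build_design(df, st_cols)
    post = _MarginalPosterior(design, spec)
    chain_thetas, coef_rngs = _run_chains(post, spec)
    n_per = min(len(t) for t in chain_thetas)
    thetas = np.stack([t[:n_per] for t in chain_thetas])  # (chains, n, ndim)

    # conditional coefficient draws
    q = design.W.shape[1]
    coefs = np.empty((spec.chains, n_per, q))
    for c in range(spec.chains):
        rng = coef_rngs[c]
        for i in range(n_per):
            coefs[c, i] = post.draw_coefficients(thetas[c, i], rng)

    param_draws: dict[str, np.ndarray] = {}
    for j, name in enumerate(design.fixed_names):
        param_draws[name] = coefs[:, :, j]
    for f_i, fac in enumerate(FACTORS):
        param_draws[f"sd_{fac}_intercept"] = np.exp(thetas[:, :, 3 * f_i])
        param_draws[f"sd_{fac}_trt"] = np.exp(thetas[:, :, 3 * f_i + 1])
        param_draws[f"cor_{fac}"] = np.tanh(thetas[:, :, 3 * f_i + 2])
    param_draws["sigma_resid"] = np.exp(thetas[:, :, -1])

    group_draws = {}
    for fac in FACTORS:
        o = design.factor_offsets[fac]
        L = len(design.factor_levels[fac])
        group_draws[fac] = coefs[:, :, o : o + 2 * L].reshape(
            spec.chains, n_per, L, 2
        )

    rhat = {name: gelman_rubin(arr) for name, arr in param_draws.items()}
    for fac in FACTORS:
        g = group_draws[fac]
        for li, lvl in enumerate(design.factor_levels[fac]):
            rhat[f"r_{fac}[{lvl},intercept]"] = gelman_rubin(g[:, :, li, 0])
            rhat[f"r_{fac}[{lvl},trt]"] = gelman_rubin(g[:, :, li, 1])

    fit = PosteriorFit(
        phenophase=spec.phenophase,
        spec=spec,
        param_draws=param_draws,
        group_draws=group_draws,
        group_levels=dict(design.factor_levels),
        rhat=rhat,
        scaling=scaling,
        metadata={
            "se_combination": spec.se_combination,
            "fixed_effect_prior": f"Normal(0, {spec.fixed_prior_sd}^2) "
            "(proper stand-in for a flat prior)",
            "st_predictors": list(st_cols),
            "n_replicates": len(df),
        },
    )
    if not fit.converged:
        logger.warning(
            "fit flagged non-converged: max R-hat = %.3f", fit.max_rhat
        )
    return fit


def fit_treatment_model(
    replicate_estimates: pd.DataFrame,
    model_spec: ModelSpec,
    scaling: ScalingRecord | None = None,
) -> PosteriorFit:
    """Fit the treatment-only hierarchical model to one phenophase's replicates.

    ``replicate_estimates`` needs columns mu, se (standardized scale),
    treatment ('otc'/'control'), species, site, subsite, year.
    """
    return _fit(replicate_estimates, [], model_spec, scaling)


def _st_columns(df: pd.DataFrame, st_predictor: str) -> tuple[pd.DataFrame, list[str]]:
    df = df.copy()
    if st_predictor == "years":
        start = df.groupby("subsite")["year"].transform("min")
        v = (df["year"] - start + 1).astype(float)
        df["years_warming"] = v - v.mean()
        return df, ["years_warming"]
    if st_predictor == "latitude":
        v = df["latitude"].astype(float)
        df["latitude_centered"] = v - v.mean()
        return df, ["latitude_centered"]
    if st_predictor == "moisture":
        df["moisture_moist"] = (df["moisture"] == "moist").astype(float)
        df["moisture_wet"] = (df["moisture"] == "wet").astype(float)
        return df, ["moisture_moist", "moisture_wet"]
    if st_predictor == "deployment":
        df["deployment_summer_only"] = (df["deployment"] == "summer_only").astype(float)
        return df, ["deployment_summer_only"]
    if st_predictor == "climate":
        return df, ["site_temp_centered", "delta_t"]
    raise ValueError(f"unknown spatiotemporal predictor {st_predictor!r}")


def fit_interaction_model(
    replicate_estimates: pd.DataFrame,
    st_predictor: str | list[str],
    model_spec: ModelSpec,
    scaling: ScalingRecord | None = None,
) -> PosteriorFit:
    """Treatment model plus fixed main effect and treatment interaction of a
    spatiotemporal predictor.

    ``st_predictor`` is one of 'years', 'latitude', 'moisture', 'deployment',
    'climate' (the latter enters both group-means-centered climate predictors
    together), or an explicit list of numeric columns.  Categorical
    predictors use indicator coding with reference levels dry (moisture) and
    year_round (deployment).  Predictors constant across the data are
    dropped with a diagnostic.
    """
    if isinstance(st_predictor, str):
        df, cols = _st_columns(replicate_estimates, st_predictor)
    else:
        df, cols = replicate_estimates.copy(), list(st_predictor)
    kept = []
    for c in cols:
        if df[c].nunique() <= 1:
            logger.warning("predictor %r constant across data; interaction dropped", c)
        else:
            kept.append(c)
    return _fit(df, kept, model_spec, scaling)


# ---------------------------------------------------------------------------
# effect summaries
# ---------------------------------------------------------------------------


def summarize_effects(fit: PosteriorFit, scaling: ScalingRecord | None = None) -> pd.DataFrame:
    """Day-unit posterior summaries for all fixed effect parameters.

    Draws are multiplied by the phenophase midpoint SD to express effects in
    days; rows carry the posterior mean, SD, 90/95% ETIs and zero-exclusion
    flags (the intercept is omitted — it is a location, not an effect; see
    :func:`phenowarm.durations.baseline_intercepts`).
    """
    scaling = scaling or fit.scaling
    if scaling is None:
        raise ValueError("scaling record required to express effects in days")
    rows = []
    for name in fit.param_draws:
        if not name.startswith("beta"):
            continue
        d = scaling.to_days(fit.draws(name))
        lo90, hi90 = compute_eti(d, 0.90)
        lo95, hi95 = compute_eti(d, 0.95)
        rows.append(
            {
                "phenophase": fit.phenophase,
                "parameter": name,
                "estimate_days": float(np.mean(d)),
                "std_error_days": float(np.std(d, ddof=1)),
                "eti90_low": lo90,
                "eti90_high": hi90,
                "eti95_low": lo95,
                "eti95_high": hi95,
                "effect_90": bool(lo90 > 0 or hi90 < 0),
                "effect_95": bool(lo95 > 0 or hi95 < 0),
                "rhat": fit.rhat[name],
            }
        )
    return pd.DataFrame(rows)
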