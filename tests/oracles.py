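"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own numerics: the interval likelihood
is evaluated directly through scipy's normal CDF and maximized by grid
search (coarse pass over the full box, then a dense 1e-3 refinement around
the coarse optimum), so agreement with the quasi-Newton fit is a genuine
two-route check.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

GRID_FINE_STEP = 1e-3


def grid_loglik(mu_grid, logsig_grid, lower, upper):
    """Log-likelihood surface via plain norm.cdf (no stable rewrites)."""
    mu = np.asarray(mu_grid)[:, None, None]
    sig = np.exp(np.asarray(logsig_grid))[None, :, None]
    lo = np.asarray(lower)[None, None, :]
    hi = np.asarray(upper)[None, None, :]
    p = norm.cdf((hi - mu) / sig) - norm.cdf((lo - mu) / sig)
    return np.sum(np.log(np.clip(p, 1e-300, None)), axis=2)


def grid_search_mle(
    lower,
    upper,
    mu_range=None,
    logsig_range=(-3.0, 2.0),
    coarse_step=0.05,
):
    """Grid-search maximizer of the interval-censored normal likelihood.

    Coarse grid at ``coarse_step`` over the full box, then exhaustive
    refinement at step 1e-3 in a +/- 2*coarse_step window around the coarse
    optimum.  Returns (mu, log_sigma).
    """
    lower = np.asarray(lower, float)
    upper = np.asarray(upper, float)
    if mu_range is None:
        mu_range = (lower.min() - 2.0, upper.max() + 2.0)

    mu_g = np.arange(mu_range[0], mu_range[1] + coarse_step, coarse_step)
    ls_g = np.arange(logsig_range[0], logsig_range[1] + coarse_step, coarse_step)
    ll = grid_loglik(mu_g, ls_g, lower, upper)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    mu0, ls0 = mu_g[i], ls_g[j]

    w = 2 * coarse_step
    mu_f = np.arange(mu0 - w, mu0 + w + GRID_FINE_STEP, GRID_FINE_STEP)
    ls_f = np.arange(
        max(ls0 - w, logsig_range[0]),
        min(ls0 + w, logsig_range[1]) + GRID_FINE_STEP,
        GRID_FINE_STEP,
    )
    ll = grid_loglik(mu_f, ls_f, lower, upper)
    i, j = np.unravel_index(np.argmax(ll), ll.shape)
    return float(mu_f[i]), float(ls_f[j])
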