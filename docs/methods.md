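# Methods

## Problem and model

Open-top chambers (OTCs) passively warm tundra plots by ~0.5–2.3 °C.
Multi-site OTC networks record, for many species and years, the day of year
(DOY) at which each plant phenophase (green up, flowering, end of flowering,
fruiting, seed dispersal, leaf senescence) is first observed. Two features
make naïve analysis biased: the event is only known to lie between the
previous census visit and the visit at which it was recorded (interval
censoring, with visit cadence varying across sites and years), and timing
varies hierarchically — among species, sites, years within sites, and
subsites within sites — in both baseline DOY and in the response to warming.

The package implements the standard two-stage solution.

**Stage 1 — replicate timing.** A *replicate* r is one treatment × species ×
subsite × year cell within a phenophase. Each observation i in the cell
contributes an interval (L_i, U_i]; the model is

    Y_i ~ Normal(mu_r, sigma_r^2),   contribution P(L_i < Y_i <= U_i),

an intercept-only interval-censored normal regression. We maximize the
likelihood in (mu, log sigma) with L-BFGS-B (analytic gradient, three
multistarts seeded by the midpoint mean/SD, final Newton polish) and take
the standard error of mu from the inverse observed information (central
differences of the analytic gradient, step 1e-5, on the standardized
scale). Whenever all intervals in a replicate share a common point —
identical bounds are the extreme case, but intervals merely touching at a
shared census date count too — the likelihood is maximized on the
sigma → 0 boundary (it rises monotonically as sigma shrinks with mu at the
common point) and carries no usable scale information; such replicates fall
back to the midpoint average, with the SE borrowed from the mean SE of
fitted replicates in the same species × subsite × treatment stratum
(phenophase mean SE when the stratum has none). Fitted SEs additionally
carry a census-resolution floor, `sqrt(mean(width^2) / 12 / n)`: an event
located only to a width-w interval cannot be known more precisely than the
rounding limit w/sqrt(12), which guards against near-degenerate replicates
whose fitted sigma collapses below the census resolution. With these two
rules the stage-1 z-scores (error over SE against the generating truth)
are calibrated: |mu_hat − mu_true| < 2·SE in roughly 95% of simulated
replicates at ~8 observations per replicate (checked in the test suite).

**Stage 2 — hierarchical measurement-error model.** Replicate means
(standardized per phenophase) with their known SEs enter

    mu_r ~ Normal( alpha + a_s + a_k + a_y + a_j
                   + (beta + b_s + b_k + b_y + b_j) * Trt_r,
                   sd_obs,r ),

with Trt_r an OTC indicator and correlated (intercept, slope) pairs per
grouping factor, (a_g, b_g) ~ MVN(0, S_g), S_g built from two SDs and a
correlation rho_g. The observation SD combines the residual scale with the
stage-1 SE in quadrature, `sd_obs = sqrt(sigma_r^2 + se_r^2)` — the
convention of measurement-error ("known SE") regression — with the literal
sum `sigma_r + se_r` available via `ModelSpec(se_combination="sum")` for
sensitivity analysis. Interaction models add a fixed main effect and
treatment interaction for one spatiotemporal predictor (years of warming,
latitude, soil-moisture class with reference *dry*, chamber deployment
period with reference *year_round*), or for the two group-means-centered
climate predictors together (between-site mean window temperature and the
within-site yearly anomaly), which are uncorrelated by construction.

Priors: Normal(0, 100^2) on fixed effects (a proper stand-in for flat
priors; on the standardized scale, where the data SD is 1, it is
numerically indistinguishable from flat), half-Student-t(df 3, scale 10) on
every SD, and uniform(-1, 1) correlations (the two-dimensional LKJ(1)
prior).

## Sampling

The model is linear-Gaussian given the variance parameters, so all
coefficients — fixed effects and group deviations — are integrated out
analytically. Writing W = [X | Z] and Sigma for the joint prior covariance
of the coefficients, the marginal likelihood of the 13 variance/correlation
hyperparameters uses the Woodbury/low-rank identities

    V = D + W Sigma W',   log|V| = log|D| + log|Sigma| + log|A|,
    A = Sigma^{-1} + W' D^{-1} W,

with D the diagonal observation variances; each evaluation costs
O(n q^2) for q coefficient columns. The hyperparameters are sampled on an
unconstrained scale (log SDs, atanh correlations, log residual SD, with the
appropriate Jacobians) by an affine-invariant ensemble sampler using
differential-evolution moves. Walkers start from a Laplace approximation —
a MAP estimate found by quasi-Newton optimization, scattered with the
MAP-Hessian-inverse Cholesky factor — so the ensemble begins in the
posterior-typical set and short warmups mix. Two independent ensembles
serve as the two chains; `iterations` counts posterior-density evaluations
per chain (ensemble steps = iterations / walkers, default 32 walkers), so
the default 2 chains × 10,000 iterations with 5,000 warmup matches the
conventional budget for this model family. For each retained hyperparameter
draw, the full coefficient vector is drawn from its exact Gaussian
conditional N(A^{-1} W' D^{-1} y, A^{-1}). This marginalization is the
package's answer to the funnel geometry that motivates non-centered
parameterizations: the deviations are never sampled at all.

Convergence is assessed with the classic split Gelman–Rubin statistic on
every stored parameter (hyperparameters, fixed effects and conditionally
drawn deviations); a fit is flagged non-converged when any split R-hat
exceeds 1.1. Summaries use equal-tailed credible intervals (symmetric
empirical quantiles) at 90% and 95%, and an effect is declared when the
interval excludes zero; no multiplicity correction is applied across
phenophases. Effects are returned in days by multiplying standardized draws
by the phenophase midpoint SD; intercepts are returned as DOY via the full
affine back-transform.

## Data preparation rules

Applied in order, each with a reconciling row ledger:

1. *Missingness* (green up and leaf senescence only): a species × subsite ×
   year cell with more than 20% of observations missing is dropped; rows
   with no recorded event are then removed everywhere.
2. *Prior visit*: the lower bound is the most recent same-plot-and-year
   visit before the recorded DOY. If the event preceded the first visit,
   the bound is the species' minimum prior-visit DOY across years minus 21
   days, floored at DOY 100 (green up) or 120 (flowering, end of
   flowering); phenophases without a stated floor use 100, with a warning.
   Intervals are half-open (prior, recorded]: the event happened strictly
   after the prior visit and at or before the recorded one.
3. *Minimum replication*: cells lacking two observations in either
   treatment arm are dropped.
4. *Outliers*: the warmed-minus-control difference of cell midpoint means
   is computed per phenophase on the raw DOY scale (the pairing is only
   defined at the cell level, which is why this precedes standardization);
   cells more than 4 SD from the phenophase mean are dropped. Phenophases
   with fewer than 3 paired cells, or zero-SD differences, are left alone.
   The rule is deliberately single-pass: re-running it on its own output
   can remove further cells because the SD shrinks, so it is not idempotent
   and is applied exactly once.
5. *Standardization*: per phenophase, both interval bounds get the same
   affine map (midpoint mean/SD), preserving interval structure so stage-1
   estimates back-transform exactly. Zero midpoint SD aborts with a
   diagnostic.

## Climate windows

The window for a species × site × phenophase is the 30 days up to the mean
event DOY (interval midpoints, both treatments and all years pooled;
clipped at DOY 1). Missing daily temperatures are infilled by linear
regression on the most-correlated other site over shared days, falling back
to the long-term day-of-year mean; infilled days are flagged. Years with
more than five infilled window days (or any unfillable window day) are
excluded, so climate interaction models carry slightly fewer replicates.
The site mean temperature is the across-year mean of retained yearly window
means; the yearly anomaly is the yearly mean minus the site mean
(**warm-year-positive** — the convention is recorded in output metadata
because the opposite sign convention also appears in the literature, and
the interaction coefficient flips sign with it).

## Duration contrasts

Phenoperiods pair a start and an end phenophase (growth: green up → leaf
senescence; flowering: start → end; fruiting: fruiting → seed dispersal —
most tundra fruits are dehiscent, so "fruiting" marks first seed
development and the period ends at dispersal). The change in duration under
warming is the difference of the two treatment-effect posteriors (end minus
start, in days). The fits are independent, so draws are paired by index
after a fixed-seed permutation: the contrast mean is exactly the difference
of component means (linearity), swapping the phases negates it
(antisymmetry), and the ETI treats the posteriors as independent — the only
defensible reading absent a joint fit. Baseline DOY per phenophase comes
from the treatment-only intercepts un-standardized to DOY; baseline period
lengths difference those draws the same way.

## Synthetic data

The generator emulates the observational design the method targets: sites →
subsites → paired warmed/control plots; species present at a random subset
of sites; per-plot-year census schedules with uniform 3–10-day cadence in a
DOY 145–260 season (occasionally starting late, so some events precede the
first visit and exercise the fallback bound); events drawn from the
stage-2 model run forward (global intercept and treatment effect per
phenophase plus correlated group deviations and Gaussian residual);
optional spatiotemporal modifiers of the warming slope (moisture,
deployment, latitude, years, site temperature, anomaly); daily site
temperature as a seasonal sinusoid plus site offset, yearly anomaly and
iid noise, with missingness; and per-plot snowmelt advanced in warmed plots
only under year-round deployment (default 1.02 days). Default truth values
are field-realistic for tundra OTC experiments: advances of a few days for
reproductive phases, sub-day shifts for vegetative ones, a delayed
senescence, baseline intercepts giving ~50-day growing and ~18-day
flowering periods, large between-species/site baseline spread (SD 7–10 d)
and small treatment-response spread (SD ~1–1.5 d), residual SD 3 d.

What the generator does *not* emulate: non-normal event-time distributions,
snow- or photoperiod-driven censoring, spatial autocorrelation among sites,
phylogenetic structure among species, taxonomy errors, or observer effects.
Passing recovery and coverage tests therefore demonstrates correctness of
the estimation machinery under the stated model, not robustness to these
real-data features.

## Numerical choices and limitations

- Interval log-probabilities use `log Phi` differences with symmetric tail
  reflection and `log1p`; gradients use log-space Mills-ratio terms, so the
  likelihood is finite and smooth far into the tails.
- Event-order enforcement across phenophases is off by default (phenophases
  are modeled independently); a rejection option exists.
- Grid-search testing oracle: coarse 0.05 grid over the full box, then an
  exhaustive 1e-3 refinement around the coarse optimum — equivalent to a
  flat 1e-3 grid for these smooth unimodal likelihoods at a fraction of the
  cost.
- Problem sizes in tests and in `scripts/acceptance.py` are scaled-down
  networks (e.g. 4–6 sites, 5–10 species, 2–4 years) chosen so the full
  hierarchy stays exercised while each fit remains a desk-scale
  computation; the sampler budget in those runs is 2 × 2,000–4,000
  iterations rather than the 2 × 10,000 default.
- With very few levels in a grouping factor (2–3 sites), the half-t prior
  on that factor's slope SD dominates and the global treatment-effect
  posterior widens accordingly; this is faithful Bayesian behaviour, not a
  defect, but it makes tiny-network recovery tests calibration-style rather
  than point-accuracy checks.
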