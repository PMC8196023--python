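"""Generator of ITEX-like phenology observation tables with known ground truth.

Emulates a multi-site open-top-chamber (OTC) warming network: sites contain
subsites, subsites contain paired warmed/control plots, species are present
at a random subset of sites, and each plot x species x year x phenophase
produces one (interval-censored) event record. Hierarchical variation enters
both the baseline timing (intercepts) and the treatment response (slopes) at
the species, site, site:year and site:subsite levels, with configurable SDs
and intercept-slope correlations, so downstream inference can be checked
against the generating truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

from .constants import (
    PHENOPHASES,
    TREATMENTS,
    MOISTURE_CLASSES,
    DEPLOYMENTS,
)

GROUP_FACTORS = ("species", "site", "site_year", "site_subsite")


# ---------------------------------------------------------------------------
# Truth parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffectTruth:
    """SDs (days) and correlation of one grouping factor's (intercept, slope)."""

    sd_intercept: float
    sd_slope: float
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.sd_intercept < 0 or self.sd_slope < 0:
            raise ValueError("group-level SDs must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("correlation must lie in [-1, 1]")

    def cov(self) -> np.ndarray:
        c = self.rho * self.sd_intercept * self.sd_slope
        return np.array(
            [[self.sd_intercept**2, c], [c, self.sd_slope**2]]
        )


@dataclass(frozen=True)
class TruthParameters:
    """Ground-truth generative parameters, all in days (DOY scale).

    ``treatment_effects`` follow the warmed-minus-control convention:
    negative values are phenological advances.  ``interactions`` modify the
    treatment slope through spatiotemporal predictors; supported keys:
    ``moisture_moist``, ``moisture_wet`` (days added to the warming effect at
    moist/wet subsites relative to dry), ``deployment_summer_only`` (days,
    relative to year-round chambers), ``latitude`` (days per degree, centered),
    ``years`` (days per year of warming, centered), ``site_temp`` (days per
    degree C of site mean window temperature), ``anomaly`` (days per degree C
    of site-year temperature anomaly).
    """

    intercepts: Mapping[str, float]
    treatment_effects: Mapping[str, float]
    groups: Mapping[str, GroupEffectTruth]
    residual_sd: float = 3.0
    interactions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        missing = set(GROUP_FACTORS) - set(self.groups)
        if missing:
            raise ValueError(f"missing group truth for factors: {sorted(missing)}")

    @classmethod
    def default(cls) -> "TruthParameters":
        """Field-realistic defaults for a tundra warming experiment.

        Baseline intercepts give a ~50-day growing period (green up to
        senescence) and an ~18-day flowering period; warming effects are a
        few days, advancing reproductive phases more than vegetative ones
        and delaying senescence.  Between-species and between-site spread in
        baseline timing dominates (SD ~ 7-10 d), treatment-response spread
        is small (SD ~ 1-2 d), matching what OTC syntheses report.
        """
        return cls(
            intercepts={
                "green_up": 165.0,
                "flowering": 175.0,
                "end_of_flowering": 193.0,
                "fruiting": 200.0,
                "seed_dispersal": 222.0,
                "leaf_senescence": 215.0,
            },
            treatment_effects={
                "green_up": -0.7,
                "flowering": -2.4,
                "end_of_flowering": -1.9,
                "fruiting": -2.6,
                "seed_dispersal": -2.9,
                "leaf_senescence": 0.8,
            },
            groups={
                "species": GroupEffectTruth(10.0, 1.5, 0.0),
                "site": GroupEffectTruth(7.0, 1.5, 0.0),
                "site_year": GroupEffectTruth(4.0, 1.0, 0.0),
                "site_subsite": GroupEffectTruth(2.0, 0.8, 0.0),
            },
            residual_sd=3.0,
        )

    def to_json(self, path) -> None:
        payload = {
            "intercepts": dict(self.intercepts),
            "treatment_effects": dict(self.treatment_effects),
            "groups": {k: asdict(v) for k, v in self.groups.items()},
            "residual_sd": self.residual_sd,
            "interactions": dict(self.interactions),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "TruthParameters":
        with open(path) as fh:
            payload = json.load(fh)
        payload["groups"] = {
            k: GroupEffectTruth(**v) for k, v in payload["groups"].items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# Design
# ---------------------------------------------------------------------------


def generate_design(
    n_sites: int,
    n_subsites_per_site: int,
    n_species: int,
    n_years: int,
    n_plots_per_treatment: int,
    seed: int,
    phenophases: tuple[str, ...] = PHENOPHASES,
    species_site_prob: float = 0.75,
) -> pd.DataFrame:
    """Build a nested design table, one row per plot x species x year x phenophase.

    Species are assigned to a random subset of sites (each species present at
    >= 1 site, each site hosting >= 1 species) to mimic incomplete species
    coverage across a network.  Latitude, soil-moisture class and chamber
    deployment period are attached as site/subsite metadata columns.
    """
    for name, v in [
        ("n_sites", n_sites),
        ("n_subsites_per_site", n_subsites_per_site),
        ("n_species", n_species),
        ("n_years", n_years),
        ("n_plots_per_treatment", n_plots_per_treatment),
    ]:
        if v < 1:
            raise ValueError(f"{name} must be >= 1, got {v}")
    unknown = set(phenophases) - set(PHENOPHASES)
    if unknown:
        raise ValueError(f"unknown phenophases: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    sites = [f"site{i:02d}" for i in range(1, n_sites + 1)]
    species = [f"sp{i:02d}" for i in range(1, n_species + 1)]
    years = list(range(2001, 2001 + n_years))

    latitude = {s: float(rng.uniform(40.0, 79.0)) for s in sites}
    deployment = {s: DEPLOYMENTS[rng.integers(len(DEPLOYMENTS))] for s in sites}

    # species -> sites presence, forced non-empty both ways
    presence = rng.random((n_species, n_sites)) < species_site_prob
    for i in range(n_species):
        if not presence[i].any():
            presence[i, rng.integers(n_sites)] = True
    for j in range(n_sites):
        if not presence[:, j].any():
            presence[rng.integers(n_species), j] = True

    rows = []
    for j, site in enumerate(sites):
        for sub_idx in range(1, n_subsites_per_site + 1):
            subsite = f"{site}_sub{sub_idx}"
            moisture = MOISTURE_CLASSES[rng.integers(len(MOISTURE_CLASSES))]
            for trt in TREATMENTS:
                for p in range(1, n_plots_per_treatment + 1):
                    plot = f"{subsite}_{trt}{p}"
                    for i, sp in enumerate(species):
                        if not presence[i, j]:
                            continue
                        for year in years:
                            for ph in phenophases:
                                rows.append(
                                    (
                                        site,
                                        subsite,
                                        plot,
                                        year,
                                        trt,
                                        sp,
                                        ph,
                                        latitude[site],
                                        moisture,
                                        deployment[site],
                                    )
                                )
    design = pd.DataFrame(
        rows,
        columns=[
            "site",
            "subsite",
            "plot",
            "year",
            "treatment",
            "species",
            "phenophase",
            "latitude",
            "moisture",
            "deployment",
        ],
    )
    return design


# ---------------------------------------------------------------------------
# Event simulation
# ---------------------------------------------------------------------------


def _draw_group_deviations(
    levels: np.ndarray, truth: GroupEffectTruth, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    chol = np.linalg.cholesky(truth.cov() + 1e-12 * np.eye(2))
    draws = rng.standard_normal((len(levels), 2)) @ chol.T
    return {lvl: draws[i] for i, lvl in enumerate(levels)}


def simulate_events(
    design: pd.DataFrame,
    truth: TruthParameters,
    seed: int,
    climate_truth: pd.DataFrame | None = None,
    enforce_order: bool = False,
    max_order_tries: int = 200,
) -> pd.DataFrame:
    """Draw one true (real-valued) event DOY per design row.

    The generative model is the inverse of the inference model: global
    intercept + group intercept deviations + treatment x (global slope +
    group slope deviations + interaction terms) + Gaussian residual.  Group
    deviations are drawn independently per phenophase, since each phenophase
    is modeled separately downstream.

    ``climate_truth`` (site, year, site_temp, anomaly) is required when the
    truth includes ``site_temp`` or ``anomaly`` interaction coefficients.

    With ``enforce_order`` the seasonal ordering green_up <= flowering <= ...
    is imposed per plot x species x year by re-drawing residuals (rejection);
    off by default because phenophases are modeled independently.
    """
    rng = np.random.default_rng(seed)
    df = design.copy()

    needs_climate = {"site_temp", "anomaly"} & set(truth.interactions)
    if needs_climate and climate_truth is None:
        raise ValueError(
            f"interactions {sorted(needs_climate)} require climate_truth"
        )

    df["site_year"] = df["site"] + ":" + df["year"].astype(str)
    df["site_subsite"] = df["subsite"]

    trt = (df["treatment"] == "otc").to_numpy(float)

    # slope modifiers from spatiotemporal interactions (shared across phases)
    slope_extra = np.zeros(len(df))
    inter = truth.interactions
    if "moisture_moist" in inter:
        slope_extra += inter["moisture_moist"] * (df["moisture"] == "moist")
    if "moisture_wet" in inter:
        slope_extra += inter["moisture_wet"] * (df["moisture"] == "wet")
    if "deployment_summer_only" in inter:
        slope_extra += inter["deployment_summer_only"] * (
            df["deployment"] == "summer_only"
        )
    if "latitude" in inter:
        lat = df["latitude"].to_numpy()
        slope_extra += inter["latitude"] * (lat - lat.mean())
    if "years" in inter:
        yr = df["year"].to_numpy(float)
        slope_extra += inter["years"] * (yr - yr.mean())
    if needs_climate:
        ct = climate_truth.set_index(["site", "year"])
        if "site_temp" in inter:
            st = ct.groupby("site")["site_temp"].mean()
            stv = df["site"].map(st).to_numpy(float)
            slope_extra += inter["site_temp"] * (stv - stv.mean())
        if "anomaly" in inter:
            anom = df.set_index(["site", "year"]).index.map(ct["anomaly"])
            slope_extra += inter["anomaly"] * np.asarray(anom, float)

    factor_levels = {
        "species": df["species"].unique(),
        "site": df["site"].unique(),
        "site_year": df["site_year"].unique(),
        "site_subsite": df["site_subsite"].unique(),
    }

    out_mu = []
    for ph in df["phenophase"].unique():
        mask = (df["phenophase"] == ph).to_numpy()
        sub = df.loc[mask]
        mean = np.full(mask.sum(), truth.intercepts[ph], float)
        slope = np.full(mask.sum(), truth.treatment_effects[ph], float)
        for fac in GROUP_FACTORS:
            devs = _draw_group_deviations(factor_levels[fac], truth.groups[fac], rng)
            dv = np.array([devs[lvl] for lvl in sub[fac]])
            mean += dv[:, 0]
            slope += dv[:, 1]
        mu = mean + trt[mask] * (slope + slope_extra[mask])
        out_mu.append(pd.Series(mu, index=sub.index))
    latent_mu = pd.concat(out_mu).sort_index().to_numpy()
    df["latent_mean"] = latent_mu  # noiseless cell mean, for calibration checks
    df["true_doy"] = latent_mu + rng.normal(0.0, truth.residual_sd, size=len(df))

    if enforce_order:
        order = {ph: i for i, ph in enumerate(PHENOPHASES)}
        key = ["plot", "species", "year"]
        ordval = df["phenophase"].map(order)
        for _ in range(max_order_tries):
            srt = df.assign(_o=ordval).sort_values("_o")
            bad = srt.groupby(key)["true_doy"].apply(
                lambda x: (np.diff(x.to_numpy()) < 0).any()
            )
            bad_keys = set(bad[bad].index)
            if not bad_keys:
                break
            idx = pd.MultiIndex.from_frame(df[key]).isin(bad_keys)
            df.loc[idx, "true_doy"] = latent_mu[idx] + rng.normal(
                0.0, truth.residual_sd, size=int(idx.sum())
            )
    return df.drop(columns=["site_year", "site_subsite"])


# ---------------------------------------------------------------------------
# Census censoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CensusConfig:
    """Census-schedule generator settings.

    Visit cadence is uniform on [interval_min, interval_max] days between
    ``season_start`` and ``season_end``; with probability ``p_late_start``
    the first visit is shifted late by ``late_start_shift`` days so that
    some events precede the first visit (exercising the fallback bound).
    ``p_random_missing`` marks recorded events missing at random, on top of
    season-end truncation.
    """

    season_start: int = 145
    season_end: int = 260
    interval_min: int = 3
    interval_max: int = 10
    p_late_start: float = 0.05
    late_start_shift: int = 25
    p_random_missing: float = 0.02

    def __post_init__(self) -> None:
        if self.interval_min < 1 or self.interval_max < self.interval_min:
            raise ValueError("require 1 <= interval_min <= interval_max")
        if self.season_end <= self.season_start:
            raise ValueError("season_end must exceed season_start")


def censor_by_census(
    true_events: pd.DataFrame, config: CensusConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Censor true event DOYs by a simulated per-plot-year census schedule.

    Returns ``(observations, visits)``.  Recorded DOY is the first visit at
    or after the true event; the prior visit is the visit immediately before.
    Events after the last visit (or hit by random missingness) get a missing
    recorded DOY; events before the first visit get a recorded DOY with no
    prior visit.  ``true_doy`` is carried through for validation.
    """
    rng = np.random.default_rng(seed)
    plot_years = true_events[["plot", "year"]].drop_duplicates()
    if len(plot_years) == 0:
        raise ValueError("no plot-years to schedule")

    visit_rows = []
    schedules: dict[tuple, np.ndarray] = {}
    for plot, year in plot_years.itertuples(index=False):
        start = config.season_start
        if rng.random() < config.p_late_start:
            start += config.late_start_shift
        visits = [start]
        while True:
            nxt = visits[-1] + int(
                rng.integers(config.interval_min, config.interval_max + 1)
            )
            if nxt > config.season_end:
                break
            visits.append(nxt)
        v = np.array(visits)
        schedules[(plot, year)] = v
        visit_rows.extend((plot, year, int(d)) for d in v)
    visits_df = pd.DataFrame(visit_rows, columns=["plot", "year", "visit_doy"])

    obs = true_events.copy()
    rec = np.full(len(obs), np.nan)
    prior = np.full(len(obs), np.nan)
    keys = list(zip(obs["plot"], obs["year"]))
    td = obs["true_doy"].to_numpy()
    for i, key in enumerate(keys):
        v = schedules[key]
        idx = int(np.searchsorted(v, td[i], side="left"))
        if idx == len(v):
            continue  # event after last visit -> missing
        rec[i] = v[idx]
        if idx > 0:
            prior[i] = v[idx - 1]
    missing = rng.random(len(obs)) < config.p_random_missing
    rec[missing] = np.nan
    prior[missing] = np.nan

    obs["doy"] = pd.array(rec, dtype="Int64")
    obs["prior_visit"] = pd.array(prior, dtype="Int64")
    return obs, visits_df


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ClimateConfig:
    """Daily mean air-temperature generator settings.

    A smooth seasonal sinusoid (peak at ``peak_doy``) plus a per-site offset,
    a per-site-year anomaly and iid daily noise.  ``injected_anomalies`` maps
    (site, year) to a degrees-C shift with known sign/magnitude so that the
    climate-interaction coefficient can be recovered exactly in tests.
    """

    mean_annual: float = -6.0
    seasonal_amplitude: float = 15.0
    peak_doy: int = 200
    site_offset_sd: float = 2.0
    anomaly_sd: float = 1.5
    daily_noise_sd: float = 2.0
    p_missing: float = 0.02
    injected_anomalies: Mapping[tuple[str, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("site_offset_sd", "anomaly_sd", "daily_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_missing < 1:
            raise ValueError("p_missing must be in [0, 1)")


def seasonal_curve(doy: np.ndarray, config: ClimateConfig) -> np.ndarray:
    return config.mean_annual + config.seasonal_amplitude * np.cos(
        2 * np.pi * (doy - config.peak_doy) / 366.0
    )


def simulate_climate(
    design: pd.DataFrame, config: ClimateConfig, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate daily site temperature series with missingness flags.

    Returns ``(daily, climate_truth)``; ``daily`` has one row per site x year
    x DOY (tmean is NaN where missing), ``climate_truth`` records the per-site
    offset and per-site-year anomaly actually used (site_temp = mean_annual +
    site offset, the site-level component shared by every day of the year).
    """
    rng = np.random.default_rng(seed)
    sites = sorted(design["site"].unique())
    years = sorted(design["year"].unique())
    doys = np.arange(1, 367)
    base = seasonal_curve(doys, config)

    truth_rows = []
    frames = []
    for site in sites:
        offset = rng.normal(0.0, config.site_offset_sd)
        for year in years:
            anomaly = rng.normal(0.0, config.anomaly_sd)
            anomaly += config.injected_anomalies.get((site, year), 0.0)
            t = base + offset + anomaly + rng.normal(
                0.0, config.daily_noise_sd, size=doys.size
            )
            miss = rng.random(doys.size) < config.p_missing
            t = np.where(miss, np.nan, t)
            frames.append(
                pd.DataFrame(
                    {
                        "site": site,
                        "year": year,
                        "doy": doys,
                        "tmean": t,
                        "is_missing": miss,
                    }
                )
            )
            truth_rows.append(
                (site, year, config.mean_annual + offset, anomaly)
            )
    daily = pd.concat(frames, ignore_index=True)
    climate_truth = pd.DataFrame(
        truth_rows, columns=["site", "year", "site_temp", "anomaly"]
    )
    return daily, climate_truth


# ---------------------------------------------------------------------------
# Snowmelt (optional per-plot column for the year-round OTC contrast)
# ---------------------------------------------------------------------------


def simulate_snowmelt(
    design: pd.DataFrame,
    seed: int,
    base_doy: float = 140.0,
    subsite_sd: float = 5.0,
    plot_sd: float = 2.0,
    otc_advance_days: float = 1.02,
) -> pd.DataFrame:
    """Per plot x year snowmelt DOY; chambers deployed year-round melt out
    ``otc_advance_days`` earlier in warmed plots (no effect for summer-only
    deployment, where chambers are installed after melt)."""
    rng = np.random.default_rng(seed)
    plots = design[
        ["site", "subsite", "plot", "year", "treatment", "deployment"]
    ].drop_duplicates()
    sub_year = plots[["subsite", "year"]].drop_duplicates()
    base = {
        (r.subsite, r.year): base_doy + rng.normal(0.0, subsite_sd)
        for r in sub_year.itertuples(index=False)
    }
    doy = np.array(
        [base[(s, y)] for s, y in zip(plots["subsite"], plots["year"])]
    )
    doy = doy + rng.normal(0.0, plot_sd, size=len(plots))
    warmed_yr = (plots["treatment"] == "otc") & (plots["deployment"] == "year_round")
    doy = doy - otc_advance_days * warmed_yr.to_numpy(float)
    out = plots.copy()
    out["snowmelt_doy"] = doy
    return out.reset_index(drop=True)
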