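"""Raw censored observations -> standardized analysis intervals.

Applies, in order: prior-visit assignment (with the conservative fallback
bound for events that preceded the first visit of the season), the 20%
missingness filter (green up and leaf senescence only), the minimum-two-
observations-per-treatment rule, the 4-SD outlier rule on paired
warmed-minus-control cell differences, and per-phenophase standardization of
the interval bounds by the midpoint mean/SD.

Every filter returns a :class:`FilterLedger` so dropped and retained row
counts always reconcile with the input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import (
    FALLBACK_FLOORS,
    DEFAULT_FALLBACK_FLOOR,
    FALLBACK_OFFSET_DAYS,
)

logger = logging.getLogger(__name__)

# A "cell" is one species x subsite x year within a phenophase: the unit the
# missingness, min-observation and outlier rules act on.
CELL_KEY = ["phenophase", "species", "site", "subsite", "year"]


@dataclass
class FilterLedger:
    """Row bookkeeping for one filtering step (or a whole prep run)."""

    input_rows: int = 0
    retained_rows: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def record(self, rule: str, n: int) -> None:
        self.dropped[rule] = self.dropped.get(rule, 0) + int(n)

    @property
    def dropped_rows(self) -> int:
        return sum(self.dropped.values())

    def check(self) -> None:
        if self.input_rows != self.retained_rows + self.dropped_rows:
            raise AssertionError(
                f"ledger does not reconcile: {self.input_rows} != "
                f"{self.retained_rows} + {self.dropped_rows}"
            )

    def merged_with(self, other: "FilterLedger") -> "FilterLedger":
        out = FilterLedger(
            input_rows=self.input_rows, retained_rows=other.retained_rows
        )
        out.dropped = dict(self.dropped)
        for k, v in other.dropped.items():
            out.dropped[k] = out.dropped.get(k, 0) + v
        return out

    def to_dict(self) -> dict:
        return {
            "input_rows": self.input_rows,
            "retained_rows": self.retained_rows,
            "dropped": dict(self.dropped),
        }


@dataclass(frozen=True)
class ScalingRecord:
    """Affine map applied to one phenophase: x_std = (x - mean) / sd."""

    mean: float
    sd: float

    def to_days(self, standardized: float | np.ndarray) -> float | np.ndarray:
        """Back-transform an *effect* (difference) to days."""
        return standardized * self.sd

    def to_doy(self, standardized: float | np.ndarray) -> float | np.ndarray:
        """Back-transform a *location* to DOY."""
        return standardized * self.sd + self.mean


# ---------------------------------------------------------------------------
# prior-visit assignment
# ---------------------------------------------------------------------------


def assign_prior_visits(
    observations: pd.DataFrame,
    visit_history: pd.DataFrame,
    fallback_offset: int = FALLBACK_OFFSET_DAYS,
    floors: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Complete the lower censoring bound for every recorded observation.

    The prior visit is the most recent visit in the same plot and year that
    strictly precedes the recorded DOY.  When none exists (the event had
    already occurred by the first visit), the bound falls back to the
    species' minimum prior-visit DOY across all years minus ``fallback_offset``
    days, floored at DOY 100 for green up and 120 for flowering / end of
    flowering (phenophases with no stated floor use 100, with a warning).

    ``visit_history`` is long format: columns plot, year, visit_doy.
    """
    floors = dict(FALLBACK_FLOORS if floors is None else floors)
    obs = observations.copy()
    visits = visit_history.sort_values("visit_doy")
    by_plot_year = {
        k: g["visit_doy"].to_numpy() for k, g in visits.groupby(["plot", "year"])
    }

    doy = obs["doy"].to_numpy(dtype="float64", na_value=np.nan)
    prior = np.full(len(obs), np.nan)
    for i, (plot, year, d) in enumerate(zip(obs["plot"], obs["year"], doy)):
        if np.isnan(d):
            continue
        v = by_plot_year.get((plot, year))
        if v is None:
            continue
        idx = int(np.searchsorted(v, d, side="left"))
        if idx > 0:
            prior[i] = v[idx - 1]

    # species-level minimum prior visit (per phenophase) for the fallback
    obs["_prior_tmp"] = prior
    sp_min = obs.groupby(["phenophase", "species"])["_prior_tmp"].min()

    need = np.isnan(prior) & ~np.isnan(doy)
    warned: set[str] = set()
    for i in np.flatnonzero(need):
        ph = obs["phenophase"].iat[i]
        sp = obs["species"].iat[i]
        floor = floors.get(ph)
        if floor is None:
            floor = DEFAULT_FALLBACK_FLOOR
            if ph not in warned:
                logger.warning(
                    "no fallback floor stated for phenophase %r; using DOY %d",
                    ph,
                    floor,
                )
                warned.add(ph)
        base = sp_min.get((ph, sp), np.nan)
        if np.isnan(base):
            bound = float(floor)
        else:
            bound = max(base - fallback_offset, float(floor))
        # fallback bound must stay below the recorded DOY
        prior[i] = min(bound, doy[i] - 1.0)

    obs = obs.drop(columns="_prior_tmp")
    obs["prior_visit"] = pd.array(prior, dtype="Float64")
    return obs


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def apply_missingness_filter(
    observations: pd.DataFrame,
    threshold: float = 0.20,
    applies_to: tuple[str, ...] = ("green_up", "leaf_senescence"),
) -> tuple[pd.DataFrame, FilterLedger]:
    """Drop cells whose fraction of missing recorded events exceeds ``threshold``.

    Applies only to the season-bounding phenophases (green up and leaf
    senescence), where missingness is informative of truncation bias; all
    other phenophases pass through untouched.
    """
    ledger = FilterLedger(input_rows=len(observations))
    if len(observations) == 0:
        ledger.retained_rows = 0
        return observations.copy(), ledger
    miss = observations["doy"].isna()
    frac = miss.groupby([observations[k] for k in CELL_KEY]).transform("mean")
    drop = frac.gt(threshold) & observations["phenophase"].isin(applies_to)
    out = observations.loc[~drop].copy()
    ledger.record("missingness_gt_threshold", int(drop.sum()))
    ledger.retained_rows = len(out)
    ledger.check()
    return out, ledger


def drop_missing_rows(observations: pd.DataFrame) -> tuple[pd.DataFrame, FilterLedger]:
    """Remove rows with no recorded event (they carry no interval)."""
    ledger = FilterLedger(input_rows=len(observations))
    keep = observations["doy"].notna()
    out = observations.loc[keep].copy()
    ledger.record("missing_event", int((~keep).sum()))
    ledger.retained_rows = len(out)
    ledger.check()
    return out, ledger


def filter_min_observations(
    observations: pd.DataFrame, min_per_treatment: int = 2
) -> tuple[pd.DataFrame, FilterLedger]:
    """Drop cells lacking ``min_per_treatment`` observations in either arm."""
    ledger = FilterLedger(input_rows=len(observations))
    if len(observations) == 0:
        ledger.retained_rows = 0
        return observations.copy(), ledger
    counts = (
        observations.groupby(CELL_KEY + ["treatment"], observed=True)
        .size()
        .unstack("treatment", fill_value=0)
    )
    for trt in ("control", "otc"):
        if trt not in counts.columns:
            counts[trt] = 0
    ok = (counts["control"] >= min_per_treatment) & (counts["otc"] >= min_per_treatment)
    ok_cells = set(ok[ok].index)
    key = pd.MultiIndex.from_frame(observations[CELL_KEY])
    keep = key.isin(ok_cells)
    out = observations.loc[keep].copy()
    ledger.record("min_observations", int((~keep).sum()))
    ledger.retained_rows = len(out)
    ledger.check()
    return out, ledger


def midpoints(observations: pd.DataFrame) -> pd.Series:
    lo = observations["prior_visit"].to_numpy(dtype="float64", na_value=np.nan)
    hi = observations["doy"].to_numpy(dtype="float64", na_value=np.nan)
    return pd.Series((lo + hi) / 2.0, index=observations.index, name="midpoint")


def remove_outliers(
    observations: pd.DataFrame, n_sd: float = 4.0, min_cells: int = 3
) -> tuple[pd.DataFrame, FilterLedger]:
    """Drop cells whose warmed-minus-control midpoint-mean difference is an
    outlier (> ``n_sd`` SDs from the phenophase mean of cell differences).

    The difference is computed per cell (species x subsite x year) on the raw
    DOY scale, before standardization.  Phenophases with fewer than
    ``min_cells`` paired cells are left untouched (SD unstable), as are
    phenophases whose cell differences have zero SD.
    """
    ledger = FilterLedger(input_rows=len(observations))
    if len(observations) == 0:
        ledger.retained_rows = 0
        return observations.copy(), ledger
    df = observations.copy()
    df["_mid"] = midpoints(df)
    cell_trt = df.groupby(CELL_KEY + ["treatment"], observed=True)["_mid"].mean()
    wide = cell_trt.unstack("treatment")
    if "otc" not in wide.columns or "control" not in wide.columns:
        out = observations.copy()
        ledger.retained_rows = len(out)
        ledger.check()
        return out, ledger
    diff = (wide["otc"] - wide["control"]).dropna()

    drop_cells: set = set()
    for ph, d in diff.groupby(level="phenophase"):
        if len(d) < min_cells:
            logger.info("outlier rule skipped for %s: only %d cells", ph, len(d))
            continue
        sd = d.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        bad = d[np.abs(d - d.mean()) > n_sd * sd]
        drop_cells.update(bad.index)

    key = pd.MultiIndex.from_frame(observations[CELL_KEY])
    keep = ~key.isin(drop_cells)
    out = observations.loc[keep].copy()
    ledger.record("outlier_4sd", int((~keep).sum()))
    ledger.retained_rows = len(out)
    ledger.check()
    return out, ledger


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------


def standardize(
    observations: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, ScalingRecord]]:
    """Standardize interval bounds per phenophase by the midpoint mean/SD.

    Both bounds get the same affine map, so the interval structure (and any
    fitted location/scale) back-transforms exactly.  Returns the table with
    ``lower_std``/``upper_std``/``midpoint`` columns plus the per-phenophase
    scaling records needed to express effects in days again.
    """
    if observations["prior_visit"].isna().any() or observations["doy"].isna().any():
        raise ValueError("bounds must be complete before standardization")
    df = observations.copy()
    df["midpoint"] = midpoints(df)
    scalings: dict[str, ScalingRecord] = {}
    lower = np.empty(len(df))
    upper = np.empty(len(df))
    for ph, g in df.groupby("phenophase", observed=True):
        m = float(g["midpoint"].mean())
        s = float(g["midpoint"].std(ddof=1))
        if not np.isfinite(s) or s == 0.0:
            raise ValueError(
                f"midpoint SD is zero/undefined for phenophase {ph!r}; "
                "cannot standardize"
            )
        scalings[ph] = ScalingRecord(mean=m, sd=s)
        idx = df.index.get_indexer(g.index)
        lower[idx] = (g["prior_visit"].to_numpy(float) - m) / s
        upper[idx] = (g["doy"].to_numpy(float) - m) / s
    df["lower_std"] = lower
    df["upper_std"] = upper
    return df, scalings


# ---------------------------------------------------------------------------
# full prep
# ---------------------------------------------------------------------------


def prepare(
    observations: pd.DataFrame,
    visit_history: pd.DataFrame,
    missingness_threshold: float = 0.20,
    min_per_treatment: int = 2,
    outlier_sd: float = 4.0,
) -> tuple[pd.DataFrame, dict[str, ScalingRecord], FilterLedger]:
    """Run the full preparation chain in the stated order.

    missingness filter -> drop unrecorded rows -> prior-visit assignment ->
    min-observations -> outliers -> standardization.
    """
    obs, ledger = apply_missingness_filter(observations, missingness_threshold)
    obs, led2 = drop_missing_rows(obs)
    ledger = ledger.merged_with(led2)
    obs = assign_prior_visits(obs, visit_history)
    obs, led3 = filter_min_observations(obs, min_per_treatment)
    ledger = ledger.merged_with(led3)
    obs, led4 = remove_outliers(obs, outlier_sd)
    ledger = ledger.merged_with(led4)
    std, scalings = standardize(obs)
    ledger.check()
    return std, scalings, ledger
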