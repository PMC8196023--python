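"""Posterior contrasts of paired phenophases: phenoperiod-duration changes.

A phenoperiod spans a starting and an ending phenophase (growth: green up ->
leaf senescence; flowering: start -> end of flowering; fruiting: fruiting ->
seed dispersal).  The warming-induced change in its duration is the
difference of the two phenophases' treatment-effect posteriors (end minus
start, in days).  The per-phenophase fits are independent, so draws are
paired by index after a fixed-seed random permutation, which makes the ETI
of the difference reproducible without asserting any joint structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import PHENOPERIODS
from .hierarchical import PosteriorFit, compute_eti
from .prep import ScalingRecord


@dataclass
class DurationContrast:
    period: str
    start_phase: str
    end_phase: str
    draws: np.ndarray  # days; end minus start
    eti90: tuple[float, float]
    eti95: tuple[float, float]

    @property
    def mean(self) -> float:
        return float(np.mean(self.draws))

    @property
    def sd(self) -> float:
        return float(np.std(self.draws, ddof=1))

    @property
    def effect_90(self) -> bool:
        lo, hi = self.eti90
        return lo > 0 or hi < 0

    @property
    def effect_95(self) -> bool:
        lo, hi = self.eti95
        return lo > 0 or hi < 0

    def to_row(self) -> dict:
        return {
            "period": self.period,
            "start_phase": self.start_phase,
            "end_phase": self.end_phase,
            "contrast_days": self.mean,
            "sd_days": self.sd,
            "eti90_low": self.eti90[0],
            "eti90_high": self.eti90[1],
            "eti95_low": self.eti95[0],
            "eti95_high": self.eti95[1],
            "effect_90": self.effect_90,
            "effect_95": self.effect_95,
        }


def _paired_day_draws(
    fit_start: PosteriorFit,
    fit_end: PosteriorFit,
    scaling_start: ScalingRecord,
    scaling_end: ScalingRecord,
    param: str,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    d_start = scaling_start.to_days(fit_start.draws(param))
    d_end = scaling_end.to_days(fit_end.draws(param))
    n = min(d_start.size, d_end.size)
    rng = np.random.default_rng(seed)
    d_start = rng.permutation(d_start)[:n]
    d_end = rng.permutation(d_end)[:n]
    return d_start, d_end


def duration_contrast(
    fit_start: PosteriorFit,
    fit_end: PosteriorFit,
    scaling_start: ScalingRecord | None = None,
    scaling_end: ScalingRecord | None = None,
    period: str = "",
    seed: int = 0,
) -> DurationContrast:
    """Change in phenoperiod duration: end-phase minus start-phase effect.

    A positive contrast lengthens the period (e.g. green up advancing while
    senescence is delayed lengthens the growing season).
    """
    scaling_start = scaling_start or fit_start.scaling
    scaling_end = scaling_end or fit_end.scaling
    if scaling_start is None or scaling_end is None:
        raise ValueError("scaling records required for day-unit contrasts")
    d_start, d_end = _paired_day_draws(
        fit_start, fit_end, scaling_start, scaling_end, "beta_trt", seed
    )
    diff = d_end - d_start
    return DurationContrast(
        period=period,
        start_phase=fit_start.phenophase or "start",
        end_phase=fit_end.phenophase or "end",
        draws=diff,
        eti90=compute_eti(diff, 0.90),
        eti95=compute_eti(diff, 0.95),
    )


def all_duration_contrasts(
    fits: dict[str, PosteriorFit],
    scalings: dict[str, ScalingRecord],
    seed: int = 0,
) -> pd.DataFrame:
    """Contrast every phenoperiod whose two phenophase fits are available;
    missing fits are skipped (reported in the 'skipped' attr)."""
    rows = []
    skipped = []
    for period, (start, end) in PHENOPERIODS.items():
        if start not in fits or end not in fits:
            skipped.append(period)
            continue
        c = duration_contrast(
            fits[start], fits[end], scalings[start], scalings[end],
            period=period, seed=seed,
        )
        rows.append(c.to_row())
    out = pd.DataFrame(rows)
    out.attrs["skipped"] = skipped
    return out


def baseline_intercepts(
    fits: dict[str, PosteriorFit],
    scalings: dict[str, ScalingRecord],
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Average event DOY per phenophase and mean phenoperiod lengths.

    Intercept draws from the treatment-only fits are un-standardized to the
    DOY scale; period lengths are differences of paired baseline draws.
    Returns (baseline table, period table).
    """
    base_rows = []
    doy_draws: dict[str, np.ndarray] = {}
    for ph, fit in fits.items():
        sc = scalings[ph]
        d = sc.to_doy(fit.draws("alpha"))
        doy_draws[ph] = d
        base_rows.append(
            {
                "phenophase": ph,
                "mean_doy": float(np.mean(d)),
                "sd_doy": float(np.std(d, ddof=1)),
            }
        )
    period_rows = []
    rng = np.random.default_rng(seed)
    for period, (start, end) in PHENOPERIODS.items():
        if start not in doy_draws or end not in doy_draws:
            continue
        n = min(doy_draws[start].size, doy_draws[end].size)
        ds = rng.permutation(doy_draws[start])[:n]
        de = rng.permutation(doy_draws[end])[:n]
        diff = de - ds
        period_rows.append(
            {
                "period": period,
                "length_days": float(np.mean(diff)),
                "sd_days": float(np.std(diff, ddof=1)),
            }
        )
    return pd.DataFrame(base_rows), pd.DataFrame(period_rows)
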