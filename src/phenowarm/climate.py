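"""Phenophase-specific climate windows, site means, anomalies and infilling.

The window for a species x site x phenophase is the 30 days up to the mean
event DOY (pooled over treatments and years).  Ambient temperature averaged
over that window per year gives yearly window means; their across-year mean
is the site mean temperature (the spatial predictor) and each year's
deviation from it is the site-year anomaly (the temporal predictor,
warm-year-positive).  Years with more than five infilled window days are
excluded, which is why climate interaction models carry slightly fewer
replicates than the treatment-only models.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WINDOW_DAYS = 30
MAX_INFILLED_WINDOW_DAYS = 5

# metadata carried on every ClimateWindowStats table
ANOMALY_SIGN_CONVENTION = "warm_year_positive (yearly mean minus site mean)"


# ---------------------------------------------------------------------------
# infilling
# ---------------------------------------------------------------------------


def infill_missing(
    series: pd.DataFrame, donor_series: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Fill missing daily temperatures for one site.

    Primary method: linear regression of the target on a donor site over the
    days both have data (pooled over years).  When no donor is given, the
    regression is degenerate, or some days remain unfilled, the long-term
    day-of-year mean across the target's own years is used.  Days that could
    not be filled by either route stay missing.

    Input/output frames have columns site, year, doy, tmean, is_missing; the
    output adds a boolean ``infilled`` column.
    """
    out = series.copy()
    out["infilled"] = False
    miss = out["tmean"].isna()
    if not miss.any():
        return out

    if donor_series is not None:
        donor = donor_series.set_index(["year", "doy"])["tmean"]
        tgt = out.set_index(["year", "doy"])
        shared = tgt["tmean"].notna() & tgt.index.isin(donor.index)
        d_shared = donor.reindex(tgt.index[shared])
        ok = d_shared.notna().to_numpy()
        x = d_shared.to_numpy()[ok]
        y = tgt.loc[shared, "tmean"].to_numpy()[ok]
        if len(x) >= 10 and np.std(x) > 0:
            slope, intercept = np.polyfit(x, y, 1)
            pred = donor.reindex(tgt.index) * slope + intercept
            fill = miss.to_numpy() & pred.notna().to_numpy()
            out.loc[fill, "tmean"] = pred.to_numpy()[fill]
            out.loc[fill, "infilled"] = True
            miss = out["tmean"].isna()
        else:
            logger.info("donor regression failed for site %s", out["site"].iat[0])

    if miss.any():
        # long-term (multi-year) day-of-year mean
        doy_mean = out.groupby("doy")["tmean"].transform("mean")
        fill = miss & doy_mean.notna()
        out.loc[fill, "tmean"] = doy_mean[fill]
        out.loc[fill, "infilled"] = True
        left = int(out["tmean"].isna().sum())
        if left:
            logger.info(
                "%d days at site %s could not be infilled", left, out["site"].iat[0]
            )
    return out


def infill_all_sites(daily: pd.DataFrame) -> pd.DataFrame:
    """Infill every site, using the most-correlated other site as donor."""
    sites = sorted(daily["site"].unique())
    wide = daily.pivot_table(
        index=["year", "doy"], columns="site", values="tmean", observed=True
    )
    corr = wide.corr()
    parts = []
    for site in sites:
        series = daily[daily["site"] == site]
        donor = None
        if len(sites) > 1:
            others = corr[site].drop(index=site).dropna()
            if len(others):
                best = others.idxmax()
                donor = daily[daily["site"] == best]
        parts.append(infill_missing(series, donor))
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------


def compute_climate_window(mean_event_doy: float) -> tuple[int, int]:
    """[mean - 30, mean] in integer DOY, clipped at DOY 1."""
    end = int(round(mean_event_doy))
    start = end - WINDOW_DAYS
    if start < 1:
        logger.info("climate window clipped at DOY 1 (mean DOY %.1f)", mean_event_doy)
        start = 1
    return start, end


def window_table(observations: pd.DataFrame) -> pd.DataFrame:
    """Mean event DOY (interval midpoints, both treatments pooled, all years)
    per species x site x phenophase, with the derived climate window."""
    df = observations.copy()
    mid = (
        df["prior_visit"].astype(float) + df["doy"].astype(float)
    ) / 2.0
    df["_mid"] = mid
    tab = (
        df.groupby(["species", "site", "phenophase"], observed=True)["_mid"]
        .mean()
        .rename("mean_event_doy")
        .reset_index()
    )
    bounds = tab["mean_event_doy"].map(compute_climate_window)
    tab["window_start"] = [b[0] for b in bounds]
    tab["window_end"] = [b[1] for b in bounds]
    return tab


# ---------------------------------------------------------------------------
# site means and anomalies
# ---------------------------------------------------------------------------


def site_and_anomaly_means(
    filled_daily: pd.DataFrame, windows: pd.DataFrame
) -> pd.DataFrame:
    """Per species x site x phenophase x year window means and anomalies.

    Years with more than ``MAX_INFILLED_WINDOW_DAYS`` infilled days inside
    the window, or with any remaining missing window day, are excluded; the
    site mean is the mean of retained yearly window means and the anomaly is
    yearly mean minus site mean (warm year positive).
    """
    daily = filled_daily.set_index(["site", "year"]).sort_index()
    rows = []
    for r in windows.itertuples(index=False):
        try:
            site_days = daily.loc[r.site]
        except KeyError:
            continue
        for year in site_days.index.unique():
            d = site_days.loc[[year]]
            w = d[(d["doy"] >= r.window_start) & (d["doy"] <= r.window_end)]
            n_inf = int(w["infilled"].sum())
            if len(w) == 0 or w["tmean"].isna().any():
                continue
            if n_inf > MAX_INFILLED_WINDOW_DAYS:
                continue
            rows.append(
                {
                    "species": r.species,
                    "site": r.site,
                    "phenophase": r.phenophase,
                    "year": int(year),
                    "window_start": r.window_start,
                    "window_end": r.window_end,
                    "year_window_mean": float(w["tmean"].mean()),
                    "n_infilled": n_inf,
                }
            )
    stats = pd.DataFrame(rows)
    if stats.empty:
        return stats
    grp = stats.groupby(["species", "site", "phenophase"], observed=True)
    stats["site_temp"] = grp["year_window_mean"].transform("mean")
    stats["anomaly"] = stats["year_window_mean"] - stats["site_temp"]
    stats.attrs["anomaly_sign"] = ANOMALY_SIGN_CONVENTION
    return stats


def group_means_center(
    stats: pd.DataFrame, replicates: pd.DataFrame
) -> pd.DataFrame:
    """Attach the two decomposed climate predictors to replicate estimates.

    ``site_temp`` (between-site, grand-mean centered) and ``delta_t`` (the
    within-site yearly anomaly, zero-mean within each site stratum by
    construction).  Replicates with no matching climate stratum are dropped
    from the climate model only (returned table is the climate-model subset).
    """
    if stats.empty:
        logger.warning("no climate stats; climate model would be empty")
        return replicates.iloc[0:0].copy()
    key = ["species", "site", "phenophase", "year"]
    merged = replicates.merge(
        stats[key + ["site_temp", "anomaly"]].drop_duplicates(key),
        on=key,
        how="left",
    )
    unmatched = merged["site_temp"].isna()
    if unmatched.any():
        logger.info(
            "%d replicates excluded from climate models (no retained window year)",
            int(unmatched.sum()),
        )
    out = merged.loc[~unmatched].copy()
    out["site_temp_centered"] = out["site_temp"] - out["site_temp"].mean()
    out["delta_t"] = out["anomaly"]
    out.attrs["anomaly_sign"] = ANOMALY_SIGN_CONVENTION
    return out
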