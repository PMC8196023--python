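import numpy as np
import pandas as pd
import pytest

from phenowarm import synthetic_data as synth
from phenowarm.constants import PHENOPHASES


def zero_variance_truth(intercept=180.0, effect=-2.4):
    zero = synth.GroupEffectTruth(0.0, 0.0)
    return synth.TruthParameters(
        intercepts={ph: intercept for ph in PHENOPHASES},
        treatment_effects={ph: effect for ph in PHENOPHASES},
        groups={f: zero for f in synth.GROUP_FACTORS},
        residual_sd=0.0,
    )


class TestGenerateDesign:
    def test_counts(self):
        d = synth.generate_design(2, 2, 3, 2, 5, seed=1)
        assert d["subsite"].nunique() == 4
        assert d["plot"].nunique() == 40  # 4 subsites x 2 treatments x 5 plots

    def test_minimal_design(self):
        d = synth.generate_design(1, 1, 1, 1, 1, seed=0)
        assert set(d["treatment"]) == {"otc", "control"}
        assert d["plot"].nunique() == 2

    def test_deterministic(self):
        a = synth.generate_design(3, 2, 5, 2, 2, seed=42)
        b = synth.generate_design(3, 2, 5, 2, 2, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_nesting_invariants(self):
        d = synth.generate_design(3, 2, 5, 2, 2, seed=7)
        # each subsite belongs to exactly one site, each plot to one treatment
        assert (d.groupby("subsite")["site"].nunique() == 1).all()
        assert (d.groupby("plot")["treatment"].nunique() == 1).all()
        assert set(d["phenophase"]) <= set(PHENOPHASES)

    @pytest.mark.parametrize("bad", [0, -1])
    def test_rejects_nonpositive_counts(self, bad):
        with pytest.raises(ValueError):
            synth.generate_design(bad, 1, 1, 1, 1, seed=0)


class TestSimulateEvents:
    def test_noise_free_limit(self):
        d = synth.generate_design(2, 1, 2, 1, 2, seed=0)
        ev = synth.simulate_events(d, zero_variance_truth(180.0, -2.4), seed=1)
        ctl = ev.loc[ev["treatment"] == "control", "true_doy"]
        otc = ev.loc[ev["treatment"] == "otc", "true_doy"]
        assert np.allclose(ctl, 180.0)
        assert np.allclose(otc, 177.6)

    def test_zero_effect_identical_in_law(self):
        truth = zero_variance_truth(effect=0.0)
        truth = synth.TruthParameters(
            intercepts=truth.intercepts,
            treatment_effects=truth.treatment_effects,
            groups=truth.groups,
            residual_sd=2.0,
        )
        d = synth.generate_design(2, 2, 3, 2, 10, seed=0)
        ev = synth.simulate_events(d, truth, seed=1)
        ctl = ev.loc[ev["treatment"] == "control", "true_doy"]
        otc = ev.loc[ev["treatment"] == "otc", "true_doy"]
        # same mean and spread within Monte Carlo error
        assert abs(ctl.mean() - otc.mean()) < 0.2
        assert abs(ctl.std() - otc.std()) < 0.2

    def test_species_sd_recovered_monte_carlo(self):
        zero = synth.GroupEffectTruth(0.0, 0.0)
        truth = synth.TruthParameters(
            intercepts={"flowering": 180.0},
            treatment_effects={"flowering": 0.0},
            groups={
                "species": synth.GroupEffectTruth(3.0, 0.0),
                "site": zero,
                "site_year": zero,
                "site_subsite": zero,
            },
            residual_sd=0.0,
        )
        d = synth.generate_design(
            1, 1, 500, 1, 1, seed=0, phenophases=("flowering",),
            species_site_prob=1.0,
        )
        ev = synth.simulate_events(d, truth, seed=1)
        sp_means = ev.groupby("species")["true_doy"].mean()
        assert sp_means.std(ddof=1) == pytest.approx(3.0, rel=0.15)

    def test_deterministic(self):
        d = synth.generate_design(2, 2, 3, 2, 2, seed=3)
        t = synth.TruthParameters.default()
        a = synth.simulate_events(d, t, seed=9)
        b = synth.simulate_events(d, t, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestCensorByCensus:
    def _events(self, doys):
        return pd.DataFrame(
            {
                "site": "s1",
                "subsite": "s1_sub1",
                "plot": "p1",
                "year": 2001,
                "treatment": "control",
                "species": "sp01",
                "phenophase": "flowering",
                "true_doy": doys,
            }
        )

    def test_recorded_is_first_visit_at_or_after(self):
        # deterministic schedule: daily cadence makes visits predictable
        ev = self._events([163.0])
        cfg = synth.CensusConfig(
            season_start=150, season_end=170, interval_min=7, interval_max=7,
            p_late_start=0.0, p_random_missing=0.0,
        )
        obs, visits = synth.censor_by_census(ev, cfg, seed=0)
        v = visits["visit_doy"].tolist()
        assert v == [150, 157, 164]
        assert obs["doy"].iat[0] == 164
        assert obs["prior_visit"].iat[0] == 157

    def test_event_before_first_visit_has_no_prior(self):
        ev = self._events([149.0])
        cfg = synth.CensusConfig(
            season_start=150, season_end=160, interval_min=7, interval_max=7,
            p_late_start=0.0, p_random_missing=0.0,
        )
        obs, _ = synth.censor_by_census(ev, cfg, seed=0)
        assert obs["doy"].iat[0] == 150
        assert pd.isna(obs["prior_visit"].iat[0])

    def test_event_after_last_visit_is_missing(self):
        ev = self._events([260.0])
        cfg = synth.CensusConfig(
            season_start=150, season_end=158, interval_min=7, interval_max=7,
            p_late_start=0.0, p_random_missing=0.0,
        )
        obs, _ = synth.censor_by_census(ev, cfg, seed=0)
        assert pd.isna(obs["doy"].iat[0])

    def test_daily_visits_give_unit_intervals(self):
        ev = self._events([163.4, 171.9])
        cfg = synth.CensusConfig(
            season_start=150, season_end=200, interval_min=1, interval_max=1,
            p_late_start=0.0, p_random_missing=0.0,
        )
        obs, _ = synth.censor_by_census(ev, cfg, seed=0)
        assert obs["doy"].tolist() == [164, 172]  # ceil of the true event
        assert (obs["doy"] - obs["prior_visit"]).tolist() == [1, 1]


class TestSimulateClimate:
    def test_no_missingness_when_disabled(self):
        d = synth.generate_design(2, 1, 1, 2, 1, seed=0)
        cfg = synth.ClimateConfig(p_missing=0.0)
        daily, _ = synth.simulate_climate(d, cfg, seed=0)
        assert daily["tmean"].notna().all()
        assert len(daily) == 2 * 2 * 366

    def test_zero_anomaly_and_noise_gives_identical_years(self):
        d = synth.generate_design(1, 1, 1, 3, 1, seed=0)
        cfg = synth.ClimateConfig(anomaly_sd=0.0, daily_noise_sd=0.0, p_missing=0.0)
        daily, _ = synth.simulate_climate(d, cfg, seed=0)
        wide = daily.pivot(index="doy", columns="year", values="tmean")
        assert np.allclose(wide.var(axis=1), 0.0)

    def test_injected_anomaly_shifts_window_mean(self):
        d = synth.generate_design(1, 1, 1, 4, 1, seed=0)
        site = d["site"].iat[0]
        cfg = synth.ClimateConfig(
            anomaly_sd=0.0, daily_noise_sd=0.0, p_missing=0.0,
            injected_anomalies={(site, 2003): 2.0},
        )
        daily, truth = synth.simulate_climate(d, cfg, seed=0)
        w = daily[(daily["doy"] >= 150) & (daily["doy"] <= 180)]
        means = w.groupby("year")["tmean"].mean()
        other = means.drop(index=2003).mean()
        assert means[2003] - other == pytest.approx(2.0, abs=1e-9)
        assert truth.loc[truth["year"] == 2003, "anomaly"].iat[0] == pytest.approx(2.0)


def test_truth_parameters_json_roundtrip(tmp_path):
    truth = synth.TruthParameters.default()
    p = tmp_path / "truth.json"
    truth.to_json(p)
    back = synth.TruthParameters.from_json(p)
    assert back == truth


def test_truth_parameters_validation():
    with pytest.raises(ValueError):
        synth.GroupEffectTruth(-1.0, 1.0)
    with pytest.raises(ValueError):
        synth.GroupEffectTruth(1.0, 1.0, rho=1.5)


class TestSnowmelt:
    def test_year_round_advance(self):
        d = synth.generate_design(4, 2, 1, 2, 3, seed=2)
        snow = synth.simulate_snowmelt(d, seed=0, plot_sd=0.0, otc_advance_days=1.0)
        yr = snow[snow["deployment"] == "year_round"]
        if len(yr):
            cell = yr.groupby(["subsite", "year", "treatment"])["snowmelt_doy"].mean()
            diff = cell.unstack("treatment")
            assert np.allclose(diff["otc"] - diff["control"], -1.0)
        so = snow[snow["deployment"] == "summer_only"]
        if len(so):
            cell = so.groupby(["subsite", "year", "treatment"])["snowmelt_doy"].mean()
            diff = cell.unstack("treatment")
            assert np.allclose(diff["otc"] - diff["control"], 0.0)
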