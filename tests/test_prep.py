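import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phenowarm import prep


def make_obs(rows):
    """rows: list of dicts with partial keys; defaults fill the rest."""
    base = dict(
        site="s1", subsite="s1_sub1", plot="p1", year=2001,
        treatment="control", species="sp01", phenophase="flowering",
        doy=np.nan, prior_visit=np.nan,
    )
    return pd.DataFrame([{**base, **r} for r in rows])


def visits_df(plot, year, doys):
    return pd.DataFrame({"plot": plot, "year": year, "visit_doy": doys})


class TestAssignPriorVisits:
    def test_most_recent_visit_before_recorded(self):
        obs = make_obs([{"doy": 164}])
        out = prep.assign_prior_visits(obs, visits_df("p1", 2001, [150, 157, 164]))
        assert out["prior_visit"].iat[0] == 157

    def test_green_up_fallback_above_floor(self):
        # species minimum prior visit 140 -> 140 - 21 = 119 >= floor 100
        obs = make_obs([
            {"phenophase": "green_up", "doy": 135},          # first-visit case
            {"phenophase": "green_up", "doy": 150, "plot": "p2"},
        ])
        vis = pd.concat([
            visits_df("p1", 2001, [135]),
            visits_df("p2", 2001, [140, 150]),
        ])
        out = prep.assign_prior_visits(obs, vis)
        assert out["prior_visit"].iat[0] == 119

    def test_flowering_fallback_floor_binds(self):
        # species minimum prior visit 130 -> max(109, 120) = 120
        obs = make_obs([
            {"doy": 125},
            {"doy": 140, "plot": "p2"},
        ])
        vis = pd.concat([
            visits_df("p1", 2001, [125]),
            visits_df("p2", 2001, [130, 140]),
        ])
        out = prep.assign_prior_visits(obs, vis)
        assert out["prior_visit"].iat[0] == 120

    def test_unfloored_phenophase_warns_and_uses_default(self, caplog):
        obs = make_obs([{"phenophase": "fruiting", "doy": 150}])
        with caplog.at_level("WARNING"):
            out = prep.assign_prior_visits(obs, visits_df("p1", 2001, [150]))
        assert "no fallback floor" in caplog.text
        assert out["prior_visit"].iat[0] == 100

    def test_bound_stays_below_recorded_doy(self):
        obs = make_obs([{"phenophase": "green_up", "doy": 101}])
        out = prep.assign_prior_visits(obs, visits_df("p1", 2001, [101]))
        assert out["prior_visit"].iat[0] < 101


class TestMissingnessFilter:
    def _cell(self, phenophase, n_missing, n_total, species="sp01"):
        rows = []
        for i in range(n_total):
            rows.append({
                "phenophase": phenophase, "species": species,
                "doy": np.nan if i < n_missing else 150 + i,
                "prior_visit": np.nan if i < n_missing else 145 + i,
                "plot": f"p{i}",
            })
        return make_obs(rows)

    def test_over_threshold_dropped(self):
        obs = self._cell("green_up", 5, 20)  # 25% > 20%
        out, ledger = prep.apply_missingness_filter(obs)
        assert len(out) == 0
        assert ledger.dropped["missingness_gt_threshold"] == 20

    def test_under_threshold_kept(self):
        obs = self._cell("green_up", 3, 20)  # 15%
        out, _ = prep.apply_missingness_filter(obs)
        assert len(out) == 20

    def test_rule_only_for_season_bounding_phases(self):
        obs = self._cell("flowering", 10, 20)  # 50% but flowering passes through
        out, _ = prep.apply_missingness_filter(obs)
        assert len(out) == 20

    def test_idempotent(self):
        obs = pd.concat(
            [self._cell("green_up", 5, 20, "sp01"),
             self._cell("green_up", 1, 20, "sp02")],
            ignore_index=True,
        )
        once, _ = prep.apply_missingness_filter(obs)
        twice, _ = prep.apply_missingness_filter(once)
        pd.testing.assert_frame_equal(once, twice)


class TestMinObservations:
    def _cell(self, n_otc, n_ctl):
        rows = []
        for i in range(n_otc):
            rows.append({"treatment": "otc", "plot": f"w{i}", "doy": 160 + i,
                         "prior_visit": 155 + i})
        for i in range(n_ctl):
            rows.append({"treatment": "control", "plot": f"c{i}", "doy": 162 + i,
                         "prior_visit": 157 + i})
        return make_obs(rows)

    def test_one_warmed_dropped(self):
        out, ledger = prep.filter_min_observations(self._cell(1, 3))
        assert len(out) == 0
        assert ledger.dropped["min_observations"] == 4

    def test_two_by_two_boundary_kept(self):
        out, _ = prep.filter_min_observations(self._cell(2, 2))
        assert len(out) == 4

    def test_empty_input(self):
        out, ledger = prep.filter_min_observations(self._cell(0, 0))
        assert len(out) == 0
        assert ledger.input_rows == 0 and ledger.dropped_rows == 0

    def test_idempotent(self):
        obs = self._cell(2, 3)
        once, _ = prep.filter_min_observations(obs)
        twice, _ = prep.filter_min_observations(once)
        pd.testing.assert_frame_equal(once, twice)


class TestRemoveOutliers:
    def _cells(self, diffs):
        """One cell per diff: control midpoint 160, otc midpoint 160+diff."""
        rows = []
        for i, d in enumerate(diffs):
            for t, mid in (("control", 160.0), ("otc", 160.0 + d)):
                for j in range(2):
                    rows.append({
                        "species": f"sp{i:02d}", "treatment": t,
                        "plot": f"{t}{i}_{j}",
                        "doy": mid + 2, "prior_visit": mid - 2,
                    })
        return make_obs(rows)

    @staticmethod
    def _diffs_with_exact_moments(extreme, n=40, mean=0.0, sd=2.0, seed=0):
        """n cell differences whose overall mean/SD are exactly (mean, sd),
        with one cell placed at ``extreme``."""
        rng = np.random.default_rng(seed)
        rest = rng.standard_normal(n - 1)
        target_sum = n * mean - extreme
        target_ss = (n - 1) * sd**2 + n * mean**2 - extreme**2  # sum of squares
        m = target_sum / (n - 1)
        dev = rest - rest.mean()
        dev *= np.sqrt((target_ss - (n - 1) * m**2) / np.sum(dev**2))
        return list(dev + m) + [extreme]

    def test_beyond_four_sd_removed(self):
        diffs = self._diffs_with_exact_moments(9.0)
        assert np.mean(diffs) == pytest.approx(0.0, abs=1e-9)
        assert np.std(diffs, ddof=1) == pytest.approx(2.0, abs=1e-9)
        obs = self._cells(diffs)
        extreme_sp = f"sp{len(diffs) - 1:02d}"
        out, ledger = prep.remove_outliers(obs)
        assert extreme_sp not in set(out["species"])  # |9| > 4 * 2
        assert ledger.dropped["outlier_4sd"] == 4

    def test_within_four_sd_kept(self):
        diffs = self._diffs_with_exact_moments(7.9)
        obs = self._cells(diffs)
        out, ledger = prep.remove_outliers(obs)
        assert len(out) == len(obs)  # |7.9| <= 4 * 2

    def test_degenerate_equal_diffs_removes_nothing(self):
        obs = self._cells([1.0, 1.0, 1.0, 1.0])
        out, _ = prep.remove_outliers(obs)
        assert len(out) == len(obs)

    def test_too_few_cells_skipped(self):
        obs = self._cells([0.0, 50.0])
        out, _ = prep.remove_outliers(obs)
        assert len(out) == len(obs)


class TestStandardize:
    def _obs(self, mids, phenophase="flowering"):
        return make_obs([
            {"doy": m + 3, "prior_visit": m - 3, "plot": f"p{i}",
             "phenophase": phenophase}
            for i, m in enumerate(mids)
        ])

    def test_unit_scaling_example(self):
        out, sc = prep.standardize(self._obs([150, 160, 170]))
        assert sc["flowering"].mean == 160
        assert sc["flowering"].sd == 10
        mids = (out["lower_std"] + out["upper_std"]) / 2
        assert np.allclose(sorted(mids), [-1, 0, 1])

    def test_affine_invariance(self):
        a, _ = prep.standardize(self._obs([150, 160, 170]))
        b, _ = prep.standardize(self._obs([155, 165, 175]))
        assert np.allclose(a["lower_std"], b["lower_std"])
        assert np.allclose(a["upper_std"], b["upper_std"])

    def test_back_transform_effect(self):
        _, sc = prep.standardize(self._obs([150, 160, 170]))
        assert sc["flowering"].to_days(0.24) == pytest.approx(2.4)

    def test_zero_sd_aborts(self):
        with pytest.raises(ValueError, match="SD"):
            prep.standardize(self._obs([160, 160, 160]))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        mids=st.lists(
            st.floats(min_value=100, max_value=300), min_size=3, max_size=12,
            unique=True,
        )
    )
    def test_strictly_monotone(self, mids):
        out, _ = prep.standardize(self._obs(mids))
        order_raw = np.argsort(out["doy"].to_numpy(float))
        order_std = np.argsort(out["upper_std"].to_numpy())
        assert (order_raw == order_std).all()


def test_full_prepare_ledger_reconciles():
    rows = []
    # two healthy cells, one under-observed cell, one missing-heavy cell
    for sp, trt_counts in (("sp01", (3, 3)), ("sp02", (2, 2)), ("sp03", (1, 3))):
        for trt, n in zip(("otc", "control"), trt_counts):
            for i in range(n):
                rows.append({
                    "species": sp, "treatment": trt, "plot": f"{sp}{trt}{i}",
                    "doy": 160 + i, "prior_visit": np.nan,
                })
    for i in range(4):
        rows.append({
            "species": "sp04", "phenophase": "green_up", "treatment": "otc",
            "plot": f"m{i}", "doy": np.nan if i < 2 else 150,
        })
    obs = make_obs(rows)
    vis = pd.DataFrame(
        {"plot": obs["plot"].unique(), "year": 2001, "visit_doy": 150}
    )
    vis = pd.concat([vis, vis.assign(visit_doy=165)], ignore_index=True)
    std, scalings, ledger = prep.prepare(obs, vis)
    ledger.check()
    assert ledger.input_rows == len(obs)
    assert ledger.retained_rows == len(std)
    assert set(std["species"]) == {"sp01", "sp02"}
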