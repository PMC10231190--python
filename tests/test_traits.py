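"""Survey fitting and trait-level statistics."""

import numpy as np
import pandas as pd
import pytest

import thermotrait as tt
from thermotrait import (ancova_season, c_availability_correlation, fit_survey,
                         multiple_regression, paired_season_test, regress_trait,
                         width_vs_amplitude)


class TestFitSurvey:
    def test_noise_free_survey_recovers_generators(self, small_survey):
        cfg, sites, params, table = small_survey
        indices = fit_survey(tt.curves_from_table(table))
        assert len(indices) == 18  # 6 sites x 3 processes
        indices = indices.assign(process=indices["process"].astype(str))
        merged = indices.merge(params, on=["site_id", "process"],
                               suffixes=("", "_true"))
        np.testing.assert_allclose(merged["t_min"], merged["t_min_true"],
                                   atol=1e-5)
        resp = indices[indices["process"] == "respiration"]
        assert resp["t_opt"].isna().all() and resp["t_max"].isna().all()
        growth = indices[indices["process"] != "respiration"]
        assert (growth["width"] > 0).all()
        ok = growth.dropna(subset=["t_opt"])
        assert ((ok["t_min"] < ok["t_opt"]) & (ok["t_opt"] < ok["t_max"])).all()

    def test_failed_fit_keeps_site_with_missing_entries(self, small_survey):
        cfg, sites, params, table = small_survey
        # sabotage one site's bacterial curve: decreasing rates -> slope <= 0
        bad = (table["site_id"] == "S001") & (table["process"] == "bacterial_growth")
        table = table.copy()
        table.loc[bad, "rate"] = np.linspace(5.0, 0.1, bad.sum())
        with pytest.warns(UserWarning, match="fit failed"):
            indices = fit_survey(tt.curves_from_table(table))
        row = indices[(indices["site_id"] == "S001")
                      & (indices["process"] == "bacterial_growth")]
        assert len(row) == 1 and row["t_min"].isna().all()
        others = indices[(indices["site_id"] == "S001")
                         & (indices["process"] != "bacterial_growth")]
        assert others["t_min"].notna().all()

    def test_empty_survey_error(self):
        with pytest.raises(ValueError, match="empty survey"):
            fit_survey([])


class TestRegressTrait:
    def test_exact_line(self):
        sites = pd.DataFrame({"site_id": [f"S{i}" for i in range(5)],
                              "mat": [0.0, 1, 2, 3, 4]})
        idx = pd.DataFrame({"site_id": sites["site_id"],
                            "process": "respiration",
                            "t_min": 2.0 * sites["mat"]})
        res = regress_trait(idx, sites, "t_min", "respiration")
        assert res.slope == pytest.approx(2.0)
        assert res.r_squared == pytest.approx(1.0)
        assert res.df2 == 3

    def test_f_equals_r2_ratio_times_df2(self, default_survey):
        cfg, sites, params, indices = default_survey
        for process in tt.PROCESSES:
            res = regress_trait(indices, sites, "t_min", process)
            implied = res.r_squared / (1 - res.r_squared) * res.df2
            assert res.f_stat == pytest.approx(implied, rel=1e-9)

    def test_df_bookkeeping_drops_with_missing_fits(self, default_survey):
        cfg, sites, params, indices = default_survey
        res_full = regress_trait(indices, sites, "t_min", "bacterial_growth")
        indices2 = indices.copy()
        one = (indices2["process"] == "bacterial_growth").idxmax()
        indices2.loc[one, "t_min"] = np.nan
        res_drop = regress_trait(indices2, sites, "t_min", "bacterial_growth")
        assert res_drop.df2 == res_full.df2 - 1

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(5)
        ps = []
        for _ in range(200):
            sites = pd.DataFrame({"site_id": range(30),
                                  "mat": rng.normal(size=30)})
            idx = pd.DataFrame({"site_id": sites["site_id"],
                                "process": "respiration",
                                "t_min": rng.normal(size=30)})
            ps.append(regress_trait(idx, sites, "t_min", "respiration").p_value)
        from scipy.stats import kstest
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_zero_variance_predictor_error(self):
        sites = pd.DataFrame({"site_id": range(5), "mat": [1.0] * 5})
        idx = pd.DataFrame({"site_id": sites["site_id"],
                            "process": "respiration",
                            "t_min": np.arange(5.0)})
        with pytest.raises(ValueError, match="zero variance"):
            regress_trait(idx, sites, "t_min", "respiration")


class TestAncova:
    @staticmethod
    def _trait_frame(rng, n=72, season_shift=0.0, sd=1.1):
        mat = rng.uniform(-3.1, 18.3, n)
        season = np.where(np.arange(n) % 2 == 0, "summer", "winter")
        t_min = -5.8 + 0.1 * mat + rng.normal(0, sd, n)
        t_min = t_min + np.where(season == "winter", season_shift, 0.0)
        sites = pd.DataFrame({"site_id": range(n), "mat": mat, "season": season})
        idx = pd.DataFrame({"site_id": range(n), "process": "respiration",
                            "t_min": t_min})
        return idx, sites

    def test_pure_mat_effect_keeps_season_null(self):
        hits = 0
        reps = 30
        for seed in range(reps):
            idx, sites = self._trait_frame(np.random.default_rng(seed))
            tab = ancova_season(idx, sites, "t_min", "respiration")
            if (tab.loc["season", "p_value"] > 0.05
                    and tab.loc["mat:season", "p_value"] > 0.05):
                hits += 1
        assert hits >= 0.8 * reps

    def test_identical_seasons_give_near_zero_season_f(self):
        rng = np.random.default_rng(3)
        n = 40
        mat = np.repeat(rng.uniform(0, 15, n // 2), 2)
        t_min = np.repeat(rng.normal(-5, 1, n // 2), 2)  # same trait both seasons
        season = np.tile(["summer", "winter"], n // 2)
        sites = pd.DataFrame({"site_id": range(n), "mat": mat, "season": season})
        idx = pd.DataFrame({"site_id": range(n), "process": "respiration",
                            "t_min": t_min})
        tab = ancova_season(idx, sites, "t_min", "respiration")
        assert tab.loc["season", "F"] == pytest.approx(0.0, abs=1e-9)

    def test_season_shift_detected_in_majority(self):
        hits = 0
        reps = 20
        for seed in range(reps):
            idx, sites = self._trait_frame(np.random.default_rng(seed),
                                           season_shift=1.0)
            tab = ancova_season(idx, sites, "t_min", "respiration")
            hits += tab.loc["season", "p_value"] < 0.05
        assert hits > reps / 2

    def test_single_season_error(self):
        idx, sites = self._trait_frame(np.random.default_rng(0))
        sites["season"] = "summer"
        with pytest.raises(ValueError, match="both seasons"):
            ancova_season(idx, sites, "t_min", "respiration")


class TestPairedSeason:
    def test_identical_pairs(self):
        res = paired_season_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == 1.0 and res.df == 2

    def test_constant_nonzero_difference_is_degenerate(self):
        res = paired_season_test([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert res.degenerate and res.mean_diff == 1.0

    def test_zero_mean_difference(self):
        summer = np.array([0.0, 0, 0, 0, 0])
        winter = np.array([-1.0, 0, 1, 2, -2])
        res = paired_season_test(summer, winter)
        assert res.statistic == pytest.approx(0.0)
        assert res.df == 4
        assert res.p_value == pytest.approx(1.0)

    def test_too_few_pairs_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            paired_season_test([1.0], [2.0])


class TestMultipleRegression:
    @staticmethod
    def _survey(rng, n=72, trait_from_mat=True):
        sites = pd.DataFrame({
            "site_id": range(n),
            "ph": rng.uniform(4, 8, n),
            "som": rng.uniform(2, 80, n),
            "mat": rng.uniform(-3.1, 18.3, n),
            "map": rng.uniform(400, 1800, n),
        })
        trait = (-11 + 0.2 * sites["mat"] + rng.normal(0, 1.0, n)
                 if trait_from_mat else rng.normal(size=n))
        idx = pd.DataFrame({"site_id": sites["site_id"],
                            "process": "bacterial_growth", "t_min": trait})
        return idx, sites

    def test_mat_only_generator_flags_mat(self):
        idx, sites = self._survey(np.random.default_rng(1))
        res = multiple_regression(idx, sites, "t_min", "bacterial_growth")
        coef = res["coefficients"]
        assert coef.loc["mat", "p_value"] < 0.001
        assert res["df2"] == 72 - 5

    def test_other_coefficients_cover_zero_at_nominal_rate(self):
        cover = {"ph": 0, "som": 0, "map": 0}
        reps = 30
        for seed in range(reps):
            idx, sites = self._survey(np.random.default_rng(seed))
            coef = multiple_regression(idx, sites, "t_min",
                                       "bacterial_growth")["coefficients"]
            for k in cover:
                cover[k] += coef.loc[k, "p_value"] > 0.05
        for k, c in cover.items():
            assert c >= 0.8 * reps, k

    def test_duplicate_predictor_collinearity_error(self):
        idx, sites = self._survey(np.random.default_rng(2))
        sites["map"] = sites["mat"]
        with pytest.raises(ValueError, match="collinear"):
            multiple_regression(idx, sites, "t_min", "bacterial_growth")

    def test_orthogonal_standardized_predictors_have_unit_vif(self):
        n = 8
        base = np.array([1.0, 1, 1, 1, -1, -1, -1, -1])
        sites = pd.DataFrame({
            "site_id": range(n),
            "ph": base,
            "som": np.array([1.0, 1, -1, -1, 1, 1, -1, -1]),
            "mat": np.array([1.0, -1, 1, -1, 1, -1, 1, -1]),
            "map": np.array([1.0, -1, -1, 1, 1, -1, -1, 1]),
        })
        idx = pd.DataFrame({"site_id": sites["site_id"],
                            "process": "bacterial_growth",
                            "t_min": np.arange(n, dtype=float)})
        res = multiple_regression(idx, sites, "t_min", "bacterial_growth")
        vifs = res["coefficients"]["vif"].dropna()
        np.testing.assert_allclose(vifs, 1.0, atol=1e-9)


class TestWidthVsAmplitude:
    @staticmethod
    def _frame(width, amp):
        n = len(width)
        sites = pd.DataFrame({"site_id": range(n),
                              "summer_temp": 10 + np.asarray(amp) / 2,
                              "winter_temp": 10 - np.asarray(amp) / 2})
        idx = pd.DataFrame({"site_id": range(n), "process": "bacterial_growth",
                            "width": width})
        return idx, sites

    def test_constant_width_gives_zero_slope(self):
        idx, sites = self._frame([55.0] * 10, np.linspace(5, 25, 10))
        res = width_vs_amplitude(idx, sites, "bacterial_growth")
        assert res.slope == pytest.approx(0.0, abs=1e-10)
        assert res.r_squared == pytest.approx(0.0, abs=1e-10)

    def test_width_equal_amplitude_gives_unit_r2(self):
        amp = np.linspace(5, 25, 10)
        idx, sites = self._frame(amp, amp)
        res = width_vs_amplitude(idx, sites, "bacterial_growth")
        assert res.r_squared == pytest.approx(1.0)

    def test_respiration_refused(self):
        idx, sites = self._frame([55.0] * 10, np.linspace(5, 25, 10))
        with pytest.raises(ValueError, match="width undefined"):
            width_vs_amplitude(idx, sites, "respiration")

    def test_default_survey_has_no_width_amplitude_link(self):
        hits = 0
        reps = 30
        for seed in range(100, 100 + reps):
            cfg = tt.SurveyConfig(seed=seed, n_sites=36)
            sites = tt.generate_sites(cfg)
            params = tt.generate_trait_params(sites, cfg)
            growth = params[params["process"] == "bacterial_growth"]
            idx = pd.DataFrame({
                "site_id": growth["site_id"],
                "process": "bacterial_growth",
                "width": (growth["t_max"] - growth["t_min"]).to_numpy(),
            })
            res = width_vs_amplitude(idx, sites, "bacterial_growth")
            hits += res.p_value > 0.05
        assert hits >= 0.85 * reps


class TestCAvailability:
    def test_exact_dependence_gives_unit_r(self):
        n = 10
        sites = pd.DataFrame({"site_id": [f"S{i}" for i in range(n)],
                              "mat": np.linspace(0, 18, n), "som": 1.0})
        curves = [tt.RateCurve(f"S{i}", "respiration", [15.0, 20.0, 25.0],
                               [0.5, sites["mat"][i] + 30.0, 1.0])
                  for i in range(n)]
        r, p = c_availability_correlation(curves, sites)
        assert r == pytest.approx(1.0)

    def test_two_sites_error(self):
        sites = pd.DataFrame({"site_id": ["A", "B"], "mat": [1.0, 2.0],
                              "som": [5.0, 5.0]})
        curves = [tt.RateCurve(s, "respiration", [20.0, 25.0], [1.0, 2.0])
                  for s in ("A", "B")]
        with pytest.raises(ValueError, match="at least 3"):
            c_availability_correlation(curves, sites)

    def test_missing_som_dropped_with_warning(self):
        n = 5
        sites = pd.DataFrame({"site_id": [f"S{i}" for i in range(n)],
                              "mat": np.linspace(0, 18, n),
                              "som": [1.0, np.nan, 1.0, 1.0, 1.0]})
        curves = [tt.RateCurve(f"S{i}", "respiration", [20.0, 25.0],
                               [float(i + 1), 2.0]) for i in range(n)]
        with pytest.warns(UserWarning, match="missing SOM"):
            c_availability_correlation(curves, sites)

    def test_default_generator_is_null(self):
        hits = 0
        reps = 30
        for seed in range(200, 200 + reps):
            cfg = tt.SurveyConfig(seed=seed, n_sites=40)
            sites = tt.generate_sites(cfg)
            params = tt.generate_trait_params(sites, cfg)
            resp = params[params["process"] == "respiration"]
            table = tt.generate_curves(resp, cfg)
            curves = tt.curves_from_table(table)
            r, p = c_availability_correlation(curves, sites)
            hits += p > 0.05
        assert hits >= 0.85 * reps
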