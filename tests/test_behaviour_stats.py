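"""Tests of the behavioural inference chain: ACF thinning, median quantile
regression, the two GLM families and Tukey pairwise contrasts."""
import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canopyflow import CountSimParams
from canopyflow import behaviour_stats as bs
from canopyflow import synthetic_data as syn
from canopyflow.types import CAMERA_POSITIONS


def _ar1(n, phi, rng):
    x = np.empty(n)
    x[0] = rng.normal()
    for i in range(1, n):
        x[i] = phi * x[i - 1] + rng.normal() * np.sqrt(1 - phi**2)
    return x


class TestAcf:
    def test_white_noise_band_coverage(self):
        rng = np.random.default_rng(12)
        vals, ci = bs.acf_profile(rng.normal(size=400), max_lag=20)
        assert ci == pytest.approx(1.96 / 20.0)
        assert np.sum(np.abs(vals) > ci) <= 3  # ~5% of 20 lags expected outside

    def test_ar1_lag_one(self):
        rng = np.random.default_rng(7)
        x = _ar1(4000, 0.8, rng)
        vals, _ = bs.acf_profile(x, max_lag=5)
        assert vals[0] == pytest.approx(0.8, abs=0.05)

    def test_alternating_series(self):
        x = np.tile([1.0, -1.0], 100)
        vals, _ = bs.acf_profile(x, max_lag=2)
        assert vals[0] == pytest.approx(-1.0, abs=0.02)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            bs.acf_profile(np.ones(100), max_lag=5)


class TestThinningInterval:
    def test_white_noise_typically_needs_interval_two(self):
        rng = np.random.default_rng(0)
        intervals = []
        for _ in range(20):
            vals, ci = bs.acf_profile(rng.normal(size=2000), max_lag=10)
            try:
                intervals.append(bs.select_thinning_interval(vals, ci))
            except ValueError:
                pass
        assert np.median(intervals) == 2

    def test_lag_four_acceptance_gives_every_fifth_record(self):
        # ACF outside the band at lags 1-3, inside at 4 and beyond
        vals = np.array([0.6, 0.4, 0.25, 0.03, 0.05, -0.02, 0.04, 0.01, -0.03, 0.02, 0.0, 0.04])
        assert bs.select_thinning_interval(vals, ci_halfwidth=0.098) == 5

    def test_ma3_series_thins_by_five(self):
        # moving-average of the last four shocks: correlated to lag 3,
        # uncorrelated beyond
        rng = np.random.default_rng(3)
        e = rng.normal(size=4003)
        x = e[3:] + 0.8 * e[2:-1] + 0.55 * e[1:-2] + 0.3 * e[:-3]
        vals, ci = bs.acf_profile(x, max_lag=5)
        assert bs.select_thinning_interval(vals, ci) == 5

    def test_persistent_series_rejected(self):
        vals = np.full(10, 0.9)
        with pytest.raises(ValueError, match="persistent"):
            bs.select_thinning_interval(vals, ci_halfwidth=0.1)


class TestThinTable:
    @staticmethod
    def _table(n_minutes, n_asu=2):
        rows = []
        for asu in range(1, n_asu + 1):
            for pos in CAMERA_POSITIONS:
                for m in range(n_minutes):
                    rows.append(
                        dict(asu_id=asu, camera_position=pos, tide="flood",
                             minute_index=m, abundance=1, watercolumn_count=0)
                    )
        return pd.DataFrame(rows)

    def test_interval_one_is_identity(self):
        t = self._table(7)
        out = bs.thin_table(t, 1)
        assert len(out) == len(t)

    def test_twentythree_rows_keep_five(self):
        out = bs.thin_table(self._table(23), 5)
        per_group = out.groupby(["asu_id", "camera_position"]).size()
        assert (per_group == 5).all()
        kept = out[(out.asu_id == 1) & (out.camera_position == CAMERA_POSITIONS[0])]
        assert list(kept["minute_index"]) == [0, 5, 10, 15, 20]

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(n=st.integers(1, 40), interval=st.integers(1, 10))
    def test_group_sizes_are_ceiling_of_ratio(self, n, interval):
        out = bs.thin_table(self._table(n, n_asu=1), interval)
        per_group = out.groupby(["asu_id", "camera_position"]).size()
        assert (per_group == -(-n // interval)).all()


class TestAttachVelocity:
    def test_interval_containment_join(self):
        tbl = TestThinTable._table(25, n_asu=1)
        adcp = pd.DataFrame({"bin_start": [0.0, 10.0, 20.0], "velocity": [11.0, 22.0, 33.0]})
        out = bs.attach_velocity(tbl, adcp)
        assert (out.loc[out.minute_index < 10, "velocity"] == 11.0).all()
        assert (out.loc[(out.minute_index >= 10) & (out.minute_index < 20), "velocity"] == 22.0).all()
        assert (out.loc[out.minute_index >= 20, "velocity"] == 33.0).all()


class TestQuantilePolyFit:
    def test_exact_quadratic_recovered(self):
        x = np.linspace(0.0, 40.0, 30)
        y = 1.0 + 0.5 * x - 0.01 * x**2
        fit = bs.quantile_poly_fit(x, y)
        assert fit.coefficients == pytest.approx([1.0, 0.5, -0.01], abs=1e-6)
        assert fit.predict(np.array([10.0]))[0] == pytest.approx(5.0, abs=1e-5)

    def test_median_regression_consistency(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 40, 800)
        y = x + rng.standard_t(df=3, size=800)
        fit = bs.quantile_poly_fit(x, y)
        assert fit.coefficients[1] == pytest.approx(1.0, abs=0.05)
        assert abs(fit.coefficients[2]) < 0.003

    def test_single_outlier_barely_moves_median_fit(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 40, 200)
        y = 2.0 + 0.3 * x + rng.normal(size=200)
        base = bs.quantile_poly_fit(x, y)
        y2 = y.copy()
        y2[0] += 500.0
        fit = bs.quantile_poly_fit(x, y2)
        grid = np.linspace(0, 40, 50)
        assert np.max(np.abs(fit.predict(grid) - base.predict(grid))) < 0.5

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            bs.quantile_poly_fit(np.ones(10), np.arange(10.0))


class TestAbundanceGlm:
    def test_poisson_data_dispersion_near_one(self, null_count_params):
        p = dataclasses.replace(null_count_params, n_asu=20, minutes_per_deployment=50)
        res = bs.fit_abundance_glm(syn.simulate_counts(p))
        assert res.dispersion == pytest.approx(1.0, abs=0.1)
        assert list(res.terms["term"]) == ["tide", "camera_position", "tide:camera_position"]
        assert (res.terms["statistic_type"] == "F").all()

    def test_down_current_position_ranked_highest_under_effect(self, null_count_params):
        hits = 0
        reps = 60
        for seed in range(reps):
            p = dataclasses.replace(
                null_count_params, beta_pos=(0.5, 0.0, 0.0, 0.0), seed=2_000 + seed
            )
            tbl = bs.thin_table(syn.simulate_counts(p), 5)
            res = bs.fit_abundance_glm(tbl)
            means = (
                res.data.assign(mu=res.fit.fittedvalues)
                .groupby("camera_position")["mu"].mean()
            )
            if means.idxmax() == "down-current 1 m":
                hits += 1
        assert hits / reps >= 0.95

    def test_all_zero_response_rejected(self, null_count_params):
        tbl = syn.simulate_counts(null_count_params)
        tbl["abundance"] = 0
        tbl["watercolumn_count"] = 0
        with pytest.raises(ValueError, match="all-zero"):
            bs.fit_abundance_glm(tbl)

    def test_single_level_factor_rejected(self, null_count_params):
        tbl = syn.simulate_counts(dataclasses.replace(null_count_params, n_flood=10))
        with pytest.raises(ValueError, match="levels"):
            bs.fit_abundance_glm(tbl)

    def test_deviance_non_increasing_as_terms_added(self, null_count_params):
        import statsmodels.api as sm

        tbl = syn.simulate_counts(null_count_params)
        fits = bs._fit_glm_chain(tbl, tbl["abundance"].to_numpy(float), sm.families.Poisson())
        deviances = [f.deviance for _, f in fits]
        assert all(d1 >= d2 - 1e-9 for d1, d2 in zip(deviances, deviances[1:]))

    def test_marginal_tests_available(self, null_count_params):
        res = bs.fit_abundance_glm(syn.simulate_counts(null_count_params), tests="marginal")
        assert set(res.terms["term"]) == {"tide", "camera_position", "tide:camera_position"}
        assert (res.terms["df"] > 0).all()


class TestProportionGlm:
    def test_null_recovers_intercept_proportion(self, null_count_params):
        p = dataclasses.replace(null_count_params, gamma0=-0.5, n_asu=20, minutes_per_deployment=50)
        res = bs.fit_proportion_glm(syn.simulate_counts(p))
        from scipy.special import expit

        fitted_p = np.asarray(res.fit.fittedvalues)
        assert fitted_p.mean() == pytest.approx(float(expit(-0.5)), abs=0.02)
        assert np.all((fitted_p > 0) & (fitted_p < 1))
        assert (res.terms["statistic_type"] == "chi2").all()

    def test_flood_effect_recovered_positive(self, null_count_params):
        hits = 0
        reps = 40
        for seed in range(reps):
            p = dataclasses.replace(null_count_params, gamma_tide=0.8, seed=5_000 + seed)
            tbl = bs.thin_table(syn.simulate_counts(p), 5)
            res = bs.fit_proportion_glm(tbl)
            # treatment coding with flood as reference: ebb coefficient < 0
            ebb_coef = res.coefficients.loc[
                res.coefficients["term"].str.contains("tide") &
                ~res.coefficients["term"].str.contains(":"), "estimate"
            ].iloc[0]
            if ebb_coef < 0:
                hits += 1
        assert hits / reps >= 0.95

    def test_watercolumn_exceeding_abundance_rejected(self, null_count_params):
        tbl = syn.simulate_counts(null_count_params)
        tbl.loc[0, "watercolumn_count"] = tbl.loc[0, "abundance"] + 1
        with pytest.raises(ValueError, match="exceeds abundance"):
            bs.fit_proportion_glm(tbl)

    def test_separation_warned(self, null_count_params):
        p = dataclasses.replace(null_count_params, gamma_pos=(-40.0, 0.0, 0.0, 0.0))
        tbl = syn.simulate_counts(p)
        with pytest.warns(RuntimeWarning, match="separation"):
            bs.fit_proportion_glm(tbl)


class TestTukey:
    def test_six_contrasts_for_camera_position(self, null_count_params):
        res = bs.fit_abundance_glm(syn.simulate_counts(null_count_params))
        contrasts = bs.tukey_pairwise(res, "camera_position")
        assert len(contrasts) == 6
        assert contrasts["p_adj"].between(0, 1).all()
        assert res.contrasts is contrasts

    def test_familywise_error_controlled_under_null(self, null_count_params):
        clean = 0
        reps = 150
        for seed in range(reps):
            p = dataclasses.replace(null_count_params, seed=9_000 + seed)
            tbl = bs.thin_table(syn.simulate_counts(p), 5)
            res = bs.fit_abundance_glm(tbl)
            contrasts = bs.tukey_pairwise(res, "camera_position")
            if contrasts["p_adj"].min() >= 0.05:
                clean += 1
        assert clean / reps >= 0.93

    def test_tide_factor_gives_single_contrast(self, null_count_params):
        res = bs.fit_abundance_glm(syn.simulate_counts(null_count_params))
        contrasts = bs.tukey_pairwise(res, "tide")
        assert len(contrasts) == 1
        assert contrasts.loc[0, "pair"] == "flood vs ebb"

    def test_unknown_factor_rejected(self, null_count_params):
        res = bs.fit_abundance_glm(syn.simulate_counts(null_count_params))
        with pytest.raises(ValueError, match="factor"):
            bs.tukey_pairwise(res, "velocity")
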