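"""Per-temperature analysis stages: age-class discrimination, age
regression diagnostics, VIP marker selection and trend fitting."""

import numpy as np
import pytest

from flyage.age_models import (ModelSettings, classify_by_age, feature_trends,
                               fit_trend, regress_age, select_markers,
                               spectral_window_features)
from flyage.containers import FeatureTable
from flyage.model_selection import cross_validate
from flyage.cross_decomposition import NIPALSPLS
from flyage.synthetic import GeneratorParams


@pytest.fixture(scope="module")
def noise_free():
    return GeneratorParams(seed=0, scatter_slope_sd=0.0, baseline_sd=0.0,
                           spectral_noise_sd=0.0, chc_noise_sd=0.0)


class TestClassification:
    def test_emits_report_and_scores(self, chc_table_30, fast_settings):
        res = classify_by_age(chc_table_30, 30, fast_settings,
                              run_permutation=False)
        assert np.isfinite(list(res.table2_row().values())[1:]).all()
        assert len(res.scores) == len(chc_table_30)
        assert set(res.scores["age_days"]) == set(range(1, 9))

    def test_informative_beats_shuffled_labels(self, chc_table_30,
                                               fast_settings):
        """The real age labels cross-validate better than shuffled ones."""
        res = classify_by_age(chc_table_30, 30, fast_settings,
                              run_permutation=False)
        rng = np.random.default_rng(0)
        shuffled = []
        for _ in range(5):
            t2 = FeatureTable(chc_table_30.data,
                              chc_table_30.meta.assign(
                                  age_days=rng.permutation(
                                      chc_table_30.meta["age_days"].to_numpy())))
            shuffled.append(classify_by_age(t2, 30, fast_settings,
                                            run_permutation=False).report.q2_cum)
        assert res.report.q2_cum > max(shuffled)

    def test_shuffled_labels_have_low_q2(self, chc_table_30, fast_settings):
        rng = np.random.default_rng(1)
        low = 0
        for i in range(20):
            t2 = FeatureTable(chc_table_30.data,
                              chc_table_30.meta.assign(
                                  age_days=rng.permutation(
                                      chc_table_30.meta["age_days"].to_numpy())))
            q2 = classify_by_age(t2, 30, ModelSettings(seed=i),
                                 run_permutation=False).report.q2_cum
            low += q2 < 0.3
        assert low >= 18

    def test_permutation_q2_intercept_negative(self, chc_table_30,
                                               fast_settings):
        res = classify_by_age(chc_table_30, 30, fast_settings)
        assert res.permutation.q2_intercept < 0

    def test_single_age_class_rejected(self, chc_table_30, fast_settings):
        sub = FeatureTable(
            chc_table_30.data[chc_table_30.meta["age_days"] == 1],
            chc_table_30.meta[chc_table_30.meta["age_days"] == 1])
        with pytest.raises(ValueError, match="age class"):
            classify_by_age(sub, 30, fast_settings)

    def test_singleton_class_rejected(self, chc_table_30, fast_settings):
        keep = (chc_table_30.meta["age_days"] != 3) | \
               (chc_table_30.meta["replicate"] == 1)
        sub = FeatureTable(chc_table_30.data[keep.to_numpy()],
                           chc_table_30.meta[keep.to_numpy()])
        with pytest.raises(ValueError, match="one sample"):
            classify_by_age(sub, 30, fast_settings)


class TestRegression:
    @pytest.mark.parametrize("temperature", [20, 25, 30])
    def test_noise_free_recovery(self, temperature, make_ftir_table,
                                 noise_free, fast_settings):
        """Without noise, spectra determine age to a fraction of a day and
        the predicted-vs-actual line has unit slope."""
        table = make_ftir_table(temperature, noise_free)
        res = regress_age(table, temperature, fast_settings,
                          run_permutation=False)
        assert res.report.rmsecv < 0.5
        assert abs(res.fitted_line[0] - 1.0) < 0.05

    @pytest.mark.parametrize("temperature", [20, 25, 30])
    def test_default_noise_r2(self, temperature, make_chc_table,
                              default_params, fast_settings):
        table = make_chc_table(temperature, default_params)
        res = regress_age(table, temperature, fast_settings,
                          run_permutation=False)
        assert res.report.r2y_cum > 0.8

    def test_permuted_ages_give_negative_q2(self, chc_table_30):
        rng = np.random.default_rng(2)
        ages = rng.permutation(chc_table_30.meta["age_days"].to_numpy(dtype=float))
        rep = cross_validate(NIPALSPLS(n_components=2), chc_table_30.X, ages,
                             seed=0)
        assert rep.q2_cum < 0

    def test_constant_age_rejected(self, chc_table_30, fast_settings):
        sub = FeatureTable(
            chc_table_30.data[chc_table_30.meta["age_days"] == 2],
            chc_table_30.meta[chc_table_30.meta["age_days"] == 2])
        with pytest.raises(ValueError, match="distinct ages"):
            regress_age(sub, 30, fast_settings)

    def test_predictions_invariant_to_feature_order(self, chc_table_30,
                                                    fast_settings, rng):
        res = regress_age(chc_table_30, 30, fast_settings,
                          run_permutation=False)
        perm = rng.permutation(chc_table_30.data.shape[1])
        shuffled = FeatureTable(chc_table_30.data.iloc[:, perm],
                                chc_table_30.meta)
        res2 = regress_age(shuffled, 30, fast_settings, run_permutation=False)
        assert np.allclose(res.predictions["predicted_age"],
                           res2.predictions["predicted_age"], atol=1e-8)


class TestMarkers:
    @pytest.mark.parametrize("temperature", [20, 25, 30])
    def test_c24_selected_at_every_temperature(self, temperature,
                                               make_chc_table, default_params,
                                               fast_settings):
        table = make_chc_table(temperature, default_params)
        clf = classify_by_age(table, temperature, fast_settings,
                              run_permutation=False)
        reg = regress_age(table, temperature, fast_settings,
                          run_permutation=False)
        markers = select_markers([clf, reg])
        assert "C24" in markers

    def test_zero_threshold_selects_all(self, chc_table_30, fast_settings):
        clf = classify_by_age(chc_table_30, 30, fast_settings,
                              run_permutation=False)
        reg = regress_age(chc_table_30, 30, fast_settings,
                          run_permutation=False)
        assert len(select_markers([clf, reg], vip_threshold=0.0)) == 37

    def test_threshold_above_max_gives_empty_list(self, chc_table_30,
                                                  fast_settings):
        clf = classify_by_age(chc_table_30, 30, fast_settings,
                              run_permutation=False)
        assert select_markers([clf], vip_threshold=1e6) == []

    def test_union_mode_is_superset(self, chc_table_30, fast_settings):
        clf = classify_by_age(chc_table_30, 30, fast_settings,
                              run_permutation=False)
        reg = regress_age(chc_table_30, 30, fast_settings,
                          run_permutation=False)
        inter = set(select_markers([clf, reg]))
        union = set(select_markers([clf, reg], mode="union"))
        assert inter <= union


class TestTrendFit:
    def test_exact_line(self):
        ages = np.arange(1, 9)
        fit = fit_trend(2 * ages + 1, ages)
        assert fit.family == "linear"
        assert fit.parameters == pytest.approx((2.0, 1.0), abs=1e-9)
        assert fit.r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("temperature", [20, 25, 30])
    def test_noise_free_c24_decay_rate_recovered(self, temperature,
                                                 make_chc_table, noise_free):
        table = make_chc_table(temperature, noise_free, filtered=False)
        grouped = table.to_frame().groupby("age_days")["C24"].mean()
        fit = fit_trend(grouped.to_numpy(), grouped.index.to_numpy(),
                        family="exponential-offset")
        planted_k = 0.25
        assert abs(fit.parameters[1] - planted_k) / planted_k < 0.10
        assert all(np.diff(fit.fitted) < 0)

    def test_constant_series_degenerate(self):
        fit = fit_trend(np.full(6, 3.3), np.arange(1, 7))
        assert fit.degenerate
        assert fit.family == "linear"
        assert fit.parameters[0] == 0.0
        assert fit.r2 == 0.0

    def test_auto_prefers_fewer_parameters_on_ties(self):
        ages = np.arange(1, 11)
        fit = fit_trend(0.5 * ages + 2, ages, family="auto")
        assert fit.family == "linear"

    def test_three_points_only_allows_linear(self):
        fit = fit_trend([3.0, 2.0, 1.5], [1, 2, 3], family="auto")
        assert fit.family == "linear"

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            fit_trend([1.0, np.nan, 2.0], [1, 2, 3])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            fit_trend([1.0, 2.0], [1, 2])


class TestSpectralTrends:
    def test_window_features_present(self, ftir_table_30):
        feats = spectral_window_features(ftir_table_30)
        assert 5 <= len(feats) <= 9
        assert all(1039.0 <= float(f) <= 1051.5 for f in feats)

    def test_trends_computed_per_feature(self, ftir_table_30):
        feats = spectral_window_features(ftir_table_30)
        trends = feature_trends(ftir_table_30, 30, feats)
        assert len(trends) == len(feats)
        assert all(np.isfinite(t.r2) for t in trends)
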