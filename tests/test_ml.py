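import numpy as np
import pandas as pd
import pytest

from tbitriage.ml import (
    CYTOKINES,
    AboveAverageImportanceSelector,
    FeatureSetSpec,
    FScorePercentileSelector,
    NestedCvConfig,
    VarianceFractionPCA,
    build_features,
    default_feature_sets,
    make_selector,
    nested_cv_evaluate,
    permutation_pvalue,
    select_features,
)
from tbitriage.simulate import simulate_cytokine_panel

FAST_CFG = dict(
    grid={"clf__n_estimators": (50,), "clf__max_depth": (2,), "clf__learning_rate": (0.1,)},
    inner_folds=3,
)


def _toy_panel(series_by_animal, groups):
    rows = []
    for animal, values in series_by_animal.items():
        for day, v in zip((7, 14, 28), values):
            rows.append({"animal_id": animal, "group": groups[animal], "day": day,
                         "cytokine": "IL-6", "concentration": v})
    return pd.DataFrame(rows)


class TestBuildFeatures:
    def test_constant_series_has_zero_differences_and_slope(self):
        panel = _toy_panel({"a": (5, 5, 5), "b": (1, 2, 3)},
                           {"a": "vehicle", "b": "treated"})
        X, y = build_features(panel, FeatureSetSpec("t", ("IL-6",), (7, 14, 28), True))
        assert X.loc["a", "IL-6_diff_d14_d7"] == 0
        assert X.loc["a", "IL-6_diff_d28_d14"] == 0
        assert X.loc["a", "IL-6_slope"] == 0

    def test_slope_is_least_squares_on_actual_days(self):
        """Series (1,2,3) at days (7,14,28): slope = Sxy/Sxx = 21/228.667."""
        panel = _toy_panel({"a": (1, 2, 3), "b": (5, 5, 5)},
                           {"a": "vehicle", "b": "treated"})
        X, _ = build_features(panel, FeatureSetSpec("t", ("IL-6",), (7, 14, 28), True))
        assert X.loc["a", "IL-6_slope"] == pytest.approx(21 / (686 / 3), rel=1e-9)
        assert X.loc["a", "IL-6_diff_d14_d7"] == 1
        assert X.loc["a", "IL-6_diff_d28_d14"] == 1

    def test_single_day_set_is_raw_panel(self):
        panel = simulate_cytokine_panel(n_vehicle=3, n_treated=3, seed=0)
        spec = [s for s in default_feature_sets() if s.name == "cytokines_day28"][0]
        X, y = build_features(panel, spec)
        assert X.shape == (6, 12)
        assert y.sum() == 3

    def test_augmented_panel_has_differences_and_slopes(self):
        panel = simulate_cytokine_panel(n_vehicle=3, n_treated=3, seed=0)
        spec = [s for s in default_feature_sets() if s.name == "cytokines_all_days"][0]
        X, _ = build_features(panel, spec)
        assert X.shape == (6, 12 * 6)  # 3 raw + 2 diffs + 1 slope per cytokine

    def test_missing_day_names_animal_and_day(self):
        panel = _toy_panel({"a": (1, 2, 3), "b": (5, 5, 5)},
                           {"a": "vehicle", "b": "treated"})
        panel = panel[~((panel["animal_id"] == "b") & (panel["day"] == 14))]
        with pytest.raises(ValueError, match="b.*day 14|14"):
            build_features(panel, FeatureSetSpec("t", ("IL-6",), (7, 14, 28), False))

    def test_augment_requires_multiple_days(self):
        with pytest.raises(ValueError):
            FeatureSetSpec("t", ("IL-6",), (28,), augment=True)


class TestSelectors:
    def _data(self, rng_seed=0):
        rng = np.random.default_rng(rng_seed)
        X = rng.normal(size=(30, 10))
        y = np.array([0] * 15 + [1] * 15)
        X[:, 3] += y * 3.0  # single informative feature
        return X, y

    def test_percentile_keeps_expected_count(self):
        X, y = self._data()
        Xt, sel = select_features(X, y, "f_score_percentile", {"percentile": 20})
        assert Xt.shape == (30, 2)

    def test_percentile_floor_keeps_single_best(self):
        X, y = self._data()
        Xt, sel = select_features(X, y, "f_score_percentile", {"percentile": 1})
        assert Xt.shape[1] == 1
        assert sel.support_[0] == 3

    def test_embedded_forest_keeps_informative_feature(self):
        X, y = self._data()
        _, sel = select_features(X, y, "embedded_forest", {"random_state": 0})
        assert 3 in sel.support_

    def test_none_strategy_is_identity(self):
        X, y = self._data()
        Xt, sel = select_features(X, y, "none")
        assert sel is None and np.array_equal(Xt, X)

    def test_pca_retains_variance_fraction(self):
        X, y = self._data()
        Xt, sel = select_features(X, y, "pca", {"variance": 0.5})
        assert Xt.shape[1] < X.shape[1]

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            make_selector("clairvoyance")


class TestNestedCv:
    def test_perfectly_separating_feature_gives_auc_one(self):
        rng = np.random.default_rng(0)
        n = 16
        y = np.array([0] * 8 + [1] * 8)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, n), rng.normal(size=n)])
        out = nested_cv_evaluate(X, y, NestedCvConfig(n_repeats=2, seed=0, **FAST_CFG))
        assert out.aucs == (1.0, 1.0)
        assert out.gate_passed

    def test_determinism_identical_seed_identical_outcome(self):
        panel = simulate_cytokine_panel(n_vehicle=6, n_treated=6, seed=2,
                                        group_effect_day28=2.0)
        spec = [s for s in default_feature_sets() if s.name == "cytokines_day28"][0]
        X, y = build_features(panel, spec)
        cfg = NestedCvConfig(n_repeats=2, seed=11, **FAST_CFG)
        a = nested_cv_evaluate(X, y, cfg)
        b = nested_cv_evaluate(X, y, cfg)
        assert a == b

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(6, 3))
        with pytest.raises(ValueError):
            nested_cv_evaluate(X, np.ones(6, dtype=int), NestedCvConfig(**FAST_CFG))

    def test_missing_values_rejected(self):
        X = np.full((6, 2), np.nan)
        y = np.array([0, 0, 0, 1, 1, 1])
        with pytest.raises(ValueError):
            nested_cv_evaluate(X, y, NestedCvConfig(**FAST_CFG))

    def test_no_leakage_from_held_out_animal(self):
        """The model fitted for an outer fold is unchanged when the
        held-out animal's features are corrupted: neither standardization
        nor fitting ever sees the held-out row."""
        from tbitriage.ml import fit_outer_fold

        rng = np.random.default_rng(3)
        n = 12
        y = np.array([0] * 6 + [1] * 6)
        X = rng.normal(size=(n, 4)) + y[:, None]
        cfg = NestedCvConfig(n_repeats=1, seed=5, **FAST_CFG)
        probe = rng.normal(size=(20, 4))
        model_a, _ = fit_outer_fold(X, y, 4, cfg)
        X_corrupt = X.copy()
        X_corrupt[4] *= 1e6
        model_b, _ = fit_outer_fold(X_corrupt, y, 4, cfg)
        assert np.allclose(
            model_a.predict_proba(probe), model_b.predict_proba(probe)
        )

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            NestedCvConfig(inner_folds=1)
        with pytest.raises(ValueError):
            NestedCvConfig(n_repeats=0)


class TestPermutationPvalue:
    def test_clean_separation_yields_smallest_p(self):
        rng = np.random.default_rng(1)
        n = 14
        y = np.array([0] * 7 + [1] * 7)
        X = np.column_stack([y * 10.0 + rng.normal(0, 0.1, n), rng.normal(size=n)])
        cfg = NestedCvConfig(n_repeats=1, seed=3, n_permutations=19, **FAST_CFG)
        out = nested_cv_evaluate(X, y, cfg)
        p = permutation_pvalue(X, y, cfg, out.mean_auc)
        assert p == pytest.approx(1 / 20)

    def test_chance_level_observed_auc_is_never_significant(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 3))
        y = np.array([0] * 6 + [1] * 6)
        cfg = NestedCvConfig(n_repeats=1, seed=3, n_permutations=19, **FAST_CFG)
        p = permutation_pvalue(X, y, cfg, 0.5)
        assert p > 0.2

    def test_zero_permutations_rejected(self):
        cfg = NestedCvConfig(n_permutations=0, **FAST_CFG)
        with pytest.raises(ValueError):
            permutation_pvalue(np.zeros((4, 2)), [0, 0, 1, 1], cfg, 0.8)
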