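"""Grouped CV, PLS temperature calibration, RF classes, combination rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from heatmir.predictors import (RfClassConfig, combine, fit_pls_temperature,
                                fit_rf_classifier, make_group_folds,
                                month_risk_dummy, PlsTemperatureModel)


def _keys(n_cows, periods=("hw", "ctrl"), reps=1):
    rows = [{"cow": c, "period": p}
            for c in range(n_cows) for p in periods for _ in range(reps)]
    return pd.DataFrame(rows)


class TestGroupFolds:
    def test_equal_group_counts(self):
        keys = _keys(5)  # 10 cow-period groups
        folds = make_group_folds(keys, k=5, seed=0)
        per_fold = folds.groupby(folds).size()
        assert (per_fold == 2).all()

    def test_no_group_split_but_cow_can_straddle_periods(self):
        keys = _keys(8, reps=3)
        folds = make_group_folds(keys, k=5, seed=1)
        tbl = keys.assign(fold=folds)
        assert (tbl.groupby(["cow", "period"])["fold"].nunique() == 1).all()
        assert (tbl.groupby("cow")["fold"].nunique() > 1).any()

    def test_determinism(self):
        keys = _keys(20)
        a = make_group_folds(keys, k=5, seed=7)
        b = make_group_folds(keys, k=5, seed=7)
        assert a.equals(b)

    def test_too_few_groups(self):
        with pytest.raises(ValueError, match="groups"):
            make_group_folds(_keys(2), k=5, seed=0)


class TestMonthRiskDummy:
    @pytest.mark.parametrize("month,expected", [
        (4, 1), (7, 1), (9, 1), (10, 0), (12, 0), (1, 0), (3, 0),
    ])
    def test_rule(self, month, expected):
        assert month_risk_dummy(month) == expected

    def test_invalid(self):
        with pytest.raises(ValueError):
            month_risk_dummy(0)


def _pls_data(n=120, p=30, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    base = rng.normal(size=(n, 1))
    X = pd.DataFrame(base + 0.3 * rng.normal(size=(n, p)),
                     columns=range(1, p + 1))
    y = (1.5 * X[1] - 0.8 * X[2] + 0.5 * X[3]).to_numpy()
    y = y + noise * rng.normal(size=n)
    keys = pd.DataFrame({"cow": np.arange(n) // 2, "period": "hw"})
    folds = make_group_folds(keys, k=5, seed=3)
    return X, y, folds, keys


class TestPlsTemperature:
    def test_noise_free_linear_map_recovered_exactly(self):
        # y exactly linear in the 3 predictors: 3 components suffice
        rng = np.random.default_rng(4)
        n = 100
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=[1, 2, 3])
        y = (1.5 * X[1] - 0.8 * X[2] + 0.5 * X[3]).to_numpy()
        keys = pd.DataFrame({"cow": np.arange(n) // 2, "period": "hw"})
        folds = make_group_folds(keys, k=5, seed=3)
        model = fit_pls_temperature(X, y, folds, keys=keys,
                                    max_components=3, r_threshold=0.0)
        r2 = model.cv_report.set_index("n_components")["r2cv"]
        assert r2.loc[3] == pytest.approx(1.0, abs=1e-6)

    def test_noise_free_wide_matrix_converges_to_exact_fit(self):
        # with 30 collinear columns more latent variables are needed, but
        # the cross-validated fit still converges to exactness
        X, y, folds, keys = _pls_data(noise=0.0)
        model = fit_pls_temperature(X, y, folds, keys=keys,
                                    max_components=15, r_threshold=0.0)
        r2 = model.cv_report.set_index("n_components")["r2cv"]
        assert r2.max() == pytest.approx(1.0, abs=1e-6)

    def test_full_rank_pls_equals_ols_oracle(self):
        rng = np.random.default_rng(1)
        n, p = 60, 5
        X = pd.DataFrame(rng.normal(size=(n, p)), columns=range(1, p + 1))
        y = rng.normal(size=n)
        keys = pd.DataFrame({"cow": np.arange(n), "period": "x"})
        folds = make_group_folds(keys, k=5, seed=0)
        model = fit_pls_temperature(X, y, folds, max_components=p,
                                    n_components=p, r_threshold=0.0)
        Xd = np.column_stack([np.ones(n), X.to_numpy()])
        beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
        assert np.allclose(model.predict(X), Xd @ beta, atol=1e-8)

    def test_noisy_calibration_slope_near_one(self):
        X, y, folds, keys = _pls_data(n=300, noise=0.5, seed=5)
        model = fit_pls_temperature(X, y, folds, keys=keys, max_components=8)
        cv = model.cv_predictions.dropna()
        slope, icpt = np.polyfit(cv["predicted"], cv["observed"], 1)
        resid = cv["observed"] - (slope * cv["predicted"] + icpt)
        se = (resid.std()
              / (np.std(cv["predicted"]) * np.sqrt(len(cv))))
        assert slope == pytest.approx(1.0, abs=3 * se)

    def test_leakage_assertion_triggers_on_split_group(self):
        X, y, folds, keys = _pls_data()
        bad = folds.copy()
        bad.iloc[0] = (bad.iloc[0] + 1) % 5  # splits cow 0's group
        with pytest.raises(AssertionError, match="split across folds"):
            fit_pls_temperature(X, y, bad, keys=keys, max_components=3)

    def test_artifact_round_trip(self):
        X, y, folds, keys = _pls_data()
        model = fit_pls_temperature(X, y, folds, max_components=4)
        clone = PlsTemperatureModel.from_dict(model.to_dict())
        assert np.allclose(clone.predict(X), model.predict(X))


def _class_data(n_per=60, sep=4.0, p=20, seed=0):
    rng = np.random.default_rng(seed)
    mus = {"X0": 0.0, "X0.5": sep, "X1": 2 * sep}
    frames, labels = [], []
    for cls, mu in mus.items():
        block = rng.normal(size=(n_per, p))
        block[:, :3] += mu
        frames.append(block)
        labels += [cls] * n_per
    X = pd.DataFrame(np.vstack(frames), columns=range(1, p + 1))
    X["month_risk"] = rng.integers(0, 2, len(X))
    labels = np.array(labels, dtype=object)
    keys = pd.DataFrame({"cow": np.arange(len(X)), "period": "hw"})
    folds = make_group_folds(keys, k=5, seed=1)
    return X, labels, folds


class TestRfClassifier:
    def test_separable_classes_high_oof_accuracy(self):
        X, labels, folds = _class_data()
        model = fit_rf_classifier(X, labels, folds, seed=0,
                                  config=RfClassConfig(n_trees=200,
                                                       n_top_variables=10))
        assert model.oof_accuracy > 0.95

    def test_label_permutation_gives_chance_accuracy(self):
        X, labels, folds = _class_data(sep=4.0)
        rng = np.random.default_rng(2)
        permuted = rng.permutation(labels)
        model = fit_rf_classifier(X, permuted, folds, seed=0,
                                  config=RfClassConfig(n_trees=200,
                                                       n_top_variables=10))
        n = len(labels)
        se = np.sqrt((1 / 3) * (2 / 3) / n)
        assert model.oof_accuracy == pytest.approx(1 / 3, abs=4 * se)

    def test_confusion_rows_sum_to_truth_counts(self):
        X, labels, folds = _class_data(n_per=30)
        model = fit_rf_classifier(X, labels, folds, seed=0,
                                  config=RfClassConfig(n_trees=100,
                                                       n_top_variables=5))
        truth = pd.Series(labels).value_counts()
        for cls in truth.index:
            assert model.oof_confusion.loc[cls].sum() == truth[cls]

    def test_seeded_runs_reproducible(self):
        X, labels, folds = _class_data(n_per=25)
        cfg = RfClassConfig(n_trees=50, n_top_variables=5)
        a = fit_rf_classifier(X, labels, folds, seed=3, config=cfg)
        b = fit_rf_classifier(X, labels, folds, seed=3, config=cfg)
        assert np.array_equal(a.predict(X), b.predict(X))
        assert a.oof_accuracy == b.oof_accuracy

    def test_month_dummy_always_in_final_columns(self):
        X, labels, folds = _class_data(n_per=25)
        model = fit_rf_classifier(X, labels, folds, seed=0,
                                  config=RfClassConfig(n_trees=50,
                                                       n_top_variables=5))
        assert "month_risk" in model.selected_columns

    def test_single_class_rejected(self):
        X, labels, folds = _class_data(n_per=20)
        with pytest.raises(ValueError, match="class"):
            fit_rf_classifier(X, np.array(["X1"] * len(X), dtype=object),
                              folds, seed=0)


class TestCombine:
    @pytest.mark.parametrize("temp,cls,expected", [
        (36.0, "X1", 1.0),    # boundary inclusive: 'at least 36'
        (36.0, "X0.5", 0.5),
        (35.9, "X1", 0.0),
        (37.2, "X0", 0.0),
        (40.0, "X0.5", 0.5),
        (35.0, "X0", 0.0),
    ])
    def test_rule_table(self, temp, cls, expected):
        assert combine(temp, cls) == expected

    def test_vectorised(self):
        out = combine(np.array([36.5, 35.0]), np.array(["X1", "X1"]))
        assert np.array_equal(out, [1.0, 0.0])

    @given(st.floats(30, 45), st.floats(0, 5),
           st.sampled_from(["X0", "X0.5", "X1"]))
    def test_monotone_in_temperature(self, temp, bump, cls):
        assert combine(temp + bump, cls) >= combine(temp, cls)

    @given(st.floats(36, 45))
    def test_monotone_in_class_above_threshold(self, temp):
        vals = [combine(temp, c) for c in ("X0", "X0.5", "X1")]
        assert vals == sorted(vals)
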