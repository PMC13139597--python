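"""Spectral heat-stress predictors and their combination.

Two models are calibrated on the reference data:

* a PLS regression predicting udder surface temperature from derivative
  spectra, with per-fold |r| >= 0.3 correlation pre-selection and a 5-fold
  cross-validation grouped on (cow, thermal period) so that a cow-period
  never sits in both calibration and validation;
* a two-stage random forest for the X0/X0.5/X1 classes: a first forest ranks
  variable importance, the final forest uses the top 50 variables plus a
  month heat-risk dummy (April-September = 1).

The combined heat-stress phenotype is 1 when the predicted temperature is at
least 36 degC and the predicted class is X1, 0.5 when at least 36 degC with
class X0.5, and 0 otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestClassifier

from .phenotype import CLASS_ORDER
from .spectra import correlation_preselect

__all__ = [
    "make_group_folds",
    "month_risk_dummy",
    "PlsTemperatureModel",
    "fit_pls_temperature",
    "RfClassConfig",
    "RfClassModel",
    "fit_rf_classifier",
    "combine",
]

COMBINE_TEMP_C = 36.0


def make_group_folds(keys: pd.DataFrame, k: int = 5, seed: int = 0) -> pd.Series:
    """Fold index (0..k-1) per record, grouped on (cow, period).

    All records sharing a cow-period key land in one fold; a seeded random
    permutation of the distinct keys is dealt round-robin so fold sizes (in
    groups) differ by at most one.
    """
    group = list(zip(keys["cow"], keys["period"]))
    uniq = sorted(set(group), key=repr)
    if len(uniq) < k:
        raise ValueError(f"only {len(uniq)} cow-period groups for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(uniq))
    fold_of = {uniq[g]: i % k for i, g in enumerate(order)}
    return pd.Series([fold_of[g] for g in group], index=keys.index, name="fold")


def month_risk_dummy(month):
    """1 for heat-risk months April-September, 0 for October-March."""
    month = np.asarray(month)
    if np.any((month < 1) | (month > 12)):
        raise ValueError("month must be 1..12")
    out = ((month >= 4) & (month <= 9)).astype(int)
    return int(out) if out.ndim == 0 else out


def _check_no_leakage(keys: pd.DataFrame, folds: pd.Series):
    """Assert no cow-period key crosses a calibration/validation split."""
    tbl = pd.DataFrame({"cow": keys["cow"].to_numpy(),
                        "period": keys["period"].to_numpy(),
                        "fold": folds.to_numpy()})
    per_group = tbl.groupby(["cow", "period"])["fold"].nunique()
    if (per_group > 1).any():
        bad = per_group[per_group > 1].index[0]
        raise AssertionError(f"cow-period group {bad!r} split across folds")


@dataclass
class PlsTemperatureModel:
    """Calibrated PLS temperature model plus everything needed to predict."""

    selected_points: list
    n_components: int
    coef: np.ndarray
    intercept: float
    x_mean: np.ndarray
    cv_report: pd.DataFrame | None = None
    cv_predictions: pd.DataFrame | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        Xs = X.loc[:, self.selected_points].to_numpy(dtype=float)
        return (Xs - self.x_mean) @ self.coef + self.intercept

    def to_dict(self) -> dict:
        return {
            "kind": "pls_temperature",
            "version": 1,
            "selected_points": [int(p) for p in self.selected_points],
            "n_components": int(self.n_components),
            "coef": [float(c) for c in self.coef],
            "intercept": float(self.intercept),
            "x_mean": [float(m) for m in self.x_mean],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PlsTemperatureModel":
        return cls(selected_points=list(d["selected_points"]),
                   n_components=int(d["n_components"]),
                   coef=np.asarray(d["coef"], dtype=float),
                   intercept=float(d["intercept"]),
                   x_mean=np.asarray(d["x_mean"], dtype=float))


def _fit_pls(Xc: np.ndarray, yc: np.ndarray, k: int) -> PLSRegression:
    pls = PLSRegression(n_components=k, scale=True)
    pls.fit(Xc, yc)
    return pls


def fit_pls_temperature(X: pd.DataFrame, y, folds: pd.Series,
                        keys: pd.DataFrame | None = None,
                        max_components: int = 50,
                        n_components: int | None = None,
                        r_threshold: float = 0.3) -> PlsTemperatureModel:
    """Calibrate the PLS surface-temperature model with grouped CV.

    For every fold the correlation pre-selection runs on the calibration
    portion only; validation predictions reuse the fold's column set.  The
    cross-validation report covers 1..``max_components`` latent variables
    (capped by the selected-feature count); the final model is refit on all
    data at the best (highest R2cv) or user-pinned component count.
    """
    y = np.asarray(y, dtype=float)
    if keys is not None:
        _check_no_leakage(keys, folds)
    folds = np.asarray(folds)
    fold_ids = np.unique(folds)
    kmax_global = max_components
    preds = {}  # n_components -> out-of-fold predictions
    for f in fold_ids:
        cal = folds != f
        val = folds == f
        Xcal, pts = correlation_preselect(X.loc[cal], y[cal], r_threshold)
        if not pts:
            raise ValueError(
                f"no spectral point reaches |r| >= {r_threshold} in fold {f}"
            )
        Xval = X.loc[val, Xcal.columns]
        kmax = min(max_components, len(pts), int(cal.sum()) - 1)
        kmax_global = min(kmax_global, kmax)
        for k in range(1, kmax + 1):
            pls = _fit_pls(Xcal.to_numpy(float), y[cal], k)
            preds.setdefault(k, np.full(len(y), np.nan))
            preds[k][val] = pls.predict(Xval.to_numpy(float)).ravel()
    rows = []
    sst = float(((y - y.mean()) ** 2).sum())
    for k in range(1, kmax_global + 1):
        p = preds[k]
        sse = float(((y - p) ** 2).sum())
        rows.append({"n_components": k,
                     "r2cv": 1.0 - sse / sst,
                     "rmsecv": float(np.sqrt(sse / len(y)))})
    report = pd.DataFrame(rows)
    if n_components is None:
        n_components = int(report.loc[report["r2cv"].idxmax(), "n_components"])
    elif n_components > kmax_global:
        import warnings
        warnings.warn(
            f"n_components={n_components} exceeds usable maximum "
            f"{kmax_global}; capped", stacklevel=2)
        n_components = kmax_global

    Xall, pts = correlation_preselect(X, y, r_threshold)
    k = min(n_components, len(pts))
    pls = _fit_pls(Xall.to_numpy(float), y, k)
    coef = pls.coef_.ravel()
    intercept = float(pls.intercept_.ravel()[0])
    x_mean = Xall.to_numpy(float).mean(axis=0)
    cvpred = pd.DataFrame({"observed": y, "predicted": preds[n_components],
                           "fold": folds}, index=X.index)
    return PlsTemperatureModel(selected_points=list(Xall.columns),
                               n_components=k, coef=coef, intercept=intercept,
                               x_mean=x_mean, cv_report=report,
                               cv_predictions=cvpred)


@dataclass
class RfClassConfig:
    n_trees: int = 500
    mtry: int | None = None          # None -> floor(sqrt(p))
    min_node_size: int = 1
    n_top_variables: int = 50
    include_month_dummy: bool = True


@dataclass
class RfClassModel:
    forest: RandomForestClassifier
    selected_columns: list
    config: RfClassConfig
    oof_confusion: pd.DataFrame | None = None
    oof_accuracy: float | None = None
    class_metrics: pd.DataFrame | None = None
    oof_predictions: pd.Series | None = None

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return self.forest.predict(X.loc[:, self.selected_columns]
                                   .to_numpy(float))


def _make_forest(config: RfClassConfig, p: int, seed: int) -> RandomForestClassifier:
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    return RandomForestClassifier(
        n_estimators=config.n_trees, criterion="gini",
        min_samples_leaf=config.min_node_size,
        max_features=min(mtry, p), random_state=seed, n_jobs=1,
    )


def _top_columns(X: pd.DataFrame, labels, config: RfClassConfig, seed: int,
                 month_col: str | None):
    """Stage-1 forest: rank impurity importance, keep the top variables."""
    rank_cols = [c for c in X.columns if c != month_col]
    stage1 = _make_forest(config, len(X.columns), seed)
    stage1.fit(X.to_numpy(float), labels)
    imp = pd.Series(stage1.feature_importances_, index=X.columns)
    top = (imp.loc[rank_cols].sort_values(ascending=False)
           .index[: config.n_top_variables].tolist())
    if month_col is not None and config.include_month_dummy:
        top = top + [month_col]
    return top


def fit_rf_classifier(X: pd.DataFrame, labels, folds: pd.Series,
                      config: RfClassConfig | None = None, seed: int = 0,
                      month_col="month_risk") -> RfClassModel:
    """Two-stage random-forest classification of X0 / X0.5 / X1.

    Variable selection (stage 1) runs inside each CV fold on the calibration
    portion to keep the out-of-fold confusion report leakage-free; the final
    model reruns both stages on the full training set.
    """
    if config is None:
        config = RfClassConfig()
    labels = np.asarray(labels, dtype=object)
    present = [c for c in CLASS_ORDER if c in set(labels)]
    counts = pd.Series(labels).value_counts()
    if len(present) < 2:
        raise ValueError(f"need >= 2 classes; got counts {counts.to_dict()}")
    month_col = month_col if month_col in X.columns else None

    folds_arr = np.asarray(folds)
    oof = np.empty(len(labels), dtype=object)
    for f in np.unique(folds_arr):
        cal = folds_arr != f
        val = folds_arr == f
        if len(set(labels[cal])) < 2:
            raise ValueError("a CV calibration fold lost all but one class")
        top = _top_columns(X.loc[cal], labels[cal], config, seed, month_col)
        forest = _make_forest(config, len(top), seed)
        forest.fit(X.loc[cal, top].to_numpy(float), labels[cal])
        oof[val] = forest.predict(X.loc[val, top].to_numpy(float))

    classes = present
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, p in zip(labels, oof):
        conf.loc[t, p] += 1
    acc = float((labels == oof).mean())
    metrics = []
    total = conf.to_numpy().sum()
    for c in classes:
        tp = conf.loc[c, c]
        fn = conf.loc[c].sum() - tp
        fp = conf[c].sum() - tp
        tn = total - tp - fn - fp
        metrics.append({"class": c,
                        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                        "specificity": tn / (tn + fp) if tn + fp else np.nan})
    top = _top_columns(X, labels, config, seed, month_col)
    final = _make_forest(config, len(top), seed)
    final.fit(X.loc[:, top].to_numpy(float), labels)
    return RfClassModel(forest=final, selected_columns=top, config=config,
                        oof_confusion=conf, oof_accuracy=acc,
                        class_metrics=pd.DataFrame(metrics),
                        oof_predictions=pd.Series(oof, index=X.index))


def combine(pred_temp, pred_class):
    """Combined heat-stress phenotype in {0, 0.5, 1}.

    1 when predicted temperature >= 36 degC and class X1; 0.5 when >= 36 degC
    and class X0.5; 0 otherwise.
    """
    scalar = np.isscalar(pred_temp) and isinstance(pred_class, str)
    temp = np.atleast_1d(np.asarray(pred_temp, dtype=float))
    cls = np.atleast_1d(np.asarray(pred_class, dtype=object))
    hot = temp >= COMBINE_TEMP_C
    out = np.where(hot & (cls == "X1"), 1.0,
                   np.where(hot & (cls == "X0.5"), 0.5, 0.0))
    return float(out[0]) if scalar else out
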