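"""End-to-end pipeline: simulate -> thi -> residuals -> phenotype ->
preprocess -> train -> predict -> combine -> analyze.

Each stage reads the CSV artifacts of its upstream stages from ``outdir``,
writes its own, and appends an entry to the run manifest.  Any contiguous
sub-range of stages can be run; a missing upstream artifact raises an error
naming the stage to run first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as hio
from . import thi as thi_mod
from .phenotype import (assemble_training_set, classify_table,
                        control_eligible)
from .population import population_filter, fit_population_model, thi_binned_means
from .predictors import (PlsTemperatureModel, RfClassConfig, combine,
                         fit_pls_temperature, fit_rf_classifier,
                         make_group_folds, month_risk_dummy)
from .simulate import SimulationConfig, simulate_dataset
from .spectra import first_derivative, select_regions
from .testday import residual_table

STAGES = ("simulate", "thi", "residuals", "phenotype", "preprocess",
          "train", "predict", "combine", "analyze")

_STAGE_INPUTS = {
    "thi": {"weather.csv": "simulate"},
    "residuals": {"testday.csv": "simulate", "pedigree.csv": "simulate"},
    "phenotype": {"surface_temps.csv": "simulate", "residuals.csv": "residuals"},
    "preprocess": {"spectra.csv": "simulate"},
    "train": {"features.csv": "preprocess", "training_set.csv": "phenotype",
              "surface_temps.csv": "simulate"},
    "predict": {"features.csv": "preprocess", "models.json": "train"},
    "combine": {"predictions.csv": "predict"},
    "analyze": {"predictions.csv": "combine", "testday.csv": "simulate",
                "pedigree.csv": "simulate"},
}

DEFAULTS = {
    "seed": 0,
    "outdir": "heatmir_run",
    "simulation": {},
    "folds": 5,
    "max_components": 50,
    "n_components": None,
    "r_threshold": 0.3,
    "n_extra_controls": None,   # None -> bring X0 up to |X1|
    "min_bin": 50,
    "population_var_ratios": [0.05, 0.05, 0.90],
}


def load_config(path) -> dict:
    import yaml

    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    cfg = {**DEFAULTS, **user}
    cfg["simulation"] = {**DEFAULTS["simulation"], **(user.get("simulation") or {})}
    return cfg


def _need(outdir: Path, fname: str, stage: str):
    path = outdir / fname
    if not path.exists():
        src = _STAGE_INPUTS.get(stage, {}).get(fname, "an earlier stage")
        raise FileNotFoundError(
            f"stage '{stage}' needs {fname}; run stage '{src}' first"
        )
    return path


def _read_testday(path):
    df = pd.read_csv(path)
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def stage_simulate(cfg: dict, outdir: Path) -> None:
    sim_cfg = SimulationConfig(seed=cfg["seed"], **cfg["simulation"])
    ds = simulate_dataset(sim_cfg)
    hio.write_csv(ds.weather, outdir / "weather.csv")
    hio.write_csv(ds.cows, outdir / "cows.csv")
    hio.write_csv(ds.pedigree, outdir / "pedigree.csv")
    hio.write_csv(ds.testday, outdir / "testday.csv")
    hio.write_spectra_csv(ds.spectra, outdir / "spectra.csv")
    hio.write_csv(ds.surface_temps, outdir / "surface_temps.csv")
    hio.write_manifest(outdir, cfg, "simulate",
                       [outdir / f for f in
                        ("weather.csv", "cows.csv", "pedigree.csv",
                         "testday.csv", "spectra.csv", "surface_temps.csv")],
                       seeds={"master": cfg["seed"]})


def stage_thi(cfg: dict, outdir: Path) -> None:
    weather = pd.read_csv(_need(outdir, "weather.csv", "thi"),
                          parse_dates=["timestamp"])
    daily = thi_mod.daily_mean_thi(weather)
    daily = thi_mod.add_thi_window(daily)
    hio.write_csv(daily, outdir / "daily_thi.csv")
    hio.write_manifest(outdir, cfg, "thi", [outdir / "daily_thi.csv"])


def stage_residuals(cfg: dict, outdir: Path) -> None:
    testday = _read_testday(_need(outdir, "testday.csv", "residuals"))
    pedigree = pd.read_csv(_need(outdir, "pedigree.csv", "residuals"))
    res = residual_table(testday, pedigree)
    keep = ["sample_id"] + [c for c in res.columns
                            if c.startswith(("res_", "sres_"))]
    hio.write_csv(res[keep], outdir / "residuals.csv")
    hio.write_manifest(outdir, cfg, "residuals", [outdir / "residuals.csv"])


def stage_phenotype(cfg: dict, outdir: Path) -> None:
    surface = pd.read_csv(_need(outdir, "surface_temps.csv", "phenotype"))
    residuals = pd.read_csv(_need(outdir, "residuals.csv", "phenotype"))
    testday = _read_testday(_need(outdir, "testday.csv", "phenotype"))
    merged = surface.merge(residuals, on="sample_id", how="left")
    heat = merged[merged["period"] == "heat_wave"]
    ctrl = merged[merged["period"] == "thermoneutral"]
    classified = classify_table(heat, ctrl)

    td = testday.merge(residuals, on="sample_id")
    td["month"] = pd.to_datetime(td["date"]).dt.month
    eligible = td[[control_eligible(m, t) for m, t in
                   zip(td["month"], td["thi_td3d"])]]
    # keep the control pool disjoint from the visit records
    eligible = eligible[~eligible["sample_id"].isin(merged["sample_id"])]
    n_x1 = int((classified["ref_class"] == "X1").sum())
    n_x0 = int((classified["ref_class"] == "X0").sum())
    n_extra = cfg.get("n_extra_controls")
    if n_extra is None:
        n_extra = max(0, n_x1 - n_x0)
    train = assemble_training_set(classified, eligible, n_extra,
                                  seed=cfg["seed"] + 1)
    cols = ["sample_id", "label", "provenance"]
    hio.write_csv(train[cols], outdir / "training_set.csv")
    hio.write_csv(classified[["sample_id", "farm", "mean_temp", "ref_class"]],
                  outdir / "reference_classes.csv")
    hio.write_manifest(outdir, cfg, "phenotype",
                       [outdir / "training_set.csv",
                        outdir / "reference_classes.csv"])


def stage_preprocess(cfg: dict, outdir: Path) -> None:
    spectra = hio.read_spectra_csv(_need(outdir, "spectra.csv", "preprocess"))
    feats = select_regions(first_derivative(spectra))
    out = feats.copy()
    out.columns = [f"pt_{c:04d}" for c in feats.columns]
    out.index.name = "sample_id"
    out.to_csv(outdir / "features.csv", float_format=hio.FLOAT_FMT)
    hio.write_manifest(outdir, cfg, "preprocess", [outdir / "features.csv"])


def _read_features(path) -> pd.DataFrame:
    df = pd.read_csv(path, index_col=0)
    df.columns = [int(c.split("_")[1]) for c in df.columns]
    return df


def stage_train(cfg: dict, outdir: Path) -> None:
    feats = _read_features(_need(outdir, "features.csv", "train"))
    train = pd.read_csv(_need(outdir, "training_set.csv", "train"))
    surface = pd.read_csv(_need(outdir, "surface_temps.csv", "train"))
    testday = _read_testday(_need(outdir, "testday.csv", "train"))

    # temperature model: all surface-temperature records (both periods)
    temp_tbl = surface.merge(
        testday[["sample_id", "animal", "date"]], on="sample_id")
    keys = pd.DataFrame({"cow": temp_tbl["cow"], "period": temp_tbl["period"]})
    folds = make_group_folds(keys, k=cfg["folds"], seed=cfg["seed"] + 2)
    Xt = feats.loc[temp_tbl["sample_id"]]
    folds.index = Xt.index
    keys.index = Xt.index
    pls = fit_pls_temperature(
        Xt, temp_tbl["mean_temp"].to_numpy(), folds, keys=keys,
        max_components=cfg["max_components"],
        n_components=cfg["n_components"], r_threshold=cfg["r_threshold"])

    # class model: labelled training set + month-risk dummy
    cls_tbl = train.merge(testday[["sample_id", "animal", "date"]],
                          on="sample_id")
    Xc = feats.loc[cls_tbl["sample_id"]].copy()
    month = pd.to_datetime(cls_tbl["date"]).dt.month
    Xc["month_risk"] = month_risk_dummy(month.to_numpy())
    period = np.where(cls_tbl["provenance"].eq("augmented"),
                      "control_pool", "heat_wave_visit")
    ckeys = pd.DataFrame({"cow": cls_tbl["animal"].to_numpy(),
                          "period": period}, index=Xc.index)
    cfolds = make_group_folds(ckeys, k=cfg["folds"], seed=cfg["seed"] + 3)
    rf = fit_rf_classifier(Xc, cls_tbl["label"].to_numpy(), cfolds,
                           seed=cfg["seed"] + 4)

    artifact = {
        "version": 1,
        "pls": pls.to_dict(),
        "pls_cv": {"n_components": int(pls.n_components),
                   "r2cv": float(pls.cv_report.loc[
                       pls.cv_report["n_components"] == pls.n_components,
                       "r2cv"].iloc[0]),
                   "rmsecv": float(pls.cv_report.loc[
                       pls.cv_report["n_components"] == pls.n_components,
                       "rmsecv"].iloc[0])},
        "rf": {
            "selected_columns": [str(c) for c in rf.selected_columns],
            "config": vars(rf.config),
            "seed": cfg["seed"] + 4,
            "training_file": "training_set.csv",
            "oof_accuracy": rf.oof_accuracy,
        },
    }
    with open(outdir / "models.json", "w", encoding="utf-8") as fh:
        json.dump(artifact, fh, indent=1)
    hio.write_csv(pls.cv_report, outdir / "pls_cv_report.csv")
    hio.write_manifest(outdir, cfg, "train",
                       [outdir / "models.json", outdir / "pls_cv_report.csv"])


def _refit_rf(cfg: dict, outdir: Path, feats: pd.DataFrame, artifact: dict):
    """Rebuild the final (seeded, deterministic) class forest from the
    stored recipe + training table."""
    train = pd.read_csv(outdir / artifact["rf"]["training_file"])
    testday = _read_testday(outdir / "testday.csv")
    cls_tbl = train.merge(testday[["sample_id", "date"]], on="sample_id")
    Xc = feats.loc[cls_tbl["sample_id"]].copy()
    Xc["month_risk"] = month_risk_dummy(
        pd.to_datetime(cls_tbl["date"]).dt.month.to_numpy())
    cols = [c if c == "month_risk" else int(c)
            for c in artifact["rf"]["selected_columns"]]
    from .predictors import _make_forest

    rfcfg = RfClassConfig(**{k: v for k, v in artifact["rf"]["config"].items()})
    forest = _make_forest(rfcfg, len(cols), artifact["rf"]["seed"])
    forest.fit(Xc.loc[:, cols].to_numpy(float), cls_tbl["label"].to_numpy())
    return forest, cols


def stage_predict(cfg: dict, outdir: Path) -> None:
    feats = _read_features(_need(outdir, "features.csv", "predict"))
    with open(_need(outdir, "models.json", "predict"), encoding="utf-8") as fh:
        artifact = json.load(fh)
    pls = PlsTemperatureModel.from_dict(artifact["pls"])
    pred_temp = pls.predict(feats)
    testday = _read_testday(outdir / "testday.csv")
    month = pd.to_datetime(
        testday.set_index("sample_id").loc[feats.index, "date"]).dt.month
    forest, cols = _refit_rf(cfg, outdir, feats, artifact)
    Xall = feats.copy()
    Xall["month_risk"] = month_risk_dummy(month.to_numpy())
    pred_class = forest.predict(Xall.loc[:, cols].to_numpy(float))
    out = pd.DataFrame({"sample_id": feats.index,
                        "pred_temp_c": pred_temp,
                        "pred_class": pred_class})
    hio.write_csv(out, outdir / "predictions.csv")
    hio.write_manifest(outdir, cfg, "predict", [outdir / "predictions.csv"])


def stage_combine(cfg: dict, outdir: Path) -> None:
    pred = pd.read_csv(_need(outdir, "predictions.csv", "combine"))
    pred["combined"] = combine(pred["pred_temp_c"].to_numpy(),
                               pred["pred_class"].to_numpy())
    hio.write_csv(pred, outdir / "predictions.csv")
    hio.write_manifest(outdir, cfg, "combine", [outdir / "predictions.csv"])


def stage_analyze(cfg: dict, outdir: Path) -> None:
    pred = pd.read_csv(_need(outdir, "predictions.csv", "analyze"))
    if "combined" not in pred.columns:
        raise FileNotFoundError(
            "stage 'analyze' needs the combined value; run stage 'combine' first"
        )
    testday = _read_testday(_need(outdir, "testday.csv", "analyze"))
    pedigree = pd.read_csv(_need(outdir, "pedigree.csv", "analyze"))
    tbl = testday.merge(pred, on="sample_id")
    tbl["htd"] = tbl["herd"].astype(str) + ":" + tbl["date"].astype(str)
    filtered, report = population_filter(tbl)
    fit = fit_population_model(filtered, pedigree=pedigree,
                  var_ratios=tuple(cfg["population_var_ratios"]))
    sols = []
    for factor in ("lact_class", "dim_class", "milk_class", "htd"):
        for level, value in fit[factor].items():
            sols.append({"factor": factor, "level": level, "solution": value})
    hio.write_csv(pd.DataFrame(sols), outdir / "population_solutions.csv")
    summary = thi_binned_means(tbl, min_bin=cfg["min_bin"])
    hio.write_csv(summary, outdir / "thi_summary.csv")
    with open(outdir / "filter_report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
    hio.write_manifest(outdir, cfg, "analyze",
                       [outdir / "population_solutions.csv",
                        outdir / "thi_summary.csv"])


_STAGE_FN = {
    "simulate": stage_simulate, "thi": stage_thi,
    "residuals": stage_residuals, "phenotype": stage_phenotype,
    "preprocess": stage_preprocess, "train": stage_train,
    "predict": stage_predict, "combine": stage_combine,
    "analyze": stage_analyze,
}


def run_pipeline(cfg: dict, outdir, stages=None) -> Path:
    """Execute a contiguous range of pipeline stages.

    ``stages`` may be None (all), a list of stage names, or a string
    ``"first..last"``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if stages is None:
        todo = list(STAGES)
    elif isinstance(stages, str):
        first, _, last = stages.partition("..")
        last = last or first
        i, j = STAGES.index(first), STAGES.index(last)
        todo = list(STAGES[i:j + 1])
    else:
        todo = list(stages)
    for s in todo:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}; valid: {STAGES}")
    for s in todo:
        _STAGE_FN[s](cfg, outdir)
    return outdir / "manifest.jsonl"
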