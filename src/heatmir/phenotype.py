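"""Reference heat-stress classes from udder temperatures and milk residuals.

A heat-wave record is classified against the farm's own thermoneutral-day
temperature distribution (mean, SD over the control visit) combined with
standardized test-day residuals of protein % and Mg:

* affected (X1): udder temperature above mean + 3 SD AND both residuals
  below -0.1;
* non-affected (X0): temperature below mean + 2 SD AND both residuals at or
  above -0.1;
* intermediate (X0.5): everything else (the grey zone, including all
  temperatures between the 2 SD and 3 SD bounds).

The RF training set takes all X1 records, the rule-based X0 records enlarged
with randomly drawn low-THI non-summer controls, and a random sample of the
intermediates sized to match X1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CLASS_ORDER",
    "ThermoneutralStats",
    "thermoneutral_stats",
    "classify_reference",
    "classify_table",
    "control_eligible",
    "assemble_training_set",
]

CLASS_ORDER = ("X0", "X0.5", "X1")

SUMMER_MONTHS = (6, 7, 8)
CONTROL_THI_LIMIT = 60
RESIDUAL_LIMIT = -0.1


@dataclass
class ThermoneutralStats:
    farm: object
    mean: float
    sd: float
    n: int


def thermoneutral_stats(controls: pd.DataFrame, farm) -> ThermoneutralStats:
    """Mean and sample SD of thermoneutral-day mean udder temperatures."""
    sub = controls[controls["farm"] == farm]
    if len(sub) < 2:
        raise ValueError(
            f"farm {farm!r} has {len(sub)} thermoneutral record(s); need >= 2"
        )
    temps = sub["mean_temp"].to_numpy(dtype=float)
    return ThermoneutralStats(
        farm=farm, mean=float(temps.mean()),
        sd=float(temps.std(ddof=1)), n=len(temps),
    )


def classify_reference(mean_temp: float, stats: ThermoneutralStats,
                       r_protein: float, r_mg: float,
                       farm=None) -> str:
    """Classify one heat-wave record as X0, X0.5 or X1.

    Thresholds are strict as printed: a temperature exactly at mean + 3 SD
    or a residual exactly at -0.1 does not qualify for X1.
    """
    if farm is not None and farm != stats.farm:
        raise ValueError(
            f"record farm {farm!r} does not match stats farm {stats.farm!r}"
        )
    hot = mean_temp > stats.mean + 3.0 * stats.sd
    cool = mean_temp < stats.mean + 2.0 * stats.sd
    depressed = (r_protein < RESIDUAL_LIMIT) and (r_mg < RESIDUAL_LIMIT)
    normal = (r_protein >= RESIDUAL_LIMIT) and (r_mg >= RESIDUAL_LIMIT)
    if hot and depressed:
        return "X1"
    if cool and normal:
        return "X0"
    return "X0.5"


def classify_table(heatwave: pd.DataFrame, controls: pd.DataFrame) -> pd.DataFrame:
    """Classify every heat-wave record, keying thermoneutral stats per farm.

    ``heatwave`` needs ``farm, mean_temp, sres_protein_pct, sres_mg_conc``.
    Returns a copy with a ``ref_class`` column.
    """
    out = heatwave.copy()
    stats = {f: thermoneutral_stats(controls, f) for f in out["farm"].unique()}
    out["ref_class"] = [
        classify_reference(t, stats[f], rp, rm, farm=f)
        for f, t, rp, rm in zip(out["farm"], out["mean_temp"],
                                out["sres_protein_pct"], out["sres_mg_conc"])
    ]
    return out


def control_eligible(month: int, thi_td3d: int) -> bool:
    """Eligibility of a historical record for control augmentation.

    True outside June-August when the 4-day THI window is strictly below 60.
    """
    if not 1 <= int(month) <= 12:
        raise ValueError(f"invalid month {month!r}")
    return int(month) not in SUMMER_MONTHS and thi_td3d < CONTROL_THI_LIMIT


def assemble_training_set(classified: pd.DataFrame, eligible: pd.DataFrame,
                          n_extra_controls: int, seed: int,
                          n_intermediate: int | None = None) -> pd.DataFrame:
    """Balanced labelled training table for the class model.

    * all X1 records (provenance "rule");
    * all rule-based X0 records plus ``n_extra_controls`` drawn without
      replacement from the eligible low-THI pool (provenance "augmented");
    * a random sample of intermediates labelled X0.5, sized ``|X1|`` unless
      overridden.
    """
    rng = np.random.default_rng(seed)
    x1 = classified[classified["ref_class"] == "X1"]
    if len(x1) < 1:
        raise ValueError("no X1 records; cannot assemble a training set")
    x0 = classified[classified["ref_class"] == "X0"]
    mid = classified[classified["ref_class"] == "X0.5"]
    if n_extra_controls > len(eligible):
        raise ValueError(
            f"requested {n_extra_controls} augmented controls but the "
            f"eligible pool holds only {len(eligible)}"
        )
    if n_intermediate is None:
        n_intermediate = len(x1)
    if n_intermediate > len(mid):
        n_intermediate = len(mid)

    parts = [x1.assign(label="X1", provenance="rule"),
             x0.assign(label="X0", provenance="rule")]
    if n_extra_controls > 0:
        pick = rng.choice(len(eligible), size=n_extra_controls, replace=False)
        parts.append(eligible.iloc[np.sort(pick)]
                     .assign(label="X0", provenance="augmented"))
    if n_intermediate > 0:
        pick = rng.choice(len(mid), size=n_intermediate, replace=False)
        parts.append(mid.iloc[np.sort(pick)]
                     .assign(label="X0.5", provenance="rule"))
    out = pd.concat(parts, ignore_index=True)
    return out
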