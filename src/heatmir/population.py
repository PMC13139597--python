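"""Population-scale application of the combined heat-stress phenotype.

The combined 0 / 0.5 / 1 phenotype is computed for every routine milk
recording, filtered (herd-test-day size >= 10, DIM 5-365, milk yield >= 3
kg), transformed into Snell scores, and analysed with a mixed model

    y = HTD + lact_class + DIM_class(5 d) + milk_class(7) + animal + pe + e

whose fixed-effect solutions profile heat-stress susceptibility over parity,
lactation stage and production level.  THI-binned averages of the combined
value summarise the population response curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .mme import RandomTerm, a_inverse, solve_mme
from .testday import _dummies, lactation_class

__all__ = [
    "population_filter",
    "milk_yield_class",
    "dim_class_5d",
    "snell_scores",
    "SnellTransform",
    "fit_population_model",
    "thi_binned_means",
]

MIN_HTD_RECORDS = 10
MIN_MILK_KG = 3.0

_MILK_BIN_LOWER = (15.0, 20.0, 25.0, 30.0, 35.0, 40.0)


def population_filter(records: pd.DataFrame):
    """Record filters ahead of the population mixed model.

    Keeps records with DIM in [5, 365], 24 h milk yield >= 3 kg, and
    belonging to a herd-test-day (``htd`` column) holding at least 10
    eligible records.  The HTD size criterion is evaluated after the
    record-level filters, then re-checked once.  Returns
    ``(filtered, report)`` with drop counts per criterion.
    """
    n0 = len(records)
    dim_ok = (records["dim"] >= 5) & (records["dim"] <= 365)
    milk_ok = records["milk_kg"] >= MIN_MILK_KG
    kept = records[dim_ok & milk_ok]
    report = {
        "input": n0,
        "dropped_dim": int((~dim_ok).sum()),
        "dropped_milk": int((milk_ok[dim_ok] == False).sum()),  # noqa: E712
    }
    dropped_htd = 0
    for _ in range(2):  # single pass + one re-check
        sizes = kept.groupby("htd")["htd"].transform("size")
        small = sizes < MIN_HTD_RECORDS
        dropped_htd += int(small.sum())
        if not small.any():
            break
        kept = kept[~small]
    report["dropped_htd"] = dropped_htd
    report["kept"] = len(kept)
    return kept.copy(), report


def milk_yield_class(milk_kg):
    """7 milk-yield classes: <15, [15,20), [20,25), ..., [35,40), >=40 kg."""
    milk = np.asarray(milk_kg, dtype=float)
    if np.any(milk < MIN_MILK_KG):
        raise ValueError(f"milk yield below {MIN_MILK_KG} kg; filter first")
    out = np.searchsorted(_MILK_BIN_LOWER, milk, side="right") + 1
    return int(out) if out.ndim == 0 else out


def dim_class_5d(dim):
    """5-day DIM classes on [5, 365]: class = (DIM-5)//5 + 1, DIM 365 -> 73."""
    dim = np.asarray(dim)
    if np.any((dim < 5) | (dim > 365)):
        raise ValueError("DIM must lie in [5, 365]; filter first")
    out = (np.asarray(dim, dtype=int) - 5) // 5 + 1
    return int(out) if out.ndim == 0 else out


@dataclass
class SnellTransform:
    """Scores for ordered categories from a logistic-liability construction.

    Cumulative proportions P_k map to boundaries t_k = logit(P_k) on a
    standard logistic liability scale; a category's score is the mean of the
    logistic variable truncated to its interval, so scores are strictly
    increasing and invariant to rescaling the frequencies.
    """

    categories: list
    frequencies: np.ndarray
    scores: np.ndarray

    def mapping(self) -> dict:
        return dict(zip(self.categories, self.scores))


def _logistic_partial_mean(a: float, b: float) -> float:
    """E[X | a < X < b] for standard logistic X (a, b may be +-inf)."""

    def antideriv(x):
        # d/dx [x*F(x) - log(1+e^x)] = x*f(x); -> 0 at both infinities
        if np.isinf(x):
            return 0.0
        return x / (1.0 + np.exp(-x)) - np.logaddexp(0.0, x)

    def cdf(x):
        if x == -np.inf:
            return 0.0
        if x == np.inf:
            return 1.0
        return 1.0 / (1.0 + np.exp(-x))

    mass = cdf(b) - cdf(a)
    return (antideriv(b) - antideriv(a)) / mass


def snell_scores(frequencies, categories=None) -> SnellTransform:
    """Snell-type scores for ordered categories with the given frequencies."""
    freq = np.asarray(frequencies, dtype=float)
    if len(freq) < 2:
        raise ValueError("need at least 2 categories")
    if np.any(freq <= 0):
        raise ValueError(
            "zero-frequency category; merge it with a neighbour before scoring"
        )
    if categories is None:
        categories = list(range(len(freq)))
    p = freq / freq.sum()
    cum = np.cumsum(p)
    bounds = np.concatenate(
        [[-np.inf], np.log(cum[:-1] / (1.0 - cum[:-1])), [np.inf]]
    )
    scores = np.array([
        _logistic_partial_mean(bounds[i], bounds[i + 1])
        for i in range(len(freq))
    ])
    return SnellTransform(categories=list(categories), frequencies=freq,
                          scores=scores)


def _population_design(records: pd.DataFrame):
    htd = records["htd"].astype(str)
    lact = pd.Series(lactation_class(records["lactation"].to_numpy()))
    dimc = pd.Series(dim_class_5d(records["dim"].to_numpy()))
    milkc = pd.Series(milk_yield_class(records["milk_kg"].to_numpy()))
    parts, labels = [], []
    for i, (name, series) in enumerate(
        [("htd", htd), ("lact_class", lact),
         ("dim_class", dimc), ("milk_class", milkc)]
    ):
        mat, lv = _dummies(series.reset_index(drop=True), drop_first=(i > 0))
        parts.append(mat)
        labels.extend((name, l) for l in lv)
    return sp.hstack(parts, format="csr"), labels


def fit_population_model(records: pd.DataFrame, pedigree: pd.DataFrame | None = None,
            var_ratios=(0.05, 0.05, 0.90), response: str = "snell"):
    """Mixed model on the Snell-scored combined phenotype.

    ``records`` must already be ``population_filter``-ed and carry ``combined``
    (values 0/0.5/1), ``htd``, ``animal``, ``lactation``, ``dim``,
    ``milk_kg``.  Variance components default to
    animal : permanent-environment : residual = 0.05 : 0.05 : 0.90 of the
    response variance.  If a pedigree is given the animal effect is
    structured by A-inverse, otherwise animals are treated as unrelated.

    Returns a dict with fixed-effect solution Series per factor, the Snell
    transform used, and the MME solution.
    """
    records = records.reset_index(drop=True)
    vals = records["combined"].to_numpy(dtype=float)
    levels, counts = np.unique(vals, return_counts=True)
    if response == "snell" and len(levels) >= 2:
        tr = snell_scores(counts, categories=list(levels))
        y = np.array([tr.mapping()[v] for v in vals])
    else:
        tr = None
        y = vals
    vy = float(np.var(y))
    if vy == 0.0:
        raise ValueError("combined phenotype is constant; nothing to fit")
    ra, rp, re = var_ratios
    X, labels = _population_design(records)

    if pedigree is not None:
        animals = pedigree["animal"].tolist()
        ainv = a_inverse(pedigree)
    else:
        animals = list(pd.unique(records["animal"]))
        ainv = sp.identity(len(animals), format="csr")
    a_idx = {a: i for i, a in enumerate(animals)}
    rec_a = np.array([a_idx[a] for a in records["animal"]])
    n = len(records)
    ones = np.ones(n)
    Za = sp.csr_matrix((ones, (np.arange(n), rec_a)), shape=(n, len(animals)))
    rec_ids = list(pd.unique(records["animal"]))
    p_idx = {a: i for i, a in enumerate(rec_ids)}
    rec_p = np.array([p_idx[a] for a in records["animal"]])
    Zp = sp.csr_matrix((ones, (np.arange(n), rec_p)), shape=(n, len(rec_ids)))

    sigma2_e = re * vy
    terms = [
        RandomTerm("animal", Za, ainv / (ra * vy)),
        RandomTerm("perm_env", Zp, sp.identity(len(rec_ids)) / (rp * vy)),
    ]
    sol = solve_mme(X, terms, y, sigma2_e)
    fixed = pd.Series(sol.fixed, index=pd.MultiIndex.from_tuples(labels))
    out = {"solution": sol, "snell": tr, "fixed": fixed}
    for factor in ("htd", "lact_class", "dim_class", "milk_class"):
        s = fixed.loc[factor]
        out[factor] = s
    return out


def thi_binned_means(records: pd.DataFrame, min_bin: int = 1000) -> pd.DataFrame:
    """Mean combined value (and predicted temperature) per integer THI class.

    Bins with fewer than ``min_bin`` records are suppressed.
    """
    cols = {"n": ("combined", "size"), "mean_combined": ("combined", "mean")}
    if "pred_temp_c" in records.columns:
        cols["mean_pred_temp"] = ("pred_temp_c", "mean")
    out = (records.groupby("thi_td3d").agg(**cols).reset_index())
    return out[out["n"] >= min_bin].reset_index(drop=True)
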