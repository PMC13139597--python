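"""Temperature-humidity index (THI) computation.

The THI combines dry-bulb temperature and relative humidity into a single
heat-load scalar for livestock.  Hourly THI values are aggregated into daily
means, and test-day heat load is summarised as ``thi_td3d``: the mean daily
THI over a test day and the three preceding days, rounded to the nearest
integer (half away from zero).  The 4-day window captures the lag between the
onset of hot weather and its effect on milk composition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "hourly_thi",
    "daily_mean_thi",
    "thi_window",
    "add_thi_window",
    "round_half_away",
]

#: temperature (deg C) at which THI is insensitive to relative humidity
#: (1.8*T - 26 = 0)
RH_NEUTRAL_TEMP_C = 130.0 / 9.0


def hourly_thi(temp_c, rh_pct):
    """THI from dry-bulb temperature (deg C) and relative humidity (%).

    THI = (1.8*T + 32) - [(0.55 - 0.0055*RH) * (1.8*T - 26)]

    Parameters accept scalars or arrays.  RH outside [0, 100] is rejected,
    not clipped.
    """
    temp_c = np.asarray(temp_c, dtype=float)
    rh_pct = np.asarray(rh_pct, dtype=float)
    if np.any(rh_pct < 0.0) or np.any(rh_pct > 100.0):
        bad = rh_pct[(rh_pct < 0.0) | (rh_pct > 100.0)]
        raise ValueError(
            f"relative humidity must be within [0, 100] %; got {bad.flat[0]!r}"
        )
    f = 1.8 * temp_c + 32.0
    out = f - (0.55 - 0.0055 * rh_pct) * (1.8 * temp_c - 26.0)
    if out.ndim == 0:
        return float(out)
    return out


def round_half_away(x):
    """Round to nearest integer with ties going away from zero."""
    x = np.asarray(x, dtype=float)
    out = np.copysign(np.floor(np.abs(x) + 0.5), x)
    if out.ndim == 0:
        return int(out)
    return out.astype(int)


def daily_mean_thi(hourly: pd.DataFrame, strict: bool = True,
                   min_hours: int = 20) -> pd.DataFrame:
    """Aggregate hourly weather into daily mean THI per station.

    Parameters
    ----------
    hourly
        Columns ``station``, ``timestamp`` (hour resolution), ``temp_c``,
        ``rh_pct``.
    strict
        Require exactly 24 hourly values per station-day.  In lenient mode
        days with at least ``min_hours`` values are averaged and the rest
        dropped.

    Returns
    -------
    DataFrame with columns ``station``, ``date``, ``thi_daily``.
    """
    df = hourly.copy()
    ts = pd.to_datetime(df["timestamp"])
    if df.duplicated(subset=["station", "timestamp"]).any():
        raise ValueError("duplicate station/timestamp rows in hourly weather")
    df["thi"] = hourly_thi(df["temp_c"].to_numpy(), df["rh_pct"].to_numpy())
    df["date"] = ts.dt.date
    grouped = df.groupby(["station", "date"], sort=True)["thi"].agg(["mean", "size"])
    if strict:
        bad = grouped[grouped["size"] != 24]
        if len(bad):
            station, date = bad.index[0]
            raise ValueError(
                f"incomplete day: station {station!r} date {date} has "
                f"{int(bad['size'].iloc[0])} hourly values (24 required); "
                f"{len(bad)} incomplete station-days in total"
            )
    else:
        grouped = grouped[grouped["size"] >= min_hours]
    out = grouped.reset_index()[["station", "date", "mean"]]
    out.columns = ["station", "date", "thi_daily"]
    return out


def thi_window(daily: pd.DataFrame, station, date) -> int:
    """Rounded mean daily THI over ``date`` and the 3 preceding days.

    Raises ``ValueError`` naming any missing day.
    """
    date = pd.Timestamp(date).date()
    sub = daily[daily["station"] == station].set_index("date")["thi_daily"]
    wanted = [date - pd.Timedelta(days=k).to_pytimedelta() for k in (3, 2, 1, 0)]
    missing = [d for d in wanted if d not in sub.index]
    if missing:
        raise ValueError(
            f"missing daily THI for station {station!r} on "
            + ", ".join(str(d) for d in missing)
        )
    vals = np.array([sub.loc[d] for d in wanted], dtype=float)
    return round_half_away(vals.mean())


def add_thi_window(daily: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ``thi_td3d`` for every station-day with 3 predecessors.

    Returns ``daily`` with an added integer column ``thi_td3d``; days whose
    window is incomplete are dropped.
    """
    out = []
    for station, sub in daily.groupby("station", sort=True):
        sub = sub.sort_values("date").reset_index(drop=True)
        n = len(sub)
        if n < 4:
            continue
        dates = pd.to_datetime(sub["date"]).to_numpy()
        vals = sub["thi_daily"].to_numpy()
        win = np.convolve(vals, np.ones(4) / 4.0, mode="valid")  # rows 3..n-1
        # a window is valid only over 4 consecutive calendar days
        span_ok = (dates[3:] - dates[:-3]) == np.timedelta64(3, "D")
        keep = sub.iloc[3:].copy()
        keep["thi_td3d"] = round_half_away(win)
        out.append(keep[span_ok])
    if not out:
        return daily.iloc[0:0].assign(thi_td3d=pd.Series(dtype=int))
    return pd.concat(out, ignore_index=True)
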