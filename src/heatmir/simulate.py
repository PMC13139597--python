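"""Synthetic multi-farm dairy datasets with planted heat-stress effects.

Everything downstream of raw data collection is exercisable on the output of
this module: hourly in-barn weather with seasonal/diurnal structure and
farm-specific heat-wave episodes, a sire-connected pedigree, monthly
test-day records whose protein %, Mg concentration and milk yield are
depressed under heat load, 1,060-point FT-MIR-like spectra carrying a
planted heat-stress signature, and PM/AM udder surface temperatures rising
with heat load.

The planted heat load of a record is

    load = max(0, THI_td3d - threshold) * (1 - tolerance)
           * parity_multiplier * stage_multiplier

with a per-cow tolerance in [0, 1] and susceptibility multipliers that make
older cows and early-lactation cows respond more strongly (the pattern the
population analysis is expected to recover).  Setting the multipliers to 1
and the tolerance spread to 0 recovers the bare
``effect_size * THI excess`` formulation.

Ground-truth columns in the outputs are prefixed ``true_``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from . import thi as thi_mod
from .spectra import N_POINTS
from .testday import lactation_class

__all__ = [
    "HeatWave",
    "SimulationConfig",
    "SimulationDataset",
    "generate_weather",
    "generate_pedigree",
    "generate_cows",
    "generate_testday_records",
    "generate_spectra",
    "generate_surface_temperatures",
    "simulate_dataset",
]


@dataclass(frozen=True)
class HeatWave:
    farm: int
    start: str          # ISO date of the first wave day
    length_days: int
    peak_thi: float     # target daily THI on the middle wave day


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic multi-farm experiment.

    Defaults emulate a 5-farm temperate-climate design: two years of hourly
    in-barn weather, one summer heat wave per farm whose peak coincides with
    a monthly test day, an October thermoneutral control visit, and planted
    trait depressions strongest for protein % and Mg.
    """

    seed: int = 0
    n_farms: int = 5
    n_cows_per_farm: int = 70
    n_years: int = 2
    start_year: int = 2022
    test_day_of_month: int = 15

    # weather structure
    annual_mean_temp_c: float = 10.5
    seasonal_amplitude_c: float = 8.0
    diurnal_amplitude_c: float = 4.0
    temp_noise_sd: float = 0.5
    rh_base_pct: float = 70.0
    rh_temp_slope: float = 1.5       # % RH per deg C above the annual mean
    rh_noise_sd: float = 3.0
    heat_waves: tuple = None         # tuple of HeatWave; None -> default set

    # heat response
    thi_threshold: float = 60.0
    baseline_temp_mean: float = 35.0     # thermoneutral udder temp, deg C
    farm_temp_offsets: tuple = (0.0, 0.1, -0.2, 0.15, 0.3)
    temp_heat_slope: float = 0.25        # deg C per THI unit of heat load
    surface_temp_noise_sd: float = 0.30
    tolerance_mean: float = 0.30
    tolerance_sd: float = 0.15
    lactation_susceptibility: tuple = (0.6, 1.0, 1.4)   # parity class 1/2/3+
    dim_susceptibility: tuple = (0.6, 0.9, 35.0, 55.0)  # base, amp, peak, width
    # trait depression per THI unit of heat load
    trait_effect_sizes: dict = field(default_factory=lambda: {
        "milk_kg": 0.04, "fat_pct": 0.0, "protein_pct": 0.012, "mg_conc": 0.5,
    })

    # spectra
    spectral_noise_sd: float = 0.001
    hs_signature: np.ndarray = None      # None -> default smooth signature
    hs_signature_scale: float = 1.0

    # trait noise / variance structure
    trait_noise_sd: dict = field(default_factory=lambda: {
        "milk_kg": 1.8, "fat_pct": 0.30, "protein_pct": 0.10, "mg_conc": 3.5,
    })
    genetic_sd: dict = field(default_factory=lambda: {
        "milk_kg": 1.5, "fat_pct": 0.25, "protein_pct": 0.12, "mg_conc": 3.0,
    })
    herd_year_sd: dict = field(default_factory=lambda: {
        "milk_kg": 1.0, "fat_pct": 0.15, "protein_pct": 0.08, "mg_conc": 2.0,
    })

    def __post_init__(self):
        for name in ("n_farms", "n_cows_per_farm", "n_years"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("tolerance_sd", "spectral_noise_sd", "temp_noise_sd",
                     "surface_temp_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.heat_waves is None:
            self.heat_waves = self.default_heat_waves()
        self.heat_waves = tuple(self.heat_waves)
        self._check_wave_overlap()
        if self.hs_signature is None:
            self.hs_signature = default_heat_signature() * self.hs_signature_scale
        self.hs_signature = np.asarray(self.hs_signature, dtype=float)
        if self.hs_signature.shape != (N_POINTS,):
            raise ValueError(
                f"hs_signature must have exactly {N_POINTS} points, got "
                f"{self.hs_signature.shape}"
            )

    def default_heat_waves(self) -> tuple:
        """One summer wave per farm, peak day on the monthly test day."""
        year = self.start_year + self.n_years - 1
        waves = []
        for f in range(self.n_farms):
            month = 6 + f % 3
            start = pd.Timestamp(year, month, self.test_day_of_month - 3)
            waves.append(HeatWave(farm=f, start=str(start.date()),
                                  length_days=7, peak_thi=74.0 + f % 3))
        return tuple(waves)

    def _check_wave_overlap(self):
        by_farm = {}
        for w in self.heat_waves:
            s = pd.Timestamp(w.start)
            e = s + pd.Timedelta(days=w.length_days - 1)
            for s2, e2 in by_farm.get(w.farm, []):
                if s <= e2 and s2 <= e:
                    raise ValueError(
                        f"overlapping heat waves for farm {w.farm}: "
                        f"{s.date()}..{e.date()} vs {s2.date()}..{e2.date()}"
                    )
            by_farm.setdefault(w.farm, []).append((s, e))

    def farm_baseline_temp(self, farm: int) -> float:
        off = self.farm_temp_offsets[farm % len(self.farm_temp_offsets)]
        return self.baseline_temp_mean + off

    def child_seed(self, component: str) -> np.random.Generator:
        """Deterministic per-component RNG derived from the master seed."""
        ss = np.random.SeedSequence(
            [self.seed, int.from_bytes(component.encode(), "little") % (2**31)]
        )
        return np.random.default_rng(ss)


# fixed internal RNG stream for the spectral shape library (not a study knob)
_SHAPE_SEED = 20240601


def _smooth_shape(rng: np.random.Generator, n_bumps: int,
                  amp: float = 1.0, widths=(15.0, 80.0)) -> np.ndarray:
    grid = np.arange(1, N_POINTS + 1, dtype=float)
    out = np.zeros(N_POINTS)
    for _ in range(n_bumps):
        center = rng.uniform(10, N_POINTS - 10)
        width = rng.uniform(*widths)
        out += rng.normal(0, amp) * np.exp(-0.5 * ((grid - center) / width) ** 2)
    return out


def spectral_shapes() -> dict:
    """Fixed baseline and per-component signature shapes (length 1,060).

    The baseline is broad; absorption-band signatures use narrower bumps so
    they survive the gap-5 derivative like real MIR bands do.
    """
    rng = np.random.default_rng(_SHAPE_SEED)
    return {
        "baseline": 0.5 + 0.2 * _smooth_shape(rng, 12),
        "fat": _smooth_shape(rng, 8, widths=(8.0, 40.0)),
        "protein": _smooth_shape(rng, 8, widths=(8.0, 40.0)),
        "mg": _smooth_shape(rng, 8, widths=(8.0, 40.0)),
    }


def default_heat_signature() -> np.ndarray:
    """Planted heat-stress perturbation per unit heat load (absorbance)."""
    rng = np.random.default_rng(_SHAPE_SEED + 1)
    sig = _smooth_shape(rng, 10, amp=1.0, widths=(6.0, 25.0))
    peak = np.max(np.abs(sig))
    return 0.003 * sig / peak


# ---------------------------------------------------------------------------
# weather
# ---------------------------------------------------------------------------

def _deterministic_temp(cfg: SimulationConfig, farm: int,
                        hours: pd.DatetimeIndex) -> np.ndarray:
    doy = hours.dayofyear.to_numpy(dtype=float)
    hod = hours.hour.to_numpy(dtype=float)
    seasonal = cfg.seasonal_amplitude_c * np.cos(
        2 * np.pi * (doy - 200.0) / 365.25
    )
    diurnal = cfg.diurnal_amplitude_c * np.cos(2 * np.pi * (hod - 15.0) / 24.0)
    return cfg.annual_mean_temp_c + seasonal + diurnal + 0.2 * farm


def _rh_from_temp(cfg: SimulationConfig, temp: np.ndarray) -> np.ndarray:
    rh = cfg.rh_base_pct - cfg.rh_temp_slope * (temp - cfg.annual_mean_temp_c)
    return np.clip(rh, 5.0, 100.0)


def _wave_envelope(wave: HeatWave, dates: np.ndarray) -> np.ndarray:
    """Triangular day-level envelope, 1.0 at the middle wave day."""
    start = np.datetime64(pd.Timestamp(wave.start).date())
    day = (dates - start).astype("timedelta64[D]").astype(int)
    mid = (wave.length_days - 1) // 2
    half = max(mid, wave.length_days - 1 - mid, 1)
    env = 1.0 - np.abs(day - mid) / (half + 1.0)
    env[(day < 0) | (day >= wave.length_days)] = 0.0
    return np.clip(env, 0.0, 1.0)


def _calibrate_wave_amplitude(cfg: SimulationConfig, farm: int,
                              wave: HeatWave) -> float:
    """Temperature bump (deg C) whose peak-day daily-mean THI hits the target."""
    mid = pd.Timestamp(wave.start) + pd.Timedelta(days=(wave.length_days - 1) // 2)
    hours = pd.date_range(mid, periods=24, freq="h")
    t0 = _deterministic_temp(cfg, farm, hours)

    def daily_thi_gap(amp):
        t = t0 + amp
        rh = _rh_from_temp(cfg, t)
        return float(np.mean(thi_mod.hourly_thi(t, rh))) - wave.peak_thi

    return brentq(daily_thi_gap, -40.0, 60.0, xtol=1e-10)


def generate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Hourly weather per farm: ``station, timestamp, temp_c, rh_pct``.

    Coverage starts 4 days before 1 January of the first year so every
    test day has a complete 4-day THI window.
    """
    start = pd.Timestamp(config.start_year, 1, 1) - pd.Timedelta(days=4)
    end = pd.Timestamp(config.start_year + config.n_years - 1, 12, 31, 23)
    hours = pd.date_range(start, end, freq="h")
    dates = hours.normalize().to_numpy().astype("datetime64[D]")
    rng = config.child_seed("weather")
    frames = []
    for farm in range(config.n_farms):
        t_det = _deterministic_temp(config, farm, hours)
        for wave in config.heat_waves:
            if wave.farm != farm:
                continue
            amp = _calibrate_wave_amplitude(config, farm, wave)
            t_det = t_det + amp * _wave_envelope(wave, dates)
        rh_det = _rh_from_temp(config, t_det)
        temp = t_det + rng.normal(0.0, config.temp_noise_sd, len(hours))
        rh = np.clip(rh_det + rng.normal(0.0, config.rh_noise_sd, len(hours)),
                     5.0, 100.0)
        frames.append(pd.DataFrame({
            "station": farm, "timestamp": hours, "temp_c": temp, "rh_pct": rh,
        }))
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# pedigree and cows
# ---------------------------------------------------------------------------

def generate_pedigree(config: SimulationConfig, cows: pd.DataFrame) -> pd.DataFrame:
    """Pedigree table ``animal, sire, dam`` (0 = unknown), parents first.

    Sires are founders assigned round-robin across all cows, so every sire
    with >= 2 daughters connects herds.
    """
    sires = sorted(cows["sire"].unique())
    rows = [{"animal": s, "sire": 0, "dam": 0} for s in sires]
    rows += [{"animal": a, "sire": s, "dam": 0}
             for a, s in zip(cows["animal"], cows["sire"])]
    return pd.DataFrame(rows)


def generate_cows(config: SimulationConfig) -> pd.DataFrame:
    """Cow profiles: farm, sire, parity origin, calving schedule, tolerance,
    genetic merit per trait."""
    rng = config.child_seed("cows")
    n_total = config.n_farms * config.n_cows_per_farm
    n_sires = max(2, n_total // 15)
    traits = list(config.genetic_sd)
    sire_bv = {t: rng.normal(0, config.genetic_sd[t], n_sires) for t in traits}
    rows = []
    idx = 0
    for farm in range(config.n_farms):
        for _ in range(config.n_cows_per_farm):
            sire = idx % n_sires
            row = {
                "animal": f"F{farm}C{idx:04d}",
                "farm": farm,
                "sire": f"S{sire:03d}",
                "parity0": int(rng.integers(1, 5)),
                "calving_month": int(rng.integers(1, 13)),
                "calving_day": int(rng.integers(1, 29)),
                "tolerance": float(np.clip(
                    rng.normal(config.tolerance_mean, config.tolerance_sd),
                    0.0, 1.0)),
            }
            for t in traits:
                row[f"bv_{t}"] = (sire_bv[t][sire] / 2.0
                                  + rng.normal(0, config.genetic_sd[t]
                                               * np.sqrt(0.75)))
                row[f"pe_{t}"] = rng.normal(0, 0.8 * config.genetic_sd[t])
            rows.append(row)
            idx += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# test-day records
# ---------------------------------------------------------------------------

_WILMINK = {
    # trait -> (a, b, c): a + b*exp(-0.05*DIM) + c*DIM
    "milk_kg": (35.0, -14.0, -0.025),
    "fat_pct": (3.9, 0.9, 0.0015),
    "protein_pct": (3.2, 0.7, 0.0012),
    "mg_conc": (100.0, 8.0, 0.01),
}

_PARITY_SHIFT = {"milk_kg": (0.0, 2.5, 4.0), "fat_pct": (0.0, 0.05, 0.1),
                 "protein_pct": (0.0, 0.03, 0.05), "mg_conc": (0.0, 0.5, 1.0)}


def _stage_multiplier(cfg: SimulationConfig, dim):
    base, amp, peak, width = cfg.dim_susceptibility
    dim = np.asarray(dim, dtype=float)
    return base + amp * np.exp(-0.5 * ((dim - peak) / width) ** 2)


def heat_load(cfg: SimulationConfig, thi_td3d, tolerance, lactation, dim):
    """Planted heat load: THI excess x (1 - tolerance) x susceptibility."""
    excess = np.maximum(0.0, np.asarray(thi_td3d, dtype=float) - cfg.thi_threshold)
    lclass = np.asarray(lactation_class(lactation))
    lmult = np.asarray(cfg.lactation_susceptibility)[lclass - 1]
    return excess * (1.0 - np.asarray(tolerance)) * lmult * _stage_multiplier(cfg, dim)


def _thi_windows(config: SimulationConfig, weather: pd.DataFrame) -> pd.DataFrame:
    daily = thi_mod.daily_mean_thi(weather, strict=True)
    return thi_mod.add_thi_window(daily)


def generate_testday_records(cows: pd.DataFrame, weather: pd.DataFrame,
                             config: SimulationConfig) -> pd.DataFrame:
    """Monthly test-day records with planted heat depressions.

    trait = lactation curve + parity shift + herd-year + genetic + permanent
    environment - effect_size x heat_load + noise, with the milk-yield
    depression scaled by the cow's production level.
    """
    rng = config.child_seed("testday")
    windows = _thi_windows(config, weather)
    thi_lookup = {(s, d): t for s, d, t in
                  zip(windows["station"], windows["date"], windows["thi_td3d"])}
    hy_effect = {}
    for farm in range(config.n_farms):
        for year in range(config.start_year, config.start_year + config.n_years):
            hy_effect[(farm, year)] = {
                t: rng.normal(0, sd) for t, sd in config.herd_year_sd.items()
            }
    traits = list(_WILMINK)
    rows = []
    for cow in cows.itertuples(index=False):
        for yr_idx in range(config.n_years):
            year = config.start_year + yr_idx
            calving = pd.Timestamp(year, cow.calving_month, cow.calving_day)
            lact_no = cow.parity0 + yr_idx
            for m_off in range(1, 14):
                td = (calving + pd.DateOffset(months=m_off)).replace(
                    day=config.test_day_of_month)
                dim = (td - calving).days
                if dim < 5 or dim > 365:
                    continue
                key = (cow.farm, td.date())
                if key not in thi_lookup:
                    if td.year >= config.start_year + config.n_years:
                        continue
                    raise ValueError(f"missing weather for farm {cow.farm} "
                                     f"on {td.date()}")
                thi = thi_lookup[key]
                load = float(heat_load(config, thi, cow.tolerance,
                                       lact_no, dim))
                lclass = lactation_class(lact_no)
                row = {
                    "sample_id": f"{cow.animal}_{td.date()}",
                    "animal": cow.animal, "herd": cow.farm,
                    "date": td.date(), "lactation": lact_no, "dim": dim,
                    "thi_td3d": thi, "true_heat_load": load,
                    "true_tolerance": cow.tolerance,
                }
                for t in traits:
                    a, b, c = _WILMINK[t]
                    base = a + b * np.exp(-0.05 * dim) + c * dim
                    base += _PARITY_SHIFT[t][lclass - 1]
                    base += hy_effect[(cow.farm, year)][t]
                    base += getattr(cow, f"bv_{t}") + getattr(cow, f"pe_{t}")
                    eff = config.trait_effect_sizes.get(t, 0.0)
                    if t == "milk_kg":
                        eff = eff * base / 30.0
                    base -= eff * load
                    base += rng.normal(0, config.trait_noise_sd[t])
                    row[t] = base
                rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(["herd", "animal", "date"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------

def generate_spectra(records: pd.DataFrame,
                     config: SimulationConfig) -> pd.DataFrame:
    """1,060-point spectra as linear mixtures of composition + heat signature.

    spectrum = baseline + sig_fat*(fat - 4.2) + sig_protein*(protein - 3.4)
               + sig_mg*(Mg - 100) + hs_signature*heat_load + noise
    """
    rng = config.child_seed("spectra")
    shapes = spectral_shapes()
    n = len(records)
    fat = records["fat_pct"].to_numpy(float) - 4.2
    prot = records["protein_pct"].to_numpy(float) - 3.4
    mg = records["mg_conc"].to_numpy(float) - 100.0
    load = records["true_heat_load"].to_numpy(float)
    spec = (shapes["baseline"][None, :]
            + 0.02 * np.outer(fat, shapes["fat"])
            + 0.03 * np.outer(prot, shapes["protein"])
            + 0.0005 * np.outer(mg, shapes["mg"])
            + np.outer(load, config.hs_signature))
    spec += rng.normal(0.0, config.spectral_noise_sd, spec.shape)
    cols = np.arange(1, N_POINTS + 1)
    return pd.DataFrame(spec, index=pd.Index(records["sample_id"],
                                             name="sample_id"), columns=cols)


# ---------------------------------------------------------------------------
# surface temperatures
# ---------------------------------------------------------------------------

def _farm_visits(config: SimulationConfig) -> pd.DataFrame:
    """Two visits per farm: the peak day of its first heat wave and an
    October thermoneutral day of the same year."""
    rows = []
    seen = set()
    for w in config.heat_waves:
        if w.farm in seen:
            continue
        seen.add(w.farm)
        peak = (pd.Timestamp(w.start)
                + pd.Timedelta(days=(w.length_days - 1) // 2))
        rows.append({"farm": w.farm, "date": peak.date(),
                     "period": "heat_wave"})
        ctrl = pd.Timestamp(peak.year, 10, config.test_day_of_month)
        rows.append({"farm": w.farm, "date": ctrl.date(),
                     "period": "thermoneutral"})
    return pd.DataFrame(rows)


def generate_surface_temperatures(cows: pd.DataFrame, weather: pd.DataFrame,
                                  records: pd.DataFrame,
                                  config: SimulationConfig,
                                  visits: pd.DataFrame | None = None
                                  ) -> pd.DataFrame:
    """PM/AM udder surface temperatures for every cow milked on a visit day.

    PM uses the 17:00 hourly THI of the visit day, AM the (cooler) 06:00 THI
    of the next morning; the stored ``mean_temp`` is their average, matching
    the one-record-per-cow-visit convention of the reference data.
    """
    if visits is None:
        visits = _farm_visits(config)
    rng = config.child_seed("surface")
    w = weather.copy()
    w["key"] = list(zip(w["station"], pd.to_datetime(w["timestamp"])))
    thi_hour = dict(zip(w["key"], thi_mod.hourly_thi(
        w["temp_c"].to_numpy(), w["rh_pct"].to_numpy())))
    cow_info = cows.set_index("animal")
    rows = []
    for visit in visits.itertuples(index=False):
        day_rec = records[(records["herd"] == visit.farm)
                          & (records["date"] == visit.date)]
        base = config.farm_baseline_temp(visit.farm)
        pm_key = (visit.farm, pd.Timestamp(visit.date) + pd.Timedelta(hours=17))
        am_key = (visit.farm, pd.Timestamp(visit.date)
                  + pd.Timedelta(days=1, hours=6))
        if pm_key not in thi_hour or am_key not in thi_hour:
            raise ValueError(
                f"missing hourly weather for farm {visit.farm} around "
                f"{visit.date}"
            )
        for rec in day_rec.itertuples(index=False):
            tol = cow_info.loc[rec.animal, "tolerance"]
            temps = {}
            for tag, key in (("pm", pm_key), ("am", am_key)):
                load = float(heat_load(config, thi_hour[key], tol,
                                       rec.lactation, rec.dim))
                temps[tag] = (base + config.temp_heat_slope * load
                              + rng.normal(0, config.surface_temp_noise_sd))
            rows.append({
                "sample_id": rec.sample_id, "cow": rec.animal,
                "farm": visit.farm, "date": visit.date,
                "period": visit.period,
                "pm_temp": temps["pm"], "am_temp": temps["am"],
                "mean_temp": 0.5 * (temps["pm"] + temps["am"]),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class SimulationDataset:
    config: SimulationConfig
    weather: pd.DataFrame
    cows: pd.DataFrame
    pedigree: pd.DataFrame
    testday: pd.DataFrame
    spectra: pd.DataFrame
    surface_temps: pd.DataFrame


def simulate_dataset(config: SimulationConfig) -> SimulationDataset:
    """Run the full generator chain for one configuration."""
    weather = generate_weather(config)
    cows = generate_cows(config)
    pedigree = generate_pedigree(config, cows)
    testday = generate_testday_records(cows, weather, config)
    spectra = generate_spectra(testday, config)
    surface = generate_surface_temperatures(cows, weather, testday, config)
    return SimulationDataset(config=config, weather=weather, cows=cows,
                             pedigree=pedigree, testday=testday,
                             spectra=spectra, surface_temps=surface)
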