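"""Synthetic-data generator: determinism, planted effects, invariants."""

import numpy as np
import pandas as pd
import pytest

from heatmir import thi as thi_mod
from heatmir.simulate import (HeatWave, SimulationConfig, generate_cows,
                              generate_pedigree, generate_spectra,
                              generate_surface_temperatures,
                              generate_testday_records, generate_weather,
                              heat_load, simulate_dataset)
from heatmir.spectra import N_POINTS


def small_cfg(**kw):
    base = dict(seed=3, n_farms=2, n_cows_per_farm=10, n_years=1)
    base.update(kw)
    return SimulationConfig(**base)


NEUTRAL = dict(tolerance_sd=0.0, tolerance_mean=0.0,
               lactation_susceptibility=(1.0, 1.0, 1.0),
               dim_susceptibility=(1.0, 0.0, 35.0, 55.0))


class TestConfig:
    def test_counts_validated(self):
        with pytest.raises(ValueError, match="n_farms"):
            small_cfg(n_farms=0)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValueError, match="spectral_noise_sd"):
            small_cfg(spectral_noise_sd=-0.1)

    def test_overlapping_heat_waves_rejected(self):
        waves = (HeatWave(0, "2022-06-10", 7, 74.0),
                 HeatWave(0, "2022-06-14", 5, 75.0))
        with pytest.raises(ValueError, match="overlap"):
            small_cfg(heat_waves=waves)

    def test_wrong_signature_length_rejected(self):
        with pytest.raises(ValueError, match="1060"):
            small_cfg(hs_signature=np.zeros(100))


class TestWeather:
    def test_record_count_is_hours_times_farms(self):
        cfg = small_cfg()
        w = generate_weather(cfg)
        hours_per_farm = (365 + 4) * 24
        assert len(w) == cfg.n_farms * hours_per_farm
        assert w.groupby("station").size().nunique() == 1

    def test_degenerate_config_gives_constant_temperature(self):
        cfg = small_cfg(seasonal_amplitude_c=0.0, diurnal_amplitude_c=0.0,
                        temp_noise_sd=0.0, heat_waves=())
        w = generate_weather(cfg)
        per_farm = w.groupby("station")["temp_c"].nunique()
        assert (per_farm == 1).all()

    def test_rh_within_physical_bounds(self):
        w = generate_weather(small_cfg())
        assert w["rh_pct"].between(5.0, 100.0).all()

    def test_planted_wave_peak_daily_thi_recovered(self):
        """Closed loop: the daily THI recomputed by the THI module on the
        planted peak day lands within 1 unit of the configured target."""
        cfg = small_cfg(n_farms=1,
                        heat_waves=(HeatWave(0, "2022-07-12", 7, 75.0),))
        daily = thi_mod.daily_mean_thi(generate_weather(cfg))
        peak_day = pd.Timestamp("2022-07-15").date()
        got = daily.loc[daily["date"] == peak_day, "thi_daily"].iloc[0]
        assert got == pytest.approx(75.0, abs=1.0)


class TestPedigree:
    def test_single_cow_has_founder_parents(self):
        cfg = SimulationConfig(seed=1, n_farms=1, n_cows_per_farm=1, n_years=1)
        cows = generate_cows(cfg)
        ped = generate_pedigree(cfg, cows)
        founders = ped[(ped["sire"] == 0) & (ped["dam"] == 0)]
        assert len(founders) >= 1

    def test_topological_order(self, ref_dataset):
        seen = set()
        for a, s, d in ref_dataset.pedigree[["animal", "sire", "dam"]
                                            ].itertuples(index=False):
            for p in (s, d):
                assert p == 0 or p in seen
            seen.add(a)

    def test_sires_connect_farms(self, ref_dataset):
        cows = ref_dataset.cows
        farms_per_sire = cows.groupby("sire")["farm"].nunique()
        assert (farms_per_sire >= 2).any()


class TestTestdayRecords:
    def test_heat_term_formula_via_paired_configs(self):
        """With identical seeds, records of an effect-free run differ from an
        effect-e run by exactly effect x THI excess (tolerance 0)."""
        cfg0 = small_cfg(trait_effect_sizes={"protein_pct": 0.0},
                         **NEUTRAL)
        cfg1 = small_cfg(trait_effect_sizes={"protein_pct": 0.02},
                         **NEUTRAL)
        w = generate_weather(cfg0)
        cows = generate_cows(cfg0)
        r0 = generate_testday_records(cows, w, cfg0)
        r1 = generate_testday_records(cows, generate_weather(cfg1), cfg1)
        diff = r0["protein_pct"] - r1["protein_pct"]
        excess = np.maximum(0.0, r0["thi_td3d"] - cfg0.thi_threshold)
        assert np.allclose(diff, 0.02 * excess, atol=1e-9)
        hot = excess > 0
        assert hot.any() and np.allclose(diff[~hot], 0.0)

    def test_heat_load_formula_direct(self):
        cfg = small_cfg(**NEUTRAL)
        assert heat_load(cfg, cfg.thi_threshold + 10, 0.0, 1, 100) \
            == pytest.approx(10.0)
        assert heat_load(cfg, cfg.thi_threshold - 1, 0.0, 1, 100) == 0.0
        assert heat_load(cfg, cfg.thi_threshold + 10, 0.25, 1, 100) \
            == pytest.approx(7.5)

    def test_all_dim_at_least_five(self, ref_dataset):
        assert (ref_dataset.testday["dim"] >= 5).all()

    def test_missing_weather_names_date(self):
        cfg = small_cfg()
        w = generate_weather(cfg)
        w = w[pd.to_datetime(w["timestamp"]) < "2022-06-01"]
        cows = generate_cows(cfg)
        with pytest.raises(ValueError, match=r"\d{4}-\d{2}-\d{2}"):
            generate_testday_records(cows, w, cfg)

    def test_planted_depression_recovered_in_group_means(self, ref_dataset):
        """Heat-wave minus thermoneutral protein means recover the planted
        depression within 3 Monte-Carlo standard errors."""
        td = ref_dataset.testday
        cfg = ref_dataset.config
        hot = td[td["true_heat_load"] > 0]
        cool = td[td["true_heat_load"] == 0]
        # compare each hot record to the same cow's cool records (removes
        # cow-level effects); remaining curve/herd-year noise enters the SE
        cool_mean = cool.groupby("animal")["protein_pct"].mean()
        paired = hot.join(cool_mean.rename("cool"), on="animal")
        delta = paired["protein_pct"] - paired["cool"]
        planted = -cfg.trait_effect_sizes["protein_pct"] * \
            paired["true_heat_load"]
        gap = delta - planted
        se = gap.std() / np.sqrt(len(gap))
        assert abs(gap.mean()) < 3 * se + 0.05  # 0.05: curve/season imbalance


class TestSpectra:
    def test_exactly_1060_points(self, ref_dataset):
        assert ref_dataset.spectra.shape[1] == N_POINTS

    def test_zero_noise_equal_composition_identical_spectra(self):
        cfg = small_cfg(spectral_noise_sd=0.0)
        rec = pd.DataFrame({
            "sample_id": ["r1", "r2"], "fat_pct": 4.0, "protein_pct": 3.3,
            "mg_conc": 101.0, "true_heat_load": 0.0,
        })
        spec = generate_spectra(rec, cfg)
        assert np.array_equal(spec.iloc[0].to_numpy(), spec.iloc[1].to_numpy())

    def test_spectrum_linear_in_protein(self):
        cfg = small_cfg(spectral_noise_sd=0.0)
        rec = pd.DataFrame({
            "sample_id": ["lo", "hi", "hi2"], "fat_pct": 4.0,
            "protein_pct": [3.0, 3.5, 4.0], "mg_conc": 100.0,
            "true_heat_load": 0.0,
        })
        spec = generate_spectra(rec, cfg)
        d1 = spec.iloc[1] - spec.iloc[0]
        d2 = spec.iloc[2] - spec.iloc[0]
        assert np.allclose(d2, 2 * d1, atol=1e-12)

    def test_affected_minus_unaffected_proportional_to_signature(self):
        cfg = small_cfg(spectral_noise_sd=0.0005)
        rng = np.random.default_rng(0)
        n = 400
        rec = pd.DataFrame({
            "sample_id": [f"r{i}" for i in range(n)],
            "fat_pct": rng.normal(4.2, 0.3, n),
            "protein_pct": rng.normal(3.4, 0.15, n),
            "mg_conc": rng.normal(100, 4, n),
            "true_heat_load": np.r_[np.zeros(n // 2),
                                    np.full(n - n // 2, 8.0)],
        })
        spec = generate_spectra(rec, cfg)
        diff = (spec.iloc[n // 2:].mean() - spec.iloc[: n // 2].mean()
                ).to_numpy()
        sig = cfg.hs_signature
        slope = (diff @ sig) / (sig @ sig)
        assert slope == pytest.approx(8.0, rel=0.15)
        assert slope > 0


class TestSurfaceTemps:
    def test_mean_is_average_of_pm_and_am(self, ref_dataset):
        st = ref_dataset.surface_temps
        assert np.allclose(st["mean_temp"],
                           0.5 * (st["pm_temp"] + st["am_temp"]))

    def test_zero_slope_zero_noise_gives_farm_baseline(self):
        cfg = small_cfg(temp_heat_slope=0.0, surface_temp_noise_sd=0.0)
        w = generate_weather(cfg)
        cows = generate_cows(cfg)
        rec = generate_testday_records(cows, w, cfg)
        st = generate_surface_temperatures(cows, w, rec, cfg)
        for farm, sub in st.groupby("farm"):
            assert np.allclose(sub["mean_temp"],
                               cfg.farm_baseline_temp(farm))

    def test_heat_wave_hotter_than_thermoneutral_every_farm(self, ref_dataset):
        st = ref_dataset.surface_temps
        means = st.groupby(["farm", "period"])["mean_temp"].mean().unstack()
        assert (means["heat_wave"] > means["thermoneutral"]).all()


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        a = simulate_dataset(small_cfg())
        b = simulate_dataset(small_cfg())
        for name in ("weather", "cows", "pedigree", "testday", "spectra",
                     "surface_temps"):
            pd.testing.assert_frame_equal(getattr(a, name), getattr(b, name))

    def test_different_seed_differs(self):
        a = simulate_dataset(small_cfg(seed=3))
        b = simulate_dataset(small_cfg(seed=4))
        assert (len(a.testday) != len(b.testday)
                or not np.allclose(a.testday["protein_pct"],
                                   b.testday["protein_pct"]))
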