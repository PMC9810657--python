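"""Tests for the synthetic campaign generator and its truth ledger."""

import numpy as np
import pandas as pd
import pytest

from coastalghg import equilibrator_qc as eq
from coastalghg import gas_physics as gp
from coastalghg import synthetic_data as sd
from coastalghg.exceptions import ConfigurationError


def quiet_config(**overrides):
    """A deterministic scenario: no diel signal, no noise, no lag."""
    defaults = dict(
        pco2_diel_amplitude_uatm=0.0, pco2_noise_uatm=0.0, ch4_noise_frac=0.0,
        twater_diel_amplitude_c=0.0, lag_tau_s=0.0,
        noise_co2_ppm=0.0, noise_ch4_ppm=0.0,
        wind_constant_ms=4.0,
        salinity_range=(6.8, 6.8), seed=0,
    )
    defaults.update(overrides)
    return sd.preset_config("macroalgae-summer", **defaults)


class TestSimulateTruth:
    def test_seeded_determinism(self):
        cfg = sd.preset_config("macroalgae-summer", seed=9)
        t1 = sd.simulate_truth(cfg)
        t2 = sd.simulate_truth(cfg)
        pd.testing.assert_frame_equal(t1.truth, t2.truth)
        pd.testing.assert_frame_equal(t1.environment, t2.environment)
        s1 = sd.render_stream(t1)
        s2 = sd.render_stream(t2)
        pd.testing.assert_frame_equal(s1.records, s2.records)
        assert np.array_equal(s1.contaminated, s2.contaminated)

    def test_quiet_scenario_daily_equals_instantaneous(self):
        truth = sd.simulate_truth(quiet_config())
        for col, gas in (("flux_ch4", "CH4"), ("flux_co2", "CO2")):
            inst = truth.truth[col]
            assert inst.std() / max(abs(inst.mean()), 1e-12) < 1e-6
            daily = truth.daily.set_index("gas").loc[gas, "true_flux"]
            assert daily == pytest.approx(inst.iloc[0], rel=1e-6)

    def test_ledger_fluxes_satisfy_bulk_equation_exactly(self, ch4):
        truth = sd.simulate_truth(sd.preset_config("mixed_vegetation-fall", seed=3)).truth
        again = gp.sea_air_flux(
            ch4, truth["k_ch4_ms"].to_numpy(), truth["K0_ch4"].to_numpy(),
            truth["p_ch4_sea_uatm"].to_numpy(), truth["p_ch4_air_uatm"].to_numpy(),
        )
        assert np.array_equal(again, truth["flux_ch4"].to_numpy())

    def test_trapezoid_conservation(self):
        cfg = sd.preset_config("bare_sediment-summer", seed=6, n_days=2)
        truth = sd.simulate_truth(cfg)
        t = truth.truth.set_index("timestamp")
        for day in range(2):
            lo = t.index[0] + pd.Timedelta(days=day)
            seg = t.loc[lo : lo + pd.Timedelta(days=1)]
            trap = np.trapezoid(seg["flux_ch4"].to_numpy()) / (len(seg) - 1)
            ledger = truth.daily.set_index(["date", "gas"]).loc[(lo.date(), "CH4"), "true_flux"]
            assert trap == pytest.approx(ledger, rel=1e-9)

    def test_ch4_persistently_supersaturated(self):
        for preset in ("macroalgae-summer", "mixed_vegetation-winter"):
            truth = sd.simulate_truth(sd.preset_config(preset, seed=1)).truth
            assert (truth["p_ch4_sea_uatm"] > truth["p_ch4_air_uatm"]).all()
            assert (truth["flux_ch4"] > 0).all()

    def test_salinity_in_brackish_band(self):
        truth = sd.simulate_truth(sd.preset_config("macroalgae-spring", seed=4))
        assert 6.6 <= truth.salinity <= 7.0

    def test_afternoon_pco2_minimum(self):
        cfg = sd.preset_config("macroalgae-summer", seed=0, pco2_noise_uatm=0.0)
        truth = sd.simulate_truth(cfg).truth.set_index("timestamp")
        argmin = truth["p_co2_sea_uatm"].idxmin()
        assert 13 <= argmin.hour <= 17

    def test_invalid_config_names_offending_keys(self):
        with pytest.raises(ConfigurationError, match="zu_m"):
            sd.ScenarioConfig(zu_m=-1.0)
        with pytest.raises(ConfigurationError, match="unknown preset"):
            sd.preset_config("kelp-forest-summer")


class TestRenderStream:
    def test_zero_lag_zero_noise_records_equal_truth(self):
        cfg = quiet_config()
        truth = sd.simulate_truth(cfg)
        stream = sd.render_stream(truth)
        water = stream.records[stream.records["phase"] == "water"]
        expected = truth.truth.set_index("timestamp")["p_ch4_sea_uatm"] / cfg.pressure_atm
        # compare at exact minute marks to avoid interpolation between rows
        on_minute = water[water["timestamp"].dt.second == 0]
        got = on_minute.set_index("timestamp")["xch4_ppm"]
        ref = expected.loc[got.index]
        assert np.allclose(got.to_numpy(), ref.to_numpy(), rtol=1e-12)

    def test_first_order_relaxation_after_phase_switch(self):
        tau = 60.0
        cfg = quiet_config(lag_tau_s=tau)
        truth = sd.simulate_truth(cfg)
        stream = sd.render_stream(truth)
        rec = stream.records
        # first air window starts 35 min in; the signal relaxes from the
        # water value toward the air value exponentially
        switch = rec["timestamp"].iloc[0] + pd.Timedelta(minutes=35)
        air = rec[(rec["timestamp"] >= switch)
                  & (rec["timestamp"] < switch + pd.Timedelta(minutes=10))]
        x_air = cfg.xch4_air_ppm
        x_water = rec[rec["timestamp"] < switch]["xch4_ppm"].iloc[-1]
        dt = (air["timestamp"] - switch).dt.total_seconds().to_numpy() + cfg.record_period_s
        expected = x_air + (x_water - x_air) * np.exp(-dt / tau)
        assert np.allclose(air["xch4_ppm"].to_numpy(), expected, rtol=1e-6)
        # discrepancy below 1 % of the jump after five time constants
        late = dt >= 5 * tau
        jump = abs(x_water - x_air)
        assert (np.abs(air["xch4_ppm"].to_numpy()[late] - x_air) < 0.01 * jump).all()

    def test_contaminated_records_confined_to_switch_heads(self):
        cfg = sd.preset_config("macroalgae-summer", seed=5)
        stream = sd.render_stream(sd.simulate_truth(cfg))
        t0 = stream.records["timestamp"].iloc[0]
        since = (stream.records["timestamp"] - t0).dt.total_seconds() % 2700.0
        since = np.where(since < 2100, since, since - 2100)
        assert (since[stream.contaminated] < 2 * cfg.lag_tau_s).all()

    def test_csv_roundtrip_lossless(self, tmp_path):
        cfg = sd.preset_config("bare_sediment-winter", seed=2)
        paths = sd.write_campaign(cfg, tmp_path)
        gas_df, env_df, truth, stream = sd.generate_campaign(cfg)
        read_back = eq.read_gas_csv(paths["gas"])
        pd.testing.assert_frame_equal(read_back, stream.records, check_exact=False, rtol=1e-12)
        env_back = eq.read_env_csv(paths["env"])
        pd.testing.assert_frame_equal(env_back, env_df, check_exact=False, rtol=1e-12)


class TestRecovery:
    def test_pipeline_recovers_daily_truth(self):
        out = sd.recovery_experiment("macroalgae-summer", n_replicates=10, seed=21)
        assert out["within_2se"].mean() >= 0.9
        for gas, sub in out.groupby("gas"):
            se = sub["error"].std(ddof=1) / np.sqrt(len(sub))
            assert abs(sub["error"].mean()) <= 3 * se + 1e-12
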