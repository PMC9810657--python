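"""Synthetic equilibrator campaigns with a ground-truth ledger.

Generates complete, seeded campaigns for a shallow brackish coastal
site: environmental forcing (AR(1)-persistent Weibull wind, diel water
temperature, constant salinity drawn from the brackish 6.6-7.0 PSU
band), true dissolved-gas fields (a diel pCO2 cycle whose
undersaturation peaks in the 13:00-17:00 afternoon window, persistent
CH4 supersaturation at tens of nmol L^-1), and the raw analyzer stream
that an equilibrator/CRDS loop would log: 45-minute cycles of 35 min
water + 10 min air, 10-s records, first-order response lag after every
phase switch, and additive instrument noise.

Every stochastic draw flows from one seeded generator, so a fixed seed
reproduces the campaign byte for byte.  The truth ledger records the
per-minute partial pressures, solubilities, transfer velocities and
instantaneous fluxes (computed with the same bulk formulation the
pipeline uses, so ledger fluxes satisfy the flux equation exactly),
the per-day true net fluxes, the cycle boundaries, and the set of
lag-contaminated records — which makes every pipeline stage testable
without any field data.

Presets encode per-habitat, per-season parameter sets whose daily net
fluxes land inside the magnitudes reported for Baltic coastal
macroalgae, mixed vegetation and bare sediment habitats (CH4 roughly
0.1-2.9 mg m^-2 d^-1; CO2 roughly -763 to +390 mg m^-2 d^-1); they are
calibration envelopes, not fitted distributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats

from . import equilibrator_qc, gas_physics
from .constants import CONSTANTS, get_gas
from .exceptions import ConfigurationError

__all__ = [
    "ScenarioConfig",
    "CampaignTruth",
    "RenderedStream",
    "PRESETS",
    "preset_config",
    "simulate_truth",
    "render_stream",
    "generate_campaign",
    "write_campaign",
    "recovery_experiment",
]


@dataclass(frozen=True)
class ScenarioConfig:
    """All knobs of one synthetic campaign.

    Units: partial pressures in uatm, mole fractions in ppm, dissolved
    CH4 in nmol L^-1, temperatures in degC, wind in m s^-1, times in the
    unit named by the field.  ``pco2_min_hour`` places the diel pCO2
    minimum (peak CO2 uptake) within the afternoon window.
    """

    habitat_id: str = "macroalgae"
    season: str = "summer"
    n_days: int = 1
    seed: int = 0
    start: str = "2020-07-06"
    # true dissolved-gas fields
    pco2_sea_mean_uatm: float = 270.0
    pco2_diel_amplitude_uatm: float = 150.0
    pco2_min_hour: float = 15.0
    pco2_noise_uatm: float = 5.0
    pco2_noise_persistence_min: float = 30.0
    ch4_nmol_l: float = 53.0
    ch4_noise_frac: float = 0.02
    xco2_air_ppm: float = 418.0
    xch4_air_ppm: float = 1.95
    # environmental forcing
    twater_mean_c: float = 17.0
    twater_diel_amplitude_c: float = 1.0
    twater_max_hour: float = 16.0
    salinity_range: tuple[float, float] = (6.6, 7.0)
    wind_weibull_shape: float = 2.0
    wind_weibull_scale: float = 4.0
    wind_persistence_min: float = 60.0
    wind_constant_ms: float | None = None  # bypass stochastic wind entirely
    drag_coefficient: float = 1.3e-3
    zu_m: float = 1.5
    pressure_atm: float = 1.0
    # observation process
    water_minutes: float = 35.0
    air_minutes: float = 10.0
    record_period_s: float = 10.0
    lag_tau_s: float = 60.0
    noise_co2_ppm: float = 0.5
    noise_ch4_ppm: float = 0.001

    def __post_init__(self) -> None:
        bad = []
        for name in (
            "n_days", "wind_weibull_shape", "wind_weibull_scale",
            "wind_persistence_min", "drag_coefficient", "zu_m", "pressure_atm",
            "water_minutes", "air_minutes", "record_period_s",
            "ch4_nmol_l", "xco2_air_ppm", "xch4_air_ppm",
        ):
            if getattr(self, name) <= 0:
                bad.append(name)
        for name in (
            "pco2_diel_amplitude_uatm", "pco2_noise_uatm", "ch4_noise_frac",
            "twater_diel_amplitude_c", "lag_tau_s", "noise_co2_ppm", "noise_ch4_ppm",
        ):
            if getattr(self, name) < 0:
                bad.append(name)
        if not (self.salinity_range[0] <= self.salinity_range[1]):
            bad.append("salinity_range")
        if self.wind_constant_ms is not None and self.wind_constant_ms < 0:
            bad.append("wind_constant_ms")
        if bad:
            raise ConfigurationError(f"invalid scenario configuration keys: {bad}")

    @property
    def cycle_minutes(self) -> float:
        return self.water_minutes + self.air_minutes


@dataclass
class CampaignTruth:
    """Ground-truth ledger of one simulated campaign.

    ``truth`` holds the per-minute state (including one endpoint row at
    the end of the last day so daily trapezoidal integrals close);
    ``environment`` is the 1-min environmental series the pipeline sees;
    ``daily`` the true daily net fluxes (trapezoidal time average) with
    a per-day SE over the ledger's 15-min true flux means;
    ``cycle_windows`` the scheduled (habitat, water, air) windows.
    """

    config: ScenarioConfig
    environment: pd.DataFrame
    truth: pd.DataFrame
    daily: pd.DataFrame
    salinity: float
    cycle_windows: list[tuple[pd.Timestamp, pd.Timestamp, pd.Timestamp]] = field(
        default_factory=list
    )


@dataclass
class RenderedStream:
    """A rendered raw analyzer stream plus its contamination ledger.

    ``contaminated`` are positional indices of records still relaxing
    toward the new phase's concentration (within two lag time constants
    of a phase switch)."""

    records: pd.DataFrame
    contaminated: np.ndarray


# per-season environmental baselines and per-habitat gas levels; values
# chosen so default daily net fluxes land inside the seasonal magnitudes
# observed for each habitat type
_SEASON_BASE = {
    "spring": {"start": "2020-05-18", "twater_mean_c": 11.0, "wind_weibull_scale": 4.5},
    "summer": {"start": "2020-07-06", "twater_mean_c": 17.0, "wind_weibull_scale": 4.0},
    "fall": {"start": "2020-10-22", "twater_mean_c": 10.0, "wind_weibull_scale": 5.0},
    "winter": {"start": "2020-11-30", "twater_mean_c": 4.0, "wind_weibull_scale": 5.5},
}

_HABITAT_SEASON = {
    ("macroalgae", "spring"): {"pco2_sea_mean_uatm": 300, "pco2_diel_amplitude_uatm": 100, "ch4_nmol_l": 18},
    ("macroalgae", "summer"): {"pco2_sea_mean_uatm": 270, "pco2_diel_amplitude_uatm": 150, "ch4_nmol_l": 53},
    ("macroalgae", "fall"): {"pco2_sea_mean_uatm": 330, "pco2_diel_amplitude_uatm": 100, "ch4_nmol_l": 90},
    ("macroalgae", "winter"): {"pco2_sea_mean_uatm": 450, "pco2_diel_amplitude_uatm": 20, "ch4_nmol_l": 10},
    ("mixed_vegetation", "spring"): {"pco2_sea_mean_uatm": 280, "pco2_diel_amplitude_uatm": 120, "ch4_nmol_l": 20},
    ("mixed_vegetation", "summer"): {"pco2_sea_mean_uatm": 250, "pco2_diel_amplitude_uatm": 170, "ch4_nmol_l": 60},
    ("mixed_vegetation", "fall"): {"pco2_sea_mean_uatm": 310, "pco2_diel_amplitude_uatm": 120, "ch4_nmol_l": 140},
    ("mixed_vegetation", "winter"): {"pco2_sea_mean_uatm": 460, "pco2_diel_amplitude_uatm": 20, "ch4_nmol_l": 12},
    ("bare_sediment", "spring"): {"pco2_sea_mean_uatm": 410, "pco2_diel_amplitude_uatm": 40, "ch4_nmol_l": 20},
    ("bare_sediment", "summer"): {"pco2_sea_mean_uatm": 480, "pco2_diel_amplitude_uatm": 60, "ch4_nmol_l": 55},
    ("bare_sediment", "fall"): {"pco2_sea_mean_uatm": 350, "pco2_diel_amplitude_uatm": 60, "ch4_nmol_l": 120},
    ("bare_sediment", "winter"): {"pco2_sea_mean_uatm": 470, "pco2_diel_amplitude_uatm": 20, "ch4_nmol_l": 12},
}

PRESETS: dict[str, dict] = {
    f"{habitat}-{season}": {
        "habitat_id": habitat,
        "season": season,
        **_SEASON_BASE[season],
        **gas_levels,
    }
    for (habitat, season), gas_levels in _HABITAT_SEASON.items()
}


def preset_config(name: str, **overrides) -> ScenarioConfig:
    """Build a ScenarioConfig from a named preset, e.g.
    ``macroalgae-summer``; keyword overrides win."""
    if name not in PRESETS:
        raise ConfigurationError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = {**PRESETS[name], **overrides}
    valid = {f.name for f in fields(ScenarioConfig)}
    unknown = set(params) - valid
    if unknown:
        raise ConfigurationError(f"unknown scenario keys: {sorted(unknown)}")
    return ScenarioConfig(**params)


def _ar1(rng: np.random.Generator, n: int, dt_min: float, persistence_min: float) -> np.ndarray:
    """Standard-normal AR(1) series with the given e-folding persistence."""
    phi = float(np.exp(-dt_min / persistence_min))
    eps = rng.standard_normal(n)
    z = np.empty(n)
    z[0] = eps[0]
    innov = np.sqrt(1.0 - phi**2)
    # z[t] = phi*z[t-1] + sqrt(1-phi^2)*eps[t]  via an IIR filter
    z[1:] = signal.lfilter([1.0], [1.0, -phi], innov * eps[1:], zi=[phi * z[0]])[0]
    return z


def simulate_truth(config: ScenarioConfig) -> CampaignTruth:
    """Simulate environmental forcing and true dissolved-gas fields.

    State is generated on a 1-min grid (plus a closing endpoint row);
    instantaneous fluxes are evaluated with the package's own bulk flux
    functions from the ledger's own k, K0 and partial pressures.
    """
    rng = np.random.default_rng(config.seed)
    n_min = config.n_days * 1440
    idx = pd.date_range(config.start, periods=n_min + 1, freq="1min")
    hours = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    # --- environment -------------------------------------------------
    salinity = float(rng.uniform(*config.salinity_range))
    twater = config.twater_mean_c + config.twater_diel_amplitude_c * np.cos(
        2 * np.pi * (hours - config.twater_max_hour) / 24.0
    )
    z = _ar1(rng, n_min + 1, 1.0, config.wind_persistence_min)
    if config.wind_constant_ms is not None:
        u10 = np.full(n_min + 1, float(config.wind_constant_ms))
    else:
        u10 = stats.weibull_min.ppf(
            stats.norm.cdf(z), config.wind_weibull_shape, scale=config.wind_weibull_scale
        )
    u10 = np.clip(u10, 0.0, None)
    ustar = np.sqrt(config.drag_coefficient) * u10
    # what the mast sensor at zu would read given the true U10
    u_sensor = u10 - (ustar / CONSTANTS.kappa) * np.log(10.0 / config.zu_m)
    u_sensor = np.clip(u_sensor, 0.0, None)

    # --- true gas fields ---------------------------------------------
    pco2_sea = (
        config.pco2_sea_mean_uatm
        - config.pco2_diel_amplitude_uatm
        * np.cos(2 * np.pi * (hours - config.pco2_min_hour) / 24.0)
        + config.pco2_noise_uatm
        * _ar1(rng, n_min + 1, 1.0, config.pco2_noise_persistence_min)
    )
    pco2_sea = np.clip(pco2_sea, 1.0, None)

    ch4_conc = (
        config.ch4_nmol_l
        * 1e-6  # nmol L^-1 -> mol m^-3
        * (1.0 + config.ch4_noise_frac * _ar1(rng, n_min + 1, 1.0, config.pco2_noise_persistence_min))
    )
    ch4_conc = np.clip(ch4_conc, 1e-9, None)

    co2 = get_gas("CO2")
    ch4 = get_gas("CH4")
    t_kelvin = twater + 273.15
    sol_co2 = gas_physics.solubility(co2, t_kelvin, salinity)
    sol_ch4 = gas_physics.solubility(ch4, t_kelvin, salinity)
    pch4_sea = ch4_conc / sol_ch4.K0 * 1e6  # atm -> uatm
    pco2_air = config.xco2_air_ppm * config.pressure_atm
    pch4_air = config.xch4_air_ppm * config.pressure_atm

    sc_co2 = gas_physics.schmidt_number(co2, twater, salinity)
    sc_ch4 = gas_physics.schmidt_number(ch4, twater, salinity)
    k_co2 = gas_physics.gas_transfer_velocity(u10, sc_co2)
    k_ch4 = gas_physics.gas_transfer_velocity(u10, sc_ch4)
    flux_co2 = gas_physics.sea_air_flux(co2, k_co2.k_ms, sol_co2.K0, pco2_sea, pco2_air)
    flux_ch4 = gas_physics.sea_air_flux(ch4, k_ch4.k_ms, sol_ch4.K0, pch4_sea, pch4_air)

    truth = pd.DataFrame(
        {
            "timestamp": idx,
            "twater_c": twater,
            "salinity": salinity,
            "u10_ms": u10,
            "p_co2_sea_uatm": pco2_sea,
            "p_co2_air_uatm": pco2_air,
            "p_ch4_sea_uatm": pch4_sea,
            "p_ch4_air_uatm": pch4_air,
            "K0_co2": sol_co2.K0,
            "K0_ch4": sol_ch4.K0,
            "sc_co2": sc_co2,
            "sc_ch4": sc_ch4,
            "k_co2_ms": k_co2.k_ms,
            "k_ch4_ms": k_ch4.k_ms,
            "flux_co2": flux_co2,
            "flux_ch4": flux_ch4,
        }
    )

    environment = pd.DataFrame(
        {
            "timestamp": idx[:-1],
            "twater_c": twater[:-1],
            "salinity": salinity,
            "wind_ms": u_sensor[:-1],
            "ustar_ms": ustar[:-1],
            "zu_m": config.zu_m,
            "pressure_atm": config.pressure_atm,
        }
    )

    # --- daily truth: trapezoidal time average over each day ---------
    daily_rows = []
    t = truth.set_index("timestamp")
    for day in range(config.n_days):
        lo = idx[0] + pd.Timedelta(days=day)
        hi = lo + pd.Timedelta(days=1)
        seg = t.loc[lo:hi]  # inclusive of the closing endpoint
        quarter = t.loc[lo : hi - pd.Timedelta(minutes=1)]
        for gas_name, col in (("CO2", "flux_co2"), ("CH4", "flux_ch4")):
            mean = float(np.trapezoid(seg[col].to_numpy(), dx=1.0) / (len(seg) - 1))
            q15 = quarter[col].resample("15min").mean()
            se = float(q15.std(ddof=1) / np.sqrt(len(q15)))
            daily_rows.append(
                {
                    "date": lo.date(),
                    "gas": gas_name,
                    "true_flux": mean,
                    "true_se": se,
                }
            )
    daily = pd.DataFrame(daily_rows)

    windows = []
    cycle = pd.Timedelta(minutes=config.cycle_minutes)
    water = pd.Timedelta(minutes=config.water_minutes)
    start = idx[0]
    end = idx[0] + pd.Timedelta(days=config.n_days)
    cur = start
    while cur < end:
        windows.append((cur, cur + water, min(cur + cycle, end)))
        cur += cycle

    return CampaignTruth(config, environment, truth, daily, salinity, windows)


def render_stream(truth: CampaignTruth, config: ScenarioConfig | None = None) -> RenderedStream:
    """Render the raw 10-s analyzer stream the CRDS loop would log.

    Water-phase targets are the ledger's sea partial pressures expressed
    as dry mole fractions at the campaign pressure; air-phase targets the
    atmospheric mole fractions.  The measured value relaxes toward the
    target with a first-order response (time constant ``lag_tau_s``),
    so every phase switch contaminates the following records; those
    within two time constants of a switch are indexed as contaminated.
    Gaussian instrument noise is added last.
    """
    config = config or truth.config
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EA]))
    dt = config.record_period_s
    n_rec = int(config.n_days * 86400 / dt)
    t_sec = np.arange(n_rec) * dt
    idx = pd.to_datetime(truth.truth["timestamp"].iloc[0]) + pd.to_timedelta(t_sec, unit="s")

    cycle_s = config.cycle_minutes * 60.0
    within = t_sec % cycle_s
    is_water = within < config.water_minutes * 60.0
    phase = np.where(is_water, "water", "air")

    truth_sec = (
        truth.truth["timestamp"] - truth.truth["timestamp"].iloc[0]
    ).dt.total_seconds().to_numpy()
    targets = {}
    for gas_key, col, air_ppm in (
        ("xco2_ppm", "p_co2_sea_uatm", config.xco2_air_ppm),
        ("xch4_ppm", "p_ch4_sea_uatm", config.xch4_air_ppm),
    ):
        sea_ppm = (
            np.interp(t_sec, truth_sec, truth.truth[col].to_numpy())
            / config.pressure_atm
        )
        targets[gas_key] = np.where(is_water, sea_ppm, air_ppm)

    a = float(np.exp(-dt / config.lag_tau_s)) if config.lag_tau_s > 0 else 0.0
    data = {"timestamp": idx, "phase": phase, "habitat": config.habitat_id}
    noise_sd = {"xco2_ppm": config.noise_co2_ppm, "xch4_ppm": config.noise_ch4_ppm}
    for gas_key, target in targets.items():
        if a > 0:
            # x[t] = (1-a)*target[t] + a*x[t-1], x[0] = target[0]
            x = signal.lfilter([1.0 - a], [1.0, -a], target, zi=[a * target[0]])[0]
        else:
            x = target.copy()
        x = x + rng.normal(0.0, noise_sd[gas_key], size=n_rec)
        data[gas_key] = np.clip(x, 1e-6, None)
    data["flag"] = "ok"

    records = pd.DataFrame(data).rename(columns={"flag": "qc_flag"})
    records["qc_flag"] = "ok"

    # seconds since the most recent phase switch (window starts at 0 and
    # at the water->air boundary of each cycle)
    since_switch = np.where(
        is_water, within, within - config.water_minutes * 60.0
    )
    contaminated = np.flatnonzero(since_switch < 2.0 * config.lag_tau_s)
    return RenderedStream(records, contaminated)


def generate_campaign(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame, CampaignTruth, RenderedStream]:
    """Simulate truth and render its stream; returns
    (gas records, environment series, truth ledger, rendered stream)."""
    truth = simulate_truth(config)
    stream = render_stream(truth, config)
    return stream.records, truth.environment, truth, stream


def write_campaign(config: ScenarioConfig, out_dir) -> dict[str, Path]:
    """Write gas, environment and truth-ledger CSVs in the schemas the
    QC pipeline reads; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    gas_df, env_df, truth, stream = generate_campaign(config)
    paths = {
        "gas": out / "gas_records.csv",
        "env": out / "environment.csv",
        "truth": out / "truth_ledger.csv",
        "daily_truth": out / "truth_daily.csv",
    }
    gas_df.rename(columns={"qc_flag": "flag"}).to_csv(paths["gas"], index=False)
    env_df.to_csv(paths["env"], index=False)
    truth.truth.to_csv(paths["truth"], index=False)
    truth.daily.to_csv(paths["daily_truth"], index=False)
    return paths


def recovery_experiment(
    preset: str,
    n_replicates: int = 100,
    seed: int = 0,
    **config_overrides,
) -> pd.DataFrame:
    """Monte-Carlo recovery check: run the full QC/flux pipeline on
    independently seeded one-day campaigns and compare the recovered
    daily net fluxes with the ledger truth.

    Returns one row per (replicate, gas) with the pipeline estimate,
    the true daily flux, the ledger SE, their difference, and whether
    the estimate falls within two ledger SEs of truth.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(n_replicates):
        child = int(rng.integers(2**31))
        config = preset_config(preset, n_days=1, seed=child, **config_overrides)
        gas_df, env_df, truth, _ = generate_campaign(config)
        result = equilibrator_qc.compute_fluxes(gas_df, env_df)
        daily = result.daily.set_index("gas")
        truth_daily = truth.daily.set_index("gas")
        for gas_name in ("CO2", "CH4"):
            est = float(daily.loc[gas_name, "mean_flux"])
            tru = float(truth_daily.loc[gas_name, "true_flux"])
            t_se = float(truth_daily.loc[gas_name, "true_se"])
            rows.append(
                {
                    "replicate": rep,
                    "seed": child,
                    "gas": gas_name,
                    "estimate": est,
                    "truth": tru,
                    "truth_se": t_se,
                    "error": est - tru,
                    "within_2se": abs(est - tru) <= 2.0 * t_se,
                }
            )
    return pd.DataFrame(rows)
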