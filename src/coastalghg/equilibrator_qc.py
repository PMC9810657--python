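"""Quality control and flux pipeline for equilibrator/CRDS gas streams.

A fast-response showerhead equilibrator feeds a cavity ring-down
spectrometer that alternates between the water-equilibrated headspace
(35 min) and ambient air (10 min); one complete cycle is 45 minutes and
the raw 1-Hz signal is averaged and logged every 10 s.  This module

* segments a logged stream into measurement cycles,
* purges transition periods after phase switches and station moves
  (the analyzer needs time to relax to sharp concentration changes),
* joins the environmental series and evaluates the bulk flux for every
  retained water-phase record, using each cycle's own purged air window
  as the atmospheric reference,
* averages fluxes to clock-aligned intervals (15 min by default),
  composites them into 2-hour diel bins, and integrates daily net
  fluxes with a standard error taken over the interval means.

All tabular data are pandas DataFrames; the expected CSV schemas are
documented on the readers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import gas_physics
from .constants import CONSTANTS, get_gas
from .exceptions import ConfigurationError, InvalidInputError, StructuralFormatError

__all__ = [
    "QCConfig",
    "MeasurementCycle",
    "DailyFlux",
    "PipelineResult",
    "read_gas_csv",
    "read_env_csv",
    "parse_cycles",
    "filter_transitions",
    "resample_mean",
    "diel_composite",
    "daily_net_flux",
    "join_environment",
    "compute_fluxes",
    "write_daily_csv",
]

GAS_COLUMNS = {"CO2": "xco2_ppm", "CH4": "xch4_ppm"}

#: qc flags that exclude a record from averaging
BAD_FLAGS = ("transition", "malfunction", "low_flow")


@dataclass(frozen=True)
class QCConfig:
    """Tunable parameters of the QC/flux pipeline.

    purge_s
        Seconds discarded after every phase switch or station move
        (analyzer response time); applied to both water and air windows.
    avg_width
        Averaging interval for flux series (pandas offset string).
    max_env_gap
        Largest tolerated time gap when joining the environmental
        series onto gas records (nearest neighbour in time).
    min_coverage
        Minimum fraction of a day's averaging intervals that must hold
        data for a daily net flux to be reported.
    water_minutes / air_minutes
        Nominal window lengths of one measurement cycle.
    duration_tolerance
        Relative deviation from the nominal window lengths beyond which
        a cycle is flagged partial.
    apply_vapor_correction
        Present for completeness; the analyzer measures a dried gas
        stream so no water-vapor correction is applied by default.
    """

    purge_s: float = 300.0
    avg_width: str = "15min"
    max_env_gap: str = "15min"
    min_coverage: float = 0.5
    water_minutes: float = 35.0
    air_minutes: float = 10.0
    duration_tolerance: float = 0.25
    record_period_s: float = 10.0
    apply_vapor_correction: bool = False

    def __post_init__(self) -> None:
        if self.purge_s < 0:
            raise ConfigurationError("purge_s must be >= 0")
        if not 0 < self.min_coverage <= 1:
            raise ConfigurationError("min_coverage must be in (0, 1]")
        if self.apply_vapor_correction:
            raise ConfigurationError(
                "water-vapor correction is not implemented: the analyzer "
                "measures a dried gas stream"
            )


@dataclass
class MeasurementCycle:
    """One water->air measurement cycle of the equilibrator loop.

    Windows are half-open ``[start, end)`` timestamp pairs; ``air_window``
    is ``None`` for a truncated final cycle.  ``cycle_index`` counts
    consecutively within one habitat deployment.
    """

    habitat_id: str
    cycle_index: int
    water_window: tuple[pd.Timestamp, pd.Timestamp]
    air_window: tuple[pd.Timestamp, pd.Timestamp] | None
    partial: bool = False


@dataclass
class DailyFlux:
    """Daily-integrated net sea-air flux (mg m^-2 d^-1) with its
    standard error over the day's interval means."""

    habitat_id: str
    date: object
    gas: str
    mean_flux: float
    se_flux: float
    n_intervals: int
    reason: str | None = None


@dataclass
class PipelineResult:
    """Everything the pipeline computed, from record level to daily."""

    records: pd.DataFrame
    flux_intervals: pd.DataFrame
    daily: pd.DataFrame
    cycles: list[MeasurementCycle] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers


def read_gas_csv(path) -> pd.DataFrame:
    """Read a logged analyzer stream.

    Expected columns: ``timestamp,phase,habitat,xco2_ppm,xch4_ppm,flag``
    with phase in {water, air} and flag in {ok, transition, malfunction,
    low_flow}.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {"timestamp", "phase", "habitat", "xco2_ppm", "xch4_ppm", "flag"}
    missing = required - set(df.columns)
    if missing:
        raise StructuralFormatError(f"gas CSV missing columns {sorted(missing)}")
    df = df.rename(columns={"flag": "qc_flag"})
    ok = df["qc_flag"] == "ok"
    nonpos = ok & ((df["xco2_ppm"] <= 0) | (df["xch4_ppm"] <= 0))
    if nonpos.any():
        raise StructuralFormatError(
            f"{int(nonpos.sum())} ok-flagged records with non-positive mole fractions"
        )
    return df


def read_env_csv(path) -> pd.DataFrame:
    """Read the environmental series.

    Expected columns:
    ``timestamp,twater_c,salinity,wind_ms,ustar_ms,zu_m,pressure_atm``.
    """
    df = pd.read_csv(path, parse_dates=["timestamp"])
    required = {
        "timestamp", "twater_c", "salinity", "wind_ms",
        "ustar_ms", "zu_m", "pressure_atm",
    }
    missing = required - set(df.columns)
    if missing:
        raise StructuralFormatError(f"environment CSV missing columns {sorted(missing)}")
    return df


def write_daily_csv(daily: pd.DataFrame, path) -> None:
    """Write daily net fluxes as ``habitat,date,gas,mean_flux_mg_m2_d,se_flux,n``."""
    out = daily.rename(
        columns={
            "habitat_id": "habitat",
            "mean_flux": "mean_flux_mg_m2_d",
            "se_flux": "se_flux",
            "n_intervals": "n",
        }
    )
    cols = ["habitat", "date", "gas", "mean_flux_mg_m2_d", "se_flux", "n"]
    out[cols].to_csv(path, index=False)


# ---------------------------------------------------------------------------
# cycle segmentation


def _runs(df: pd.DataFrame):
    """Contiguous runs of constant (phase, habitat); yields index slices."""
    change = (
        (df["phase"] != df["phase"].shift())
        | (df["habitat"] != df["habitat"].shift())
    ).cumsum()
    for _, idx in df.groupby(change, sort=False).groups.items():
        yield idx


def parse_cycles(df: pd.DataFrame, config: QCConfig = QCConfig()) -> list[MeasurementCycle]:
    """Segment a sorted record stream into water->air measurement cycles.

    Every record belongs to at most one cycle window; leading air records
    (before the first water window) are orphans.  A final cycle without
    an air window, or one whose window durations deviate from the nominal
    35/10 min by more than the configured tolerance, is flagged partial.
    A run that repeats the phase of the previous run (which can only
    happen across a station move) violates the water/air alternation and
    raises a structural error.
    """
    if df.empty:
        return []
    ts = df["timestamp"]
    if not ts.is_monotonic_increasing or ts.duplicated().any():
        raise StructuralFormatError("timestamps must be strictly increasing")

    period = pd.Timedelta(seconds=config.record_period_s)
    runs = []
    for idx in _runs(df):
        sub = df.loc[idx]
        runs.append(
            {
                "phase": sub["phase"].iloc[0],
                "habitat": sub["habitat"].iloc[0],
                "start": sub["timestamp"].iloc[0],
                "end": sub["timestamp"].iloc[-1] + period,
            }
        )

    cycles: list[MeasurementCycle] = []
    per_habitat_counter: dict[str, int] = {}
    i = 0
    n_cycle = 0
    while i < len(runs):
        run = runs[i]
        if i > 0 and runs[i - 1]["phase"] == run["phase"]:
            raise StructuralFormatError(
                f"water/air alternation violated at cycle {n_cycle} "
                f"({run['habitat']}, {run['start']})"
            )
        if run["phase"] == "air":
            i += 1  # leading air run: orphan records
            continue
        if run["phase"] != "water":
            raise StructuralFormatError(f"unknown phase {run['phase']!r}")
        water = (run["start"], run["end"])
        air = None
        if i + 1 < len(runs) and runs[i + 1]["phase"] == "air" and runs[i + 1]["habitat"] == run["habitat"]:
            air = (runs[i + 1]["start"], runs[i + 1]["end"])
            i += 2
        else:
            i += 1

        water_min = (water[1] - water[0]).total_seconds() / 60.0
        partial = air is None or abs(water_min - config.water_minutes) > (
            config.duration_tolerance * config.water_minutes
        )
        if air is not None:
            air_min = (air[1] - air[0]).total_seconds() / 60.0
            partial = partial or abs(air_min - config.air_minutes) > (
                config.duration_tolerance * config.air_minutes
            )
        habitat = run["habitat"]
        index = per_habitat_counter.get(habitat, 0)
        per_habitat_counter[habitat] = index + 1
        cycles.append(MeasurementCycle(habitat, index, water, air, partial))
        n_cycle += 1
    return cycles


def assign_cycles(df: pd.DataFrame, cycles: Sequence[MeasurementCycle]) -> pd.Series:
    """Map each record to the position of its cycle in ``cycles``
    (-1 for orphans), by half-open window membership and habitat."""
    out = pd.Series(-1, index=df.index, dtype=int)
    ts = df["timestamp"]
    for pos, cyc in enumerate(cycles):
        windows = [cyc.water_window] + ([cyc.air_window] if cyc.air_window else [])
        for lo, hi in windows:
            mask = (ts >= lo) & (ts < hi) & (df["habitat"] == cyc.habitat_id)
            out[mask] = pos
    return out


def filter_transitions(
    df: pd.DataFrame,
    cycles: Sequence[MeasurementCycle],
    purge_s: float = 300.0,
) -> pd.DataFrame:
    """Flag records measured within ``purge_s`` seconds after any phase
    switch or station move as ``transition``.

    Each cycle window (water and air) starts at such a switch, so the
    purge applies to the head of every window.  Records already flagged
    malfunction/low_flow keep their flag; ok records outside purge
    windows are untouched.  A purge longer than a nominal phase window
    cannot leave any data and is a configuration error.
    """
    if purge_s < 0:
        raise ConfigurationError("purge must be >= 0")
    windows = []
    full_windows = []
    for cyc in cycles:
        windows.append(cyc.water_window)
        if cyc.air_window is not None:
            windows.append(cyc.air_window)
        if not cyc.partial:
            full_windows.extend(windows[-2:])
    # truncated cycles may be arbitrarily short; judge the purge against
    # the complete phase windows only
    if full_windows:
        shortest = min((hi - lo).total_seconds() for lo, hi in full_windows)
        if purge_s > shortest:
            raise ConfigurationError(
                f"purge of {purge_s:.0f}s exceeds the shortest phase window "
                f"({shortest:.0f}s); no data would survive"
            )
    out = df.copy()
    if purge_s == 0:
        return out
    purge = pd.Timedelta(seconds=purge_s)
    ts = out["timestamp"]
    in_purge = pd.Series(False, index=out.index)
    for lo, _ in windows:
        in_purge |= (ts >= lo) & (ts < lo + purge)
    out.loc[in_purge & (out["qc_flag"] == "ok"), "qc_flag"] = "transition"
    return out


# ---------------------------------------------------------------------------
# averaging


def resample_mean(series: pd.Series, width: str = "15min") -> pd.DataFrame:
    """Average a timestamped series over clock-aligned half-open
    intervals ``[t, t+width)``.

    Returns a DataFrame indexed by interval start with columns
    ``mean``, ``sd`` (sample SD, 0 for a single constant interval of
    n >= 2, NaN for n = 1) and ``n``.  Intervals without records appear
    with NaN mean and n = 0.
    """
    if pd.Timedelta(width) <= pd.Timedelta(0):
        raise InvalidInputError("interval width must be positive")
    if series.empty:
        return pd.DataFrame(columns=["mean", "sd", "n"])
    grouped = series.resample(width, closed="left", label="left")
    out = pd.DataFrame(
        {"mean": grouped.mean(), "sd": grouped.std(ddof=1), "n": grouped.count()}
    )
    out["n"] = out["n"].astype(int)
    return out


def diel_composite(flux_means: pd.Series) -> pd.DataFrame:
    """Composite interval flux means into twelve 2-hour diel bins.

    Bin ``b`` collects local hours ``[2b, 2b+2)``.  Returns one row per
    contributing bin with ``mean``, ``se`` (SD of contributing interval
    means / sqrt(n)) and ``n``.  Empty input yields an empty composite.
    """
    valid = flux_means.dropna()
    if valid.empty:
        return pd.DataFrame(columns=["bin", "hour_start", "mean", "se", "n"])
    bins = valid.index.hour // 2
    grouped = valid.groupby(bins)
    out = pd.DataFrame(
        {
            "bin": grouped.mean().index,
            "hour_start": grouped.mean().index * 2,
            "mean": grouped.mean().to_numpy(),
            "se": (grouped.std(ddof=1) / np.sqrt(grouped.count())).to_numpy(),
            "n": grouped.count().to_numpy(),
        }
    ).reset_index(drop=True)
    return out


def daily_net_flux(
    flux_means: pd.Series,
    habitat: str,
    gas: str,
    min_coverage: float = 0.5,
    width: str = "15min",
) -> list[DailyFlux]:
    """Integrate interval flux means to daily net fluxes.

    Fluxes are already expressed per day (mg m^-2 d^-1), so the daily
    net flux is the unweighted mean of the day's interval means; its
    standard error is the SD of those means over sqrt(n).  Days covering
    less than ``min_coverage`` of the possible intervals are emitted as
    missing with a reason rather than silently dropped.
    """
    slots_per_day = pd.Timedelta(days=1) / pd.Timedelta(width)
    results: list[DailyFlux] = []
    for date, day in flux_means.groupby(flux_means.index.date):
        vals = day.dropna()
        coverage = len(vals) / slots_per_day
        if coverage < min_coverage:
            results.append(
                DailyFlux(
                    habitat, date, gas, float("nan"), float("nan"), len(vals),
                    reason=f"coverage {coverage:.0%} below {min_coverage:.0%}",
                )
            )
            continue
        mean = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
        results.append(DailyFlux(habitat, date, gas, mean, se, len(vals)))
    return results


# ---------------------------------------------------------------------------
# flux computation


def join_environment(
    gas_df: pd.DataFrame, env_df: pd.DataFrame, max_gap: str = "15min"
) -> pd.DataFrame:
    """Nearest-neighbour-in-time join of the environmental series onto
    gas records; records farther than ``max_gap`` from any environmental
    observation get NaN environment (and hence NaN flux)."""
    env = env_df.sort_values("timestamp")
    joined = pd.merge_asof(
        gas_df.sort_values("timestamp"),
        env,
        on="timestamp",
        direction="nearest",
        tolerance=pd.Timedelta(max_gap),
    )
    return joined


def _cycle_air_reference(
    df: pd.DataFrame, cycle_ids: pd.Series, cycles: Sequence[MeasurementCycle]
) -> pd.DataFrame:
    """Per-cycle atmospheric mole-fraction reference: the mean of each
    cycle's purged, ok air records.  Cycles without usable air records
    (e.g. a truncated final cycle) inherit the nearest preceding
    reference within the same habitat, else the nearest following one."""
    rows = []
    for pos, cyc in enumerate(cycles):
        mask = (cycle_ids == pos) & (df["phase"] == "air") & (df["qc_flag"] == "ok")
        rec = {"cycle_pos": pos, "habitat": cyc.habitat_id}
        for gas, col in GAS_COLUMNS.items():
            vals = df.loc[mask, col]
            rec[f"air_{col}"] = float(vals.mean()) if len(vals) else np.nan
        rows.append(rec)
    ref = pd.DataFrame(rows)
    for col in [c for c in ref.columns if c.startswith("air_")]:
        ref[col] = ref.groupby("habitat")[col].transform(lambda s: s.ffill().bfill())
    return ref


def compute_fluxes(
    gas_df: pd.DataFrame,
    env_df: pd.DataFrame,
    config: QCConfig = QCConfig(),
) -> PipelineResult:
    """Run the full record->daily pipeline.

    Steps: cycle segmentation, transition purging, per-cycle air
    reference, environment join, bulk flux per retained water record for
    both gases, interval averaging, and daily integration.  Returns the
    record-level table (with all physical intermediates), the interval
    means, and the daily net fluxes.
    """
    cycles = parse_cycles(gas_df, config)
    df = filter_transitions(gas_df, cycles, config.purge_s)
    cycle_ids = assign_cycles(df, cycles)
    df = df.assign(cycle_pos=cycle_ids)
    air_ref = _cycle_air_reference(df, cycle_ids, cycles)

    water = df[
        (df["phase"] == "water") & (df["qc_flag"] == "ok") & (df["cycle_pos"] >= 0)
    ].copy()
    water = water.merge(
        air_ref.drop(columns="habitat"), on="cycle_pos", how="left"
    )
    water = join_environment(water, env_df, config.max_env_gap)

    kappa = CONSTANTS.kappa
    u10 = (
        water["wind_ms"]
        + (water["ustar_ms"] / kappa) * np.log(10.0 / water["zu_m"])
    ).clip(lower=0.0)
    t_kelvin = water["twater_c"] + 273.15

    records = []
    for gas_name, col in GAS_COLUMNS.items():
        gas = get_gas(gas_name)
        sol = gas_physics.solubility(gas, t_kelvin.to_numpy(), water["salinity"].to_numpy())
        sc = gas_physics.schmidt_number(
            gas, water["twater_c"].to_numpy(), water["salinity"].to_numpy()
        )
        k = gas_physics.gas_transfer_velocity(u10.to_numpy(), sc)
        p_sea = water[col].to_numpy() * water["pressure_atm"].to_numpy()
        p_air = water[f"air_{col}"].to_numpy() * water["pressure_atm"].to_numpy()
        flux = gas_physics.sea_air_flux(gas, k.k_ms, sol.K0, p_sea, p_air)
        records.append(
            pd.DataFrame(
                {
                    "timestamp": water["timestamp"].to_numpy(),
                    "habitat_id": water["habitat"].to_numpy(),
                    "gas": gas_name,
                    "flux_mg_m2_d": flux,
                    "k_ms": k.k_ms,
                    "k_cmh": k.k_cmh,
                    "K0_mol_m3_atm": sol.K0,
                    "schmidt": sc,
                    "u10_ms": u10.to_numpy(),
                    "p_sea_uatm": p_sea,
                    "p_air_uatm": p_air,
                    "cycle_pos": water["cycle_pos"].to_numpy(),
                }
            )
        )
    record_df = pd.concat(records, ignore_index=True) if records else pd.DataFrame()

    interval_frames = []
    daily_rows: list[DailyFlux] = []
    for (habitat, gas_name), sub in record_df.groupby(["habitat_id", "gas"], sort=True):
        series = sub.set_index("timestamp")["flux_mg_m2_d"].sort_index()
        intervals = resample_mean(series, config.avg_width)
        frame = intervals.reset_index(names="timestamp")
        frame.insert(1, "habitat_id", habitat)
        frame.insert(2, "gas", gas_name)
        interval_frames.append(frame)
        daily_rows.extend(
            daily_net_flux(
                intervals["mean"], habitat, gas_name,
                min_coverage=config.min_coverage, width=config.avg_width,
            )
        )
    flux_intervals = (
        pd.concat(interval_frames, ignore_index=True)
        if interval_frames
        else pd.DataFrame(columns=["timestamp", "habitat_id", "gas", "mean", "sd", "n"])
    )
    daily = pd.DataFrame(
        [
            {
                "habitat_id": d.habitat_id,
                "date": d.date,
                "gas": d.gas,
                "mean_flux": d.mean_flux,
                "se_flux": d.se_flux,
                "n_intervals": d.n_intervals,
                "reason": d.reason,
            }
            for d in daily_rows
        ]
    )
    return PipelineResult(record_df, flux_intervals, daily, list(cycles))
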