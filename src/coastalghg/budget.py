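"""Seasonal/annual integration and the net greenhouse-gas balance.

Daily mean sea-air fluxes (mg m^-2 d^-1) are integrated season by
season to first-order cumulative annual fluxes (g m^-2 y^-1) with an
error propagated from the daily standard errors under the assumption of
independent seasonal campaigns.  CH4 fluxes are converted to CO2
equivalents with the sustained-flux global warming potential (SGWP,
45 on a mass basis over a 100-year horizon) — appropriate for
ecosystems that exchange gas with the atmosphere continuously rather
than as a one-time pulse — and combined with the CO2 flux into a net
GHG balance.  When the water is a CO2 sink, the CO2-equivalent CH4
efflux *offsets* a fraction of that sink; when it is a CO2 source, the
CH4 flux *augments* the source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .constants import get_gas
from .exceptions import ConfigurationError, InvalidInputError

__all__ = [
    "SEASONS",
    "DEFAULT_SEASON_LENGTHS",
    "SeasonalSummary",
    "AnnualBudget",
    "GHGBalance",
    "co2_equivalent",
    "seasonal_summaries_from_daily",
    "annual_cumulative",
    "ghg_balance",
    "format_balance_table",
]

SEASONS = ("spring", "summer", "fall", "winter")

#: quarter-year season lengths (days); override via ``season_lengths``
DEFAULT_SEASON_LENGTHS: Mapping[str, float] = {s: 365.25 / 4 for s in SEASONS}

#: the only CO2-equivalence horizon with a shipped SGWP value (years)
SUPPORTED_HORIZON = 100


@dataclass(frozen=True)
class SeasonalSummary:
    """Season-level daily flux statistics for one habitat and gas."""

    habitat_id: str
    season: str
    gas: str
    daily_mean: float  # mg m^-2 d^-1
    daily_se: float  # mg m^-2 d^-1
    n_days: int
    season_length_days: float

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise InvalidInputError(f"unknown season {self.season!r}")
        if self.daily_se < 0:
            raise InvalidInputError("daily_se must be >= 0")
        if self.season_length_days <= 0:
            raise InvalidInputError("season_length_days must be positive")


@dataclass(frozen=True)
class AnnualBudget:
    """Cumulative annual flux (g m^-2 y^-1) and its propagated error."""

    habitat_id: str
    gas: str
    cumulative_flux: float
    propagated_error: float


@dataclass(frozen=True)
class GHGBalance:
    """Net greenhouse-gas balance of one habitat over one period.

    ``net_balance = f_co2 + co2eq_ch4`` in g CO2-eq per the period's
    area-time basis.  ``offset_percent`` expresses the CO2-equivalent
    CH4 flux relative to the magnitude of the CO2 flux:
    ``offset`` when the CO2 flux is a sink (f_co2 < 0), ``augmentation``
    when it is a source.  Undefined (NaN, with a reason) when f_co2 = 0.
    """

    habitat_id: str
    period: str
    f_co2: float
    f_ch4: float
    co2eq_ch4: float
    net_balance: float
    offset_percent: float
    offset_type: str  # "offset" | "augmentation" | "undefined"
    reason: str | None = None

    def rounded(self) -> tuple[float, float]:
        """(net balance, offset) at reporting precision: nearest integer
        g CO2-eq and nearest integer percent."""
        pct = round(self.offset_percent) if math.isfinite(self.offset_percent) else float("nan")
        return round(self.net_balance), pct


def co2_equivalent(f_ch4: float, horizon: int = 100) -> float:
    """CO2-equivalent of a CH4 flux on the same area-time basis.

    Multiplies by the mass-basis SGWP of CH4 (45 over 100 years); sign
    is preserved.  Only the 100-year horizon has a shipped SGWP value.
    """
    if horizon != SUPPORTED_HORIZON:
        raise ConfigurationError(
            f"unsupported SGWP horizon {horizon}; only {SUPPORTED_HORIZON} years available"
        )
    return f_ch4 * get_gas("CH4").sgwp_100


def seasonal_summaries_from_daily(
    daily: pd.DataFrame,
    season_of_date,
    season_lengths: Mapping[str, float] = DEFAULT_SEASON_LENGTHS,
) -> list[SeasonalSummary]:
    """Collapse a daily-flux table (pipeline output) to seasonal summaries.

    ``season_of_date`` maps a date to a season label.  The seasonal
    daily mean is the mean of valid daily means; its SE is the SD of the
    daily means over sqrt(n_days) (campaign-level spread, not the
    within-day SEs).
    """
    valid = daily.dropna(subset=["mean_flux"])
    out = []
    for (habitat, gas), sub in valid.groupby(["habitat_id", "gas"]):
        seasons = sub["date"].map(season_of_date)
        for season, rows in sub.groupby(seasons):
            n = len(rows)
            se = float(rows["mean_flux"].std(ddof=1) / n**0.5) if n > 1 else float(rows["se_flux"].iloc[0])
            out.append(
                SeasonalSummary(
                    habitat, season, gas,
                    daily_mean=float(rows["mean_flux"].mean()),
                    daily_se=se,
                    n_days=n,
                    season_length_days=season_lengths[season],
                )
            )
    return out


def annual_cumulative(summaries: Iterable[SeasonalSummary]) -> AnnualBudget:
    """First-order annual flux from four seasonal summaries.

    cumulative = sum(daily_mean_s * length_s) / 1000 (mg -> g);
    error = sqrt(sum((daily_se_s * length_s)^2)) / 1000, treating
    seasons as independent campaigns.  All four seasons are required.
    """
    summaries = list(summaries)
    if not summaries:
        raise InvalidInputError("no seasonal summaries given")
    habitat = summaries[0].habitat_id
    gas = summaries[0].gas
    if any(s.habitat_id != habitat or s.gas != gas for s in summaries):
        raise InvalidInputError("summaries mix habitats or gases")
    present = {s.season for s in summaries}
    missing = [s for s in SEASONS if s not in present]
    if missing:
        raise InvalidInputError(f"missing seasons for {habitat}/{gas}: {missing}")
    total = sum(s.daily_mean * s.season_length_days for s in summaries) / 1000.0
    err = math.sqrt(
        sum((s.daily_se * s.season_length_days) ** 2 for s in summaries)
    ) / 1000.0
    return AnnualBudget(habitat, gas, total, err)


def ghg_balance(
    f_co2: float,
    f_ch4: float,
    horizon: int = 100,
    habitat_id: str = "",
    period: str = "annual",
) -> GHGBalance:
    """Net GHG balance and offset/augmentation metric.

    ``f_co2`` (g CO2 m^-2 per period) and ``f_ch4`` (g CH4 m^-2 per
    period) must share the same area-time basis.  The offset percentage
    is 100 * co2eq_ch4 / |f_co2|, labelled ``offset`` for a CO2 sink and
    ``augmentation`` for a CO2 source; it is undefined for f_co2 = 0.
    """
    co2eq = co2_equivalent(f_ch4, horizon)
    net = f_co2 + co2eq
    if f_co2 < 0:
        return GHGBalance(
            habitat_id, period, f_co2, f_ch4, co2eq, net,
            100.0 * co2eq / abs(f_co2), "offset",
        )
    if f_co2 > 0:
        return GHGBalance(
            habitat_id, period, f_co2, f_ch4, co2eq, net,
            100.0 * co2eq / f_co2, "augmentation",
        )
    return GHGBalance(
        habitat_id, period, f_co2, f_ch4, co2eq, net, float("nan"),
        "undefined", reason="CO2 flux is zero; offset ratio undefined",
    )


def format_balance_table(balances: Sequence[GHGBalance]) -> str:
    """Aligned-column text table of net balances and offsets, at the
    reporting precision (integer g CO2-eq, integer percent)."""
    header = (
        f"{'habitat':<18}{'period':<10}{'F_CO2':>9}{'F_CH4':>9}"
        f"{'CO2eq_CH4':>11}{'net':>7}{'offset':>9}  type"
    )
    lines = [header, "-" * len(header)]
    for b in balances:
        net, pct = b.rounded()
        pct_txt = f"{pct:.0f}%" if math.isfinite(b.offset_percent) else "n/a"
        lines.append(
            f"{b.habitat_id:<18}{b.period:<10}{b.f_co2:>9.1f}{b.f_ch4:>9.2f}"
            f"{b.co2eq_ch4:>11.2f}{net:>7.0f}{pct_txt:>9}  {b.offset_type}"
        )
    return "\n".join(lines)
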