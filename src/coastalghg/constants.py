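"""Physical constants and per-gas coefficient sets.

The per-gas data (molar masses, solubility fits, Schmidt-number
polynomials, sustained-flux global warming potentials) ship as a
structured YAML file inside the package so coefficient provenance stays
auditable; this module loads it once and exposes frozen dataclasses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources

import yaml

from .exceptions import InvalidInputError

__all__ = [
    "GasSpecies",
    "PhysicalConstants",
    "CONSTANTS",
    "get_gas",
    "available_gases",
]


@dataclass(frozen=True)
class PhysicalConstants:
    """Site-independent constants of the flux formulation.

    Attributes
    ----------
    kappa : von Karman constant (dimensionless).
    R : ideal-gas constant in m^3 atm K^-1 mol^-1.
    T_STD : standard temperature in kelvin.
    reference_salinity_sea : salinity of the "sea water" Schmidt-number
        endpoint (PSU).
    sc_reference : Schmidt number that normalises the gas-transfer
        velocity parameterisation (CO2 in sea water at 20 degC).
    """

    kappa: float = 0.4
    R: float = 8.20573e-5
    T_STD: float = 273.15
    reference_salinity_sea: float = 35.0
    sc_reference: float = 660.0

    def __post_init__(self) -> None:
        for name in ("kappa", "R", "T_STD", "reference_salinity_sea", "sc_reference"):
            if getattr(self, name) <= 0:
                raise InvalidInputError(f"physical constant {name} must be positive")


CONSTANTS = PhysicalConstants()


@dataclass(frozen=True)
class GasSpecies:
    """Per-gas constants required to turn a partial-pressure gradient into
    a mass flux.

    ``solubility_constants`` holds the six coefficients {A1..A3, B1..B3}
    of the ln-solubility fit; ``solubility_form`` says whether the fit
    natively returns the Bunsen coefficient (``"bunsen"``) or the
    volumetric solubility in mol L^-1 atm^-1 (``"k0_mol_per_l_atm"``).
    ``sc_coefficients_*`` are 5-element polynomial coefficients in water
    temperature (degC), lowest order first.
    """

    name: str
    molar_mass: float
    sgwp_100: float
    solubility_form: str
    solubility_constants: dict[str, float]
    solubility_valid_celsius: tuple[float, float]
    sc_coefficients_fresh: tuple[float, ...]
    sc_coefficients_sea: tuple[float, ...]
    sc_valid_celsius: tuple[float, float]

    def __post_init__(self) -> None:
        if self.molar_mass <= 0:
            raise InvalidInputError(f"{self.name}: molar mass must be positive")
        if self.sgwp_100 < 1:
            raise InvalidInputError(f"{self.name}: sgwp_100 must be >= 1")
        missing = {"A1", "A2", "A3", "B1", "B2", "B3"} - set(self.solubility_constants)
        if missing:
            raise InvalidInputError(
                f"{self.name}: incomplete solubility constants, missing {sorted(missing)}"
            )
        if len(self.sc_coefficients_fresh) != 5 or len(self.sc_coefficients_sea) != 5:
            raise InvalidInputError(
                f"{self.name}: Schmidt polynomials must have 5 coefficients"
            )
        if self.solubility_form not in ("bunsen", "k0_mol_per_l_atm"):
            raise InvalidInputError(
                f"{self.name}: unknown solubility form {self.solubility_form!r}"
            )


@lru_cache(maxsize=1)
def _load_gases() -> dict[str, GasSpecies]:
    text = resources.files("coastalghg").joinpath("data/gas_constants.yaml").read_text()
    raw = yaml.safe_load(text)
    gases = {}
    for name, rec in raw["gases"].items():
        gases[name] = GasSpecies(
            name=name,
            molar_mass=float(rec["molar_mass"]),
            sgwp_100=float(rec["sgwp_100"]),
            solubility_form=rec["solubility_form"],
            solubility_constants={k: float(v) for k, v in rec["solubility_constants"].items()},
            solubility_valid_celsius=tuple(rec["solubility_valid_celsius"]),
            sc_coefficients_fresh=tuple(rec["sc_coefficients_fresh"]),
            sc_coefficients_sea=tuple(rec["sc_coefficients_sea"]),
            sc_valid_celsius=tuple(rec["sc_valid_celsius"]),
        )
    return gases


def available_gases() -> tuple[str, ...]:
    """Names of the gases with shipped coefficient sets."""
    return tuple(_load_gases())


def get_gas(name: str) -> GasSpecies:
    """Look up a gas by name (``"CO2"`` or ``"CH4"``, case-insensitive)."""
    gases = _load_gases()
    key = name.upper().replace("₂", "2").replace("₄", "4")
    if key not in gases:
        raise InvalidInputError(f"unknown gas {name!r}; available: {sorted(gases)}")
    return gases[key]
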