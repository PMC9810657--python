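"""Bulk sea-air gas-exchange physics.

Pure, vectorised functions implementing the standard bulk flux
formulation used for equilibrator campaigns in brackish coastal water:

* neutral-stability logarithmic adjustment of measured wind to 10 m,
* gas solubility (Bunsen coefficient and volumetric K0) from the
  fitted ln-solubility coefficient sets of the cited references,
* Schmidt numbers with linear fresh/sea-water interpolation in salinity
  for brackish sites,
* quadratic-wind gas transfer velocity normalised to Sc = 660,
* the bulk flux F = k * K0 * (pGas_sea - pGas_air), returned in
  mg m^-2 d^-1 (positive = efflux from water to atmosphere).

All functions accept scalars or numpy arrays and broadcast; NaNs in the
data arguments propagate so missing records stay missing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .constants import CONSTANTS, GasSpecies, PhysicalConstants
from .exceptions import InvalidInputError, RangeError

__all__ = [
    "WindObservation",
    "Solubility",
    "TransferVelocity",
    "adjust_wind_to_10m",
    "solubility",
    "schmidt_number",
    "gas_transfer_velocity",
    "sea_air_flux",
]

#: seconds-per-hour / metres-per-centimetre: cm h^-1 -> m s^-1 divisor
_CMH_PER_MS = 3.6e5
#: mg per g times seconds per day: mol m^-2 s^-1 * (g/mol) -> mg m^-2 d^-1
_MG_PER_DAY = 1.0e3 * 86400.0


@dataclass(frozen=True)
class WindObservation:
    """A wind measurement at sensor height ``zu`` (m above the surface)."""

    U: float
    u_star: float
    zu: float

    def __post_init__(self) -> None:
        if self.zu <= 0:
            raise InvalidInputError(f"sensor height zu must be positive, got {self.zu}")
        if self.U < 0 or self.u_star < 0:
            raise InvalidInputError("wind speed and friction velocity must be >= 0")


class Solubility(NamedTuple):
    """Bunsen coefficient (dimensionless) and volumetric solubility
    K0 (mol m^-3 atm^-1) of a gas at given temperature and salinity."""

    beta: float
    K0: float


class TransferVelocity(NamedTuple):
    """Gas transfer (piston) velocity in m s^-1 and cm h^-1."""

    k_ms: float
    k_cmh: float


def adjust_wind_to_10m(
    obs: WindObservation, constants: PhysicalConstants = CONSTANTS
) -> float:
    """Scale a wind measurement to the 10 m reference height.

    Assumes a logarithmic profile with neutral stability:
    ``U10 = U + (u*/kappa) * ln(10/zu)``.  For sensors above 10 m the
    log term is negative and the formula can produce a negative speed at
    very low winds; such results are clamped to 0 with a warning.
    """
    u10 = obs.U + (obs.u_star / constants.kappa) * np.log(10.0 / obs.zu)
    if u10 < 0:
        warnings.warn(
            f"adjusted 10 m wind {u10:.3f} m/s is negative; clamping to 0",
            stacklevel=2,
        )
        u10 = 0.0
    return float(u10)


def _finite(values) -> np.ndarray:
    a = np.atleast_1d(np.asarray(values, dtype=float))
    return a[np.isfinite(a)]


def _check_range(name: str, value, lo: float, hi: float, what: str) -> None:
    finite = _finite(value)
    if finite.size and ((finite < lo).any() or (finite > hi).any()):
        raise RangeError(
            f"{what} outside the fitted validity range [{lo}, {hi}] for {name}"
        )


def solubility(
    gas: GasSpecies,
    T,
    S,
    constants: PhysicalConstants = CONSTANTS,
) -> Solubility:
    """Gas solubility at water temperature ``T`` (kelvin) and salinity
    ``S`` (PSU).

    Evaluates the fitted ln-solubility polynomial
    ``ln(sol) = A1 + A2*(100/T) + A3*ln(T/100)
    + S*[B1 + B2*(T/100) + B3*(T/100)^2]``.
    Depending on the gas's native fit the result is the Bunsen
    coefficient (volume of gas at STP dissolved per volume of water) or
    the volumetric solubility in mol L^-1 atm^-1; both members of the
    returned pair are always populated, related through the ideal-gas
    identity ``K0 = beta / (R * T_STD)``.
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    lo_c, hi_c = gas.solubility_valid_celsius
    _check_range(gas.name, T - 273.15, lo_c, hi_c, "water temperature (degC)")
    _check_range(gas.name, S, 0.0, 40.0, "salinity (PSU)")

    c = gas.solubility_constants
    t100 = T / 100.0
    ln_sol = (
        c["A1"]
        + c["A2"] * (100.0 / T)
        + c["A3"] * np.log(t100)
        + S * (c["B1"] + c["B2"] * t100 + c["B3"] * t100**2)
    )
    sol = np.exp(ln_sol)

    rt = constants.R * constants.T_STD  # m^3 atm mol^-1 at STP
    if gas.solubility_form == "bunsen":
        beta = sol
        k0 = beta / rt  # mol m^-3 atm^-1
    else:  # volumetric fit in mol L^-1 atm^-1
        k0 = sol * 1000.0  # mol m^-3 atm^-1
        beta = k0 * rt
    if beta.ndim == 0:
        return Solubility(float(beta), float(k0))
    return Solubility(beta, k0)


def schmidt_number(
    gas: GasSpecies,
    T,
    S,
    constants: PhysicalConstants = CONSTANTS,
):
    """Schmidt number at water temperature ``T`` (degC) and salinity ``S``.

    Sc is evaluated from the gas's fresh-water (S = 0) and sea-water
    (S = 35) temperature polynomials and linearly interpolated in
    salinity between the two endpoints, the standard treatment for
    brackish sites.  Salinities above the sea-water endpoint would be an
    extrapolation and are refused.
    """
    T = np.asarray(T, dtype=float)
    S = np.asarray(S, dtype=float)
    lo_c, hi_c = gas.sc_valid_celsius
    _check_range(gas.name, T, lo_c, hi_c, "water temperature (degC)")
    _check_range(
        gas.name, S, 0.0, constants.reference_salinity_sea, "salinity (PSU)"
    )

    sc_fresh = np.polynomial.polynomial.polyval(T, gas.sc_coefficients_fresh)
    sc_sea = np.polynomial.polynomial.polyval(T, gas.sc_coefficients_sea)
    sc = sc_fresh + (sc_sea - sc_fresh) * S / constants.reference_salinity_sea
    if sc.ndim == 0:
        return float(sc)
    return sc


def gas_transfer_velocity(
    U10, Sc, constants: PhysicalConstants = CONSTANTS
) -> TransferVelocity:
    """Gas transfer velocity from 10 m wind speed and Schmidt number.

    Uses the quadratic wind-speed parameterisation
    ``k = 0.251 * U10^2 * (Sc/660)^-0.5`` whose coefficient yields k in
    cm h^-1; the m s^-1 value used by the flux equation is derived by
    explicit unit conversion and both are returned.
    """
    U10 = np.asarray(U10, dtype=float)
    Sc = np.asarray(Sc, dtype=float)
    if (_finite(Sc) <= 0).any():
        raise InvalidInputError("Schmidt number must be positive")
    if (_finite(U10) < 0).any():
        raise InvalidInputError("U10 must be >= 0")

    k_cmh = 0.251 * U10**2 * (Sc / constants.sc_reference) ** -0.5
    k_ms = k_cmh / _CMH_PER_MS
    if k_cmh.ndim == 0:
        return TransferVelocity(float(k_ms), float(k_cmh))
    return TransferVelocity(k_ms, k_cmh)


def sea_air_flux(gas: GasSpecies, k_ms, K0, p_sea, p_air):
    """Bulk sea-air flux in mg m^-2 d^-1.

    ``F = k * K0 * (pGas_sea - pGas_air)`` with k in m s^-1, K0 in
    mol m^-3 atm^-1 and partial pressures in microatmospheres, giving a
    molar flux in mol m^-2 s^-1 that is converted to mg m^-2 d^-1 with
    the gas's molar mass.  Positive fluxes are effluxes from the water
    to the atmosphere.  NaN in any data argument yields NaN (missing
    record), it never raises.
    """
    k_ms = np.asarray(k_ms, dtype=float)
    K0 = np.asarray(K0, dtype=float)
    if (_finite(k_ms) < 0).any():
        raise InvalidInputError("gas transfer velocity must be >= 0")
    if (_finite(K0) <= 0).any():
        raise InvalidInputError("K0 must be positive")

    p_sea = np.asarray(p_sea, dtype=float)
    p_air = np.asarray(p_air, dtype=float)
    f_mol = k_ms * K0 * (p_sea - p_air) * 1e-6  # mol m^-2 s^-1
    flux = f_mol * gas.molar_mass * _MG_PER_DAY
    if flux.ndim == 0:
        return float(flux)
    return flux
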