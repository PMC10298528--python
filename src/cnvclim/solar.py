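"""Annual solar radiation at a site from latitude and sunshine fraction.

The estimate follows the classical sunshine-duration route: daily
extraterrestrial irradiation H0 is computed from solar geometry
(declination, sunset hour angle, Sun-Earth distance correction), averaged
over the year using one representative day per month, and scaled by an
annual clearness index Kbar derived from the annual sunshine fraction S.

All angles are handled in radians internally; site latitudes are accepted
in degrees at the table-level API.  Radiation is reported in MJ/m^2/day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SolarConstants",
    "declination",
    "sunset_hour_angle",
    "extraterrestrial_daily",
    "annual_mean_ho",
    "clearness_index",
    "annual_radiation",
    "radiation_table",
]

#: Klein's representative day of each month (day-of-year on which daily H0
#: is closest to the monthly mean).
KLEIN_DAYS: tuple[int, ...] = (17, 47, 75, 105, 135, 162, 198, 228, 258, 288, 318, 344)

_DAYS_PER_YEAR = 365  # fixed-length year; no leap handling


@dataclass(frozen=True)
class SolarConstants:
    """Physical constants of the sunshine-radiation relationship.

    Parameters
    ----------
    gsc:
        Solar constant in W/m^2 (modern satellite value 1361).
    k_clear:
        World-average clear-sky clearness index; the clearness index
        equals ``k_clear`` when the sunshine fraction is 1.
    beta, gamma:
        Empirical constants of the sunshine-clearness relationship
        ``Kbar = k_clear * (beta + (1 - beta) * S**gamma)``.
    representative_days:
        Day-of-year used for each month when averaging H0 over the year.
    kbar_form:
        ``"multiplicative"`` (default) uses the product form above;
        ``"exponent"`` reads the relationship as
        ``Kbar = k_clear**beta + (1 - beta) * S**gamma`` instead.  Both
        coincide at S=1.
    """

    gsc: float = 1361.0
    k_clear: float = 0.7191
    beta: float = 0.1930
    gamma: float = 0.7283
    representative_days: Sequence[int] = field(default=KLEIN_DAYS)
    kbar_form: str = "multiplicative"

    def __post_init__(self) -> None:
        if not self.gsc > 0:
            raise ValueError("solar constant must be positive")
        if not 0 < self.k_clear < 1:
            raise ValueError("clear-sky clearness index must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if not self.gamma > 0:
            raise ValueError("gamma must be positive")
        if len(self.representative_days) != 12:
            raise ValueError("need one representative day per month")
        if self.kbar_form not in ("multiplicative", "exponent"):
            raise ValueError(f"unknown kbar_form {self.kbar_form!r}")


DEFAULT_CONSTANTS = SolarConstants()


def declination(n):
    """Solar declination (radians) on day-of-year ``n``.

    delta = 23.45 * (pi/180) * sin(2*pi*(284 + n)/365)

    ``n`` may be a scalar or array in [1, 365].
    """
    n = np.asarray(n)
    if np.any((n < 1) | (n > _DAYS_PER_YEAR)):
        raise ValueError("day-of-year must lie in [1, 365]")
    out = 23.45 * (math.pi / 180.0) * np.sin(2.0 * math.pi * (284 + n) / _DAYS_PER_YEAR)
    return out if out.ndim else float(out)


def sunset_hour_angle(phi, delta):
    """Sunset hour angle omega_s (radians) at latitude ``phi`` (radians).

    omega_s = acos(-tan(phi) * tan(delta)), with the argument clamped to
    [-1, 1] so polar night yields 0 and polar day yields pi.
    """
    phi = np.asarray(phi, dtype=float)
    if np.any(np.abs(phi) >= math.pi / 2):
        raise ValueError("latitude must satisfy |phi| < pi/2 radians")
    arg = np.clip(-np.tan(phi) * np.tan(np.asarray(delta, dtype=float)), -1.0, 1.0)
    out = np.arccos(arg)
    return out if out.ndim else float(out)


def extraterrestrial_daily(phi, n, constants: SolarConstants = DEFAULT_CONSTANTS):
    """Daily extraterrestrial irradiation H0 in MJ/m^2/day.

    H0 = (86400 * Gsc / pi) * (1 + 0.033 * cos(2*pi*n/365))
         * (cos(phi) cos(delta) sin(omega_s) + omega_s sin(phi) sin(delta))

    evaluated at latitude ``phi`` (radians) on day-of-year ``n``; the
    Joule result is divided by 1e6.  Non-negative everywhere because the
    clamped sunset hour angle zeroes the bracket in polar night.
    """
    phi = np.asarray(phi, dtype=float)
    n_arr = np.asarray(n)
    delta = declination(n_arr)
    ws = sunset_hour_angle(phi, delta)
    orbital = 1.0 + 0.033 * np.cos(2.0 * math.pi * n_arr / _DAYS_PER_YEAR)
    bracket = np.cos(phi) * np.cos(delta) * np.sin(ws) + ws * np.sin(phi) * np.sin(delta)
    joules = (86400.0 * constants.gsc / math.pi) * orbital * np.maximum(bracket, 0.0)
    out = joules / 1e6
    return out if out.ndim else float(out)


def annual_mean_ho(phi, constants: SolarConstants = DEFAULT_CONSTANTS):
    """Annual mean of daily H0 (MJ/m^2/day) at latitude ``phi`` (radians).

    The mean of the 12 monthly values, each evaluated at the month's
    representative day.
    """
    days = np.asarray(constants.representative_days)
    phi = np.asarray(phi, dtype=float)
    monthly = extraterrestrial_daily(phi[..., None] if phi.ndim else phi, days, constants)
    out = np.mean(monthly, axis=-1)
    return out if np.ndim(out) else float(out)


def clearness_index(s, constants: SolarConstants = DEFAULT_CONSTANTS):
    """Annual clearness index Kbar from annual sunshine fraction ``s``.

    Multiplicative form (default): Kbar = k_clear * (beta + (1-beta) * s**gamma).
    Maps [0, 1] monotonically onto [k_clear*beta, k_clear].
    """
    s = np.asarray(s, dtype=float)
    if np.any((s < 0) | (s > 1)):
        raise ValueError("sunshine fraction must lie in [0, 1]")
    c = constants
    if c.kbar_form == "multiplicative":
        out = c.k_clear * (c.beta + (1.0 - c.beta) * s**c.gamma)
    else:
        out = c.k_clear**c.beta + (1.0 - c.beta) * s**c.gamma
    return out if out.ndim else float(out)


def annual_radiation(latitude_deg, sunshine_fraction,
                     constants: SolarConstants = DEFAULT_CONSTANTS):
    """Annual average daily surface radiation Hbar = Kbar * Hbar0 (MJ/m^2/day)."""
    phi = np.deg2rad(np.asarray(latitude_deg, dtype=float))
    out = clearness_index(sunshine_fraction, constants) * annual_mean_ho(phi, constants)
    return out if np.ndim(out) else float(out)


def radiation_table(sites: pd.DataFrame,
                    latitude_col: str = "latitude",
                    sunshine_col: str = "SUN_yearly",
                    constants: SolarConstants = DEFAULT_CONSTANTS) -> pd.DataFrame:
    """Per-site radiation table with columns ``Ho``, ``K`` and ``H``.

    ``sites`` must carry latitude in degrees and an annual sunshine
    fraction in [0, 1]; the returned frame preserves the input index.
    """
    phi = np.deg2rad(sites[latitude_col].to_numpy(dtype=float))
    s = sites[sunshine_col].to_numpy(dtype=float)
    ho = annual_mean_ho(phi, constants)
    k = clearness_index(s, constants)
    return pd.DataFrame({"Ho": ho, "K": k, "H": k * ho}, index=sites.index)
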