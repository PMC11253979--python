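"""Sinusoidal circadian drivers for clock-regulated renal quantities.

Every clock-regulated quantity ``X_p`` (GFR, the apical Na+ transporters
NHE3, SGLT1, NKCC2, NCC, ENaC, and renal blood flow) is modelled as a
sinusoid of zeitgeber time ``t`` (hours since lights-on)::

    X_p(t) = X_p0 * (1 + gamma_p * sin(2*pi*(t + 6 - theta_p) / 24))

where ``X_p0`` is the daily mean, ``gamma_p`` the fractional oscillation
amplitude, and ``theta_p`` the peak time (ZT hours).  For nocturnal rats
ZT0 (lights-on) starts the rest phase and ZT12 the active phase.

Drivers are stored as dimensionless multipliers (mean 1.0); physical means
such as SNGFR live in the modules that consume them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DRIVER_NAMES",
    "SEXES",
    "DriverSpec",
    "wrap_zt",
    "driver_value",
    "default_driver_table",
    "daily_mean",
    "hourly_grid",
    "driver_table_frame",
]

#: Recognised driver identifiers, in table order.
DRIVER_NAMES = ("GFR", "NHE3", "SGLT1", "NKCC2", "NCC", "ENaC", "RBF")

#: Recognised sex labels.
SEXES = ("male", "female")

# (fractional amplitude, peak ZT in hours); identical for both sexes.
_AMPLITUDE_PEAK = {
    "GFR": (0.14, 18.0),
    "NHE3": (0.40, 14.0),
    "SGLT1": (0.20, 14.0),
    "NKCC2": (0.20, 14.0),
    "NCC": (0.20, 14.0),
    "ENaC": (0.56, 14.0),
    "RBF": (0.20, 10.0),
}


def wrap_zt(t):
    """Reduce zeitgeber time(s) to the canonical interval [0, 24)."""
    return np.asarray(t, dtype=float) % 24.0


def hourly_grid() -> np.ndarray:
    """Canonical 24-point hourly evaluation grid over one period."""
    return np.arange(24.0)


@dataclass(frozen=True)
class DriverSpec:
    """One circadian-modulated quantity.

    Parameters
    ----------
    name
        Driver identifier (free-form; the built-in table uses
        :data:`DRIVER_NAMES`).
    mean
        Daily mean ``X_p0`` in the quantity's native units
        (dimensionless multiplier 1.0 by default).
    amplitude_frac
        Fractional oscillation amplitude ``gamma_p`` in [0, 1).
    peak_zt
        Peak time ``theta_p`` in ZT hours, [0, 24).
    """

    name: str
    amplitude_frac: float
    peak_zt: float
    mean: float = 1.0

    def __post_init__(self):
        if not 0.0 <= self.amplitude_frac < 1.0:
            raise ValueError(
                f"amplitude_frac must lie in [0, 1); got {self.amplitude_frac!r} "
                f"for driver {self.name!r}"
            )
        if not 0.0 <= self.peak_zt < 24.0:
            raise ValueError(
                f"peak_zt must lie in [0, 24); got {self.peak_zt!r} for driver {self.name!r}"
            )
        if self.mean <= 0.0:
            raise ValueError(f"mean must be positive; got {self.mean!r}")

    def with_amplitude(self, amplitude_frac: float) -> "DriverSpec":
        """Return a copy with a different fractional amplitude (override hook)."""
        return replace(self, amplitude_frac=float(amplitude_frac))


def driver_value(spec: DriverSpec, t):
    """Evaluate a circadian driver at zeitgeber time(s) ``t`` (hours).

    Returns ``mean * (1 + gamma * sin(2*pi*(t + 6 - theta)/24))``; the maximum
    ``mean*(1+gamma)`` is attained exactly at ``t = theta`` and the minimum
    ``mean*(1-gamma)`` at ``t = theta +/- 12``.  Accepts scalars or arrays.
    """
    t = wrap_zt(t)
    phase = 2.0 * np.pi * (t + 6.0 - spec.peak_zt) / 24.0
    value = spec.mean * (1.0 + spec.amplitude_frac * np.sin(phase))
    if np.ndim(value) == 0:
        return float(value)
    return value


def default_driver_table(sex: str) -> dict[str, DriverSpec]:
    """Built-in driver table for one sex.

    Male and female rats share the same peak times and amplitudes; sex
    differences in mean transporter activity are carried by the transport
    parameters, not the modulation table.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    return {
        name: DriverSpec(name=name, amplitude_frac=amp, peak_zt=peak)
        for name, (amp, peak) in _AMPLITUDE_PEAK.items()
    }


def daily_mean(spec: DriverSpec, grid: Iterable[float]) -> float:
    """Arithmetic mean of a driver over an evaluation grid.

    For any uniform grid of at least two points per 24-h period this equals
    ``spec.mean`` (a sinusoid averages to its mean).
    """
    grid = np.atleast_1d(np.asarray(list(grid), dtype=float))
    if grid.size == 0:
        raise ValueError("daily_mean requires a non-empty grid")
    return float(np.mean(driver_value(spec, grid)))


def driver_table_frame(tables: Mapping[str, Mapping[str, DriverSpec]]) -> pd.DataFrame:
    """Tidy frame of driver tables keyed by sex (columns: name, sex, mean,
    amplitude_frac, peak_zt), suitable for CSV export."""
    rows = [
        {
            "name": spec.name,
            "sex": sex,
            "mean": spec.mean,
            "amplitude_frac": spec.amplitude_frac,
            "peak_zt": spec.peak_zt,
        }
        for sex, table in tables.items()
        for spec in table.values()
    ]
    return pd.DataFrame(rows, columns=["name", "sex", "mean", "amplitude_frac", "peak_zt"])
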