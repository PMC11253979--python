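"""Nephron population, whole-kidney GFR, and filtered Na+ load.

The kidney model distinguishes six nephron classes: one superficial nephron
(two thirds of the population) and five juxtamedullary nephrons reaching 1-5
mm into the inner medulla.  Single-nephron GFR (SNGFR) is 30/45 nl/min for
superficial/juxtamedullary nephrons in male rats and 24/36 nl/min in female
rats, so male kidneys filter 25% more than female kidneys.  The reduced-order
transport chain collapses the classes into one representative nephron with
the population-weighted SNGFR; class metadata is retained for reporting.

Absolute per-kidney outputs additionally depend on the nephron count per
kidney and the plasma Na+ concentration, neither of which enters any of the
ratio/percentage predictions.  Defaults are standard rat values (36,000
nephrons per kidney; plasma Na+ 144 mmol/L) and are overridable.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .drivers import DriverSpec, default_driver_table, driver_value

__all__ = [
    "NephronClass",
    "KidneyScale",
    "nephron_classes",
    "representative_sngfr",
    "whole_kidney_gfr",
    "filtered_na",
    "nephron_table_frame",
]


@dataclass(frozen=True)
class NephronClass:
    label: str                # "superficial" or "jm1".."jm5"
    population_frac: float    # dimensionless; fractions sum to 1
    sngfr: float              # nl/min
    im_depth: float           # mm into the inner medulla (0 for superficial)


@dataclass(frozen=True)
class KidneyScale:
    """Per-kidney scale constants (convention-dependent, see module docs)."""

    nephrons_per_kidney: float = 36_000.0
    plasma_na: float = 144.0  # mmol/L

    def __post_init__(self):
        if self.nephrons_per_kidney <= 0 or self.plasma_na <= 0:
            raise ValueError("KidneyScale fields must be positive")


_SNGFR = {"male": (30.0, 45.0), "female": (24.0, 36.0)}  # (superficial, juxtamedullary) nl/min
_JM_FRACS = (0.4 / 3, 0.3 / 3, 0.15 / 3, 0.1 / 3, 0.05 / 3)


def nephron_classes(sex: str) -> list[NephronClass]:
    """The six nephron classes for one sex."""
    if sex not in _SNGFR:
        raise ValueError(f"unknown sex {sex!r}; expected 'male' or 'female'")
    sup, jm = _SNGFR[sex]
    classes = [NephronClass("superficial", 2.0 / 3.0, sup, 0.0)]
    classes += [
        NephronClass(f"jm{i + 1}", frac, jm, float(i + 1))
        for i, frac in enumerate(_JM_FRACS)
    ]
    return classes


def representative_sngfr(sex: str) -> float:
    """Population-weighted mean SNGFR (nl/min): 35 for males, 28 for females."""
    return float(sum(c.population_frac * c.sngfr for c in nephron_classes(sex)))


def whole_kidney_gfr(sex, t=None, scale: KidneyScale = KidneyScale(),
                     gfr_driver: DriverSpec | None = None):
    """Whole-kidney GFR in mL/min per kidney at zeitgeber time ``t``.

    ``t=None`` evaluates at the daily-mean driver.  Accepts scalar or array t.
    """
    if gfr_driver is None:
        gfr_driver = default_driver_table(sex)["GFR"]
    base = representative_sngfr(sex) * scale.nephrons_per_kidney * 1e-6  # nl -> mL
    if t is None:
        return base * gfr_driver.mean
    return base * driver_value(gfr_driver, t)


def filtered_na(sex, t=None, scale: KidneyScale = KidneyScale(),
                gfr_driver: DriverSpec | None = None):
    """Filtered Na+ load in umol/min per kidney (GFR x plasma [Na+])."""
    return whole_kidney_gfr(sex, t, scale, gfr_driver) * scale.plasma_na


def nephron_table_frame(sex: str) -> pd.DataFrame:
    """Nephron class table for CSV export."""
    rows = [
        {
            "label": c.label,
            "population_frac": c.population_frac,
            "sngfr": c.sngfr,
            "im_depth": c.im_depth,
        }
        for c in nephron_classes(sex)
    ]
    return pd.DataFrame(rows, columns=["label", "population_frac", "sngfr", "im_depth"])
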