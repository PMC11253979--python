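"""Outer-medullary oxygen delivery, shunting, and partial pressure.

The outer-medullary oxygen tension follows a lumped balance::

    pO2 = (D_O2 - X_O2 - Q_O2) / alpha

where D_O2 is the oxygen delivered by the medullary blood flow
(D_O2 = MRBF x CaO2), X_O2 the fraction shunted between descending and
ascending vasa recta (2.6% of delivery), Q_O2 the medullary oxygen
consumption, and ``alpha`` a pressure-conversion factor (umol min^-1
mmHg^-1).  The arterial oxygen content is

    CaO2 = Hb x 1.34 x SaO2 + 0.003 x PaO2   (mL O2 per dL, here per L)

``alpha`` has no independent measurement; it is calibrated per sex so the
daily-mean medullary pO2 equals the reference 22.5 mmHg (midpoint of the
reported 15-30 mmHg range; assumed equal between sexes).  Under
interventions alpha stays at its control value, so pO2 changes are genuine
predictions.  All O2 amounts are kept in umol/min; mL O2 at STP are
converted with 22.4 mL/mmol.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .drivers import DriverSpec, driver_value, hourly_grid

__all__ = [
    "OxygenationParams",
    "OxygenationState",
    "default_oxygenation_params",
    "arterial_o2_content",
    "oxygen_delivery",
    "oxygen_shunt",
    "calibrate_alpha",
    "po2",
    "experimental_po2",
    "medullary_oxygenation",
]

_RBF_DRIVER = DriverSpec(name="RBF", amplitude_frac=0.20, peak_zt=10.0)


@dataclass(frozen=True)
class OxygenationParams:
    """Hemodynamic constants and the calibrated pressure-conversion factor."""

    sex: str
    mrbf_mean: float                  # medullary renal blood flow, mL/min
    hb: float                         # hemoglobin, g/L
    hb_o2_capacity: float = 1.34      # mL O2 per g Hb
    sao2: float = 0.95                # arterial O2 saturation, fraction
    pao2: float = 88.0                # arterial pO2, mmHg
    dissolved_coeff: float = 0.003    # mL O2 per dL blood per mmHg
    shunt_frac: float = 0.026         # fraction of delivery shunted DVR->AVR
    mean_po2_ref: float = 22.5        # calibration reference, mmHg
    o2_molar_volume: float = 22.4     # mL O2 per mmol at STP
    rbf_driver: DriverSpec = _RBF_DRIVER
    alpha: float | None = None        # umol min^-1 mmHg^-1, set by calibrate_alpha

    def __post_init__(self):
        for name in ("mrbf_mean", "hb", "hb_o2_capacity", "sao2", "pao2",
                     "mean_po2_ref", "o2_molar_volume"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 < self.shunt_frac < 1.0:
            raise ValueError("shunt_frac must lie in (0, 1)")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive once calibrated")


@dataclass(frozen=True)
class OxygenationState:
    """Delivery/shunt/consumption balance and pO2 at one zeitgeber time."""

    sex: str
    zt: float
    do2: float       # umol/min
    xo2: float       # umol/min
    qo2_med: float   # umol/min
    po2: float       # mmHg


_SEX_DEFAULTS = {"male": (2.26, 146.0), "female": (1.81, 141.0)}


def default_oxygenation_params(sex: str) -> OxygenationParams:
    """Built-in hemodynamic parameters (MRBF 2.26/1.81 mL/min and Hb 146/141
    g/L for male/female rats); ``alpha`` is left uncalibrated."""
    if sex not in _SEX_DEFAULTS:
        raise ValueError(f"unknown sex {sex!r}")
    mrbf, hb = _SEX_DEFAULTS[sex]
    return OxygenationParams(sex=sex, mrbf_mean=mrbf, hb=hb)


def arterial_o2_content(params: OxygenationParams) -> float:
    """Arterial O2 content CaO2 in mL O2 per litre of blood (bound +
    dissolved; the dissolved per-dL coefficient is converted to per-L)."""
    bound = params.hb * params.hb_o2_capacity * params.sao2
    dissolved = params.dissolved_coeff * params.pao2 * 10.0  # per dL -> per L
    return bound + dissolved


def oxygen_delivery(params: OxygenationParams, t=None):
    """Medullary O2 delivery D_O2 in umol/min at zeitgeber time(s) ``t``
    (``None`` = daily-mean blood flow)."""
    cao2_per_ml = arterial_o2_content(params) / 1000.0  # mL O2 per mL blood
    rbf = params.rbf_driver.mean if t is None else driver_value(params.rbf_driver, t)
    do2_ml = params.mrbf_mean * rbf * cao2_per_ml       # mL O2/min
    return do2_ml / params.o2_molar_volume * 1000.0     # -> umol/min


def oxygen_shunt(params: OxygenationParams, do2):
    """O2 shunted between descending and ascending vasa recta (umol/min)."""
    do2 = np.asarray(do2, dtype=float)
    if np.any(do2 < 0):
        raise ValueError("oxygen delivery must be non-negative")
    out = params.shunt_frac * do2
    return float(out) if np.ndim(out) == 0 else out


def calibrate_alpha(params: OxygenationParams, qo2_med_profile,
                    grid=None) -> OxygenationParams:
    """Calibrate the pressure-conversion factor ``alpha``.

    ``qo2_med_profile`` is the control medullary QO2 (umol/min) evaluated on
    ``grid`` (hourly by default).  ``alpha`` is chosen as the daily mean of
    ``(D_O2 - X_O2 - Q_O2)`` divided by the reference mean pO2, which makes
    the daily-mean pO2 equal the reference exactly for each sex.
    """
    grid = hourly_grid() if grid is None else np.asarray(grid, dtype=float)
    qo2 = np.asarray(qo2_med_profile, dtype=float)
    if qo2.shape != grid.shape:
        raise ValueError("qo2_med_profile and grid must have matching shapes")
    do2 = oxygen_delivery(params, grid)
    numerator = do2 - oxygen_shunt(params, do2) - qo2
    mean_num = float(np.mean(numerator))
    if mean_num <= 0:
        raise ValueError(
            "mean medullary O2 balance is non-positive; the transport model is "
            "inconsistent with the oxygenation parameters"
        )
    return replace(params, alpha=mean_num / params.mean_po2_ref)


def po2(params: OxygenationParams, t, qo2_med):
    """Outer-medullary pO2 (mmHg) at time(s) ``t`` for a given medullary QO2.

    Linear in ``qo2_med`` with slope exactly ``-1/alpha``.
    """
    if params.alpha is None:
        raise ValueError("alpha is not calibrated; run calibrate_alpha first")
    do2 = oxygen_delivery(params, t)
    out = (do2 - oxygen_shunt(params, do2) - np.asarray(qo2_med, dtype=float)) / params.alpha
    return float(out) if np.ndim(out) == 0 else out


def experimental_po2(t, mean: float = 22.5, amplitude_frac: float = 0.08,
                     peak_zt: float = 13.0):
    """Experimental outer-medullary pO2 sinusoid (mean 22.5 mmHg, 8%
    amplitude, peak ZT13), used as the measured comparator."""
    spec = DriverSpec(name="pO2_exp", mean=mean, amplitude_frac=amplitude_frac,
                      peak_zt=peak_zt)
    return driver_value(spec, t)


def medullary_oxygenation(sex, ts, intervention=None, model=None, scale=None,
                          params: OxygenationParams | None = None) -> list[OxygenationState]:
    """Medullary oxygen balance states over zeitgeber times ``ts``.

    ``alpha`` is always calibrated on the control (no-intervention) hourly
    medullary QO2 profile, also when an intervention is simulated, so treated
    pO2 values are predictions rather than re-anchored quantities.
    """
    from .nephron import KidneyScale
    from .transport import REGION_SEGMENTS, simulate_profile

    scale = KidneyScale() if scale is None else scale
    if params is None:
        params = default_oxygenation_params(sex)
    ts = np.atleast_1d(np.asarray(ts, dtype=float))

    def med_qo2(sim):
        return (sum(sim["qo2_active"][s] for s in REGION_SEGMENTS["medulla"])
                + sum(sim["qo2_basal"][s] for s in REGION_SEGMENTS["medulla"]))

    if params.alpha is None:
        control_hourly = simulate_profile(sex, hourly_grid(), model=model, scale=scale)
        params = calibrate_alpha(params, med_qo2(control_hourly))

    sim = simulate_profile(sex, ts, intervention=intervention, model=model, scale=scale)
    qo2 = med_qo2(sim)
    do2 = np.atleast_1d(oxygen_delivery(params, ts))
    xo2 = np.atleast_1d(oxygen_shunt(params, do2))
    p = np.atleast_1d(po2(params, ts, qo2))
    return [
        OxygenationState(sex=sex, zt=float(ts[i] % 24.0), do2=float(do2[i]),
                         xo2=float(xo2[i]), qo2_med=float(qo2[i]), po2=float(p[i]))
        for i in range(ts.size)
    ]
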