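"""Oxygen consumption from active Na+ transport, basal allocation, efficiency.

Active Na+ reabsorption through the basolateral Na-K-ATPase costs one mole
of O2 per 15 moles of Na+ (3 Na+ per ATP, 5 ATP per O2)::

    QO2_active = T_Na_active / 15

On top of that, a fixed basal consumption covers other transport processes
and intracellular metabolism; at baseline (all circadian drivers at their
daily means) it equals 25% of total QO2, i.e. QO2_basal = (1/3) QO2_active*.
The basal part is allocated per segment proportionally to the segment's
baseline active QO2 (which preserves the 25% whole-kidney split and keeps
regional aggregation well defined) and does not vary with time of day.

Transport efficiency is the number of moles of Na+ reabsorbed per mole of
O2 consumed, T_Na_total / QO2_total; passive (paracellular) transport costs
no ATP, so passive-rich segments are more efficient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "NA_PER_O2",
    "BASAL_FRACTION",
    "BASAL_OVER_ACTIVE_STAR",
    "qo2_active",
    "basal_allocation",
    "efficiency",
    "BaselineReference",
    "baseline_reference",
    "OxygenBudget",
    "kidney_oxygen",
    "oxygen_frame",
]

#: Moles of Na+ reabsorbed per mole of O2 consumed by the Na-K-ATPase route.
NA_PER_O2 = 15.0

#: Basal share of total QO2 at baseline (whole kidney); overridable in
#: :func:`basal_allocation` (reported range ~25-30%).
BASAL_FRACTION = 0.25

#: QO2_basal / QO2_active* implied by the basal fraction: f/(1-f).
BASAL_OVER_ACTIVE_STAR = BASAL_FRACTION / (1.0 - BASAL_FRACTION)


def qo2_active(tna_active):
    """Active O2 consumption (umol O2/min) for an active Na+ flux (umol/min)."""
    tna_active = np.asarray(tna_active, dtype=float)
    if np.any(tna_active < 0):
        raise ValueError("active Na+ transport must be non-negative")
    out = tna_active / NA_PER_O2
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class BaselineReference:
    """Per-segment active T_Na and QO2 at baseline (drivers at their means).

    Must be recomputed whenever the calibrated parameters change.
    """

    sex: str
    tna_active: Mapping[str, float]   # umol Na+/min per segment
    qo2_active: Mapping[str, float]   # umol O2/min per segment

    @property
    def qo2_active_total(self) -> float:
        return float(sum(self.qo2_active.values()))


def baseline_reference(baseline_state) -> BaselineReference:
    """Build the baseline (starred) reference from a kidney state simulated
    at mean drivers (``simulate_kidney(sex, t=None, ...)``)."""
    if baseline_state.zt is not None:
        raise ValueError("baseline reference requires a state at mean drivers (zt=None)")
    tna = {seg: fl.na_active for seg, fl in baseline_state.flows.items()}
    return BaselineReference(
        sex=baseline_state.sex,
        tna_active=tna,
        qo2_active={seg: v / NA_PER_O2 for seg, v in tna.items()},
    )


def basal_allocation(baseline: BaselineReference,
                     basal_fraction: float = BASAL_FRACTION) -> dict[str, float]:
    """Fixed per-segment basal QO2 (umol O2/min), time-invariant.

    Each segment receives ``(f/(1-f))`` of its own baseline active QO2, so
    the whole-kidney basal/total ratio at baseline is exactly ``f``.
    """
    if baseline is None:
        raise ValueError("baseline reference is required for the basal allocation")
    if not 0.0 <= basal_fraction < 1.0:
        raise ValueError("basal_fraction must lie in [0, 1)")
    ratio = basal_fraction / (1.0 - basal_fraction)
    return {seg: ratio * q for seg, q in baseline.qo2_active.items()}


def efficiency(tna_total, qo2_total) -> float:
    """Na+ transport efficiency: mol Na+ reabsorbed per mol O2 consumed."""
    if qo2_total <= 0:
        raise ZeroDivisionError("efficiency undefined for non-positive QO2")
    return tna_total / qo2_total


@dataclass(frozen=True)
class OxygenBudget:
    """Segmental/regional/whole-kidney O2 consumption at one zeitgeber time."""

    sex: str
    zt: float | None
    intervention: str
    qo2_active: Mapping[str, float]     # per segment, umol O2/min
    qo2_basal: Mapping[str, float]
    qo2_total: Mapping[str, float]
    regional: Mapping[str, Mapping[str, float]]  # cortex/medulla/whole -> active/basal/total
    efficiency: Mapping[str, float]     # per segment/region/whole (NaN where QO2 = 0)


def kidney_oxygen(state, baseline: BaselineReference,
                  basal_fraction: float = BASAL_FRACTION) -> OxygenBudget:
    """Oxygen budget of a simulated kidney state.

    ``state`` is a :class:`~circakidney.transport.KidneyState`; ``baseline``
    must come from the same calibrated parameters and sex.
    """
    from .transport import REGION_SEGMENTS, SEGMENT_GROUPS  # local: avoids cycle

    if set(state.flows) != set(baseline.qo2_active):
        raise ValueError("segment map of state and baseline reference differ")
    if state.sex != baseline.sex:
        raise ValueError("state and baseline reference are for different sexes")

    active = {seg: qo2_active(fl.na_active) for seg, fl in state.flows.items()}
    basal = basal_allocation(baseline, basal_fraction)
    total = {seg: active[seg] + basal[seg] for seg in active}

    regional = {}
    for region, segs in REGION_SEGMENTS.items():
        regional[region] = {
            "active": sum(active[s] for s in segs),
            "basal": sum(basal[s] for s in segs),
            "total": sum(total[s] for s in segs),
        }
    regional["whole"] = {
        k: regional["cortex"][k] + regional["medulla"][k] for k in ("active", "basal", "total")
    }

    eff = {}
    for seg, fl in state.flows.items():
        eff[seg] = fl.na_total / total[seg] if total[seg] > 0 else float("nan")
    for group, segs in SEGMENT_GROUPS.items():
        tna = sum(state.flows[s].na_total for s in segs)
        q = sum(total[s] for s in segs)
        eff[group] = tna / q if q > 0 else float("nan")
    for region, segs in REGION_SEGMENTS.items():
        tna = sum(state.flows[s].na_total for s in segs)
        eff[region] = tna / regional[region]["total"]
    tna_whole = sum(fl.na_total for fl in state.flows.values())
    eff["whole"] = tna_whole / regional["whole"]["total"]

    return OxygenBudget(
        sex=state.sex, zt=state.zt, intervention=state.intervention,
        qo2_active=active, qo2_basal=basal, qo2_total=total,
        regional=regional, efficiency=eff,
    )


def oxygen_frame(budget: OxygenBudget) -> pd.DataFrame:
    """Tidy export: one row per segment and region with qo2_active, qo2_basal,
    qo2_total (umol O2/min) and efficiency (mol Na+/mol O2)."""
    zt = np.nan if budget.zt is None else budget.zt
    rows = [
        {
            "sex": budget.sex, "zt": zt, "intervention": budget.intervention,
            "segment": seg, "qo2_active": budget.qo2_active[seg],
            "qo2_basal": budget.qo2_basal[seg], "qo2_total": budget.qo2_total[seg],
            "efficiency": budget.efficiency[seg],
        }
        for seg in budget.qo2_active
    ]
    for region, agg in budget.regional.items():
        rows.append({
            "sex": budget.sex, "zt": zt, "intervention": budget.intervention,
            "segment": region, "qo2_active": agg["active"], "qo2_basal": agg["basal"],
            "qo2_total": agg["total"], "efficiency": budget.efficiency[region],
        })
    return pd.DataFrame(rows)
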