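"""Scenario configuration, tabular output, and test-fixture generation.

Scenarios are described by a small TOML file (key = value, nested sections)
selecting sexes, zeitgeber times, an intervention, and optional parameter
overrides.  Unknown keys are a hard error.  Example::

    sexes = ["male", "female"]
    zt = [2, 6, 14, 18]

    [intervention]
    kind = "loop_diuretic"

    [overrides.drivers.RBF]
    amplitude_frac = 0.40

    [overrides.oxygenation]
    mean_po2_ref = 25.0

Outputs are tidy RFC-4180 CSVs (UTF-8, '.' decimal separator) with a unit
header comment; all flow quantities are per kidney.
"""

from __future__ import annotations

import io
import tomllib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import transport
from .drivers import DriverSpec, default_driver_table
from .interventions import InterventionSpec, compare_scenarios, comparison_frame
from .nephron import KidneyScale
from .oxygen import baseline_reference, kidney_oxygen, oxygen_frame
from .oxygenation import default_oxygenation_params
from .transport import (CalibratedModel, CalibrationTarget, compute_metrics,
                        model_from_vector, model_to_vector, parameter_bounds,
                        simulate_kidney, state_frame)

__all__ = [
    "ScenarioConfig",
    "load_config",
    "run_scenario",
    "FixtureSet",
    "generate_fixtures",
]

DEFAULT_ZT = (2.0, 6.0, 14.0, 18.0)


@dataclass(frozen=True)
class ScenarioConfig:
    """A validated simulation scenario."""

    sexes: tuple[str, ...] = ("male", "female")
    zt: tuple[float, ...] = DEFAULT_ZT
    intervention: InterventionSpec = InterventionSpec()
    driver_overrides: dict = field(default_factory=dict)       # name -> field -> value
    oxygenation_overrides: dict = field(default_factory=dict)  # field -> value
    scale: KidneyScale = KidneyScale()
    output_dir: Path | None = None

    def __post_init__(self):
        for s in self.sexes:
            if s not in ("male", "female"):
                raise ValueError(f"unknown sex {s!r}")
        for t in self.zt:
            if not 0.0 <= t < 24.0:
                raise ValueError(f"zt values must lie in [0, 24); got {t!r}")

    def driver_tables(self) -> dict[str, dict[str, DriverSpec]]:
        tables = {sex: dict(default_driver_table(sex)) for sex in self.sexes}
        for name, fields in self.driver_overrides.items():
            for sex in self.sexes:
                tables[sex][name] = replace(tables[sex][name], **fields)
        return tables

    def oxygenation_params(self, sex):
        return replace(default_oxygenation_params(sex), **self.oxygenation_overrides)


_TOP_KEYS = {"sexes", "zt", "intervention", "overrides", "output_dir", "scale"}
_DRIVER_FIELDS = {"mean", "amplitude_frac", "peak_zt"}
_OX_FIELDS = {
    "mrbf_mean", "hb", "hb_o2_capacity", "sao2", "pao2", "dissolved_coeff",
    "shunt_frac", "mean_po2_ref", "o2_molar_volume",
}
_INT_FIELDS = {"kind", "inhibition_dark", "inhibition_light", "enac_inhibition", "efficacy"}
_SCALE_FIELDS = {"nephrons_per_kidney", "plasma_na"}


def load_config(path) -> ScenarioConfig:
    """Parse and validate a scenario TOML file.  Unknown keys are rejected."""
    raw = tomllib.loads(Path(path).read_text())
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")

    kwargs = {}
    if "sexes" in raw:
        kwargs["sexes"] = tuple(raw["sexes"])
    if "zt" in raw:
        kwargs["zt"] = tuple(float(t) for t in raw["zt"])
    if "intervention" in raw:
        sec = raw["intervention"]
        bad = set(sec) - _INT_FIELDS
        if bad:
            raise ValueError(f"unknown intervention key(s): {sorted(bad)}")
        kwargs["intervention"] = InterventionSpec(**sec)
    if "scale" in raw:
        sec = raw["scale"]
        bad = set(sec) - _SCALE_FIELDS
        if bad:
            raise ValueError(f"unknown scale key(s): {sorted(bad)}")
        kwargs["scale"] = KidneyScale(**sec)
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])

    overrides = raw.get("overrides", {})
    bad = set(overrides) - {"drivers", "oxygenation"}
    if bad:
        raise ValueError(f"unknown overrides section(s): {sorted(bad)}")
    driver_over = {}
    for name, fields in overrides.get("drivers", {}).items():
        if name not in default_driver_table("male"):
            raise ValueError(f"unknown driver {name!r}")
        badf = set(fields) - _DRIVER_FIELDS
        if badf:
            raise ValueError(f"unknown driver field(s) for {name}: {sorted(badf)}")
        # validation of ranges happens in DriverSpec
        replace(default_driver_table("male")[name], **fields)
        driver_over[name] = dict(fields)
    ox_over = dict(overrides.get("oxygenation", {}))
    badf = set(ox_over) - _OX_FIELDS
    if badf:
        raise ValueError(f"unknown oxygenation field(s): {sorted(badf)}")
    return ScenarioConfig(driver_overrides=driver_over, oxygenation_overrides=ox_over,
                          **kwargs)


def _write_csv(frame: pd.DataFrame, path: Path, unit_comment: str) -> None:
    buf = io.StringIO()
    buf.write(f"# {unit_comment}\n")
    frame.to_csv(buf, index=False, float_format="%.10g", lineterminator="\n")
    path.write_text(buf.getvalue())


def run_scenario(config: ScenarioConfig, model: CalibratedModel | None = None,
                 output_dir=None) -> dict[str, pd.DataFrame]:
    """Simulate a scenario and return (and optionally write) tidy tables.

    Returns a dict with ``transport`` and ``oxygen`` frames and, when the
    scenario has an intervention, a ``comparison`` frame.  With an output
    directory the frames are written as ``transport.csv``, ``oxygen.csv``,
    ``comparison.csv``; repeated runs of one config are byte-identical.
    """
    model = transport._resolve_model(model)
    interv = config.intervention if config.intervention.kind != "none" else None

    t_rows, o_rows, comps = [], [], []
    for sex in config.sexes:
        baseline = baseline_reference(simulate_kidney(sex, None, model=model,
                                                      scale=config.scale))
        for t in config.zt:
            state = simulate_kidney(sex, t, intervention=interv, model=model,
                                    scale=config.scale)
            t_rows.append(state_frame(state))
            o_rows.append(oxygen_frame(kidney_oxygen(state, baseline)))
            if interv is not None:
                comps.extend(compare_scenarios(sex, t, interv, model=model,
                                               scale=config.scale))

    out = {
        "transport": pd.concat(t_rows, ignore_index=True),
        "oxygen": pd.concat(o_rows, ignore_index=True),
    }
    if comps:
        out["comparison"] = comparison_frame(comps)

    output_dir = output_dir or config.output_dir
    if output_dir is not None:
        output_dir = Path(output_dir)
        output_dir.mkdir(parents=True, exist_ok=True)
        _write_csv(out["transport"], output_dir / "transport.csv",
                   "Na+ flows in umol/min, volumes in uL/min; per kidney")
        _write_csv(out["oxygen"], output_dir / "oxygen.csv",
                   "QO2 in umol O2/min, efficiency in mol Na+/mol O2; per kidney")
        if "comparison" in out:
            _write_csv(out["comparison"], output_dir / "comparison.csv",
                       "QO2 umol O2/min, pO2 mmHg, urine Na+ umol/min, volume uL/min; per kidney")
    return out


# --------------------------------------------------------------------------
# fixtures for property and recovery tests
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSet:
    """Reproducible collection of perturbed parameter sets and surrogate
    calibration registries (forward-simulated from known parameters)."""

    seed: int
    models: tuple[CalibratedModel, ...]
    surrogates: tuple[tuple[CalibratedModel, tuple[CalibrationTarget, ...]], ...]


#: Metric ids used for surrogate registries in beta-recovery tests; these are
#: the metrics with strong sensitivity to the activity exponents.
RECOVERY_IDS = tuple(
    [f"swing_{g}_{sex}" for sex in ("male", "female") for g in ("pt", "tal", "dt")]
    + [f"qo2_swing_{r}_{sex}" for sex in ("male", "female")
       for r in ("whole", "cortex", "medulla")]
    + [f"cnt_na_zt0_vs_zt12_{sex}" for sex in ("male", "female")]
)


def generate_fixtures(seed: int, n_models: int = 20, n_surrogates: int = 3) -> FixtureSet:
    """Seeded fixture generation.

    ``models`` are random-but-valid parameter sets (bounds-respecting
    perturbations of the documented initial point) for conservation and
    monotonicity property tests; ``surrogates`` pair a known ("true") model
    with a registry of its own forward-simulated metric values, for
    parameter-recovery tests.
    """
    rng = np.random.default_rng(seed)
    lo, hi = parameter_bounds()
    x0 = model_to_vector(transport.default_initial_model())

    def perturbed(rel):
        x = x0 * rng.uniform(1.0 - rel, 1.0 + rel, size=x0.shape)
        return model_from_vector(np.clip(x, lo, hi))

    models = tuple(perturbed(0.35) for _ in range(n_models))

    surrogates = []
    for _ in range(n_surrogates):
        truth = perturbed(0.15)
        metrics = compute_metrics(truth, ids=RECOVERY_IDS)
        registry = tuple(
            CalibrationTarget(id=i, printed=metrics[i], weight=1.0, kind="pct_change")
            for i in RECOVERY_IDS
        )
        surrogates.append((truth, registry))
    return FixtureSet(seed=seed, models=models, surrogates=tuple(surrogates))
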