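"""Scenario presets, configuration loading, and report generation.

Four design scenarios probe how electrode layout and operating potential
shape HOCl dosimetry along the catheter:

* **scenario1** — WE and CE in the hub only, WE at 1.5 V vs Ag/AgCl and CE
  at -0.6 V, 48 h constant polarization.  Protects the hub, the usual
  entry point of intraluminal contamination.
* **scenario1_relax** — scenario 1 followed by 120 h at open circuit, to
  watch post-polarization diffusion and decay of the accumulated HOCl.
* **scenario2_1.7V / scenario2_1.9V** — scenario 1 with the WE potential
  raised, boosting the oxidation overpotential.
* **scenario3** — the WE wire extended through the connectors and the full
  0.3 m tube (diameter unchanged), generating HOCl along the whole lumen.
* **scenario4** — the extended WE with its diameter enlarged in the hub
  (6.15e-4 m) and reduced in the connector/tube (0.54e-4 m) so that both
  regions see the same wire-surface-to-fluid-volume ratio.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import chemistry as chem
from .chemistry import ChemistryParams, ReactionNetwork, initial_composition
from .constants import HOUR, T_HUB_DEFAULT, T_TUBE_DEFAULT
from .electrodes import counter_electrode, working_electrode
from .geometry import DEFAULT_CELLS, Segment, build_grid
from .oracles import conservation_audit
from .solver import Phase, Schedule, SimulationResult, integrate, ph_field

__all__ = [
    "ScenarioConfig",
    "SCENARIOS",
    "default_config",
    "scenario_config",
    "load_config",
    "run_scenario",
    "run_config",
]


class ConfigError(ValueError):
    """Invalid or inconsistent configuration input."""


_SEGMENT_NAMES = ("hub", "luer_top", "luer_bottom", "tube")


@dataclass
class ScenarioConfig:
    """Full model configuration with the parameter-table defaults.

    ``we_diameters`` maps segment name to the WE wire diameter there (m,
    absent segments carry no wire); likewise ``ce_diameters`` for the CE.
    """

    name: str = "custom"
    # geometry (m / K)
    segment_lengths: dict = field(default_factory=lambda: {
        "hub": 3.26e-2, "luer_top": 6.4e-3, "luer_bottom": 1.22e-2, "tube": 0.3})
    segment_diameters: dict = field(default_factory=lambda: {
        "hub": 5.4e-3, "luer_top": 4.0e-3, "luer_bottom": 1.6e-3, "tube": 1.6e-3})
    segment_temperatures: dict = field(default_factory=lambda: {
        "hub": T_HUB_DEFAULT, "luer_top": T_HUB_DEFAULT,
        "luer_bottom": T_HUB_DEFAULT, "tube": T_TUBE_DEFAULT})
    we_diameters: dict = field(default_factory=lambda: {"hub": 2.45e-4})
    ce_diameters: dict = field(default_factory=lambda: {"hub": 2.45e-4})
    # electrochemistry
    E0_we: float = 1.297          # V vs Ag/AgCl
    E0_ce: float = -0.197
    i0_we: float = 0.032          # A/m^2
    i0_ce: float = 0.003
    alpha_we: float = 0.95
    alpha_ce: float = 0.05
    we_potential: float = 1.5     # V vs Ag/AgCl
    ce_potential: float = -0.6
    # initial electrolyte
    pH0: float = 5.5
    C0_NaCl: float = 154.04       # mol/m^3
    # schedule / output
    polarization_hours: float = 48.0
    relaxation_hours: float = 0.0
    snapshot_hours: tuple = (0, 8, 16, 24, 32, 40, 48)
    # numerics
    cells_per_segment: dict = field(default_factory=lambda: dict(DEFAULT_CELLS))
    rtol: float = 1e-6
    atol: float = 1e-9
    chemistry: ChemistryParams = field(default_factory=ChemistryParams)

    def validate(self):
        for mapping, what in (
            (self.segment_lengths, "segment length"),
            (self.segment_diameters, "segment diameter"),
        ):
            for seg in _SEGMENT_NAMES:
                if mapping.get(seg, 0) <= 0:
                    raise ConfigError(f"{what} for {seg!r} must be positive")
        for role, diams in (("we_diameters", self.we_diameters),
                            ("ce_diameters", self.ce_diameters)):
            for seg, d in diams.items():
                if seg not in _SEGMENT_NAMES:
                    raise ConfigError(f"{role}: unknown segment {seg!r}")
                if d <= 0:
                    raise ConfigError(f"{role}[{seg!r}] must be positive")
                if d >= self.segment_diameters[seg]:
                    raise ConfigError(
                        f"{role}[{seg!r}] = {d} does not fit the lumen")
        if not (0 < self.pH0 < 14):
            raise ConfigError(f"pH0 = {self.pH0} outside (0, 14)")
        if self.C0_NaCl <= 0:
            raise ConfigError("C0_NaCl must be positive")
        if self.polarization_hours < 0 or self.relaxation_hours < 0:
            raise ConfigError("schedule durations must be nonnegative")
        if self.polarization_hours + self.relaxation_hours <= 0:
            raise ConfigError("schedule has zero total duration")
        for seg, n in self.cells_per_segment.items():
            if seg not in _SEGMENT_NAMES:
                raise ConfigError(f"cells_per_segment: unknown segment {seg!r}")
            if int(n) < 2:
                raise ConfigError(f"cells_per_segment[{seg!r}] must be >= 2")
        horizon = self.polarization_hours + self.relaxation_hours
        if max(self.snapshot_hours) > horizon + 1e-9:
            raise ConfigError("snapshots extend past the schedule")
        return self

    # -- assembly ---------------------------------------------------------

    def segments(self) -> list[Segment]:
        return [
            Segment(
                name=seg,
                length=self.segment_lengths[seg],
                diameter=self.segment_diameters[seg],
                temperature=self.segment_temperatures[seg],
                d_we=self.we_diameters.get(seg, 0.0),
                d_ce=self.ce_diameters.get(seg, 0.0),
            )
            for seg in _SEGMENT_NAMES
        ]

    def build(self):
        """Grid, reaction network, electrodes, schedule, snapshot times."""
        self.validate()
        grid = build_grid(self.segments(), self.cells_per_segment,
                          self.chemistry.D298)
        network = ReactionNetwork(self.chemistry)
        electrodes = (
            working_electrode(self.we_potential, self.E0_we, self.i0_we,
                              self.alpha_we),
            counter_electrode(self.ce_potential, self.E0_ce, self.i0_ce,
                              self.alpha_ce),
        )
        phases = []
        if self.polarization_hours > 0:
            phases.append(Phase(0.0, self.polarization_hours * HOUR,
                                self.we_potential, self.ce_potential))
        if self.relaxation_hours > 0:
            t0 = self.polarization_hours * HOUR
            phases.append(Phase(t0, t0 + self.relaxation_hours * HOUR))
        schedule = Schedule(phases)
        snapshots = np.asarray(self.snapshot_hours, dtype=float) * HOUR
        return grid, network, electrodes, schedule, snapshots

    def to_dict(self) -> dict:
        d = asdict(self)
        d["snapshot_hours"] = list(self.snapshot_hours)
        return d


def default_config() -> ScenarioConfig:
    return ScenarioConfig(name="scenario1")


def _hourly(last: float) -> tuple:
    return tuple(range(0, int(last) + 1))


def scenario_config(name: str) -> ScenarioConfig:
    """Preset configuration for a named scenario."""
    key = name.lower().replace(" ", "").replace("-", "_")
    if key in ("scenario1", "s1"):
        return ScenarioConfig(name="scenario1")
    if key in ("scenario1_relax", "s1_relax", "relax"):
        return ScenarioConfig(
            name="scenario1_relax",
            relaxation_hours=120.0,
            snapshot_hours=(0, 8, 16, 24, 32, 40, 48, 72, 96, 120, 144, 168),
        )
    if key in ("scenario2_1.7v", "scenario2_17", "s2_17"):
        return ScenarioConfig(name="scenario2_1.7V", we_potential=1.7)
    if key in ("scenario2_1.9v", "scenario2_19", "s2_19"):
        return ScenarioConfig(name="scenario2_1.9V", we_potential=1.9)
    if key in ("scenario3", "s3"):
        return ScenarioConfig(
            name="scenario3",
            we_diameters={"hub": 2.45e-4, "luer_top": 2.45e-4,
                          "luer_bottom": 2.45e-4, "tube": 2.45e-4},
            snapshot_hours=_hourly(48),
        )
    if key in ("scenario4", "s4"):
        return ScenarioConfig(
            name="scenario4",
            we_diameters={"hub": 6.15e-4, "luer_top": 0.54e-4,
                          "luer_bottom": 0.54e-4, "tube": 0.54e-4},
            snapshot_hours=_hourly(48),
        )
    raise ConfigError(f"unknown scenario {name!r}")


SCENARIOS = (
    "scenario1",
    "scenario1_relax",
    "scenario2_1.7V",
    "scenario2_1.9V",
    "scenario3",
    "scenario4",
)

# YAML keys accepted by load_config, mapped onto ScenarioConfig fields.
_SCALAR_KEYS = {
    "name", "E0_we", "E0_ce", "i0_we", "i0_ce", "alpha_we", "alpha_ce",
    "we_potential", "ce_potential", "pH0", "C0_NaCl",
    "polarization_hours", "relaxation_hours", "rtol", "atol",
}
_DICT_KEYS = {
    "segment_lengths", "segment_diameters", "segment_temperatures",
    "we_diameters", "ce_diameters", "cells_per_segment",
}
_CHEMISTRY_KEYS = {f.name for f in ChemistryParams.__dataclass_fields__.values()}


def load_config(path) -> ScenarioConfig:
    """Load and validate a YAML configuration file.

    An empty file yields the full default (scenario 1) configuration.  A
    ``scenario`` key selects a preset as the base; any other recognized
    key overrides the base value.  Unknown keys, out-of-range values and
    inconsistent geometry raise :class:`ConfigError`.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration root must be a mapping")
    base = raw.pop("scenario", None)
    cfg = scenario_config(base) if base else default_config()
    chem_over = raw.pop("chemistry", {}) or {}
    if not isinstance(chem_over, dict):
        raise ConfigError("'chemistry' must be a mapping")
    for key, value in chem_over.items():
        if key not in _CHEMISTRY_KEYS:
            raise ConfigError(f"unknown chemistry key {key!r}")
        setattr(cfg.chemistry, key, value)
    snapshots = raw.pop("snapshot_hours", None)
    if snapshots is not None:
        cfg.snapshot_hours = tuple(float(s) for s in snapshots)
    for key, value in raw.items():
        if key in _SCALAR_KEYS:
            setattr(cfg, key, value)
        elif key in _DICT_KEYS:
            if not isinstance(value, dict):
                raise ConfigError(f"{key!r} must be a mapping")
            merged = dict(getattr(cfg, key))
            if key in ("we_diameters", "ce_diameters"):
                merged = dict(value)  # wire layout replaces, not merges
            else:
                merged.update(value)
            setattr(cfg, key, merged)
        else:
            raise ConfigError(f"unknown configuration key {key!r}")
    cfg.validate()
    return cfg


def run_config(cfg: ScenarioConfig, output_dir=None) -> SimulationResult:
    """Run a configuration; optionally write reports to ``output_dir``."""
    grid, network, electrodes, schedule, snapshots = cfg.build()
    c0 = initial_composition(cfg.pH0, cfg.C0_NaCl, cfg.chemistry)
    result = integrate(
        c0, grid, network, electrodes=electrodes, schedule=schedule,
        snapshots=snapshots, rtol=cfg.rtol, atol=cfg.atol,
    )
    if output_dir is not None:
        write_reports(cfg, result, output_dir)
    return result


def run_scenario(name: str, output_dir=None) -> SimulationResult:
    """Run a named scenario preset (see :data:`SCENARIOS`)."""
    return run_config(scenario_config(name), output_dir)


def summarize(cfg: ScenarioConfig, result: SimulationResult) -> dict:
    """Headline quantities of a run: extrema, locations, final pH, charge."""
    t_final = float(result.times[-1])
    final = result.fields[-1]
    hocl = final[chem.I_HOCL]  # mol/m^3 == mM numerically
    k_max = int(np.argmax(hocl))
    ph_final = ph_field(final)
    total_charge = 0.0
    for series in result.currents.values():
        total_charge += float(np.trapezoid(series, result.times))
    summary = {
        "scenario": cfg.name,
        "t_final_h": t_final / HOUR,
        "max_HOCl_mM": float(hocl.max()),
        "max_HOCl_x_m": float(result.grid.x[k_max]),
        "max_HOCl_compartment": str(result.grid.labels[k_max]),
        "min_pH": float(ph_final.min()),
        "max_pH": float(ph_final.max()),
        "net_charge_passed_C": total_charge,
        "compartment_final_HOCl_mM": {
            comp: result.volume_average(comp, "HOCl", t_final)
            for comp in result.grid.compartments
        },
        "compartment_final_pH": {
            comp: float(ph_final[result.grid.cells_in(comp)].min())
            for comp in result.grid.compartments
        },
    }
    audit = conservation_audit(result)
    summary["audit"] = audit.as_dict()
    return summary


def write_reports(cfg: ScenarioConfig, result: SimulationResult, output_dir):
    """Write profile/volume-average CSVs, a JSON summary, and the audit."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.profiles_frame().to_csv(out / "profiles.csv", index=False,
                                   float_format="%.10e")
    result.volume_average_frame().to_csv(out / "volume_averages.csv", index=False,
                                         float_format="%.10e")
    summary = summarize(cfg, result)
    (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
    (out / "audit.txt").write_text(str(conservation_audit(result)) + "\n")
    (out / "config.json").write_text(
        json.dumps(cfg.to_dict(), indent=2, sort_keys=True, default=float)
    )
    return out
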