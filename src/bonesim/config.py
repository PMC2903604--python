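"""Run configuration, file I/O and the run manifest.

Configurations are plain JSON or YAML mappings mirroring the parameter
dataclasses; unknown keys are rejected and missing keys fall back to the
defaults that reproduce the reference setup (80x80 mesh, Table thresholds,
phi = 30 degrees).  Density fields travel as comma-separated text matrices
(one line per mesh row, 6 decimals); run outputs are ``history.csv``,
``density_final.csv`` and ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .engine import ScenarioConfig, Simulation, SimulationState
from .fe_core import (
    DENSITY_CEIL,
    DENSITY_FLOOR,
    DensityField,
    LoadSpec,
    MaterialLaw,
    Mesh,
    MeshSpec,
    build_mesh,
)
from .mechanosensing import InfluenceParams
from .remodeling import RemodelingParams

__all__ = [
    "RunConfig",
    "load_config",
    "config_to_dict",
    "write_density",
    "read_density",
    "write_outputs",
]


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved run configuration (serializable to the manifest)."""

    mesh: MeshSpec = field(default_factory=MeshSpec)
    material: MaterialLaw = field(default_factory=MaterialLaw)
    load: LoadSpec = field(default_factory=LoadSpec)
    remodeling: RemodelingParams = field(default_factory=RemodelingParams)
    influence: InfluenceParams = field(default_factory=InfluenceParams)
    scenario: ScenarioConfig = field(default_factory=ScenarioConfig)
    seed: int = 0
    out_dir: str = "runs"

    def simulation(self) -> Simulation:
        return Simulation(
            mesh=build_mesh(self.mesh),
            material=self.material,
            params=self.remodeling,
            influence=self.influence,
            load_magnitude=self.scenario.load_magnitude,
            orientation_phi=self.load.orientation_phi,
        )


_SECTIONS = {
    "mesh": MeshSpec,
    "material": MaterialLaw,
    "load": LoadSpec,
    "remodeling": RemodelingParams,
    "influence": InfluenceParams,
    "scenario": ScenarioConfig,
}


def _build_section(cls, data: dict, section: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(
            f"unknown key(s) {sorted(unknown)} in config section {section!r}; "
            f"allowed: {sorted(names)}"
        )
    if section == "scenario" and isinstance(data.get("disconnect_elements"), list):
        data = dict(data)
        data["disconnect_elements"] = tuple(
            tuple(el) for el in data["disconnect_elements"]
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {section!r}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON or YAML config; empty files give defaults.

    Units throughout: lengths mm, stresses and SED thresholds MPa, strains
    reported in microstrain.
    """
    text = Path(path).read_text()
    if not text.strip():
        raw: dict = {}
    elif str(path).endswith((".yml", ".yaml")):
        raw = yaml.safe_load(text) or {}
    else:
        raw = json.loads(text)
    if not isinstance(raw, dict):
        raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")

    top_allowed = set(_SECTIONS) | {"seed", "out_dir"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ValueError(
            f"unknown top-level config key(s) {sorted(unknown)}; "
            f"allowed: {sorted(top_allowed)}"
        )
    kwargs = {
        name: _build_section(cls, raw.get(name, {}) or {}, name)
        for name, cls in _SECTIONS.items()
    }
    return RunConfig(
        **kwargs, seed=int(raw.get("seed", 0)), out_dir=str(raw.get("out_dir", "runs"))
    )


def config_to_dict(config: RunConfig) -> dict:
    """Round-trippable dict form of a config (input to :func:`load_config`)."""
    out: dict = {}
    for name, _ in _SECTIONS.items():
        section = dataclasses.asdict(getattr(config, name))
        if name == "scenario" and section.get("disconnect_elements") is not None:
            section["disconnect_elements"] = [
                list(el) for el in section["disconnect_elements"]
            ]
        out[name] = section
    out["seed"] = config.seed
    out["out_dir"] = config.out_dir
    return out


def write_density(density, path: str | Path) -> None:
    """Write a density matrix as comma-separated text, 6 decimals."""
    m = np.asarray(getattr(density, "m", density), dtype=float)
    np.savetxt(path, m, fmt="%.6f", delimiter=",")


def read_density(path: str | Path) -> DensityField:
    m = np.loadtxt(path, delimiter=",", ndmin=2)
    if m.size == 0:
        raise ValueError(f"density file {path} is empty")
    if m.min() < DENSITY_FLOOR - 1e-9 or m.max() > DENSITY_CEIL + 1e-9:
        raise ValueError(
            f"density file {path} holds values outside "
            f"[{DENSITY_FLOOR}, {DENSITY_CEIL}]"
        )
    return DensityField(m)


def write_outputs(
    state: SimulationState,
    out_dir: str | Path,
    config: Optional[RunConfig] = None,
    sim: Optional[Simulation] = None,
) -> dict[str, Path]:
    """Write history.csv, density_final.csv and manifest.json for a run."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        files = {
            "history": out / "history.csv",
            "density": out / "density_final.csv",
            "manifest": out / "manifest.json",
        }
        state.history_frame().to_csv(files["history"], index=False)
        write_density(state.density, files["density"])
        manifest: dict = {"iterations": state.iteration}
        if config is not None:
            manifest["config"] = config_to_dict(config)
            manifest["seed"] = config.seed
            manifest["derived"] = {
                "tau1_per_MPa": config.remodeling.tau1,
                "h_quadratic_offset": config.remodeling.h,
            }
        if sim is not None:
            manifest["resolved_load_magnitude_MPa"] = sim.load_magnitude
        files["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    except OSError as exc:
        raise OSError(f"failed writing run outputs under {out}: {exc}") from exc
    return files
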