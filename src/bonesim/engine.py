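"""Iterative adaptation engine and scenario presets.

One iteration is one activation/formation epoch: solve the static FE
problem, refresh the osteocyte SED field, detect the trabecular surface,
accumulate and edge-correct the stimulus, draw one uniform number per
surface site (row-major order) to decide osteoclast activation, and apply
the density update.  No calendar time is claimed for an iteration.

The seven study scenarios are preset schedules of the load factor, load
orientation and threshold scale applied on top of a homeostatic
architecture produced by :func:`bootstrap_homeostasis`.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .fe_core import (
    DENSITY_FLOOR,
    DensityField,
    LoadSpec,
    MaterialLaw,
    Mesh,
    MeshSpec,
    build_mesh,
    solve_static,
    young_modulus,
    _as_density_array,
)
from .mechanosensing import (
    VOID_THRESHOLD,
    InfluenceParams,
    edge_correction,
    influence_kernel,
    stimulus_grid,
)
from .remodeling import (
    RemodelingParams,
    resorption_probability,
    site_update,
    surface_site_mask,
)

__all__ = [
    "SCENARIOS",
    "SimulationState",
    "ScenarioConfig",
    "Simulation",
    "calibrate_load_magnitude",
    "seed_porosity",
    "disuse_load_factor",
    "bootstrap_homeostasis",
    "BootstrapResult",
    "run_scenario",
    "step",
]

SCENARIOS = (
    "homeostasis",
    "disuse",
    "overload",
    "disconnect",
    "rotate",
    "phys_up",
    "phys_down",
    "menopause",
)

HISTORY_COLUMNS = [
    "iteration",
    "bone_mass",
    "bone_mass_pct",
    "volume_fraction",
    "avg_strain_ue",
    "n_sites",
    "n_activated",
]


@dataclass
class SimulationState:
    """Mutable state of a running simulation.

    ``history`` accumulates one metrics row per iteration (plus the initial
    row), so its length is always ``iteration + 1``.  Identical config and
    seed reproduce identical histories bit for bit.
    """

    iteration: int
    density: np.ndarray  # (ny_total, nx_total)
    rng: np.random.Generator
    reference_mass: float
    history: list = dc_field(default_factory=list)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history, columns=HISTORY_COLUMNS)


@dataclass(frozen=True)
class ScenarioConfig:
    """A preset adaptation experiment.

    ``B`` is the end fraction of the reference load reached by the disuse
    schedule; ``load_magnitude=None`` means the calibrated reference
    magnitude (see :func:`calibrate_load_magnitude`).  ``disconnect_elements``
    lists ``(row, col)`` element indices set to floor density at the start of
    the disconnect scenario (``None`` selects two strut cuts automatically).
    """

    scenario: str = "homeostasis"
    iterations: int = 500
    seed: int = 0
    B: float = 0.8
    load_magnitude: Optional[float] = None
    disconnect_elements: Optional[tuple] = None

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; available: {', '.join(SCENARIOS)}"
            )
        if not (0.0 < self.B <= 1.0):
            raise ValueError(f"B must lie in (0, 1], got {self.B}")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def calibrate_load_magnitude(
    mesh: Mesh,
    material: MaterialLaw = MaterialLaw(),
    params: RemodelingParams = RemodelingParams(),
    influence: InfluenceParams = InfluenceParams(),
    m0: float = 0.7,
    target_stimulus: Optional[float] = None,
) -> float:
    """Reference load magnitude placing the initial state at the set point.

    The reference stimulus of the adaptation runs is the average of the two
    adaptive-zone thresholds, (K_AD1 + K_AD2)/2.  For the uniform initial
    plate of density ``m0`` under the biaxial +/-sigma load, the interior
    stimulus is ``S_c * sigma**2 * (1 + nu) / E(m0)`` with ``S_c`` the total
    influence weight at the mesh center; solving for sigma gives the load
    magnitude (MPa) at which the start of a run is mechanically homeostatic.
    The value adapts automatically to the mesh resolution through ``S_c``.
    """
    if target_stimulus is None:
        target_stimulus = 0.5 * (params.K_AD1 + params.K_AD2) * params.threshold_scale
    # total influence weight at the center of a fully filled remodelable grid
    t = mesh.spec.side_plate_thickness
    cy, cx = t + mesh.spec.ny // 2, t + mesh.spec.nx // 2
    d = np.hypot(
        mesh.element_centers_x - mesh.element_centers_x[cy, cx],
        mesh.element_centers_y - mesh.element_centers_y[cy, cx],
    )
    sc = np.exp(-d[mesh.remodelable] / influence.D_mm).sum()
    e0 = young_modulus(m0, material)
    sed_per_sigma2 = (1.0 + material.poisson_ratio) / e0
    return float(np.sqrt(target_stimulus / (sc * sed_per_sigma2)))


def seed_porosity(
    mesh: Mesh, density, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    """Set a random fraction of remodelable elements to floor density.

    Surface remodeling needs an initial bone/void interface to act on; a
    void-free uniform plate has no surface sites at all.  The seeded pores
    nucleate the surface on which the rule set then operates.
    """
    m = _as_density_array(density).copy()
    rows, cols = np.nonzero(mesh.remodelable)
    n = int(round(fraction * len(rows)))
    pick = rng.choice(len(rows), size=n, replace=False)
    m[rows[pick], cols[pick]] = DENSITY_FLOOR
    return m


def disuse_load_factor(t: float, B: float = 0.8) -> float:
    """Disuse schedule: load factor falling linearly from 1 at t=0 to B at t=1."""
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"schedule fraction t must lie in [0, 1], got {t}")
    return 1.0 - (1.0 - B) * t


class Simulation:
    """Precomputed context (mesh, kernels, schedules) for adaptation runs."""

    def __init__(
        self,
        mesh: Optional[Mesh] = None,
        material: MaterialLaw = MaterialLaw(),
        params: RemodelingParams = RemodelingParams(),
        influence: InfluenceParams = InfluenceParams(),
        load_magnitude: Optional[float] = None,
        orientation_phi: float = 30.0,
        apply_edge_correction: bool = True,
        bone_threshold: float = 0.5,
    ):
        self.mesh = mesh if mesh is not None else build_mesh(MeshSpec())
        self.material = material
        self.params = params
        self.influence = influence
        self.orientation_phi = orientation_phi
        self.bone_threshold = bone_threshold
        if load_magnitude is None:
            load_magnitude = calibrate_load_magnitude(
                self.mesh, material, params, influence
            )
        self.load_magnitude = float(load_magnitude)
        self._kernel = influence_kernel(self.mesh, influence)
        self._correction = (
            edge_correction(self.mesh, influence)
            if apply_edge_correction
            else np.ones((self.mesh.ny_total, self.mesh.nx_total))
        )

    # -- single pipeline stages -------------------------------------------

    def solve(self, density, load_factor: float = 1.0, phi: Optional[float] = None):
        load = LoadSpec(
            magnitude=self.load_magnitude,
            orientation_phi=self.orientation_phi if phi is None else phi,
            load_factor=load_factor,
        )
        return solve_static(self.mesh, density, load, self.material)

    def stimulus(self, density, fe) -> np.ndarray:
        raw = stimulus_grid(
            self.mesh, density, fe.sed, self.influence, kernel=self._kernel
        )
        return raw * self._correction

    # -- state management --------------------------------------------------

    def init_state(
        self,
        density,
        seed: int,
        load_factor: float = 1.0,
        phi: Optional[float] = None,
    ) -> SimulationState:
        m = _as_density_array(density).copy()
        state = SimulationState(
            iteration=0,
            density=m,
            rng=np.random.default_rng(seed),
            reference_mass=float(m[self.mesh.remodelable].sum()),
        )
        fe = self.solve(m, load_factor, phi)
        n_sites = int(surface_site_mask(self.mesh, m).sum())
        state.history.append(self._metrics_row(state, fe, n_sites, 0))
        return state

    def _metrics_row(self, state, fe, n_sites: int, n_activated: int) -> dict:
        m = state.density
        sel = self.mesh.remodelable
        mass = float(m[sel].sum())
        bone = sel & (m >= self.bone_threshold)
        avg_ue = (
            float(fe.max_abs_principal_strain[bone].mean() * 1e6)
            if bone.any()
            else float("nan")
        )
        return {
            "iteration": state.iteration,
            "bone_mass": mass,
            "bone_mass_pct": 100.0 * (mass - state.reference_mass)
            / state.reference_mass,
            "volume_fraction": float(m[sel].mean()),
            "avg_strain_ue": avg_ue,
            "n_sites": n_sites,
            "n_activated": n_activated,
        }

    def step(
        self,
        state: SimulationState,
        load_factor: float = 1.0,
        phi: Optional[float] = None,
        threshold_scale: Optional[float] = None,
    ) -> SimulationState:
        """Advance one iteration in place and return the state."""
        params = (
            self.params
            if threshold_scale is None
            else self.params.scaled(threshold_scale)
        )
        try:
            fe = self.solve(state.density, load_factor, phi)
        except RuntimeError as exc:
            raise RuntimeError(f"iteration {state.iteration + 1}: {exc}") from exc
        P = self.stimulus(state.density, fe)
        mask = surface_site_mask(self.mesh, state.density)
        rows, cols = np.nonzero(mask)  # row-major site order
        p = resorption_probability(P[rows, cols], params)
        draws = state.rng.random(len(rows))
        activated = draws < p
        state.density[rows, cols] = site_update(
            state.density[rows, cols], P[rows, cols], activated, params
        )
        state.iteration += 1
        state.history.append(
            self._metrics_row(state, fe, len(rows), int(activated.sum()))
        )
        return state

    def run(
        self,
        state: SimulationState,
        iterations: int,
        load_factor: Callable[[float], float] | float = 1.0,
        phi: Optional[float] = None,
        threshold_scale: Optional[float] = None,
    ) -> SimulationState:
        """Run ``iterations`` steps; ``load_factor`` may be a schedule f(t)."""
        for i in range(iterations):
            t = i / max(iterations - 1, 1)
            lf = load_factor(t) if callable(load_factor) else load_factor
            self.step(state, lf, phi, threshold_scale)
        return state


def step(
    sim: Simulation,
    state: SimulationState,
    load_factor: float = 1.0,
    phi: Optional[float] = None,
    threshold_scale: Optional[float] = None,
) -> SimulationState:
    """Functional wrapper over :meth:`Simulation.step`."""
    return sim.step(state, load_factor, phi, threshold_scale)


@dataclass
class BootstrapResult:
    density: DensityField
    state: SimulationState
    converged: bool


def bootstrap_homeostasis(
    sim: Simulation,
    seed: int = 0,
    m0: float = 0.7,
    initial_porosity: float = 0.05,
    tol: float = 0.005,
    window: int = 100,
    max_iterations: int = 2000,
) -> BootstrapResult:
    """Equilibrate a homeostatic architecture under the reference load.

    Starts from the uniform plate ``m0`` with a seeded pore fraction (to
    nucleate the remodeling surface) and iterates until the trailing-window
    relative change of total bone mass falls below ``tol`` (default 0.5% over
    ``window`` iterations) or ``max_iterations`` is reached; in the latter
    case the field is returned with ``converged=False``.
    """
    rng = np.random.default_rng(seed)
    m = DensityField.uniform(sim.mesh, m0).m
    if initial_porosity > 0:
        m = seed_porosity(sim.mesh, m, initial_porosity, rng)
    state = sim.init_state(m, seed=int(rng.integers(2**31 - 1)))
    converged = False
    masses = [state.history[-1]["bone_mass"]]
    for _ in range(max_iterations):
        sim.step(state)
        masses.append(state.history[-1]["bone_mass"])
        if len(masses) > window:
            past = masses[-1 - window]
            if past > 0 and abs(masses[-1] - past) / past < tol:
                converged = True
                break
    return BootstrapResult(
        density=DensityField(state.density.copy()), state=state, converged=converged
    )


def _auto_disconnect(sim: Simulation, density: np.ndarray) -> tuple:
    """Pick two strut cuts: discs around the densest bone elements nearest
    the (1/3, 1/3) and (2/3, 2/3) points of the remodelable region."""
    mesh = sim.mesh
    m = density
    targets = []
    for fy, fx in ((1 / 3, 1 / 3), (2 / 3, 2 / 3)):
        ty = mesh.spec.side_plate_thickness + fy * mesh.spec.ny
        tx = mesh.spec.side_plate_thickness + fx * mesh.spec.nx
        rows, cols = np.nonzero(mesh.remodelable & (m >= sim.bone_threshold))
        if len(rows) == 0:
            raise ValueError("no bone phase to disconnect")
        d2 = (rows - ty) ** 2 + (cols - tx) ** 2
        k = int(np.argmin(d2))
        targets.append((int(rows[k]), int(cols[k])))
    elements = []
    radius = 2
    for r0, c0 in targets:
        for dr in range(-radius, radius + 1):
            for dc in range(-radius, radius + 1):
                if dr * dr + dc * dc <= radius * radius:
                    r, c = r0 + dr, c0 + dc
                    if (
                        0 <= r < mesh.ny_total
                        and 0 <= c < mesh.nx_total
                        and mesh.remodelable[r, c]
                    ):
                        elements.append((r, c))
    return tuple(elements)


def run_scenario(
    config: ScenarioConfig,
    sim: Simulation,
    start_density,
) -> SimulationState:
    """Apply a scenario's schedules to a starting architecture and iterate.

    Load factors: 1.2 for overload, 1.08 / 0.92 for the physiological
    increase / decrease, the linear disuse schedule ending at ``B``;
    menopause combines the 0.92 load with a 1.2 threshold scale; rotate
    switches the principal-stress orientation to 0 degrees; disconnect sets
    the listed (or auto-selected) elements to floor density at t0.
    """
    m = _as_density_array(start_density).copy()
    phi = None
    threshold_scale = None
    load_factor: Callable[[float], float] | float = 1.0
    if config.scenario == "disuse":
        load_factor = lambda t: disuse_load_factor(t, config.B)  # noqa: E731
    elif config.scenario == "overload":
        load_factor = 1.2
    elif config.scenario == "phys_up":
        load_factor = 1.08
    elif config.scenario == "phys_down":
        load_factor = 0.92
    elif config.scenario == "menopause":
        load_factor = 0.92
        threshold_scale = 1.2
    elif config.scenario == "rotate":
        phi = 0.0
    elif config.scenario == "disconnect":
        elements = config.disconnect_elements
        if elements is None:
            elements = _auto_disconnect(sim, m)
        for r, c in elements:
            if not sim.mesh.remodelable[r, c]:
                raise ValueError(f"disconnect element ({r}, {c}) is not remodelable")
            m[r, c] = DENSITY_FLOOR

    lf0 = load_factor(0.0) if callable(load_factor) else load_factor
    state = sim.init_state(m, seed=config.seed, load_factor=lf0, phi=phi)
    return sim.run(
        state,
        config.iterations,
        load_factor=load_factor,
        phi=phi,
        threshold_scale=threshold_scale,
    )
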