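"""Deterministic toy architectures for testing and experimentation.

Every fixture is a density field on a given mesh, generated from the fixture
name, its options and a seed; the same inputs always reproduce the same
field.  They cover the situations the remodeling rules must handle: a
uniform plate, single and crossed struts, artificially disconnected struts,
and random porous fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fe_core import DENSITY_CEIL, DENSITY_FLOOR, DensityField, Mesh

__all__ = ["Fixture", "FIXTURE_NAMES", "make_fixture"]

FIXTURE_NAMES = (
    "uniform",
    "x_strut",
    "cross_lattice",
    "disconnected_struts",
    "random_porous",
)


@dataclass(frozen=True)
class Fixture:
    name: str
    density: DensityField
    description: str


def _blank(mesh: Mesh) -> np.ndarray:
    m = np.full((mesh.ny_total, mesh.nx_total), DENSITY_CEIL)
    m[mesh.remodelable] = DENSITY_FLOOR
    return m


def _strut_rows(mesh: Mesh, width: int) -> slice:
    t = mesh.spec.side_plate_thickness
    r0 = t + (mesh.spec.ny - width) // 2
    return slice(r0, r0 + width)


def _cross_lattice(mesh: Mesh, spacing: int, width: int) -> np.ndarray:
    m = _blank(mesh)
    t = mesh.spec.side_plate_thickness
    for r in range(t, t + mesh.spec.ny, spacing):
        m[r : min(r + width, t + mesh.spec.ny), t : t + mesh.spec.nx] = DENSITY_CEIL
    for c in range(t, t + mesh.spec.nx, spacing):
        m[t : t + mesh.spec.ny, c : min(c + width, t + mesh.spec.nx)] = DENSITY_CEIL
    return m


def make_fixture(name: str, mesh: Mesh, seed: int = 0, **options) -> Fixture:
    """Build a named fixture on ``mesh``.

    Options: ``value`` (uniform), ``width`` (x_strut), ``spacing``/``width``
    (cross_lattice, disconnected_struts), ``cut_elements`` (disconnected
    struts; list of (row, col)), ``porosity`` (random_porous).
    """
    if name == "uniform":
        value = options.pop("value", 0.7)
        density = DensityField.uniform(mesh, value)
        desc = f"uniform remodelable density m = {value}"
    elif name == "x_strut":
        width = int(options.pop("width", 4))
        m = _blank(mesh)
        t = mesh.spec.side_plate_thickness
        m[_strut_rows(mesh, width), t : t + mesh.spec.nx] = DENSITY_CEIL
        density = DensityField(m)
        desc = f"one horizontal strut of {width} element rows at full density"
    elif name == "cross_lattice":
        spacing = int(options.pop("spacing", 10))
        width = int(options.pop("width", 3))
        density = DensityField(_cross_lattice(mesh, spacing, width))
        desc = f"orthogonal strut lattice, spacing {spacing}, width {width}"
    elif name == "disconnected_struts":
        spacing = int(options.pop("spacing", 10))
        width = int(options.pop("width", 3))
        m = _cross_lattice(mesh, spacing, width)
        cuts = options.pop("cut_elements", None)
        if cuts is None:
            # default: sever the central horizontal strut in two places
            t = mesh.spec.side_plate_thickness
            rows = range(t, t + mesh.spec.ny, spacing)
            r = list(rows)[len(list(rows)) // 2]
            for fx in (0.3, 0.7):
                c = t + int(fx * mesh.spec.nx)
                cuts = [(rr, cc) for rr in range(r, r + width) for cc in (c, c + 1)]
                m[tuple(zip(*cuts))] = DENSITY_FLOOR
            desc = "strut lattice with the central horizontal strut cut twice"
        else:
            for r, c in cuts:
                m[r, c] = DENSITY_FLOOR
            desc = f"strut lattice with {len(cuts)} elements cut to floor density"
        density = DensityField(m)
    elif name == "random_porous":
        porosity = float(options.pop("porosity", 0.4))
        rng = np.random.default_rng(seed)
        m = _blank(mesh)
        sel = mesh.remodelable
        m[sel] = np.where(
            rng.random(int(sel.sum())) < porosity, DENSITY_FLOOR, DENSITY_CEIL
        )
        density = DensityField(m)
        desc = f"iid random porous field, porosity {porosity}, seed {seed}"
    else:
        raise ValueError(
            f"unknown fixture {name!r}; available: {', '.join(FIXTURE_NAMES)}"
        )
    if options:
        raise ValueError(f"unknown option(s) for fixture {name!r}: {sorted(options)}")
    return Fixture(name=name, density=density, description=desc)
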