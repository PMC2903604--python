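"""Plane-stress voxel finite-element core.

A rectangular trabecular region is discretized into four-node bilinear
quadrilateral elements on a regular grid.  Each element carries a relative
mineral density ``m`` in [0.01, 1.0]; the tissue Young's modulus follows the
power law ``E = E_max * m**r``.  The region is framed by non-remodeling side
plates of full density that distribute the edge tractions evenly, and is
loaded by a uniform far-field stress whose principal values are ``+sigma``
(tension) and ``-sigma`` (compression) at an angle ``phi`` to the horizontal.

All lengths are in mm, stresses and strain-energy densities (SED) in MPa,
strains dimensionless (converted to microstrain only at reporting time).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "DENSITY_FLOOR",
    "DENSITY_CEIL",
    "MaterialLaw",
    "MeshSpec",
    "Mesh",
    "LoadSpec",
    "DensityField",
    "FEResult",
    "young_modulus",
    "build_mesh",
    "stress_tensor",
    "tractions_from_stress",
    "boundary_tractions",
    "element_stiffness_unit",
    "solve_static",
]

#: lower clip of the relative density; encodes fully resorbed / void tissue
DENSITY_FLOOR = 0.01
#: relative density of fully mineralized tissue
DENSITY_CEIL = 1.0


@dataclass(frozen=True)
class MaterialLaw:
    """Density-dependent isotropic elasticity, ``E(m) = E_max * m**r``.

    Parameters
    ----------
    E_max : float
        Tissue-level Young's modulus of fully mineralized bone, MPa.
    r : float
        Density-modulus exponent (cubic for trabecular tissue).
    poisson_ratio : float
        Poisson's ratio, shared by all densities.
    """

    E_max: float = 500.0
    r: float = 3.0
    poisson_ratio: float = 0.3

    def __post_init__(self) -> None:
        if self.E_max <= 0:
            raise ValueError(f"E_max must be positive, got {self.E_max}")
        if self.r < 1:
            raise ValueError(f"density-modulus exponent r must be >= 1, got {self.r}")
        if not (0.0 <= self.poisson_ratio < 0.5):
            raise ValueError(
                f"poisson_ratio must lie in [0, 0.5), got {self.poisson_ratio}"
            )


def young_modulus(m, law: MaterialLaw = MaterialLaw()):
    """Young's modulus in MPa for relative density ``m`` (scalar or array)."""
    arr = np.asarray(m, dtype=float)
    tol = 1e-12
    if arr.size and (arr.min() < DENSITY_FLOOR - tol or arr.max() > DENSITY_CEIL + tol):
        bad = arr[(arr < DENSITY_FLOOR - tol) | (arr > DENSITY_CEIL + tol)].flat[0]
        raise ValueError(
            f"relative density {bad} outside the admissible range "
            f"[{DENSITY_FLOOR}, {DENSITY_CEIL}]"
        )
    out = law.E_max * arr**law.r
    return out if arr.ndim else float(out)


@dataclass(frozen=True)
class MeshSpec:
    """Geometry of the remodelable region and its side-plate frame.

    ``nx`` x ``ny`` elements span ``width_mm`` x ``height_mm``; the frame adds
    ``side_plate_thickness`` rows/columns of fixed full-density elements on
    every edge.
    """

    nx: int = 80
    ny: int = 80
    width_mm: float = 2.0
    height_mm: float = 2.0
    thickness_mm: float = 0.02
    side_plate_thickness: int = 2

    def __post_init__(self) -> None:
        if self.nx < 4 or self.ny < 4:
            raise ValueError(f"nx and ny must be >= 4, got {self.nx}x{self.ny}")
        if self.width_mm <= 0 or self.height_mm <= 0 or self.thickness_mm <= 0:
            raise ValueError("mesh dimensions must be positive")
        if self.side_plate_thickness < 0:
            raise ValueError("side_plate_thickness must be >= 0")

    @property
    def hx(self) -> float:
        return self.width_mm / self.nx

    @property
    def hy(self) -> float:
        return self.height_mm / self.ny

    @property
    def element_area_mm2(self) -> float:
        return self.hx * self.hy


class Mesh:
    """A built regular quadrilateral mesh.

    Elements are indexed row-major from the lower-left corner; element
    ``(row, col)`` spans ``[col*hx, (col+1)*hx] x [row*hy, (row+1)*hy]``.
    Node ``(row, col)`` sits at ``(col*hx, row*hy)`` and has dofs
    ``(2*id, 2*id+1)`` with ``id = row*(nx_total+1) + col``.
    """

    def __init__(self, spec: MeshSpec):
        self.spec = spec
        t = spec.side_plate_thickness
        self.nx_total = spec.nx + 2 * t
        self.ny_total = spec.ny + 2 * t
        self.hx = spec.hx
        self.hy = spec.hy
        self.n_nodes = (self.nx_total + 1) * (self.ny_total + 1)
        self.n_dofs = 2 * self.n_nodes
        self.n_elements = self.nx_total * self.ny_total

        rows, cols = np.meshgrid(
            np.arange(self.ny_total), np.arange(self.nx_total), indexing="ij"
        )
        self.element_centers_x = (cols + 0.5) * self.hx
        self.element_centers_y = (rows + 0.5) * self.hy

        mask = np.zeros((self.ny_total, self.nx_total), dtype=bool)
        mask[t : t + spec.ny, t : t + spec.nx] = True
        self.remodelable = mask

        # connectivity: element (r, c) -> nodes counter-clockwise from LL
        n_per_row = self.nx_total + 1
        n1 = rows * n_per_row + cols
        n2 = n1 + 1
        n3 = n2 + n_per_row
        n4 = n1 + n_per_row
        conn = np.stack([n1, n2, n3, n4], axis=-1).reshape(-1, 4)
        self.connectivity = conn
        dof = np.empty((self.n_elements, 8), dtype=np.int64)
        dof[:, 0::2] = 2 * conn
        dof[:, 1::2] = 2 * conn + 1
        self.element_dofs = dof
        # scatter indices for vectorized sparse assembly
        self._asm_rows = np.repeat(dof, 8, axis=1).ravel()
        self._asm_cols = np.tile(dof, (1, 8)).ravel()

    @property
    def n_remodelable(self) -> int:
        return int(self.remodelable.sum())

    def node_coords(self) -> np.ndarray:
        """(n_nodes, 2) array of node coordinates in mm."""
        n_per_row = self.nx_total + 1
        ids = np.arange(self.n_nodes)
        return np.column_stack(
            [(ids % n_per_row) * self.hx, (ids // n_per_row) * self.hy]
        )


def build_mesh(spec: MeshSpec = MeshSpec()) -> Mesh:
    """Build the mesh (node coordinates, connectivity, remodelable mask)."""
    return Mesh(spec)


@dataclass(frozen=True)
class LoadSpec:
    """Far-field loading: principal stresses ``(+magnitude, -magnitude)``.

    ``orientation_phi`` is the angle (degrees) of the tensile principal axis
    to the horizontal; ``load_factor`` scales all boundary tractions
    uniformly (used by scenario schedules).
    """

    magnitude: float = 2.0
    orientation_phi: float = 30.0
    load_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.magnitude < 0:
            raise ValueError(f"load magnitude must be >= 0, got {self.magnitude}")


def stress_tensor(load: LoadSpec) -> tuple[float, float, float]:
    """Cartesian components ``(sxx, syy, sxy)`` of the applied stress, MPa.

    Rotation of ``diag(+s, -s)`` by ``phi``: ``sxx = s*cos(2*phi)``,
    ``syy = -s*cos(2*phi)``, ``sxy = s*sin(2*phi)``.
    """
    s = load.magnitude * load.load_factor
    phi = np.deg2rad(load.orientation_phi)
    return (s * np.cos(2 * phi), -s * np.cos(2 * phi), s * np.sin(2 * phi))


def tractions_from_stress(
    mesh: Mesh, sxx: float, syy: float, sxy: float
) -> np.ndarray:
    """Consistent nodal force vector for a uniform boundary stress state.

    On each outer edge with outward normal ``n`` the traction is ``sigma @ n``
    (per unit length, times plate thickness); linear shape functions put half
    of each edge segment's load on each of its two end nodes.
    """
    th = mesh.spec.thickness_mm
    f = np.zeros(mesh.n_dofs)
    n_per_row = mesh.nx_total + 1

    def add_edge(node_ids: np.ndarray, seg_len: float, tx: float, ty: float) -> None:
        w = np.full(node_ids.shape, seg_len)
        w[0] *= 0.5
        w[-1] *= 0.5
        f[2 * node_ids] += tx * w * th
        f[2 * node_ids + 1] += ty * w * th

    bottom = np.arange(n_per_row)
    top = np.arange(n_per_row) + mesh.ny_total * n_per_row
    left = np.arange(mesh.ny_total + 1) * n_per_row
    right = left + mesh.nx_total

    add_edge(right, mesh.hy, sxx, sxy)  # n = +x
    add_edge(left, mesh.hy, -sxx, -sxy)  # n = -x
    add_edge(top, mesh.hx, sxy, syy)  # n = +y
    add_edge(bottom, mesh.hx, -sxy, -syy)  # n = -y
    return f


def boundary_tractions(mesh: Mesh, load: LoadSpec) -> np.ndarray:
    """Nodal force vector equivalent to the biaxial principal-stress loading."""
    sxx, syy, sxy = stress_tensor(load)
    return tractions_from_stress(mesh, sxx, syy, sxy)


def _elasticity_matrix(E: float, nu: float) -> np.ndarray:
    c = E / (1.0 - nu * nu)
    return c * np.array(
        [[1.0, nu, 0.0], [nu, 1.0, 0.0], [0.0, 0.0, (1.0 - nu) / 2.0]]
    )


_GAUSS = 1.0 / np.sqrt(3.0)
_GAUSS_PTS = [(-_GAUSS, -_GAUSS), (_GAUSS, -_GAUSS), (_GAUSS, _GAUSS), (-_GAUSS, _GAUSS)]


def _b_matrix(xi: float, eta: float, hx: float, hy: float) -> np.ndarray:
    """Strain-displacement matrix of the bilinear quad at local (xi, eta)."""
    # shape function derivatives wrt local coords; nodes CCW from (-1,-1)
    dN_dxi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_deta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    dN_dx = dN_dxi * 2.0 / hx
    dN_dy = dN_deta * 2.0 / hy
    B = np.zeros((3, 8))
    B[0, 0::2] = dN_dx
    B[1, 1::2] = dN_dy
    B[2, 0::2] = dN_dy
    B[2, 1::2] = dN_dx
    return B


def element_stiffness_unit(mesh: Mesh, nu: float) -> np.ndarray:
    """8x8 stiffness of one element for ``E = 1`` MPa (2x2 Gauss, exact here).

    With the affine square-element mapping the integrand is quadratic in the
    local coordinates, so the 2x2 rule integrates it exactly; element
    stiffness scales linearly with ``E``.
    """
    D = _elasticity_matrix(1.0, nu)
    det_j = (mesh.hx / 2.0) * (mesh.hy / 2.0)
    K = np.zeros((8, 8))
    for xi, eta in _GAUSS_PTS:
        B = _b_matrix(xi, eta, mesh.hx, mesh.hy)
        K += B.T @ D @ B * det_j
    return K * mesh.spec.thickness_mm


@dataclass
class DensityField:
    """Per-element relative mineralization on the full (framed) grid.

    Side-plate elements are held at full density and never remodel; the
    remodelable interior lives in ``[DENSITY_FLOOR, DENSITY_CEIL]``.
    """

    m: np.ndarray

    @classmethod
    def uniform(cls, mesh: Mesh, value: float = 0.7) -> "DensityField":
        m = np.full((mesh.ny_total, mesh.nx_total), DENSITY_CEIL)
        m[mesh.remodelable] = value
        return cls(m)

    def copy(self) -> "DensityField":
        return DensityField(self.m.copy())

    def volume_fraction(self, mesh: Mesh) -> float:
        return float(self.m[mesh.remodelable].mean())

    def bone_mass(self, mesh: Mesh) -> float:
        return float(self.m[mesh.remodelable].sum())


def _as_density_array(density) -> np.ndarray:
    return np.asarray(getattr(density, "m", density), dtype=float)


@dataclass
class FEResult:
    """Static linear solution fields.

    ``strain`` holds per-element centroid strains in Voigt order
    ``(exx, eyy, gamma_xy)``; ``sed`` the strain-energy density in MPa;
    ``max_abs_principal_strain`` the scalar strain measure used for
    reporting (dimensionless; multiply by 1e6 for microstrain).
    """

    displacement: np.ndarray  # (n_nodes, 2), mm
    strain: np.ndarray  # (ny_total, nx_total, 3)
    sed: np.ndarray  # (ny_total, nx_total), MPa
    max_abs_principal_strain: np.ndarray  # (ny_total, nx_total)


def _default_constraints(mesh: Mesh) -> dict[int, float]:
    """Minimal kinematic constraints removing the three rigid-body modes.

    The lower-left corner node is pinned and the lower-right corner is held
    vertically; the self-equilibrated edge tractions carry the load.
    """
    ll = 0
    lr = mesh.nx_total
    return {2 * ll: 0.0, 2 * ll + 1: 0.0, 2 * lr + 1: 0.0}


def solve_static(
    mesh: Mesh,
    density,
    load: Optional[LoadSpec] = None,
    material: MaterialLaw = MaterialLaw(),
    forces: Optional[np.ndarray] = None,
    dirichlet: Optional[dict[int, float]] = None,
) -> FEResult:
    """Solve the static plane-stress problem and report strain and SED.

    Parameters
    ----------
    density : DensityField or ndarray
        Relative density per element on the full grid.
    load : LoadSpec, optional
        Biaxial principal-stress loading; ignored if ``forces`` is given.
    forces : ndarray, optional
        Explicit nodal force vector (advanced use / testing).
    dirichlet : dict, optional
        ``{dof index: prescribed displacement}``; defaults to the minimal
        rigid-body constraints.
    """
    m = _as_density_array(density)
    if m.shape != (mesh.ny_total, mesh.nx_total):
        raise ValueError(
            f"density shape {m.shape} does not match mesh "
            f"{(mesh.ny_total, mesh.nx_total)}"
        )
    E = young_modulus(m, material).ravel()

    k_unit = element_stiffness_unit(mesh, material.poisson_ratio)
    data = (E[:, None] * k_unit.ravel()[None, :]).ravel()
    K = sp.coo_matrix(
        (data, (mesh._asm_rows, mesh._asm_cols)), shape=(mesh.n_dofs, mesh.n_dofs)
    ).tocsc()

    if forces is None:
        if load is None:
            raise ValueError("either a LoadSpec or an explicit force vector is required")
        forces = boundary_tractions(mesh, load)

    bc = _default_constraints(mesh) if dirichlet is None else dict(dirichlet)
    fixed = np.fromiter(bc.keys(), dtype=np.int64)
    fixed_vals = np.fromiter(bc.values(), dtype=float)
    free = np.setdiff1d(np.arange(mesh.n_dofs), fixed, assume_unique=False)

    u = np.zeros(mesh.n_dofs)
    u[fixed] = fixed_vals
    K_csr = K.tocsr()
    rhs = forces[free] - K_csr[free][:, fixed] @ fixed_vals
    try:
        # MMD ordering on the symmetric pattern roughly halves the fill-in
        lu = spla.splu(K_csr[free][:, free].tocsc(), permc_spec="MMD_AT_PLUS_A")
        u[free] = lu.solve(rhs)
    except (RuntimeError, ValueError) as exc:  # singular factorization
        raise RuntimeError(f"static FE solve failed (singular system?): {exc}") from exc
    if not np.all(np.isfinite(u)):
        raise RuntimeError("static FE solve produced non-finite displacements")

    # centroid strains, per-element stress and SED
    B0 = _b_matrix(0.0, 0.0, mesh.hx, mesh.hy)
    ue = u[mesh.element_dofs]  # (n_el, 8)
    eps = ue @ B0.T  # (n_el, 3)
    D1 = _elasticity_matrix(1.0, material.poisson_ratio)
    sig = (eps @ D1.T) * E[:, None]
    sed = 0.5 * np.einsum("ij,ij->i", sig, eps)

    exx, eyy, gxy = eps[:, 0], eps[:, 1], eps[:, 2]
    center = 0.5 * (exx + eyy)
    radius = np.sqrt((0.5 * (exx - eyy)) ** 2 + (0.5 * gxy) ** 2)
    pmax = np.maximum(np.abs(center + radius), np.abs(center - radius))

    shape = (mesh.ny_total, mesh.nx_total)
    return FEResult(
        displacement=u.reshape(-1, 2),
        strain=eps.reshape(shape + (3,)),
        sed=np.maximum(sed, 0.0).reshape(shape),
        max_abs_principal_strain=pmax.reshape(shape),
    )
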