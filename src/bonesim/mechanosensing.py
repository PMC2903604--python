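"""Osteocyte mechanosensing: from element SED to the surface stimulus.

One osteocyte sits at the center of every bone-filled element and senses the
local strain-energy density R (MPa).  The remodeling stimulus at a surface
location x is the distance-weighted sum over osteocytes,

    P(x) = sum_i mu_i * R_i * exp(-d_i(x) / D),

where D is the decay distance (influence drops to exp(-1) = 0.36788 at
d = D).  Sites near the mesh edge see a truncated osteocyte neighborhood, so
a precomputed geometric correction factor (normalized to the mesh center)
multiplies the raw stimulus there.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve
from scipy.spatial import cKDTree

from .fe_core import DENSITY_FLOOR, FEResult, Mesh, _as_density_array

__all__ = [
    "VOID_THRESHOLD",
    "InfluenceParams",
    "OsteocyteField",
    "influence_factor",
    "build_osteocyte_field",
    "compute_stimulus",
    "influence_kernel",
    "stimulus_grid",
    "edge_correction",
]

#: elements with m strictly above this host an osteocyte / count as bone
VOID_THRESHOLD = DENSITY_FLOOR + 1e-9


@dataclass(frozen=True)
class InfluenceParams:
    """Spatial influence of an osteocyte.

    ``D_mm`` is the exponential decay distance (100 um).  ``cutoff_radius_mm``
    truncates the summation for speed; at the default 5*D the dropped weights
    are below 0.7%.  ``None`` means exact summation over all osteocytes.
    """

    D_mm: float = 0.1
    cutoff_radius_mm: Optional[float] = 0.5

    def __post_init__(self) -> None:
        if self.D_mm <= 0:
            raise ValueError(f"decay distance D must be positive, got {self.D_mm}")
        if self.cutoff_radius_mm is not None and self.cutoff_radius_mm <= 0:
            raise ValueError("cutoff_radius_mm must be positive or None")


def influence_factor(d, params: InfluenceParams = InfluenceParams()):
    """Dimensionless weight ``exp(-d/D)`` for distance ``d`` (mm)."""
    arr = np.asarray(d, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError(f"distance must be >= 0, got {arr.min()}")
    out = np.exp(-arr / params.D_mm)
    return out if arr.ndim else float(out)


@dataclass
class OsteocyteField:
    """Osteocytes of the current architecture.

    ``positions`` are element-center coordinates (mm) of every bone-filled
    remodelable element, ``mu`` the per-cell mechanosensitivity (uniform 1 by
    default) and ``R`` the SED each cell senses, refreshed after every FE
    solve.  Side plates carry no osteocytes.
    """

    positions: np.ndarray  # (N, 2) mm
    rows: np.ndarray  # (N,) element row indices
    cols: np.ndarray  # (N,) element col indices
    mu: np.ndarray  # (N,)
    R: np.ndarray  # (N,) MPa

    def __len__(self) -> int:
        return len(self.mu)

    def refresh_sed(self, fe: FEResult) -> None:
        """Copy each osteocyte's host-element SED from an FE solution."""
        self.R = fe.sed[self.rows, self.cols].astype(float)


def build_osteocyte_field(
    mesh: Mesh, density, void_threshold: float = VOID_THRESHOLD
) -> OsteocyteField:
    m = _as_density_array(density)
    bone = mesh.remodelable & (m > void_threshold)
    rows, cols = np.nonzero(bone)
    pos = np.column_stack(
        [mesh.element_centers_x[rows, cols], mesh.element_centers_y[rows, cols]]
    )
    n = len(rows)
    return OsteocyteField(
        positions=pos, rows=rows, cols=cols, mu=np.ones(n), R=np.zeros(n)
    )


def compute_stimulus(
    sites: np.ndarray,
    field: OsteocyteField,
    params: InfluenceParams = InfluenceParams(),
) -> np.ndarray:
    """Accumulated stimulus P (MPa) at each site location.

    ``sites`` is an (M, 2) array of evaluation points (surface-element
    centroids).  With a cutoff radius only osteocytes within it contribute;
    with ``cutoff_radius_mm=None`` the sum is exact.
    """
    sites = np.atleast_2d(np.asarray(sites, dtype=float))
    P = np.zeros(len(sites))
    if len(field) == 0 or len(sites) == 0:
        return P
    w = field.mu * field.R
    if params.cutoff_radius_mm is None:
        # exact double sum, chunked to bound memory
        chunk = max(1, int(2e7) // max(len(field), 1))
        for i in range(0, len(sites), chunk):
            d = np.sqrt(
                ((sites[i : i + chunk, None, :] - field.positions[None, :, :]) ** 2).sum(
                    axis=-1
                )
            )
            P[i : i + chunk] = (w[None, :] * np.exp(-d / params.D_mm)).sum(axis=1)
        return P
    tree = cKDTree(field.positions)
    neighbors = tree.query_ball_point(sites, params.cutoff_radius_mm)
    for i, idx in enumerate(neighbors):
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.sqrt(((field.positions[idx] - sites[i]) ** 2).sum(axis=1))
        P[i] = (w[idx] * np.exp(-d / params.D_mm)).sum()
    return P


def influence_kernel(mesh: Mesh, params: InfluenceParams) -> np.ndarray:
    """Grid convolution kernel of the influence function.

    Entry (dr, dc) holds ``exp(-d/D)`` for the center-to-center offset
    ``d = hypot(dc*hx, dr*hy)``, zeroed beyond the cutoff radius so the grid
    path and the KD-tree path sum the same osteocyte sets.
    """
    if params.cutoff_radius_mm is None:
        rx = mesh.nx_total - 1
        ry = mesh.ny_total - 1
    else:
        rx = int(np.floor(params.cutoff_radius_mm / mesh.hx))
        ry = int(np.floor(params.cutoff_radius_mm / mesh.hy))
    dc = np.arange(-rx, rx + 1) * mesh.hx
    dr = np.arange(-ry, ry + 1) * mesh.hy
    d = np.hypot(dc[None, :], dr[:, None])
    kern = np.exp(-d / params.D_mm)
    if params.cutoff_radius_mm is not None:
        kern[d > params.cutoff_radius_mm] = 0.0
    return kern


def stimulus_grid(
    mesh: Mesh,
    density,
    sed: np.ndarray,
    params: InfluenceParams = InfluenceParams(),
    mu: float | np.ndarray = 1.0,
    void_threshold: float = VOID_THRESHOLD,
    kernel: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Stimulus P evaluated at every element center via grid convolution.

    Equivalent to :func:`compute_stimulus` at element centers (same osteocyte
    set and distances) but O(N log N); this is the path the engine uses each
    iteration.
    """
    m = _as_density_array(density)
    bone = mesh.remodelable & (m > void_threshold)
    source = np.where(bone, np.asarray(sed) * mu, 0.0)
    if kernel is None:
        kernel = influence_kernel(mesh, params)
    P = fftconvolve(source, kernel, mode="same")
    return np.maximum(P, 0.0)


def edge_correction(
    mesh: Mesh, params: InfluenceParams = InfluenceParams()
) -> np.ndarray:
    """Near-edge stimulus correction factors on the full element grid.

    For a fully filled remodelable region let ``S(x)`` be the total influence
    weight reaching element center ``x``.  Surfaces near the mesh edge (and
    especially corners) have a truncated osteocyte environment, so the raw
    stimulus there is multiplied by ``S_ref / S(x)`` with ``S_ref`` the value
    at the mesh center.  Side-plate entries are set to 1.
    """
    ny, nx = mesh.spec.ny, mesh.spec.nx
    t = mesh.spec.side_plate_thickness
    dc = np.arange(-(nx - 1), nx) * mesh.hx
    dr = np.arange(-(ny - 1), ny) * mesh.hy
    kern = np.exp(-np.hypot(dc[None, :], dr[:, None]) / params.D_mm)
    S = fftconvolve(np.ones((ny, nx)), kern, mode="same")
    s_ref = S[ny // 2, nx // 2]
    factors = np.ones((mesh.ny_total, mesh.nx_total))
    factors[t : t + ny, t : t + nx] = s_ref / S
    return factors
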