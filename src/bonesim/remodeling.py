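"""Mechanostat rule set: activation probability, formation law, density update.

The accumulated stimulus P (MPa) at a trabecular surface site is compared
against four SED thresholds (Table values, MPa):

* ``K_RD``  - resorption-drift threshold (below it resorption acts alone),
* ``K_OB``  - osteoblastic formation threshold,
* ``K_AD1`` / ``K_AD2`` - lower/upper bounds of the adaptive (lazy) zone;
  ``K_AD2`` doubles as the formation-drift threshold of bone modeling.

Osteoclast activation is stochastic with a zone-dependent probability p(P):
sigmoidal in disuse, a small constant c in the adaptive zone, quadratic in
overload (clamped to 1).  An activated site resorbs a fixed density quantum
``r_oc`` = 0.38 and osteoblasts refill it according to the piecewise
formation law, which is continuous, zero below ``K_OB``, exactly ``r_oc``
across the adaptive zone (mass-neutral remodeling) and super-compensating
above ``K_AD2``.  Non-activated sites experience only the formation drift of
modeling above ``K_AD2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List

import numpy as np

from .fe_core import DENSITY_CEIL, DENSITY_FLOOR, Mesh, _as_density_array
from .mechanosensing import VOID_THRESHOLD

__all__ = [
    "RemodelingParams",
    "SurfaceSite",
    "resorption_probability",
    "overload_probability",
    "formation_amount",
    "detect_surface_sites",
    "surface_site_mask",
    "site_update",
    "QuantumDerivation",
    "resorption_quantum",
]


@dataclass(frozen=True)
class RemodelingParams:
    """All mechanostat constants.

    Thresholds and the probability-curve stimuli are in MPa.  Derived
    constants: ``tau1 = r_oc / (K_AD1 - K_OB)`` makes the formation law
    continuous at ``K_AD1``; ``h`` fixes the quadratic probability branch to
    equal ``c`` at ``K_AD2``.  ``threshold_scale`` shifts the whole rule set
    rightward by scaling every threshold (equivalently both curves are
    evaluated at ``P / threshold_scale``); it models raised mechanostat set
    points, e.g. at menopause.
    """

    K_RD: float = 0.0357
    K_OB: float = 0.0714
    K_AD1: float = 0.0918
    K_AD2: float = 0.1122
    p_max: float = 0.2
    a: float = 90.0
    b: float = 0.0714
    c: float = 0.0275
    d: float = 176.0
    g: float = 19.506
    tau2: float = 1.0  # MPa^-1
    r_oc: float = 0.38
    threshold_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.K_RD < self.K_OB < self.K_AD1 < self.K_AD2):
            raise ValueError(
                "thresholds must satisfy K_RD < K_OB < K_AD1 < K_AD2, got "
                f"{self.K_RD}, {self.K_OB}, {self.K_AD1}, {self.K_AD2}"
            )
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError(f"p_max must lie in [0, 1], got {self.p_max}")
        if self.r_oc <= 0 or self.tau2 < 0:
            raise ValueError("r_oc must be positive and tau2 non-negative")
        if self.threshold_scale <= 0:
            raise ValueError(f"threshold_scale must be positive, got {self.threshold_scale}")

    @property
    def tau1(self) -> float:
        """Formation slope below the adaptive zone, MPa^-1 (continuity at K_AD1)."""
        return self.r_oc / (self.K_AD1 - self.K_OB)

    @property
    def h(self) -> float:
        """Offset of the quadratic probability branch (continuity at K_AD2)."""
        return self.c - self.d * self.K_AD2**2 + self.g * self.K_AD2

    def check_continuity(self, tol: float = 1e-3) -> None:
        """Verify the sigmoid meets the adaptive-zone constant at ``K_AD1``."""
        sig = self.p_max / (1.0 + np.exp(self.a * (self.K_AD1 - self.b)))
        if abs(sig - self.c) > tol:
            raise ValueError(
                f"sigmoid({self.K_AD1}) = {sig:.6f} does not meet the "
                f"adaptive-zone constant c = {self.c} within {tol}"
            )

    def scaled(self, threshold_scale: float) -> "RemodelingParams":
        return replace(self, threshold_scale=threshold_scale)


def _check_nonneg(P) -> np.ndarray:
    arr = np.asarray(P, dtype=float)
    if arr.size and arr.min() < 0:
        raise ValueError(f"stimulus must be >= 0, got {arr.min()}")
    return arr


def overload_probability(
    P, params: RemodelingParams = RemodelingParams(), clamp: bool = True
):
    """Quadratic overload branch ``d*P**2 - g*P + h`` of the activation curve.

    Exposed separately because its anchor values (0.25 at 0.122436 MPa, 1 at
    0.149 MPa) are checked before clamping.  Threshold scaling applies.
    """
    arr = _check_nonneg(P)
    Ps = arr / params.threshold_scale
    q = params.d * Ps**2 - params.g * Ps + params.h
    if clamp:
        q = np.clip(q, 0.0, 1.0)
    return q if arr.ndim else float(q)


def resorption_probability(P, params: RemodelingParams = RemodelingParams()):
    """Probability of osteoclast activation per surface site, p(P) in [0, 1].

    Sigmoidal ``p_max / (1 + exp(a*(P - b)))`` in the disuse/underload range
    (P < K_AD1), the constant ``c`` across the adaptive zone, and the clamped
    quadratic branch above ``K_AD2``; continuous at both zone boundaries.
    """
    arr = _check_nonneg(P)
    Ps = arr / params.threshold_scale
    sig = params.p_max / (1.0 + np.exp(np.minimum(params.a * (Ps - params.b), 500.0)))
    quad = params.d * Ps**2 - params.g * Ps + params.h
    p = np.where(
        Ps < params.K_AD1, sig, np.where(Ps <= params.K_AD2, params.c, quad)
    )
    p = np.clip(p, 0.0, 1.0)
    return p if arr.ndim else float(p)


def formation_amount(P, params: RemodelingParams = RemodelingParams()):
    """Relative density formed by osteoblasts at an activated site, r_ob(P).

    Zero below ``K_OB``; ``tau1*(P - K_OB)`` up to ``K_AD1``; exactly
    ``r_oc`` across the adaptive zone (formation refills what the activated
    osteoclasts resorbed); ``r_oc + tau2*(P - K_AD2)`` in overload.
    Continuous and non-decreasing.
    """
    arr = _check_nonneg(P)
    Ps = arr / params.threshold_scale
    r = np.where(
        Ps <= params.K_OB,
        0.0,
        np.where(
            Ps < params.K_AD1,
            params.tau1 * (Ps - params.K_OB),
            np.where(
                Ps <= params.K_AD2,
                params.r_oc,
                params.r_oc + params.tau2 * (Ps - params.K_AD2),
            ),
        ),
    )
    return r if arr.ndim else float(r)


@dataclass
class SurfaceSite:
    """A remodelable bone element with at least one void 4-neighbor."""

    row: int
    col: int
    stimulus: float = float("nan")  # MPa, filled after the FE/stimulus pass
    activated: bool = False


def surface_site_mask(
    mesh: Mesh, density, void_threshold: float = VOID_THRESHOLD
) -> np.ndarray:
    """Boolean grid of surface sites (bone with an edge-sharing void neighbor).

    Side-plate neighbors never count as void, and remodelable elements only
    ever border side plates at the frame, so no out-of-grid handling is
    needed beyond padding with "not void".
    """
    m = _as_density_array(density)
    bone = mesh.remodelable & (m > void_threshold)
    void = mesh.remodelable & ~(m > void_threshold)
    pad = np.pad(void, 1, constant_values=False)
    has_void_neighbor = (
        pad[:-2, 1:-1] | pad[2:, 1:-1] | pad[1:-1, :-2] | pad[1:-1, 2:]
    )
    return bone & has_void_neighbor


def detect_surface_sites(
    mesh: Mesh, density, void_threshold: float = VOID_THRESHOLD
) -> List[SurfaceSite]:
    """Surface sites in deterministic row-major order."""
    mask = surface_site_mask(mesh, density, void_threshold)
    return [SurfaceSite(int(r), int(c)) for r, c in np.argwhere(mask)]


def site_update(m, P, activated, params: RemodelingParams = RemodelingParams()):
    """New relative density of surface sites after one remodeling epoch.

    Activated sites resorb the quantum ``r_oc`` and form ``r_ob(P)``; sites
    left alone by osteoclasts only experience the formation drift of
    modeling, ``tau2*(P - K_AD2)`` where P exceeds ``K_AD2``.  The result is
    clipped to the admissible density range.
    """
    m = np.asarray(m, dtype=float)
    act = np.asarray(activated, dtype=bool)
    arr = _check_nonneg(P)
    Ps = arr / params.threshold_scale
    drift = np.where(Ps > params.K_AD2, params.tau2 * (Ps - params.K_AD2), 0.0)
    formation = np.where(act, formation_amount(arr, params), drift)
    resorption = np.where(act, params.r_oc, 0.0)
    out = np.clip(m + formation - resorption, DENSITY_FLOOR, DENSITY_CEIL)
    return out if m.ndim or np.ndim(P) or np.ndim(activated) else float(out)


@dataclass(frozen=True)
class QuantumDerivation:
    """Derivation of the per-activation resorption quantum.

    A trabecular BMU resorbs a trench of ``remodeling_area_mm2`` over
    ``period_days``; dividing the daily resorbed area by the finite-element
    area gives the relative density removed per activation.
    """

    daily_area_mm2: float
    relative_density: float


def resorption_quantum(
    remodeling_area_mm2: float = 1.42e-2,
    period_days: float = 60.0,
    element_area_mm2: float = 6.25e-4,
) -> QuantumDerivation:
    daily = remodeling_area_mm2 / period_days
    return QuantumDerivation(
        daily_area_mm2=daily, relative_density=daily / element_area_mm2
    )
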