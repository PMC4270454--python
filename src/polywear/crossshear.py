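"""Principal molecular orientation search and cross-shear ratio.

Polyethylene chains at the bearing surface align with the dominant sliding
direction (the principal molecular orientation, PMO) and strain-harden
along it; sliding transverse to the PMO removes material far more readily.
The cross-shear ratio quantifies this multidirectionality as the fraction
of released frictional work perpendicular to the PMO:

    CSR = sum(W_t) / (sum(W_t) + sum(W_p))

where, per discrete interval, the frictional work is friction force
(mu * pressure * nodal area, mu = 1 by convention — it cancels in the
ratio) times the sliding increment, resolved into absolute components
along and perpendicular to a candidate direction.  The PMO is the
direction that maximises the released parallel work, found by an
exhaustive 1-degree grid search over [0, 180) refined by golden-section
to 0.01 degree.  With absolute-value components the PMO-optimal ratio is
bounded by 0.5: purely reciprocating sliding gives 0, a uniformly swept
circle of slip directions gives 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SphericalMesh
from .kinematics import SlidingField

__all__ = [
    "CrossShearField",
    "frictional_work_split",
    "find_pmo",
    "compute_csr",
]

_INV_PHI = (np.sqrt(5.0) - 1.0) / 2.0  # golden-section step


@dataclass
class CrossShearField:
    """Per-node PMO direction and cross-shear decomposition for one cycle."""

    pmo_direction: np.ndarray  # (n,) radians in [0, pi); 0 where undefined
    work_parallel: np.ndarray  # (n,) N*mm along the PMO
    work_transverse: np.ndarray  # (n,) N*mm perpendicular to the PMO
    csr: np.ndarray  # (n,) in [0, 0.5]; 0 where total work is 0
    defined: np.ndarray  # (n,) bool, False where no loaded sliding occurred


def frictional_work_split(
    increments: np.ndarray,
    pressures: np.ndarray,
    area: float,
    direction: float,
    mu: float = 1.0,
) -> tuple[float, float]:
    """Split one node's cycle frictional work about a candidate direction.

    ``increments`` is (n_intervals, 2) in the node tangent basis,
    ``pressures`` the per-interval contact pressures (MPa; intervals with
    zero pressure contribute nothing), ``area`` the nodal area (mm^2) and
    ``direction`` the candidate PMO angle in radians.  Returns
    (W_parallel, W_transverse) in N*mm.
    """
    u = np.atleast_2d(increments)
    p = np.asarray(pressures, dtype=float)
    force = mu * p * area  # N per interval
    d = np.array([np.cos(direction), np.sin(direction)])
    par = np.abs(u @ d)
    perp = np.abs(u @ np.array([-d[1], d[0]]))
    return float(np.sum(force * par)), float(np.sum(force * perp))


def _work_profile(weights: np.ndarray, alpha: np.ndarray, thetas: np.ndarray) -> np.ndarray:
    """Parallel work of each node at each candidate angle.

    ``weights`` (n, m) are per-interval work magnitudes, ``alpha`` (n, m)
    the interval slip angles, ``thetas`` (t,) the candidate directions.
    Returns (n, t).
    """
    out = np.empty((weights.shape[0], len(thetas)))
    for i, th in enumerate(thetas):
        out[:, i] = np.sum(weights * np.abs(np.cos(alpha - th)), axis=1)
    return out


def _parallel_work_at(weights: np.ndarray, alpha: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """Parallel work per node at a per-node angle ``theta`` (n,)."""
    return np.sum(weights * np.abs(np.cos(alpha - theta[:, None])), axis=1)


def _refine_golden(
    weights: np.ndarray,
    alpha: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    tol: float,
) -> np.ndarray:
    """Vectorised golden-section maximisation of W_parallel per node."""
    a, b = lo.copy(), hi.copy()
    x1 = b - _INV_PHI * (b - a)
    x2 = a + _INV_PHI * (b - a)
    f1 = _parallel_work_at(weights, alpha, x1)
    f2 = _parallel_work_at(weights, alpha, x2)
    while np.max(b - a) > tol:
        take_left = f1 >= f2
        b = np.where(take_left, x2, b)
        a = np.where(take_left, a, x1)
        x1 = b - _INV_PHI * (b - a)
        x2 = a + _INV_PHI * (b - a)
        f1 = _parallel_work_at(weights, alpha, x1)
        f2 = _parallel_work_at(weights, alpha, x2)
    return 0.5 * (a + b)


def find_pmo(
    increments: np.ndarray,
    pressures: np.ndarray,
    area: float = 1.0,
    mu: float = 1.0,
    grid_step_deg: float = 1.0,
    refine_tol_deg: float = 0.01,
) -> tuple[float, float, float]:
    """PMO of a single node: (direction in [0, pi), W_parallel, W_transverse).

    Grid search at ``grid_step_deg`` over [0, 180), ties broken towards the
    smallest angle, then golden-section refinement of the winning bracket
    to ``refine_tol_deg``.  If no work is released (never loaded or never
    sliding) the PMO is undefined and (0, 0, 0) is returned.
    """
    u = np.atleast_2d(increments)[None, :, :]  # (1, m, 2)
    p = np.asarray(pressures, dtype=float)[None, :]
    field = _csr_from_arrays(
        u, p, np.array([area]), mu, grid_step_deg, refine_tol_deg
    )
    return (
        float(field.pmo_direction[0]),
        float(field.work_parallel[0]),
        float(field.work_transverse[0]),
    )


def _csr_from_arrays(
    increments: np.ndarray,
    pressures: np.ndarray,
    areas: np.ndarray,
    mu: float,
    grid_step_deg: float,
    refine_tol_deg: float,
) -> CrossShearField:
    n_nodes = increments.shape[0]
    lengths = np.linalg.norm(increments, axis=2)  # (n, m)
    weights = mu * pressures * areas[:, None] * lengths  # (n, m) work magnitudes
    alpha = np.arctan2(increments[..., 1], increments[..., 0])  # (n, m)

    thetas = np.deg2rad(np.arange(0.0, 180.0, grid_step_deg))
    profile = _work_profile(weights, alpha, thetas)
    best = np.argmax(profile, axis=1)  # first max -> smallest-angle tie-break

    total_work = weights.sum(axis=1)
    defined = total_work > 0.0
    # plateau (all candidates tie, e.g. a uniformly swept circle): keep 0
    spread = profile.max(axis=1) - profile.min(axis=1)
    flat = spread <= 1e-12 * np.maximum(profile.max(axis=1), 1e-300)

    step = np.deg2rad(grid_step_deg)
    lo = thetas[best] - step
    hi = thetas[best] + step
    pmo = _refine_golden(weights, alpha, lo, hi, np.deg2rad(refine_tol_deg))
    pmo = np.mod(pmo, np.pi)
    pmo[flat | ~defined] = 0.0

    w_par = _parallel_work_at(weights, alpha, pmo)
    w_perp = np.sum(weights * np.abs(np.sin(alpha - pmo[:, None])), axis=1)
    total = w_par + w_perp
    csr = np.where(total > 0.0, w_perp / np.where(total > 0.0, total, 1.0), 0.0)
    w_par[~defined] = 0.0
    w_perp[~defined] = 0.0
    return CrossShearField(
        pmo_direction=pmo,
        work_parallel=w_par,
        work_transverse=w_perp,
        csr=csr,
        defined=defined,
    )


def compute_csr(
    mesh: SphericalMesh,
    sliding: SlidingField,
    interval_pressures: np.ndarray,
    mu: float = 1.0,
    grid_step_deg: float = 1.0,
    refine_tol_deg: float = 0.01,
) -> CrossShearField:
    """Cross-shear field of the whole surface for one loaded cycle.

    ``interval_pressures`` is (n_nodes, n_intervals) in MPa, aligned with
    ``sliding.increments``; intervals without contact contribute no work,
    so nodes never loaded get CSR = 0 (flagged undefined).  The ratio is
    invariant to rigid rotation of the tangent basis and to uniform
    scaling of pressure or friction coefficient.
    """
    return _csr_from_arrays(
        sliding.increments,
        np.asarray(interval_pressures, dtype=float),
        mesh.area,
        mu,
        grid_step_deg,
        refine_tol_deg,
    )
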