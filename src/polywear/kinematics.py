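"""Euler-angle hip kinematics, relative head/cup motion and slide tracks.

Rotations follow the flexion/extension -> abduction/adduction ->
internal/external-rotation sequence about the global x, y and z axes
(extrinsic, fixed-axis composition by default; an intrinsic variant is
available behind a flag).  Each axis rotation is performed by whichever
bearing component carries it in the protocol, and the motion that matters
for sliding and wear is the rotation of the head *relative to* the cup.

Sliding is bookkept in the cup's material frame: for every surface node
the per-interval slip of the rigid head counterface across that node is
expressed as a 2-vector in the node's fixed tangent basis.  This material-
frame convention is what the principal-molecular-orientation search
consumes — a point sliding on a spinning counterface without direction
change in its own frame is unidirectional sliding, exactly as for a pin on
a rotating disc.  Slide tracks (the closed path each cup node traces on the
head sphere over one cycle) are provided separately for visualisation,
together with the azimuthal-equidistant "flattened hemisphere" projection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SphericalMesh, tangent_basis
from .protocols import MotionLoadCycle

__all__ = [
    "euler_rotation",
    "motion_rotations",
    "relative_motion",
    "SlidingField",
    "compute_sliding",
    "slide_track",
    "flatten_track",
    "average_cycle_distance",
]


def _axis_rotation(axis: int, angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    m = np.eye(3)
    i, j = [(1, 2), (2, 0), (0, 1)][axis]
    m[i, i] = c
    m[j, j] = c
    m[i, j] = -s
    m[j, i] = s
    return m


def euler_rotation(
    fe_deg: float, aa_deg: float, ier_deg: float, intrinsic: bool = False
) -> np.ndarray:
    """Composed FE -> AA -> IER rotation operator (3x3, proper orthogonal).

    Extrinsic (default): each rotation is about the fixed global axis, FE
    applied first, giving R = Rz(ier) @ Ry(aa) @ Rx(fe).  Intrinsic: each
    subsequent rotation is about the already-rotated body axis.
    """
    rx = _axis_rotation(0, fe_deg)
    ry = _axis_rotation(1, aa_deg)
    rz = _axis_rotation(2, ier_deg)
    if intrinsic:
        return rx @ ry @ rz
    return rz @ ry @ rx


def motion_rotations(
    cycle: MotionLoadCycle, index: int, intrinsic: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """World rotations (R_head, R_cup) at time sample ``index``.

    Each axis of the FE -> AA -> IER sequence contributes to the component
    that carries it; an axis with carrier ``none`` contributes to neither.
    """
    fe, aa, ier = cycle.angles(index)
    r_head = np.eye(3)
    r_cup = np.eye(3)
    for axis, angle, carrier in (
        (0, fe, cycle.fe_carrier),
        (1, aa, cycle.aa_carrier),
        (2, ier, cycle.ier_carrier),
    ):
        if carrier == "none":
            continue
        step = _axis_rotation(axis, angle)
        if carrier == "head":
            r_head = step @ r_head if not intrinsic else r_head @ step
        else:
            r_cup = step @ r_cup if not intrinsic else r_cup @ step
    return r_head, r_cup


def relative_motion(
    cycle: MotionLoadCycle, index: int, intrinsic: bool = False
) -> np.ndarray:
    """Rotation of the head frame relative to the cup frame at one sample.

    R_rel = R_cup^T R_head: carrying an angle on the head or the negated
    angle on the cup yields the same relative operator.
    """
    r_head, r_cup = motion_rotations(cycle, index, intrinsic=intrinsic)
    return r_cup.T @ r_head


@dataclass
class SlidingField:
    """Per-node, per-interval sliding of the head across the cup surface.

    ``increments`` holds the slip 2-vectors in each node's fixed (east,
    north) tangent basis, arc-corrected so that their norms equal the
    great-circle ``distances``; ``cycle_distance`` is the per-node total
    over one cycle.
    """

    increments: np.ndarray  # (n_nodes, n_intervals, 2) mm
    distances: np.ndarray  # (n_nodes, n_intervals) mm
    cycle_distance: np.ndarray  # (n_nodes,) mm
    basis_east: np.ndarray  # (n_nodes, 3)
    basis_north: np.ndarray  # (n_nodes, 3)


def _relative_series(
    cycle: MotionLoadCycle, mount: np.ndarray | None, intrinsic: bool
) -> list[np.ndarray]:
    """Head-relative-to-cup rotations in the (inclined) cup frame, one per
    sample.  ``mount`` is the fixed cup-mount rotation (e.g. inclination)."""
    m = np.eye(3) if mount is None else np.asarray(mount)
    return [
        m.T @ relative_motion(cycle, j, intrinsic=intrinsic)
        for j in range(cycle.n_samples)
    ]


def _rotation_vector(m: np.ndarray) -> np.ndarray:
    """Rotation vector (axis * angle, radians) of a proper rotation matrix.

    Interval steps in a gait cycle are small (well below pi), so the
    near-pi branch is not needed; the small-angle limit is handled.
    """
    skew = np.array([m[2, 1] - m[1, 2], m[0, 2] - m[2, 0], m[1, 0] - m[0, 1]])
    cos_a = np.clip((np.trace(m) - 1.0) / 2.0, -1.0, 1.0)
    angle = np.arccos(cos_a)
    if angle < 1e-12:
        return 0.5 * skew
    return skew * (angle / (2.0 * np.sin(angle)))


def compute_sliding(
    mesh: SphericalMesh,
    cycle: MotionLoadCycle,
    mount: np.ndarray | None = None,
    intrinsic: bool = False,
) -> SlidingField:
    """Slide increments and distances for every node over one cycle.

    For the interval between samples j and j+1 (cyclically wrapped) the
    counterface step is ``dR = R_rel(j+1) R_rel(j)^T`` with rotation
    vector w; the slip of the head across node n is the velocity-form
    increment R (w x n), which is exactly tangent to the surface and whose
    norm is the small-circle path length the counterface sweeps past the
    node.  For a constant-axis interval this is exact (unidirectional
    motion stays exactly unidirectional); for mixed-axis intervals the
    error is second order in the per-interval step angle (< 0.2 rad at 16
    samples).  Sliding is evaluated on the nominal sphere radius — wear
    depths (< 0.1 mm) change it by < 1%.
    """
    n_t = cycle.n_samples
    dirs = mesh.directions
    radius = mesh.radius
    east, north = tangent_basis(dirs)
    rel = _relative_series(cycle, mount, intrinsic)

    increments = np.empty((mesh.n_nodes, n_t, 2))
    distances = np.empty((mesh.n_nodes, n_t))
    for j in range(n_t):
        d_rot = rel[(j + 1) % n_t] @ rel[j].T
        w = _rotation_vector(d_rot)
        slip = radius * np.cross(np.broadcast_to(w, dirs.shape), dirs)
        increments[:, j, 0] = np.sum(slip * east, axis=1)
        increments[:, j, 1] = np.sum(slip * north, axis=1)
        distances[:, j] = np.linalg.norm(slip, axis=1)
    return SlidingField(
        increments=increments,
        distances=distances,
        cycle_distance=distances.sum(axis=1),
        basis_east=east,
        basis_north=north,
    )


def slide_track(
    mesh: SphericalMesh,
    cycle: MotionLoadCycle,
    node_index: int,
    mount: np.ndarray | None = None,
    convention: str = "cup_on_head",
    intrinsic: bool = False,
) -> np.ndarray:
    """Closed track of one node's contact point over a cycle, (n+1, 3) mm.

    ``cup_on_head`` (default): positions of the cup node's contact point on
    the head bearing sphere, in the head frame.  ``head_on_cup``: track of
    the head material point (the one under the node at sample 0) across the
    cup surface, in the cup frame.  The final point repeats the first.
    """
    rel = _relative_series(cycle, mount, intrinsic)
    n = mesh.directions[node_index]
    if convention == "cup_on_head":
        pts = [r.T @ n for r in rel]
    elif convention == "head_on_cup":
        h = rel[0].T @ n
        pts = [r @ h for r in rel]
    else:
        raise ValueError("convention must be 'cup_on_head' or 'head_on_cup'")
    pts.append(pts[0])
    return mesh.radius * np.asarray(pts)


def flatten_track(points: np.ndarray) -> np.ndarray:
    """Azimuthal-equidistant projection of on-sphere points about the +z pole.

    The radial plot coordinate equals the arc distance from the pole along
    the sphere, so a meridian maps to a straight ray with arc length
    preserved and the equator of a sphere of radius R maps to the circle of
    radius pi R / 2.
    """
    p = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(p, axis=1)
    rho = r * np.arccos(np.clip(p[:, 2] / r, -1.0, 1.0))
    phi = np.arctan2(p[:, 1], p[:, 0])
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])


def average_cycle_distance(field: SlidingField, mesh: SphericalMesh) -> float:
    """Area-weighted surface average of the per-cycle sliding distance, mm."""
    return float(np.average(field.cycle_distance, weights=mesh.area))
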