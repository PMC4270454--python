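"""Elastic-foundation (Winkler) ball-in-socket contact.

The polyethylene layer is idealised as a bed of independent springs on the
rigid backing shell, with stiffness per unit area

    k = (1 - nu) E / [(1 + nu)(1 - 2 nu) d]

(the confined-layer modulus of a thin bonded elastic layer indented by a
rigid body).  At each time point the rigid head centre translates until the
integrated nodal pressures balance the applied load; nodal pressure is
k times the local overclosure against the *worn* cup surface
(radius + penetration per node), optionally capped by a perfectly-plastic
limit.  For the conforming, sub-yield pressures of these bearings
(peaks below ~10 MPa) the foundation model reproduces the pressure
magnitudes and contact areas the wear law needs; the wear coefficient is
itself pressure-independent over 1-10 MPa, so high contact-mechanics
fidelity is not required.

The equilibrium problem is solved over the three head-centre translations
with a damped (semismooth) Newton iteration using the analytic Jacobian of
the spring integral; the system is smooth and well conditioned at these
conformities and converges in a handful of iterations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, SolverError
from .geometry import BearingSpec, SphericalMesh, inclination_matrix
from .kinematics import motion_rotations
from .protocols import MotionLoadCycle

__all__ = [
    "ContactState",
    "foundation_modulus",
    "solve_contact",
    "solve_cycle_contact",
]


@dataclass
class ContactState:
    """Equilibrium contact solution at one time point."""

    head_center_displacement: np.ndarray  # (3,) mm, cup frame
    node_pressure: np.ndarray  # (n,) MPa, >= 0
    contact_area: float  # mm^2, total area of loaded nodes
    equilibrium_residual: float  # |force imbalance| / |applied load|
    load_vector: np.ndarray  # (3,) N, cup frame


def foundation_modulus(spec: BearingSpec) -> float:
    """Winkler stiffness of the confined polyethylene layer, MPa/mm."""
    if not spec.poisson_ratio < 0.5:  # unreachable via BearingSpec, kept for direct use
        raise ConfigurationError("nu = 0.5 gives a singular confined-layer modulus")
    return spec.foundation_modulus


def solve_contact(
    mesh: SphericalMesh,
    spec: BearingSpec,
    load_vector: np.ndarray,
    initial_displacement: np.ndarray | None = None,
    pressure_cap: float | None = None,
    tol: float = 1e-3,
    max_iter: int = 100,
) -> ContactState:
    """Solve quasi-static head/cup equilibrium for one load vector.

    ``load_vector`` is the resultant force on the head expressed in the cup
    frame, N.  ``pressure_cap`` defaults to 3x the yield stress (an upper
    bound on the mean pressure a perfectly-plastic layer can carry);
    pass ``numpy.inf`` to disable.  The returned residual is the force
    imbalance as a fraction of the applied load and satisfies
    ``residual <= tol`` on success.
    """
    load = np.asarray(load_vector, dtype=float)
    magnitude = float(np.linalg.norm(load))
    if magnitude <= 0.0:
        raise ValueError("load magnitude must be positive")
    cap = 3.0 * spec.yield_stress if pressure_cap is None else float(pressure_cap)
    k = spec.foundation_modulus
    dirs = mesh.directions
    area = mesh.area
    gap = mesh.worn_radius - spec.head_radius  # (n,) radial gap at zero displacement

    def pressures(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        over = dirs @ c - gap
        p = k * np.clip(over, 0.0, None)
        return np.minimum(p, cap), over

    def residual(c: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        p, over = pressures(c)
        force = (p * area) @ dirs
        return force - load, over

    def energy(c: np.ndarray) -> float:
        # convex spring potential minus load work; its gradient is -residual
        over = dirs @ c - gap
        o = np.clip(over, 0.0, None)
        elastic = np.where(
            k * o <= cap, 0.5 * k * o**2, cap * o - 0.5 * cap**2 / k
        )
        return float(area @ elastic - load @ c)

    u = load / magnitude
    proj = dirs @ u
    facing = proj > 0.2
    if not np.any(facing):
        raise SolverError("load direction points away from the cup surface")

    def seat(c: np.ndarray) -> np.ndarray:
        """Translate along the load axis until the surfaces just engage."""
        touch = np.min((gap - dirs @ c)[facing] / proj[facing])
        return c + u * (touch + magnitude / (k * float(area.sum())))

    if initial_displacement is not None:
        c = np.asarray(initial_displacement, dtype=float).copy()
    else:
        c = seat(np.zeros(3))

    g, over = residual(c)
    gnorm = float(np.linalg.norm(g))
    reg = 1e-9 * k * float(area.sum())
    for _ in range(max_iter):
        if not np.any(over > 0.0):  # fully separated (e.g. stale warm start)
            c = seat(c)
            g, over = residual(c)
            gnorm = float(np.linalg.norm(g))
        if gnorm <= tol * magnitude:
            p, _ = pressures(c)
            return ContactState(
                head_center_displacement=c,
                node_pressure=p,
                contact_area=float(area[p > 0.0].sum()),
                equilibrium_residual=gnorm / magnitude,
                load_vector=load,
            )
        active = (over > 0.0) & (k * over < cap)
        if not np.any(active):
            active = over > -np.inf  # fully capped: fall back to full stiffness
        w = k * area[active]
        da = dirs[active]
        jac = (da * w[:, None]).T @ da + reg * np.eye(3)
        step = np.linalg.solve(jac, -g)
        # the equilibrium is the minimum of the convex spring energy, and the
        # damped Newton step is a descent direction: backtrack on the energy
        e0 = energy(c)
        slope = float(g @ step)  # dE/dlam at 0 (grad E = -residual... = g)
        lam = 1.0
        for _ in range(40):
            if energy(c + lam * step) <= e0 + 1e-4 * lam * slope:
                break
            lam *= 0.5
        c = c + lam * step
        g, over = residual(c)
        gnorm = float(np.linalg.norm(g))
    raise SolverError(
        f"contact equilibrium not converged after {max_iter} iterations; "
        f"last residual {gnorm / magnitude:.3e} of applied load"
    )


def solve_cycle_contact(
    mesh: SphericalMesh,
    spec: BearingSpec,
    cycle: MotionLoadCycle,
    mount: np.ndarray | None = None,
    intrinsic: bool = False,
    warm_starts: list[np.ndarray] | None = None,
    **solver_kwargs,
) -> list[ContactState]:
    """Solve contact at every time sample of a motion/load cycle.

    The globally fixed load direction is re-expressed in the (possibly
    moving) cup frame at each sample: with the cup-mount rotation M (the
    inclination by default) and the cup-carried motion R_cup(t), the cup
    frame load is (R_cup(t) M)^T applied to the world load vector.
    ``warm_starts`` (one displacement per sample, e.g. from the previous
    geometry-update interval) accelerates the Newton iterations.
    """
    m = inclination_matrix(spec.inclination_deg) if mount is None else np.asarray(mount)
    states: list[ContactState] = []
    previous: np.ndarray | None = None
    for j in range(cycle.n_samples):
        _, r_cup = motion_rotations(cycle, j, intrinsic=intrinsic)
        world_load = cycle.load_direction * cycle.load_magnitude[j]
        cup_load = (r_cup @ m).T @ world_load
        start = None
        if warm_starts is not None and warm_starts[j] is not None:
            start = warm_starts[j]
        elif previous is not None:
            start = previous
        state = solve_contact(
            mesh, spec, cup_load, initial_displacement=start, **solver_kwargs
        )
        previous = state.head_center_displacement
        states.append(state)
    return states
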