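"""Multi-million-cycle wear simulation driver.

The simulation advances in geometry-update intervals: the wear and creep
computed for one representative motion/load cycle on the current (worn)
surface are scaled by the number of cycles in the interval, the nodal
coordinates are corrected, and contact and cross-shear are recomputed on
the updated geometry.  Because creep accumulates with the logarithm of
loading time, the first part of the simulation (64,000 cycles by default)
is split into 10 log-spaced intervals to resolve the fast early creep;
afterwards the update factor is fixed at 250,000 cycles up to the 5
million cycle total.

Within one interval the pipeline is: solve contact at the 16 cycle time
points -> form per-interval pressures -> cross-shear ratio via the PMO
search -> per-cycle linear wear delta = C(CSR) * sum(L_i) over loaded
intervals -> scale by the interval length -> creep increment from the
running mean contact pressure -> apply the penetration to the mesh.  The
sliding field depends only on the kinematics and the node directions, so
it is computed once per simulation.  The whole pipeline is deterministic:
identical inputs produce bit-identical results.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import wear_creep
from .contact import ContactState, solve_contact, solve_cycle_contact
from .crossshear import CrossShearField, compute_csr
from .errors import ConfigurationError
from .geometry import BearingSpec, SphericalMesh, apply_penetration, build_cup_mesh, inclination_matrix
from .kinematics import SlidingField, average_cycle_distance, compute_sliding
from .protocols import MotionLoadCycle
from .wear_creep import WearState

__all__ = [
    "UpdateSchedule",
    "SimulationSummary",
    "SimulationResult",
    "build_schedule",
    "run_simulation",
    "summarize",
    "compare_protocols",
    "first_peak_load_index",
]

logger = logging.getLogger("polywear")

#: default threshold on cumulative wear depth defining the "worn area", mm
DEFAULT_WORN_THRESHOLD = 0.01


@dataclass(frozen=True)
class UpdateSchedule:
    """Geometry-update checkpoints (in cycles) for one simulation."""

    checkpoints: np.ndarray  # strictly increasing, last = total_cycles
    initial_phase_cycles: int = 64_000
    n_log_intervals: int = 10
    steady_update_factor: int = 250_000
    total_cycles: int = 5_000_000
    cycle_period: float = 1.0  # seconds per cycle


def build_schedule(
    total_cycles: int = 5_000_000,
    initial_phase_cycles: int = 64_000,
    n_log_intervals: int = 10,
    steady_update_factor: int = 250_000,
    cycle_period: float = 1.0,
) -> UpdateSchedule:
    """Log-spaced early checkpoints followed by fixed-factor updates.

    The first ``n_log_intervals`` checkpoints are geometrically spaced over
    (0, initial_phase_cycles]; subsequent checkpoints advance by
    ``steady_update_factor`` cycles, with a final (possibly shorter)
    interval ending exactly at ``total_cycles``.
    """
    if total_cycles <= 0 or steady_update_factor <= 0 or n_log_intervals < 0:
        raise ConfigurationError("schedule counts must be positive")
    if initial_phase_cycles < 0 or initial_phase_cycles > total_cycles:
        raise ConfigurationError(
            "initial_phase_cycles must lie in [0, total_cycles]"
        )
    points: list[int] = []
    if initial_phase_cycles > 0 and n_log_intervals > 0:
        raw = initial_phase_cycles ** (
            np.arange(1, n_log_intervals + 1) / n_log_intervals
        )
        for r in raw:
            c = int(round(r))
            if c >= 1 and (not points or c > points[-1]):
                points.append(c)
    start = points[-1] if points else 0
    if steady_update_factor > total_cycles - start and start < total_cycles:
        warnings.warn(
            "steady_update_factor exceeds the remaining cycles; "
            "using a single final checkpoint",
            stacklevel=2,
        )
    nxt = start + steady_update_factor
    while nxt < total_cycles:
        points.append(nxt)
        nxt += steady_update_factor
    if not points or points[-1] != total_cycles:
        points.append(total_cycles)
    return UpdateSchedule(
        checkpoints=np.asarray(points, dtype=np.int64),
        initial_phase_cycles=initial_phase_cycles,
        n_log_intervals=n_log_intervals,
        steady_update_factor=steady_update_factor,
        total_cycles=total_cycles,
        cycle_period=cycle_period,
    )


@dataclass
class SimulationSummary:
    """Headline metrics of one completed simulation."""

    protocol: str
    wear_rate: float  # mm^3 per 10^6 cycles, slope over the final 4M cycles
    wear_rate_full_range: float  # mm^3 per 10^6 cycles, slope over the whole run
    volumetric_wear: float  # mm^3 at the end of the run
    max_linear_wear_depth: float  # mm (wear only)
    max_penetration: float  # mm (wear + creep)
    worn_area: float  # mm^2 with wear depth > worn_threshold
    worn_threshold: float  # mm
    max_csr: float
    avg_sliding_distance: float  # mm per cycle, surface average
    peak_pressure_at_first_peak_load: float  # MPa, final worn geometry
    total_cycles: int


@dataclass
class SimulationResult:
    """Full field-level outcome of one simulation."""

    spec: BearingSpec
    cycle: MotionLoadCycle
    schedule: UpdateSchedule
    mesh: SphericalMesh  # final worn mesh
    sliding: SlidingField
    wear: WearState = None  # type: ignore[assignment]
    csr: CrossShearField = None  # type: ignore[assignment]
    cycles_history: np.ndarray = None  # type: ignore[assignment]
    volume_history: np.ndarray = None  # type: ignore[assignment]
    residual_log: list = field(default_factory=list)
    final_pressures: np.ndarray = None  # type: ignore[assignment] # (n_t, n_nodes)
    peak_load_state: ContactState = None  # type: ignore[assignment]
    peak_load_index: int = 0
    summary: SimulationSummary = None  # type: ignore[assignment]


def first_peak_load_index(cycle: MotionLoadCycle) -> int:
    """Index of the first local maximum of the load waveform (cyclic)."""
    load = cycle.load_magnitude
    n = len(load)
    for j in range(n):
        if load[j] >= load[(j - 1) % n] and load[j] > load[(j + 1) % n]:
            return j
    return int(np.argmax(load))


def _interval_pressures(pressures: np.ndarray) -> np.ndarray:
    """(n_t, n) sample pressures -> (n, n_t) per-interval means (cyclic)."""
    nxt = np.roll(pressures, -1, axis=0)
    return (0.5 * (pressures + nxt)).T


def run_simulation(
    spec: BearingSpec,
    cycle: MotionLoadCycle,
    schedule: UpdateSchedule | None = None,
    target_spacing: float = 0.5,
    worn_threshold: float = DEFAULT_WORN_THRESHOLD,
    wear_scale: float = wear_creep.WEAR_COEFFICIENT_SCALE,
    csr_grid_step_deg: float = 1.0,
    intrinsic_euler: bool = False,
    mesh: SphericalMesh | None = None,
) -> SimulationResult:
    """Run a full wear + creep simulation for one motion/load protocol.

    Returns the final worn mesh, accumulated wear state, volumetric wear
    history at every geometry-update checkpoint and a summary of the
    headline metrics.  Deterministic end-to-end.
    """
    if schedule is None:
        schedule = build_schedule()
    if mesh is None:
        mesh = build_cup_mesh(spec, target_spacing)
    mount = inclination_matrix(spec.inclination_deg)
    sliding = compute_sliding(mesh, cycle, mount=mount, intrinsic=intrinsic_euler)

    state = WearState.zeros(mesh.n_nodes)
    cycles_hist = [0]
    volume_hist = [0.0]
    residual_log: list[float] = []
    warm: list[np.ndarray] | None = None
    csr_field: CrossShearField | None = None
    minutes_per_cycle = schedule.cycle_period / 60.0

    previous = 0
    for checkpoint in schedule.checkpoints:
        n_cycles = int(checkpoint) - previous
        contact_states = solve_cycle_contact(
            mesh, spec, cycle, mount=mount, intrinsic=intrinsic_euler, warm_starts=warm
        )
        warm = [s.head_center_displacement for s in contact_states]
        pressures = np.array([s.node_pressure for s in contact_states])  # (n_t, n)
        worst = max(s.equilibrium_residual for s in contact_states)
        residual_log.append(worst)
        t1_min = previous * minutes_per_cycle
        t2_min = int(checkpoint) * minutes_per_cycle

        # running time-average pressure over the full simulated history
        state.pressure_time_integral += pressures.mean(axis=0) * (t2_min - t1_min)
        state.loaded_minutes = t2_min
        state.mean_pressure = state.pressure_time_integral / state.loaded_minutes

        p_int = _interval_pressures(pressures)  # (n, n_t)
        csr_field = compute_csr(
            mesh, sliding, p_int, grid_step_deg=csr_grid_step_deg
        )
        coeff = wear_creep.wear_coefficient(csr_field.csr, scale=wear_scale)
        delta_cycle = wear_creep.linear_wear_cycle(coeff, sliding, p_int)

        d_wear = delta_cycle * n_cycles
        d_creep = wear_creep.creep_increment(state.mean_pressure, t1_min, t2_min, spec)
        state.wear_depth += d_wear
        state.creep_depth += d_creep
        state.volumetric_wear += wear_creep.volumetric_wear(d_wear, mesh)
        mesh = apply_penetration(mesh, d_wear + d_creep)

        cycles_hist.append(int(checkpoint))
        volume_hist.append(state.volumetric_wear)
        logger.info(
            "checkpoint %9d cycles: V = %8.3f mm^3, max residual %.2e",
            checkpoint, state.volumetric_wear, worst,
        )
        previous = int(checkpoint)

    result = SimulationResult(
        spec=spec,
        cycle=cycle,
        schedule=schedule,
        mesh=mesh,
        sliding=sliding,
        wear=state,
        csr=csr_field,
        cycles_history=np.asarray(cycles_hist, dtype=np.int64),
        volume_history=np.asarray(volume_hist),
        residual_log=residual_log,
    )
    # contact at the first load peak on the final worn geometry
    peak = first_peak_load_index(cycle)
    peak_states = solve_cycle_contact(
        mesh, spec, cycle, mount=mount, intrinsic=intrinsic_euler, warm_starts=warm
    )
    result.final_pressures = np.array([s.node_pressure for s in peak_states])
    result.peak_load_state = peak_states[peak]
    result.peak_load_index = peak
    result.summary = summarize(result, worn_threshold=worn_threshold)
    return result


def _slope_per_million(cycles: np.ndarray, volume: np.ndarray) -> float:
    if len(cycles) < 2:
        return 0.0
    coeffs = np.polyfit(cycles.astype(float), volume, 1)
    return float(coeffs[0] * 1e6)


def summarize(
    result: SimulationResult, worn_threshold: float = DEFAULT_WORN_THRESHOLD
) -> SimulationSummary:
    """Headline metrics of a completed run.

    The wear rate is the least-squares slope of V(cycles) over the final
    4 million cycles (excluding the creep-dominated early phase, over
    which the update intervals are log-spaced); the slope over the whole
    run is also reported.  The worn area counts nodes whose cumulative
    wear depth exceeds ``worn_threshold``.
    """
    cycles = result.cycles_history
    volume = result.volume_history
    total = int(cycles[-1])
    late = cycles >= max(0, total - 4_000_000)
    if late.sum() < 2:
        late = np.ones_like(cycles, dtype=bool)
    mesh = result.mesh
    worn = result.wear.wear_depth > worn_threshold
    return SimulationSummary(
        protocol=result.cycle.name,
        wear_rate=_slope_per_million(cycles[late], volume[late]),
        wear_rate_full_range=_slope_per_million(cycles, volume),
        volumetric_wear=float(volume[-1]),
        max_linear_wear_depth=float(result.wear.wear_depth.max()),
        max_penetration=float(result.wear.total_penetration.max()),
        worn_area=float(mesh.area[worn].sum()),
        worn_threshold=worn_threshold,
        max_csr=float(result.csr.csr.max()) if result.csr is not None else 0.0,
        avg_sliding_distance=average_cycle_distance(result.sliding, mesh),
        peak_pressure_at_first_peak_load=float(result.peak_load_state.node_pressure.max()),
        total_cycles=total,
    )


_COMPARED = {
    "wear_rate": "wear_rate",
    "worn_area": "worn_area",
    "max_linear_wear_depth": "max_linear_wear_depth",
    "max_csr": "max_csr",
    "avg_sliding_distance": "avg_sliding_distance",
}


def compare_protocols(
    summaries: list[SimulationSummary], reference: int = 0
) -> pd.DataFrame:
    """Percent differences of each summary's metrics vs a reference case.

    Rows are protocols; entries are 100 * (value - reference) / reference.
    The reference row is all zeros.  Swapping reference and comparison
    changes only the sign convention of each pairwise delta.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two summaries to compare")
    ref = summaries[reference]
    rows = {}
    for s in summaries:
        row = {}
        for col, attr in _COMPARED.items():
            value, base = getattr(s, attr), getattr(ref, attr)
            if base == 0.0:
                row[col] = 0.0 if value == 0.0 else float("nan")
            else:
                row[col] = 100.0 * (value - base) / base
        rows[s.protocol or "?"] = row
    frame = pd.DataFrame(rows).T
    frame.index.name = f"vs {ref.protocol or 'reference'} (%)"
    return frame
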