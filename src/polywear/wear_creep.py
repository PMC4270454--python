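"""Cross-shear-dependent wear law and logarithmic creep.

Volumetric wear follows the contact-area-dependent law V = C A L: wear
volume is proportional to the nominal contact area and the sliding
distance, with a wear coefficient C that is independent of contact
pressure over the 1-10 MPa range of these bearings but increases with the
cross-shear ratio.  For conventional non-cross-linked UHMWPE (GUR 1050)
the pin-on-plate-calibrated coefficient is

    C(CSR) = (8.5e-5 + 9.3 * CSR)**0.15 * S,       S = 1e-9 by default,

a sharp rise over CSR = 0-0.01 followed by a plateau (about 1.0-1.6e-9)
over CSR = 0.02-0.5.  The published form of this expression carries a
typographically corrupted scale; the exponent/scale pair used here
reproduces the published coefficient magnitudes at both ends of the CSR
range and ``S`` is exposed as a parameter.  Dividing V = C A L by the
contact area gives the linear wear depth per cycle, delta = sum_i C L_i,
accumulated over the intervals in which the node actually carries contact
pressure (the law is defined within the contact patch).

Creep deformation at a point follows the logarithmic law

    delta_cr = B * p_bar * log10(t) * d

with B the creep constant (per MPa per decade of minutes), p_bar the
average contact pressure over the loading history, t the loading time in
minutes and d the polyethylene wall thickness.  Creep is irreversible and
is superposed with wear into the total linear penetration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BearingSpec, SphericalMesh
from .kinematics import SlidingField

__all__ = [
    "WEAR_COEFFICIENT_SCALE",
    "WearState",
    "wear_coefficient",
    "linear_wear_cycle",
    "volumetric_wear",
    "creep_depth",
    "creep_increment",
]

#: default overall scale S of the wear-coefficient law (dimensionless)
WEAR_COEFFICIENT_SCALE = 1e-9


@dataclass
class WearState:
    """Accumulated per-node wear/creep state of one simulation."""

    wear_depth: np.ndarray  # (n,) mm, nondecreasing
    creep_depth: np.ndarray  # (n,) mm, nondecreasing
    mean_pressure: np.ndarray  # (n,) MPa, running time-average incl. unloaded time
    volumetric_wear: float = 0.0  # mm^3
    loaded_minutes: float = 0.0
    pressure_time_integral: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pressure_time_integral is None:
            self.pressure_time_integral = np.zeros_like(self.wear_depth)

    @property
    def total_penetration(self) -> np.ndarray:
        """Superposed linear wear + creep, mm."""
        return self.wear_depth + self.creep_depth

    @classmethod
    def zeros(cls, n_nodes: int) -> "WearState":
        return cls(
            wear_depth=np.zeros(n_nodes),
            creep_depth=np.zeros(n_nodes),
            mean_pressure=np.zeros(n_nodes),
        )


def wear_coefficient(
    csr: np.ndarray | float, scale: float = WEAR_COEFFICIENT_SCALE
) -> np.ndarray | float:
    """Wear coefficient C as a function of cross-shear ratio.

    Strictly increasing in CSR; valid for CSR in [0, 1].
    """
    c = np.asarray(csr, dtype=float)
    if np.any(c < 0.0) or np.any(c > 1.0):
        raise ValueError("CSR must lie in [0, 1]")
    out = (8.5e-5 + 9.3 * c) ** 0.15 * scale
    return float(out) if np.isscalar(csr) else out


def linear_wear_cycle(
    coefficient: np.ndarray,
    sliding: SlidingField,
    interval_pressures: np.ndarray,
) -> np.ndarray:
    """Linear wear depth increment per node for one cycle, mm.

    delta = C(CSR) * sum of interval sliding distances, counting only the
    intervals in which the node carries pressure: a node never loaded
    accrues no wear regardless of how far the counterface slides past it.
    """
    loaded = np.asarray(interval_pressures) > 0.0
    return np.asarray(coefficient) * np.sum(sliding.distances * loaded, axis=1)


def volumetric_wear(delta: np.ndarray, mesh: SphericalMesh) -> float:
    """Surface integral of a linear wear-depth field, mm^3.

    For a spatially uniform depth C*L over a contact patch of area A this
    recovers V = C A L.
    """
    return float(np.sum(np.asarray(delta) * mesh.area))


def creep_depth(
    mean_pressure: np.ndarray | float, t_minutes: float, spec: BearingSpec
) -> np.ndarray | float:
    """Total creep deformation after ``t_minutes`` of loading, mm.

    Times below 1 minute are clamped to 1 (log10(1) = 0), so creep starts
    accumulating after the first minute of loading.
    """
    t = max(float(t_minutes), 1.0)
    out = spec.creep_constant * np.asarray(mean_pressure, dtype=float) * np.log10(t) * spec.pe_wall_thickness
    return float(out) if np.isscalar(mean_pressure) else out


def creep_increment(
    mean_pressure: np.ndarray,
    t_start_minutes: float,
    t_end_minutes: float,
    spec: BearingSpec,
) -> np.ndarray:
    """Incremental creep between two loading times, using the current
    pressure history average: B * p_bar * (log10 t2 - log10 t1) * d."""
    t1 = max(float(t_start_minutes), 1.0)
    t2 = max(float(t_end_minutes), 1.0)
    if t2 < t1:
        raise ValueError("t_end_minutes must be >= t_start_minutes")
    factor = spec.creep_constant * (np.log10(t2) - np.log10(t1)) * spec.pe_wall_thickness
    return factor * np.asarray(mean_pressure, dtype=float)
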