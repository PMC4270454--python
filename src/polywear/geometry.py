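"""Bearing specification and hemispherical cup surface meshes.

The articulation is modelled as a ball-in-socket joint: a rigid spherical
femoral head running inside a polyethylene acetabular cup whose bearing
surface is a hemisphere.  Only the cup *surface* is discretised — the wear
law and the elastic-foundation contact model consume nodal pressures, areas
and sliding fields on that surface, never a through-thickness stress state —
so the mesh is a near-uniform point set on the hemisphere (Fibonacci
lattice) with equal area weights, rather than a volume mesh.

Wear and creep are accumulated as a scalar radial offset per node
(``penetration``): material removal moves the local cup surface radially
outward from the head's point of view, i.e. the local cup radius becomes
``cup_radius + penetration``.  The head stays a perfect sphere throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "BearingSpec",
    "SphericalMesh",
    "build_cup_mesh",
    "apply_inclination",
    "inclination_matrix",
    "apply_penetration",
    "tangent_basis",
]

#: golden angle in radians, used for the Fibonacci hemisphere lattice
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass(frozen=True)
class BearingSpec:
    """Geometry and material constants of one metal-on-polyethylene bearing.

    Defaults describe a nominal 28 mm diameter joint: 0.04 mm radial
    clearance, an 8 mm polyethylene wall on a 4 mm metallic backing shell,
    cup inclined 35 deg under a vertically applied resultant load
    (equivalent to a 45 deg anatomical cup with the load vector 10 deg
    medial).  Material constants are those of conventional non-cross-linked
    UHMWPE (GUR 1050).

    Parameters
    ----------
    head_radius : float
        Femoral head radius, mm.
    radial_clearance : float
        Cup radius minus head radius, mm.
    pe_wall_thickness : float
        Thickness ``d`` of the polyethylene layer, mm.  Enters both the
        elastic-foundation stiffness and the creep law.
    backing_thickness : float
        Metallic backing shell thickness, mm (rigid; bookkeeping only).
    inclination_deg : float
        Cup inclination from the global vertical, degrees.
    elastic_modulus, poisson_ratio : float
        Polyethylene elastic constants (MPa, dimensionless).
    yield_stress : float
        Initial von Mises yield stress, MPa.  Used only for the optional
        perfectly-plastic pressure cap (3x yield by default).
    creep_constant : float
        ``B`` in the logarithmic creep law, 1/(MPa*decade).
    """

    head_radius: float = 14.0
    radial_clearance: float = 0.04
    pe_wall_thickness: float = 8.0
    backing_thickness: float = 4.0
    inclination_deg: float = 35.0
    elastic_modulus: float = 500.0
    poisson_ratio: float = 0.4
    yield_stress: float = 10.8
    creep_constant: float = 7.97e-4

    def __post_init__(self) -> None:
        if self.head_radius <= 0:
            raise ConfigurationError("head_radius must be positive")
        if self.radial_clearance < 0:
            raise ConfigurationError("radial_clearance must be >= 0")
        if self.cup_radius <= 0:
            raise ConfigurationError("cup_radius must be positive")
        if not 0.0 < self.poisson_ratio < 0.5:
            raise ConfigurationError(
                "poisson_ratio must lie in (0, 0.5); nu = 0.5 makes the "
                "confined elastic layer incompressible (singular stiffness)"
            )
        if self.elastic_modulus <= 0:
            raise ConfigurationError("elastic_modulus must be positive")
        if self.pe_wall_thickness <= 0:
            raise ConfigurationError("pe_wall_thickness must be positive")
        if self.yield_stress <= 0:
            raise ConfigurationError("yield_stress must be positive")

    @property
    def cup_radius(self) -> float:
        """Cup bearing-surface radius, mm (= head radius + clearance)."""
        return self.head_radius + self.radial_clearance

    @property
    def foundation_modulus(self) -> float:
        """Winkler stiffness k of the confined polyethylene layer, MPa/mm.

        k = (1 - nu) E / [(1 + nu)(1 - 2 nu) d] for a thin elastic layer
        bonded to a rigid backing, loaded by a rigid indenter.
        """
        nu = self.poisson_ratio
        return (
            (1.0 - nu)
            * self.elastic_modulus
            / ((1.0 + nu) * (1.0 - 2.0 * nu) * self.pe_wall_thickness)
        )


@dataclass
class SphericalMesh:
    """Discretised hemispherical cup bearing surface.

    Node directions are unit vectors in the *cup frame*, whose +z axis is
    the cup pole (deepest point of the socket).  ``area`` partitions the
    hemisphere exactly; ``penetration`` is the cumulative radial material
    removal (wear + creep) at each node, so the local worn surface radius
    is ``radius + penetration``.
    """

    radius: float
    directions: np.ndarray  # (n, 3) unit vectors, cup frame
    polar_angle: np.ndarray  # (n,) radians from cup pole
    azimuth: np.ndarray  # (n,) radians
    area: np.ndarray  # (n,) mm^2 on the undeformed sphere
    penetration: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.penetration is None:
            self.penetration = np.zeros(len(self.directions))

    @property
    def n_nodes(self) -> int:
        return len(self.directions)

    @property
    def worn_radius(self) -> np.ndarray:
        """Per-node local cup surface radius including wear/creep, mm."""
        return self.radius + self.penetration

    def copy(self) -> "SphericalMesh":
        return replace(
            self,
            directions=self.directions.copy(),
            polar_angle=self.polar_angle.copy(),
            azimuth=self.azimuth.copy(),
            area=self.area.copy(),
            penetration=self.penetration.copy(),
        )


def build_cup_mesh(spec: BearingSpec, target_spacing: float = 0.5) -> SphericalMesh:
    """Build a near-uniform node set on the cup hemisphere.

    A Fibonacci lattice restricted to the hemisphere about the cup pole;
    node count is chosen as round(2 pi R^2 / spacing^2) so the mean
    inter-node spacing approximates ``target_spacing`` (default 0.5 mm,
    a typical contact-converged surface resolution for these bearings).
    Each node carries the equal area weight 2 pi R^2 / n, the standard
    quadrature weight for this lattice; the weights partition the
    hemisphere exactly.
    """
    radius = spec.cup_radius
    if not 0.0 < target_spacing <= radius / 5.0:
        raise ConfigurationError(
            f"target_spacing must be in (0, cup_radius/5 = {radius / 5.0:.3f}] mm, "
            f"got {target_spacing}"
        )
    hemisphere_area = 2.0 * np.pi * radius**2
    n = max(16, int(round(hemisphere_area / target_spacing**2)))
    i = np.arange(n)
    # cos(theta) uniform in (0, 1]: hemisphere about +z, pole-ward offset 1/2n
    z = 1.0 - (i + 0.5) / n
    polar = np.arccos(z)
    azimuth = np.mod(i * _GOLDEN_ANGLE, 2.0 * np.pi)
    s = np.sin(polar)
    directions = np.column_stack([s * np.cos(azimuth), s * np.sin(azimuth), z])
    area = np.full(n, hemisphere_area / n)
    return SphericalMesh(radius, directions, polar, azimuth, area)


def inclination_matrix(angle_deg: float) -> np.ndarray:
    """Rigid rotation placing the cup pole ``angle_deg`` from the vertical.

    The rotation is about the global x-axis (the flexion axis), so the
    pole tilts within the y-z plane while the load stays globally vertical.
    """
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def apply_inclination(mesh: SphericalMesh, spec: BearingSpec) -> np.ndarray:
    """Return the rigid cup-mount rotation for ``spec.inclination_deg``.

    The mesh itself is left in the cup frame (pole = +z); downstream
    modules compose this mount transform with any cup-carried motion.
    Being a proper rotation, it preserves all inter-node angles.
    """
    del mesh  # the transform depends only on the mount angle
    return inclination_matrix(spec.inclination_deg)


def apply_penetration(mesh: SphericalMesh, depth_increment: np.ndarray | float) -> SphericalMesh:
    """Return a mesh with ``depth_increment`` added to the penetration.

    Increments must be nonnegative: wear and creep only ever remove/displace
    material, so penetration is nondecreasing across geometry updates.
    """
    inc = np.broadcast_to(np.asarray(depth_increment, dtype=float), (mesh.n_nodes,))
    if np.any(inc < 0.0):
        raise ValueError("penetration increments must be >= 0 everywhere")
    out = mesh.copy()
    out.penetration = mesh.penetration + inc
    return out


def tangent_basis(directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fixed orthonormal tangent basis (east, north) at each node.

    east = z_hat x n / |z_hat x n| (azimuthal), north = n x east (towards
    the pole).  Nodes within ~1e-8 of the pole fall back to (x_hat, y_hat).
    The basis is attached to the cup material frame and never changes over
    a cycle, which is what the principal-molecular-orientation search needs.
    """
    n = np.atleast_2d(directions)
    east = np.column_stack([-n[:, 1], n[:, 0], np.zeros(len(n))])
    norms = np.linalg.norm(east, axis=1)
    polar = norms < 1e-8
    east[polar] = [1.0, 0.0, 0.0]
    east[~polar] /= norms[~polar, None]
    north = np.cross(n, east)
    return east, north
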