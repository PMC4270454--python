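import numpy as np
import pytest

import polywear as pw


@pytest.fixture(scope="session")
def spec() -> pw.BearingSpec:
    """Nominal 28 mm bearing, 0.04 mm clearance, 8 mm PE wall, 35 deg cup."""
    return pw.BearingSpec()


@pytest.fixture(scope="session")
def mesh(spec) -> pw.SphericalMesh:
    """Default-resolution (0.5 mm) cup surface mesh."""
    return pw.build_cup_mesh(spec, 0.5)


@pytest.fixture(scope="session")
def coarse_mesh(spec) -> pw.SphericalMesh:
    """Fast coarse mesh for engine-level tests."""
    return pw.build_cup_mesh(spec, 1.5)


@pytest.fixture(
    scope="session", params=["walking", "iso", "prosim"], ids=["walking", "iso", "prosim"]
)
def any_cycle(request) -> pw.MotionLoadCycle:
    gen = {
        "walking": pw.make_walking_cycle,
        "iso": pw.make_iso_cycle,
        "prosim": pw.make_prosim_cycle,
    }[request.param]
    return gen()


def pure_axis_cycle(axis: str, hi: float, lo: float, n_samples: int = 16,
                    carrier: str = "head", mean_load: float = 1242.0) -> pw.MotionLoadCycle:
    """Single-axis sinusoidal test cycle with the twin-peak load."""
    t = np.arange(n_samples) / n_samples
    wave = 0.5 * (hi + lo) + 0.5 * (hi - lo) * np.cos(2 * np.pi * t)
    zeros = np.zeros(n_samples)
    angles = {"fe": zeros, "aa": zeros, "ier": zeros}
    carriers = {"fe": "none", "aa": "none", "ier": "none"}
    angles[axis] = wave
    carriers[axis] = carrier
    base = pw.make_walking_cycle(n_samples=n_samples, mean_load=mean_load)
    return pw.MotionLoadCycle(
        time=t,
        fe_angle=angles["fe"],
        aa_angle=angles["aa"],
        ier_angle=angles["ier"],
        fe_carrier=carriers["fe"],
        aa_carrier=carriers["aa"],
        ier_carrier=carriers["ier"],
        load_magnitude=base.load_magnitude,
        name=f"pure_{axis}",
    )
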