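"""Gait motion/load protocols for hip-simulator wear prediction.

Three built-in one-second cycles are provided, matching the motion ranges,
moving-component assignments and cycle-average resultant loads of the three
simulator conditions compared in the study:

========  ==========================  =======================  ==========
case      flexion/extension           abduction/adduction      int/ext rot
========  ==========================  =======================  ==========
walking   +30/-15 deg on head         +5/-4 deg on head        +6/-8 head
iso       +25/-18 deg on cup          +4/-7 deg on cup         +2/-10 head
prosim    +30/-15 deg on head         (absent)                 +10/-10 cup
========  ==========================  =======================  ==========

with cycle-average loads of 1242, 1293 and 1057 N respectively and the
resultant load fixed along the global vertical.

The published sources give waveform *shapes* only graphically, so the
generators use declared analytic reconstructions: single-harmonic angle
waveforms (FE at phase zero; AA and IER lagging by a configurable phase,
default a quarter cycle) and a twin-peak stance load built from two
Gaussian bumps on a swing-phase baseline, amplitude-scaled so the sampled
cycle average matches the printed value exactly.

For the two-axis ProSim condition the two published sources of the carrier
assignment contradict each other (table: FE on head / IER on cup; text: FE
on cup / IER on head).  The table assignment is the default; pass
``text_carriers=True`` for the other.  The two machines are not kinematic
mirrors: swapping both carriers inverts the head-relative-to-cup rotation
(and moves the load axis differently over the cup), so both variants are
kept available rather than one being declared correct.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import InputError

__all__ = [
    "MotionLoadCycle",
    "make_walking_cycle",
    "make_iso_cycle",
    "make_prosim_cycle",
    "read_cycle_csv",
    "resample_cycle",
    "cycle_from_config",
]

_CARRIERS = ("head", "cup", "none")

#: swing-phase baseline of the twin-peak load curve, N
_LOAD_BASELINE = 300.0
#: centres and widths (fraction of cycle) of the two stance-load peaks
_PEAK_TIMES = (0.16, 0.48)
_PEAK_WIDTHS = (0.08, 0.08)
#: second (toe-off) peak relative to the first (heel-strike) peak
_SECOND_PEAK_RATIO = 0.9


@dataclass
class MotionLoadCycle:
    """One discretised motion/load cycle.

    Angle waveforms are in degrees at ``n_samples`` equally spaced time
    points over one period; each rotation axis is assigned to the bearing
    component that physically performs it (``head``, ``cup`` or ``none``).
    The load is a magnitude waveform along a constant global direction.
    """

    time: np.ndarray  # (n,) seconds
    fe_angle: np.ndarray  # (n,) degrees, about global x
    aa_angle: np.ndarray  # (n,) degrees, about global y
    ier_angle: np.ndarray  # (n,) degrees, about global z
    fe_carrier: str
    aa_carrier: str
    ier_carrier: str
    load_magnitude: np.ndarray  # (n,) N
    load_direction: np.ndarray = None  # type: ignore[assignment]
    period: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.load_direction is None:
            self.load_direction = np.array([0.0, 0.0, 1.0])
        self.load_direction = np.asarray(self.load_direction, dtype=float)
        self.load_direction = self.load_direction / np.linalg.norm(self.load_direction)
        for c in (self.fe_carrier, self.aa_carrier, self.ier_carrier):
            if c not in _CARRIERS:
                raise InputError(f"carrier must be one of {_CARRIERS}, got {c!r}")
        n = len(self.time)
        for arr_name in ("fe_angle", "aa_angle", "ier_angle", "load_magnitude"):
            arr = np.asarray(getattr(self, arr_name), dtype=float)
            setattr(self, arr_name, arr)
            if arr.shape != (n,):
                raise InputError(f"{arr_name} must have shape ({n},)")
        for carrier, arr_name in (
            (self.fe_carrier, "fe_angle"),
            (self.aa_carrier, "aa_angle"),
            (self.ier_carrier, "ier_angle"),
        ):
            if carrier == "none" and np.any(getattr(self, arr_name) != 0.0):
                raise InputError(f"{arr_name} has carrier 'none' but nonzero angles")

    @property
    def n_samples(self) -> int:
        return len(self.time)

    def angles(self, index: int) -> tuple[float, float, float]:
        """(FE, AA, IER) in degrees at sample ``index`` (cyclic)."""
        j = index % self.n_samples
        return float(self.fe_angle[j]), float(self.aa_angle[j]), float(self.ier_angle[j])

    @property
    def mean_load(self) -> float:
        return float(np.mean(self.load_magnitude))


def _harmonic(hi: float, lo: float, phase_deg: float, t: np.ndarray, period: float) -> np.ndarray:
    """Single-harmonic waveform with exact extremes ``hi``/``lo`` (degrees)."""
    mid = 0.5 * (hi + lo)
    amp = 0.5 * (hi - lo)
    return mid + amp * np.cos(2.0 * np.pi * t / period - np.deg2rad(phase_deg))


def _twin_peak_load(t: np.ndarray, period: float, mean_load: float) -> np.ndarray:
    """Two Gaussian stance peaks on a swing baseline, scaled to ``mean_load``."""
    bumps = np.zeros_like(t)
    for centre, width, ratio in zip(
        _PEAK_TIMES, _PEAK_WIDTHS, (1.0, _SECOND_PEAK_RATIO)
    ):
        for image in (-1.0, 0.0, 1.0):  # periodic wrap
            bumps += ratio * np.exp(
                -0.5 * ((t / period - centre - image) / width) ** 2
            )
    if mean_load <= _LOAD_BASELINE:
        raise InputError(
            f"mean load must exceed the swing baseline {_LOAD_BASELINE} N"
        )
    amplitude = (mean_load - _LOAD_BASELINE) / np.mean(bumps)
    return _LOAD_BASELINE + amplitude * bumps


def _build(
    name: str,
    ranges: dict[str, tuple[float, float] | None],
    carriers: dict[str, str],
    mean_load: float,
    n_samples: int,
    period: float,
    aa_phase_deg: float,
    ier_phase_deg: float,
) -> MotionLoadCycle:
    t = np.arange(n_samples) * period / n_samples
    phases = {"fe": 0.0, "aa": aa_phase_deg, "ier": ier_phase_deg}
    waves = {}
    for axis in ("fe", "aa", "ier"):
        rng = ranges[axis]
        if rng is None:
            waves[axis] = np.zeros(n_samples)
        else:
            waves[axis] = _harmonic(rng[0], rng[1], phases[axis], t, period)
    return MotionLoadCycle(
        time=t,
        fe_angle=waves["fe"],
        aa_angle=waves["aa"],
        ier_angle=waves["ier"],
        fe_carrier=carriers["fe"],
        aa_carrier=carriers["aa"],
        ier_carrier=carriers["ier"],
        load_magnitude=_twin_peak_load(t, period, mean_load),
        period=period,
        name=name,
    )


def make_walking_cycle(
    n_samples: int = 16,
    period: float = 1.0,
    mean_load: float = 1242.0,
    aa_phase_deg: float = 90.0,
    ier_phase_deg: float = 90.0,
) -> MotionLoadCycle:
    """Measured-walking condition: all three rotations carried by the head."""
    return _build(
        "walking",
        {"fe": (30.0, -15.0), "aa": (5.0, -4.0), "ier": (6.0, -8.0)},
        {"fe": "head", "aa": "head", "ier": "head"},
        mean_load, n_samples, period, aa_phase_deg, ier_phase_deg,
    )


def make_iso_cycle(
    n_samples: int = 16,
    period: float = 1.0,
    mean_load: float = 1293.0,
    aa_phase_deg: float = 90.0,
    ier_phase_deg: float = 90.0,
) -> MotionLoadCycle:
    """ISO-standard condition: FE and AA on the cup, IER on the head."""
    return _build(
        "iso",
        {"fe": (25.0, -18.0), "aa": (4.0, -7.0), "ier": (2.0, -10.0)},
        {"fe": "cup", "aa": "cup", "ier": "head"},
        mean_load, n_samples, period, aa_phase_deg, ier_phase_deg,
    )


def make_prosim_cycle(
    n_samples: int = 16,
    period: float = 1.0,
    mean_load: float = 1057.0,
    ier_phase_deg: float = 90.0,
    text_carriers: bool = False,
) -> MotionLoadCycle:
    """Two-axis ProSim simulator condition: FE and IER only, no AA.

    ``text_carriers=False`` (default) assigns FE to the head and IER to the
    cup; ``True`` flips both (the two published statements disagree, and the
    flip inverts the relative motion, so neither is silently "corrected").
    """
    if text_carriers:
        carriers = {"fe": "cup", "aa": "none", "ier": "head"}
    else:
        carriers = {"fe": "head", "aa": "none", "ier": "cup"}
    return _build(
        "prosim",
        {"fe": (30.0, -15.0), "aa": None, "ier": (10.0, -10.0)},
        carriers,
        mean_load, n_samples, period, 0.0, ier_phase_deg,
    )


_GENERATORS = {
    "walking": make_walking_cycle,
    "iso": make_iso_cycle,
    "prosim": make_prosim_cycle,
}


def cycle_from_config(config: dict) -> MotionLoadCycle:
    """Build a cycle from a YAML-style ``protocol`` mapping.

    Recognised keys: ``name`` (walking|iso|prosim), ``samples``,
    ``load_average_N``, ``phase_deg: {aa, ier}``, ``text_carriers``.
    """
    name = config.get("name", "walking")
    if name not in _GENERATORS:
        raise InputError(f"unknown protocol {name!r}; choose from {sorted(_GENERATORS)}")
    kwargs: dict = {}
    if "samples" in config:
        kwargs["n_samples"] = int(config["samples"])
    if "load_average_N" in config:
        kwargs["mean_load"] = float(config["load_average_N"])
    phases = config.get("phase_deg", {})
    if "ier" in phases:
        kwargs["ier_phase_deg"] = float(phases["ier"])
    if "aa" in phases and name != "prosim":
        kwargs["aa_phase_deg"] = float(phases["aa"])
    if name == "prosim" and config.get("text_carriers"):
        kwargs["text_carriers"] = True
    return _GENERATORS[name](**kwargs)


def _periodic_interp(t_new: np.ndarray, t: np.ndarray, y: np.ndarray, period: float) -> np.ndarray:
    tt = np.concatenate([t, [t[0] + period]])
    yy = np.concatenate([y, [y[0]]])
    return np.interp(np.mod(t_new, period), tt, yy)


def resample_cycle(cycle: MotionLoadCycle, n_samples: int) -> MotionLoadCycle:
    """Resample a cycle to ``n_samples`` equal steps by periodic linear
    interpolation of every waveform."""
    t_new = np.arange(n_samples) * cycle.period / n_samples
    interp = lambda y: _periodic_interp(t_new, cycle.time, y, cycle.period)  # noqa: E731
    return replace(
        cycle,
        time=t_new,
        fe_angle=interp(cycle.fe_angle),
        aa_angle=interp(cycle.aa_angle),
        ier_angle=interp(cycle.ier_angle),
        load_magnitude=interp(cycle.load_magnitude),
    )


def read_cycle_csv(
    path,
    fe_carrier: str = "head",
    aa_carrier: str = "head",
    ier_carrier: str = "head",
    n_samples: int = 16,
    angle_tol_deg: float = 0.5,
    name: str = "csv",
) -> MotionLoadCycle:
    """Read a user motion/load cycle from CSV and resample to ``n_samples``.

    Required columns: ``time_s, fe_deg, aa_deg, ier_deg, load_N`` with
    strictly increasing time covering one full period: the first row is
    the cycle start and the last row the period endpoint, so the period is
    ``time_s[-1] - time_s[0]``.  Endpoint angle mismatches beyond
    ``angle_tol_deg`` are rejected — waveforms must be cyclic.
    """
    frame = pd.read_csv(path)
    required = ["time_s", "fe_deg", "aa_deg", "ier_deg", "load_N"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise InputError(f"{path}: missing column(s) {missing}; need {required}")
    t = frame["time_s"].to_numpy(dtype=float)
    if len(t) < 3:
        raise InputError(f"{path}: need at least 3 rows, got {len(t)}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        row = int(np.argmax(dt <= 0)) + 1
        raise InputError(
            f"{path}: column time_s must be strictly increasing (violated at row {row})"
        )
    angles = {c: frame[c].to_numpy(dtype=float) for c in ("fe_deg", "aa_deg", "ier_deg")}
    load = frame["load_N"].to_numpy(dtype=float)

    for col, a in angles.items():
        if abs(a[-1] - a[0]) > angle_tol_deg:
            raise InputError(
                f"{path}: column {col} is not cyclic (start {a[0]:.3f} deg vs "
                f"period end {a[-1]:.3f} deg, tolerance {angle_tol_deg} deg)"
            )
    period = float(t[-1] - t[0])
    keep = slice(0, len(t) - 1)  # last row duplicates t=0 at the period end
    t0 = t[keep] - t[0]
    t_new = np.arange(n_samples) * period / n_samples
    interp = lambda y: _periodic_interp(t_new, t0, y[keep], period)  # noqa: E731
    return MotionLoadCycle(
        time=t_new,
        fe_angle=interp(angles["fe_deg"]),
        aa_angle=interp(angles["aa_deg"]),
        ier_angle=interp(angles["ier_deg"]),
        fe_carrier=fe_carrier,
        aa_carrier=aa_carrier,
        ier_carrier=ier_carrier,
        load_magnitude=interp(load),
        period=period,
        name=name,
    )
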