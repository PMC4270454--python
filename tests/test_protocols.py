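import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polywear as pw
from polywear.errors import InputError

CASES = {
    "walking": dict(
        gen=pw.make_walking_cycle,
        ranges={"fe": (30, -15), "aa": (5, -4), "ier": (6, -8)},
        carriers=("head", "head", "head"),
        mean_load=1242.0,
    ),
    "iso": dict(
        gen=pw.make_iso_cycle,
        ranges={"fe": (25, -18), "aa": (4, -7), "ier": (2, -10)},
        carriers=("cup", "cup", "head"),
        mean_load=1293.0,
    ),
    "prosim": dict(
        gen=pw.make_prosim_cycle,
        ranges={"fe": (30, -15), "aa": None, "ier": (10, -10)},
        carriers=("head", "none", "cup"),
        mean_load=1057.0,
    ),
}


@pytest.mark.parametrize("case", CASES.values(), ids=CASES.keys())
class TestGenerators:
    def test_rotation_ranges(self, case):
        cycle = case["gen"]()
        for axis, rng in case["ranges"].items():
            wave = getattr(cycle, f"{axis}_angle")
            if rng is None:
                np.testing.assert_array_equal(wave, 0.0)
            else:
                assert wave.max() == pytest.approx(rng[0], abs=0.1)
                assert wave.min() == pytest.approx(rng[1], abs=0.1)

    def test_mean_load_and_direction(self, case):
        cycle = case["gen"]()
        assert cycle.mean_load == pytest.approx(case["mean_load"], rel=5e-3)
        assert np.all(cycle.load_magnitude > 0)
        np.testing.assert_allclose(cycle.load_direction, [0, 0, 1])

    def test_carriers(self, case):
        cycle = case["gen"]()
        assert (cycle.fe_carrier, cycle.aa_carrier, cycle.ier_carrier) == case["carriers"]

    def test_sampling_grid(self, case):
        cycle = case["gen"]()
        assert cycle.n_samples == 16
        np.testing.assert_allclose(np.diff(cycle.time), cycle.period / 16)

    def test_deterministic(self, case):
        a, b = case["gen"](), case["gen"]()
        np.testing.assert_array_equal(a.fe_angle, b.fe_angle)
        np.testing.assert_array_equal(a.load_magnitude, b.load_magnitude)


def test_prosim_carrier_variants_are_mutual_inverses():
    """Swapping both ProSim carriers (the two contradictory published
    assignments) inverts the head-relative-to-cup rotation at every
    sample: the two machines are distinct, and both stay available."""
    table = pw.make_prosim_cycle()
    text = pw.make_prosim_cycle(text_carriers=True)
    assert (table.fe_carrier, table.ier_carrier) == ("head", "cup")
    assert (text.fe_carrier, text.ier_carrier) == ("cup", "head")
    for j in range(16):
        np.testing.assert_allclose(
            pw.relative_motion(table, j),
            pw.relative_motion(text, j).T,
            atol=1e-12,
        )


@given(
    hi=st.floats(5.0, 40.0),
    span=st.floats(1.0, 40.0),
    mean_load=st.floats(400.0, 3000.0),
)
@settings(max_examples=30, deadline=None)
def test_waveform_invariants_hold_across_configs(hi, span, mean_load):
    """Ranges and cycle-average load are reproduced for arbitrary
    generator parameters (phases kept on the 16-sample grid)."""
    cycle = pw.MotionLoadCycle(
        time=np.arange(16) / 16,
        fe_angle=pw.protocols._harmonic(hi, hi - span, 0.0, np.arange(16) / 16, 1.0),
        aa_angle=np.zeros(16),
        ier_angle=np.zeros(16),
        fe_carrier="head",
        aa_carrier="none",
        ier_carrier="none",
        load_magnitude=pw.protocols._twin_peak_load(np.arange(16) / 16, 1.0, mean_load),
    )
    assert cycle.fe_angle.max() == pytest.approx(hi, abs=0.1)
    assert cycle.fe_angle.min() == pytest.approx(hi - span, abs=0.1)
    assert cycle.mean_load == pytest.approx(mean_load, rel=5e-3)


def test_resample_round_trip_is_lossless():
    cycle = pw.make_walking_cycle()
    back = pw.resample_cycle(pw.resample_cycle(cycle, 64), 16)
    np.testing.assert_allclose(back.fe_angle, cycle.fe_angle, atol=0.2)
    np.testing.assert_allclose(back.ier_angle, cycle.ier_angle, atol=0.2)


class TestCsvReader:
    @staticmethod
    def _write(tmp_path, n_rows=101, mangle=None):
        dense = pw.make_walking_cycle(n_samples=n_rows - 1)
        import pandas as pd

        frame = pd.DataFrame(
            {
                "time_s": np.append(dense.time, dense.period),
                "fe_deg": np.append(dense.fe_angle, dense.fe_angle[0]),
                "aa_deg": np.append(dense.aa_angle, dense.aa_angle[0]),
                "ier_deg": np.append(dense.ier_angle, dense.ier_angle[0]),
                "load_N": np.append(dense.load_magnitude, dense.load_magnitude[0]),
            }
        )
        if mangle:
            frame = mangle(frame)
        path = tmp_path / "cycle.csv"
        frame.to_csv(path, index=False)
        return path

    def test_round_trips_generated_waveforms(self, tmp_path):
        path = self._write(tmp_path)
        cycle = pw.read_cycle_csv(path)
        reference = pw.make_walking_cycle()
        np.testing.assert_allclose(cycle.fe_angle, reference.fe_angle, atol=0.2)
        np.testing.assert_allclose(cycle.aa_angle, reference.aa_angle, atol=0.2)
        np.testing.assert_allclose(cycle.ier_angle, reference.ier_angle, atol=0.2)

    def test_constant_zero_cycle_is_valid(self, tmp_path):
        import pandas as pd

        path = tmp_path / "still.csv"
        pd.DataFrame(
            {
                "time_s": np.linspace(0, 1, 11),
                "fe_deg": 0.0,
                "aa_deg": 0.0,
                "ier_deg": 0.0,
                "load_N": 1000.0,
            }
        ).to_csv(path, index=False)
        cycle = pw.read_cycle_csv(path)
        np.testing.assert_array_equal(cycle.fe_angle, 0.0)
        assert cycle.mean_load == pytest.approx(1000.0)

    def test_shuffled_time_rejected(self, tmp_path):
        def shuffle(frame):
            return frame.sample(frac=1.0, random_state=1).reset_index(drop=True)

        with pytest.raises(InputError, match="strictly increasing"):
            pw.read_cycle_csv(self._write(tmp_path, mangle=shuffle))

    def test_missing_column_rejected(self, tmp_path):
        def drop(frame):
            return frame.drop(columns=["aa_deg"])

        with pytest.raises(InputError, match="aa_deg"):
            pw.read_cycle_csv(self._write(tmp_path, mangle=drop))

    def test_non_cyclic_endpoints_rejected(self, tmp_path):
        def open_loop(frame):
            frame.loc[len(frame) - 1, "fe_deg"] += 5.0
            return frame

        with pytest.raises(InputError, match="not cyclic"):
            pw.read_cycle_csv(self._write(tmp_path, mangle=open_loop))


def test_cycle_from_config():
    cycle = pw.cycle_from_config(
        {"name": "iso", "samples": 32, "load_average_N": 1300.0, "phase_deg": {"ier": 45.0}}
    )
    assert cycle.n_samples == 32
    assert cycle.mean_load == pytest.approx(1300.0, rel=5e-3)
    with pytest.raises(InputError):
        pw.cycle_from_config({"name": "jogging"})
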