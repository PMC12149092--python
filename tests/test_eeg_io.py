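"""Recording I/O, referencing and windowing."""

import logging

import numpy as np
import pytest

from vgeeg.eeg_io import (
    Recording,
    apply_reference,
    read_recording,
    segment_windows,
    write_recording,
)
from vgeeg.synthetic import CohortSpec, generate_recording


def make_recording(n_channels=3, n_samples=1000, fs=128.0, seed=0, label=0):
    rng = np.random.default_rng(seed)
    return Recording(
        rng.normal(size=(n_channels, n_samples)),
        fs,
        tuple(f"ch{i}" for i in range(n_channels)),
        "subj",
        label,
    )


class TestReadWrite:
    def test_delimited_without_header_channels_as_rows(self, tmp_path):
        p = tmp_path / "r.txt"
        p.write_text("\n".join(" ".join("1.5" for _ in range(10)) for _ in range(3)))
        rec = read_recording(p, format="delimited", label=1, sampling_rate=128.0)
        assert rec.n_channels == 3 and rec.n_samples == 10
        assert rec.label == 1

    def test_delimited_round_trip(self, tmp_path):
        rec = make_recording()
        path = write_recording(rec, tmp_path / "r.csv", format="delimited")
        back = read_recording(path)
        assert np.allclose(back.signal, rec.signal)
        assert back.channel_labels == rec.channel_labels
        assert back.sampling_rate == rec.sampling_rate
        assert (back.label, back.subject_id) == (rec.label, rec.subject_id)

    def test_array_round_trip(self, tmp_path):
        rec = make_recording(seed=1, label=1)
        path = write_recording(rec, tmp_path / "r.npy", format="array")
        back = read_recording(path)
        assert np.array_equal(back.signal, rec.signal)
        assert back.label == 1

    def test_edf_round_trip_within_quantization(self, tmp_path):
        spec = CohortSpec(
            n_subjects_per_class=1, n_channels=4, sampling_rate=128,
            duration=10, band_amplitudes_per_class={"alpha": (1.0, 1.0)},
            noise_scale=0.5, seed=2,
        )
        rec = generate_recording(spec, 1, 0)
        path = write_recording(rec, tmp_path / "r.edf", format="edf")
        back = read_recording(path)
        assert back.sampling_rate == 128.0
        assert back.channel_labels == rec.channel_labels
        assert back.label == 1
        span = rec.signal.max() - rec.signal.min()
        # 16-bit quantization: error bounded by one digital step
        assert np.abs(back.signal[:, : rec.n_samples] - rec.signal).max() < span / 2**15

    def test_nan_cell_is_parse_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1.0,2.0\nnan,3.0\n")
        with pytest.raises(ValueError, match="non-finite"):
            read_recording(p, format="delimited", label=0, sampling_rate=128.0)

    def test_non_numeric_cell_names_location(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("a,b\n1.0,2.0\n1.0,oops\n")
        with pytest.raises(ValueError, match="oops"):
            read_recording(p, format="delimited", label=0, sampling_rate=128.0)

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            read_recording("definitely/not/here.csv", label=0)


class TestReference:
    def test_common_average_zeroes_cross_channel_mean(self):
        rec = apply_reference(make_recording())
        assert np.allclose(rec.signal.mean(axis=0), 0.0)

    def test_common_average_idempotent(self):
        once = apply_reference(make_recording())
        twice = apply_reference(once)
        assert np.allclose(once.signal, twice.signal)

    def test_two_channel_hand_case(self):
        rec = Recording(
            np.array([[4.0, 6.0], [2.0, 0.0]]), 100.0, ("a", "b"), "s", 0
        )
        out = apply_reference(rec, "common_average")
        assert np.allclose(out.signal, [[1.0, 3.0], [-1.0, -3.0]])

    def test_channel_reference_zeroes_itself(self):
        rec = make_recording()
        out = apply_reference(rec, "channel:ch1")
        assert np.allclose(out.signal[1], 0.0)
        assert np.allclose(out.signal[0], rec.signal[0] - rec.signal[1])

    def test_unknown_reference_label(self):
        with pytest.raises(ValueError, match="unknown reference channel"):
            apply_reference(make_recording(), "channel:Cz")

    def test_shape_and_labels_preserved(self):
        rec = make_recording()
        out = apply_reference(rec)
        assert out.signal.shape == rec.signal.shape
        assert out.channel_labels == rec.channel_labels


class TestWindowing:
    def test_thirty_second_windows_at_250hz(self):
        rec = make_recording(n_samples=75_000, fs=250.0)
        wins = segment_windows(rec, 30.0)
        assert len(wins) == 10
        assert all(w.n_samples == 7500 for w in wins)

    def test_remainder_dropped(self):
        rec = make_recording(n_samples=int(125 * 128), fs=128.0)
        wins = segment_windows(rec, 30.0)
        assert len(wins) == 4

    def test_five_second_windows_at_128hz(self):
        rec = make_recording(n_samples=int(120 * 128), fs=128.0)
        wins = segment_windows(rec, 5.0)
        assert len(wins) == 24
        assert all(w.n_samples == 640 for w in wins)

    def test_concatenation_reconstructs_prefix(self):
        rec = make_recording(n_samples=1000, fs=128.0)
        wins = segment_windows(rec, 2.0)  # 256-sample windows -> 3 windows
        rebuilt = np.concatenate([w.signal for w in wins], axis=1)
        assert np.array_equal(rebuilt, rec.signal[:, : rebuilt.shape[1]])

    def test_windows_ordered_and_labeled(self):
        rec = make_recording(n_samples=1000, label=1)
        wins = segment_windows(rec, 1.0)
        assert [w.window_index for w in wins] == list(range(len(wins)))
        assert all(w.label == 1 and w.subject_id == "subj" for w in wins)

    def test_window_longer_than_recording_warns_empty(self, caplog):
        rec = make_recording(n_samples=100)
        with caplog.at_level(logging.WARNING):
            wins = segment_windows(rec, 10.0)
        assert wins == []
        assert any("no windows" in r.message for r in caplog.records)

    def test_invalid_window_length(self):
        with pytest.raises(ValueError):
            segment_windows(make_recording(), 0.0)


class TestRecordingValidation:
    def test_mismatched_labels(self):
        with pytest.raises(ValueError, match="labels"):
            Recording(np.zeros((2, 5)), 128.0, ("a",), "s", 0)

    def test_non_finite_sample(self):
        sig = np.zeros((2, 5))
        sig[1, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            Recording(sig, 128.0, ("a", "b"), "s", 0)
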