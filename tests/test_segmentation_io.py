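"""Segmentation protocol and file I/O: EDF, annotations, splits, balancing."""

import numpy as np
import pytest

from capnet.io import (
    ChannelNotFoundError,
    read_annotations,
    read_edf,
    write_annotations,
    write_edf,
)
from capnet.records import EEGRecord
from capnet.segmentation import (
    SplitSpec,
    assign_splits,
    attach_splits,
    balance_classes,
    extract_segments,
    resample_to_32hz,
    trim_edges,
)


def _record32(labels):
    labels = np.asarray(labels, dtype="U2")
    rng = np.random.default_rng(0)
    return EEGRecord("t", "SIM", rng.standard_normal(len(labels) * 32), 32, labels)


class TestEDF:
    def test_round_trip_within_quantization(self, tmp_path):
        t = np.arange(128 * 5) / 128
        sig = 80.0 * np.sin(2 * np.pi * 5 * t)
        path = tmp_path / "fix.edf"
        write_edf(path, {"C4-A1": sig, "C3-A2": 0.5 * sig}, 128)
        back, fs = read_edf(path, "C4-A1")
        assert fs == 128
        quant = 2 * 80.0 / 65535
        assert np.max(np.abs(back - sig)) <= 2 * quant

    def test_missing_channel_lists_available(self, tmp_path):
        path = tmp_path / "fix.edf"
        write_edf(path, {"C4-A1": np.zeros(256), "C3-A2": np.zeros(256)}, 128)
        with pytest.raises(ChannelNotFoundError, match="C4-A1.*C3-A2"):
            read_edf(path, "F3")


class TestAnnotations:
    def test_single_event_expansion(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("onset_s\tduration_s\tlabel\n10\t5\tA1\n")
        labels = read_annotations(p, n_seconds=20)
        assert list(labels[10:15]) == ["A1"] * 5
        assert np.sum(labels == "B") == 15

    def test_empty_file_defaults_to_background(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("onset_s\tduration_s\tlabel\n")
        assert np.all(read_annotations(p, n_seconds=20) == "B")

    def test_two_events_dense_runs(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("0\t2\tA1\n5\t3\tA3\n")
        labels = read_annotations(p, n_seconds=10)
        expected = ["A1", "A1", "B", "B", "B", "A3", "A3", "A3", "B", "B"]
        assert list(labels) == expected

    def test_overlapping_a_events_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("0\t5\tA1\n3\t4\tA3\n")
        with pytest.raises(ValueError, match="overlap"):
            read_annotations(p, n_seconds=10)

    def test_unknown_label_rejected(self, tmp_path):
        p = tmp_path / "a.tsv"
        p.write_text("0\t5\tA9\n")
        with pytest.raises(ValueError, match="unknown label"):
            read_annotations(p)

    def test_round_trip(self, short_record, tmp_path):
        p = tmp_path / "a.tsv"
        write_annotations(p, short_record.labels)
        back = read_annotations(p, short_record.duration_s)
        assert np.array_equal(back, short_record.labels)


class TestResample:
    def test_identity_at_32(self):
        x = np.random.default_rng(0).standard_normal(320)
        assert np.array_equal(resample_to_32hz(x, 32), x)

    def test_tone_preserved_from_512(self):
        t = np.arange(512 * 10) / 512
        x = np.sin(2 * np.pi * 5 * t)
        y = resample_to_32hz(x, 512)
        assert len(y) == 320
        f = np.fft.rfftfreq(len(y), 1 / 32)
        assert f[np.argmax(np.abs(np.fft.rfft(y)))] == pytest.approx(5.0, abs=0.1)

    def test_above_nyquist_attenuated_40db(self):
        t = np.arange(128 * 10) / 128
        x = np.sin(2 * np.pi * 30 * t)
        y = resample_to_32hz(x, 128)
        in_power = np.mean(x**2)
        # steady-state attenuation: skip the filter's edge transients
        out_power = np.mean(y[32:-32] ** 2)
        assert 10 * np.log10(out_power / in_power) <= -40

    @pytest.mark.parametrize("fs", [100, 128, 200, 512])
    @pytest.mark.parametrize("tone", [1.0, 4.0, 8.0, 12.0])
    def test_passband_flat_within_half_db(self, fs, tone):
        t = np.arange(fs * 16) / fs
        x = np.sin(2 * np.pi * tone * t)
        y = resample_to_32hz(x, fs)
        # compare RMS on the interior to dodge filter edge transients
        n = len(y)
        ratio = np.mean(y[n // 8 : -n // 8] ** 2) / np.mean(
            x[len(x) // 8 : -len(x) // 8] ** 2
        )
        assert abs(10 * np.log10(ratio)) <= 0.5

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError, match="unsupported rate"):
            resample_to_32hz(np.zeros(64), 16)


class TestExtractSegments:
    def test_central_second_labels_the_window(self):
        # 2 s of B then 3 s of A centered on an A second -> A segment
        segs = extract_segments(_record32(["B", "B", "A1", "A1", "A1"]), 5)
        assert len(segs) == 1 and segs[0].center_time_s == 2
        assert segs[0].center_label == "A"
        # 3 s of B then 2 s of A centered on a B second -> B segment
        segs = extract_segments(_record32(["B", "B", "B", "A1", "A1"]), 5)
        assert segs[0].center_label == "B"

    def test_window_one_is_the_second_itself(self):
        segs = extract_segments(_record32(["B", "A2", "B"]), 1)
        assert [s.center_label for s in segs] == ["B", "A", "B"]
        assert all(len(s.samples) == 32 for s in segs)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            extract_segments(_record32(["B"] * 8), 4)

    def test_label_locality(self):
        """Context labels never affect the segment label."""
        base = ["B", "B", "A1", "B", "B", "A3", "B", "B", "B"]
        permuted = ["A3", "B", "A1", "A2", "B", "A3", "A1", "B", "A1"]
        s1 = extract_segments(_record32(base), 3)
        s2 = extract_segments(_record32(permuted), 3)
        for a, b in zip(s1, s2):
            if base[a.center_time_s] == permuted[b.center_time_s]:
                assert a.center_label == b.center_label


class TestSplits:
    def test_block_offsets(self):
        split = assign_splits(600)
        for t, expect in [(0, "train"), (239, "train"), (240, "val"), (269, "val"),
                          (270, "test"), (299, "test"), (300, "train")]:
            assert split[t] == expect

    def test_counts_on_3000s(self):
        split = assign_splits(3000)
        assert np.sum(split == "train") == 2400
        assert np.sum(split == "val") == 300
        assert np.sum(split == "test") == 300

    def test_partial_block_same_offsets(self):
        split = assign_splits(550)
        assert np.sum(split == "train") == 240 + 240
        assert np.sum(split == "val") == 30 + 10

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SplitSpec(block_s=300, train_s=250, val_s=30, test_s=30)


class TestTrimEdges:
    def test_window_one_drops_nothing(self):
        rec = _record32(["B"] * 300)
        split = assign_splits(300)
        segs = attach_splits(extract_segments(rec, 1), split)
        assert len(trim_edges(segs, 1, split)) == len(segs)

    def test_boundary_crossing_segments_dropped(self):
        rec = _record32(["B"] * 300)
        split = assign_splits(300)
        segs = attach_splits(extract_segments(rec, 5), split)
        kept = trim_edges(segs, 5, split)
        kept_centers = {s.center_time_s for s in kept}
        # brute-force: a center survives iff its 5 s coverage shares one split
        expected = {
            t
            for t in range(2, 298)
            if len({split[u] for u in range(t - 2, t + 3)}) == 1
        }
        assert kept_centers == expected
        assert 241 not in kept_centers  # val window covering a train second

    def test_split_disjointness_after_trim(self, short_record_32):
        split = assign_splits(short_record_32.duration_s)
        segs = attach_splits(extract_segments(short_record_32, 5), split)
        kept = trim_edges(segs, 5, split)
        coverage: dict[int, set] = {}
        for s in kept:
            for t in s.covered_seconds:
                coverage.setdefault(t, set()).add(s.split)
        assert all(len(v) == 1 for v in coverage.values())

    def test_count_conservation(self, short_record_32):
        split = assign_splits(short_record_32.duration_s)
        segs = attach_splits(extract_segments(short_record_32, 7), split)
        kept = trim_edges(segs, 7, split)
        dropped = len(segs) - len(kept)
        assert dropped > 0 and len(kept) + dropped == len(segs)


class TestBalance:
    def _segments(self, labels, split="train"):
        segs = extract_segments(_record32(labels), 1)
        for s in segs:
            s.split = split
        return segs

    def test_equal_counts_after_balancing(self):
        labels = ["A1"] * 10 + ["B"] * 40
        out = balance_classes(self._segments(labels), seed=0)
        a = sum(s.center_label == "A" for s in out)
        b = sum(s.center_label == "B" for s in out)
        assert a == b == 10

    def test_a_segments_never_removed(self):
        labels = ["A1", "A2", "A3"] * 5 + ["B"] * 60
        out = balance_classes(self._segments(labels), seed=1)
        assert sum(s.center_label == "A" for s in out) == 15

    def test_minority_b_warns_and_keeps(self):
        labels = ["A1"] * 10 + ["B"] * 3
        segs = self._segments(labels)
        with pytest.warns(UserWarning, match="not balancing"):
            out = balance_classes(segs, seed=0)
        assert len(out) == len(segs)

    def test_no_a_drops_all_b_with_warning(self):
        segs = self._segments(["B"] * 10)
        with pytest.warns(UserWarning, match="no A segments"):
            out = balance_classes(segs, seed=0)
        assert out == []

    def test_same_seed_same_survivors(self):
        labels = ["A1"] * 8 + ["B"] * 50
        s1 = balance_classes(self._segments(labels), seed=42)
        s2 = balance_classes(self._segments(labels), seed=42)
        assert [s.center_time_s for s in s1] == [s.center_time_s for s in s2]

    def test_count_conservation(self):
        labels = ["A1"] * 8 + ["B"] * 50
        segs = self._segments(labels)
        out = balance_classes(segs, seed=0)
        assert len(segs) - len(out) == 50 - 8
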