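"""Marker table parsing, round-trips, and gap interpolation."""

import numpy as np
import pytest

from softarm import (
    SchemaError,
    TrajectorySet,
    interpolate_gaps,
    read_markers,
    write_markers,
)

HEADER = "frame\tm1_x\tm1_y\tm1_z\tm2_x\tm2_y\tm2_z\tm3_x\tm3_y\tm3_z"


def write_tsv(path, rows, header=HEADER, comments=()):
    lines = list(comments) + [header] + rows
    path.write_text("\n".join(lines) + "\n")


class TestReadMarkers:
    def test_parses_numeric_table(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(
            p,
            ["0\t1\t2\t3\t4\t5\t6\t7\t8\t9", "1\t1\t2\t3\t4\t5\t6\t7\t8\t9"],
        )
        traj = read_markers(p, "tsv")
        assert traj.n_frames == 2 and traj.n_markers == 3
        assert traj.marker_labels == ["m1", "m2", "m3"]
        assert not traj.gap_mask.any()
        np.testing.assert_allclose(traj.positions[0, 1], [4, 5, 6])

    def test_blank_cell_becomes_gap(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(
            p,
            ["0\t1\t2\t3\t4\t5\t6\t7\t8\t9", "1\t1\t2\t3\t\t\t\t7\t8\t9"],
        )
        traj = read_markers(p, "tsv")
        assert traj.gap_mask[1, 1]
        assert not traj.gap_mask[0, 1]
        assert np.isnan(traj.positions[1, 1]).all()

    def test_zero_sentinel_only_with_flag(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["0\t0\t0\t0\t4\t5\t6\t7\t8\t9"])
        assert not read_markers(p, "tsv").gap_mask[0, 0]
        assert read_markers(p, "tsv", zero_is_gap=True).gap_mask[0, 0]

    def test_units_scaled_to_mm(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(
            p,
            ["0\t1\t2\t3\t4\t5\t6\t7\t8\t9"],
            comments=["# units: cm", "# sample_rate: 100"],
        )
        traj = read_markers(p, "tsv")
        np.testing.assert_allclose(traj.positions[0, 0], [10, 20, 30])
        assert traj.sample_rate == 100.0

    def test_fewer_than_three_markers_rejected(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text("frame,m1_x,m1_y,m1_z\n0,1,2,3\n")
        with pytest.raises(SchemaError):
            read_markers(p, "csv")

    def test_extra_columns_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        write_tsv(p, ["0\t1\t2\t3\t4\t5\t6\t7\t8\t9\t10\t11"])
        with pytest.raises(SchemaError):
            read_markers(p, "tsv")

    def test_missing_file_raises_io_error(self, tmp_path):
        with pytest.raises(OSError):
            read_markers(tmp_path / "absent.tsv", "tsv")


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["tsv", "csv"])
    def test_write_read_identical(self, tmp_path, small_traj, dialect):
        p = tmp_path / f"t.{dialect}"
        write_markers(small_traj, p, dialect)
        back = read_markers(p, dialect)
        np.testing.assert_allclose(
            back.positions, small_traj.positions, atol=1e-9
        )
        assert back.marker_labels == small_traj.marker_labels
        assert back.sample_rate == small_traj.sample_rate

    def test_roundtrip_preserves_gaps(self, tmp_path, small_traj):
        small_traj.positions[3, 2] = np.nan
        traj = TrajectorySet(
            small_traj.marker_labels,
            small_traj.positions,
            small_traj.sample_rate,
        )
        p = tmp_path / "t.tsv"
        write_markers(traj, p)
        back = read_markers(p)
        assert back.gap_mask[3, 2] and back.gap_mask.sum() == 1

    def test_read_write_read_idempotent(self, tmp_path, small_traj):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_markers(small_traj, p1)
        write_markers(read_markers(p1), p2)
        assert p1.read_text() == p2.read_text()


def traj_with_gap(frames_missing, n_frames=8):
    positions = np.tile(
        np.array([[0.0, 0, 0], [10, 2, 0], [20, 0, 0]]), (n_frames, 1, 1)
    )
    positions += np.arange(n_frames)[:, None, None]  # drift so interp visible
    for f in frames_missing:
        positions[f, 1] = np.nan
    return TrajectorySet(["a", "b", "c"], positions, 150.0)


class TestInterpolateGaps:
    def test_single_gap_linear_midpoint(self):
        t = traj_with_gap([3])
        out = interpolate_gaps(t, max_gap_frames=1)
        assert not out.gap_mask.any()
        expected = 0.5 * (t.positions[2, 1] + t.positions[4, 1])
        np.testing.assert_allclose(out.positions[3, 1], expected)

    def test_gap_longer_than_max_stays_masked(self):
        t = traj_with_gap([2, 3, 4, 5, 6])
        out = interpolate_gaps(t, max_gap_frames=3)
        assert out.gap_mask[:, 1].sum() == 5

    def test_leading_gap_never_filled(self):
        t = traj_with_gap([0])
        out = interpolate_gaps(t, max_gap_frames=10)
        assert out.gap_mask[0, 1]

    def test_trailing_gap_never_filled(self):
        t = traj_with_gap([7])
        out = interpolate_gaps(t, max_gap_frames=10)
        assert out.gap_mask[7, 1]

    def test_never_alters_unmasked_samples(self):
        t = traj_with_gap([3, 4])
        out = interpolate_gaps(t, max_gap_frames=2)
        valid = ~t.gap_mask
        np.testing.assert_array_equal(
            out.positions[valid], t.positions[valid]
        )
        assert not out.gap_mask[3, 1] and not out.gap_mask[4, 1]

    def test_noop_when_no_gaps(self, small_traj):
        out = interpolate_gaps(small_traj, max_gap_frames=5)
        np.testing.assert_array_equal(out.positions, small_traj.positions)
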