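"""Reading, writing and gap handling for marker trajectory tables.

The plain-text dialects (TSV/CSV) use one row per frame: a ``frame``
column followed by ``<label>_x``, ``<label>_y``, ``<label>_z`` for each
marker in anatomical proximal -> distal order. A header row with the
labels is required. Optional ``#`` comment lines before the header may
declare ``# units: mm|cm|m`` and ``# sample_rate: <Hz>``; coordinates
are scaled to mm at the reader boundary, the internal unit throughout.

Blank or non-numeric cells are gaps. Some capture systems emit exact
(0, 0, 0) for a lost marker; pass ``zero_is_gap=True`` to treat those as
gaps too (off by default so legitimate origin-adjacent data survives).

The binary C3D dialect is read through ``ezc3d`` (or ``c3d``) when one
of those packages is installed; it is optional and import is deferred.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SchemaError

__all__ = ["TrajectorySet", "read_markers", "write_markers", "interpolate_gaps"]

_UNIT_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}


@dataclass
class TrajectorySet:
    """Time-indexed 3D positions of N ordered markers.

    positions has shape (n_frames, n_markers, 3) in mm, NaN where
    gap_mask is True. Marker order is anatomical, proximal -> distal.
    """

    marker_labels: list[str]
    positions: np.ndarray
    sample_rate: float = 150.0
    gap_mask: np.ndarray | None = None
    frame_index: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise SchemaError(
                f"positions must be (frames, markers, 3), got "
                f"{self.positions.shape}"
            )
        n_frames, n_markers, _ = self.positions.shape
        if n_markers < 3:
            raise SchemaError(f"need at least 3 markers, got {n_markers}")
        if n_frames < 1:
            raise SchemaError("need at least 1 frame")
        if len(self.marker_labels) != n_markers:
            raise SchemaError(
                f"{len(self.marker_labels)} labels for {n_markers} markers"
            )
        if not self.sample_rate > 0:
            raise SchemaError(f"sample_rate must be > 0, got {self.sample_rate}")
        if self.gap_mask is None:
            self.gap_mask = ~np.all(np.isfinite(self.positions), axis=2)
        else:
            self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
            if self.gap_mask.shape != (n_frames, n_markers):
                raise SchemaError("gap_mask shape mismatch")
        if self.frame_index is None:
            self.frame_index = np.arange(n_frames)
        else:
            self.frame_index = np.asarray(self.frame_index, dtype=int)
        if not np.all(np.isfinite(self.positions[~self.gap_mask])):
            raise SchemaError("non-finite positions outside the gap mask")
        # gaps are NaN internally regardless of what the source stored
        self.positions = self.positions.copy()
        self.positions[self.gap_mask] = np.nan

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_markers(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds."""
        return self.frame_index / self.sample_rate

    def copy(self) -> "TrajectorySet":
        return TrajectorySet(
            marker_labels=list(self.marker_labels),
            positions=self.positions.copy(),
            sample_rate=self.sample_rate,
            gap_mask=self.gap_mask.copy(),
            frame_index=self.frame_index.copy(),
        )


def _parse_header(columns: Sequence[str]) -> list[str]:
    cols = [str(c).strip() for c in columns]
    if not cols or cols[0].lower() != "frame":
        raise SchemaError("first column must be 'frame'")
    coord_cols = cols[1:]
    if len(coord_cols) % 3 != 0:
        raise SchemaError(
            f"{len(coord_cols)} coordinate columns, not a multiple of 3"
        )
    labels = []
    for i in range(0, len(coord_cols), 3):
        triple = coord_cols[i : i + 3]
        bases = []
        for col, axis in zip(triple, ("x", "y", "z")):
            if not col.lower().endswith("_" + axis):
                raise SchemaError(
                    f"expected column ending '_{axis}', got '{col}'"
                )
            bases.append(col[: -2])
        if len(set(bases)) != 1:
            raise SchemaError(f"inconsistent marker label in columns {triple}")
        labels.append(bases[0])
    return labels


def read_markers(
    path,
    dialect: str = "tsv",
    *,
    zero_is_gap: bool = False,
    sample_rate: float | None = None,
) -> TrajectorySet:
    """Read a marker trajectory table.

    Parameters
    ----------
    path : path-like
        File to read.
    dialect : {"tsv", "csv", "c3d"}
        Text dialects parse the layout described in the module docstring;
        "c3d" requires an installed C3D backend (ezc3d or c3d).
    zero_is_gap : bool
        Treat exact (0, 0, 0) marker samples as gaps.
    sample_rate : float, optional
        Override the file's declared (or default 150 Hz) sampling rate.

    Raises
    ------
    SchemaError
        Fewer than 3 markers, malformed header, or inconsistent column
        counts across rows.
    """
    path = Path(path)
    if dialect == "c3d":
        traj = _read_c3d(path, zero_is_gap=zero_is_gap)
    elif dialect in ("tsv", "csv"):
        traj = _read_text(path, sep="\t" if dialect == "tsv" else ",",
                          zero_is_gap=zero_is_gap)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    if sample_rate is not None:
        traj.sample_rate = float(sample_rate)
    return traj


def _read_text(path: Path, sep: str, zero_is_gap: bool) -> TrajectorySet:
    meta = {"units": "mm", "sample_rate": 150.0}
    rows: list[list[str]] = []
    header: list[str] | None = None
    with open(path, "r") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                stripped = line[1:].strip()
                if ":" in stripped:
                    key, _, value = stripped.partition(":")
                    key = key.strip().lower()
                    if key == "units":
                        meta["units"] = value.strip().lower()
                    elif key == "sample_rate":
                        meta["sample_rate"] = float(value.strip())
            elif line.strip() == "":
                continue
            elif header is None:
                header = line.split(sep)
            else:
                fields = line.split(sep)
                if len(fields) != len(header):
                    raise SchemaError(
                        f"row {len(rows) + 1} has {len(fields)} columns, "
                        f"header has {len(header)}"
                    )
                rows.append(fields)
    if header is None:
        raise SchemaError("missing header row")
    if not rows:
        raise SchemaError("no data rows")
    labels = _parse_header(header)
    if len(labels) < 3:
        raise SchemaError(f"need at least 3 markers, got {len(labels)}")

    if meta["units"] not in _UNIT_TO_MM:
        raise SchemaError(f"unknown units {meta['units']!r}")
    scale = _UNIT_TO_MM[meta["units"]]

    def to_float(cell: str) -> float:
        # python's float() is a correctly rounded parser (unlike the
        # approximate pandas one), so write -> read is ulp-exact
        try:
            return float(cell)
        except ValueError:
            return np.nan

    try:
        frame_index = np.array([int(float(r[0])) for r in rows])
    except ValueError as exc:
        raise SchemaError(f"non-numeric frame column: {exc}") from exc
    coords = np.array([[to_float(c) for c in r[1:]] for r in rows])
    positions = coords.reshape(len(rows), len(labels), 3) * scale
    gap_mask = ~np.all(np.isfinite(positions), axis=2)
    if zero_is_gap:
        gap_mask |= np.all(positions == 0.0, axis=2)
    return TrajectorySet(
        marker_labels=labels,
        positions=positions,
        sample_rate=meta["sample_rate"],
        gap_mask=gap_mask,
        frame_index=frame_index,
    )


def _read_c3d(path: Path, zero_is_gap: bool) -> TrajectorySet:
    try:
        import ezc3d
    except ImportError as exc:
        raise ImportError(
            "reading C3D files requires the optional 'ezc3d' package "
            "(pip install ezc3d); TSV/CSV dialects need no extra package"
        ) from exc
    c3d = ezc3d.c3d(str(path))
    points = c3d["data"]["points"]  # (4, n_markers, n_frames)
    labels = list(c3d["parameters"]["POINT"]["LABELS"]["value"])
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    positions = np.transpose(points[:3], (2, 1, 0)).astype(float)
    gap_mask = ~np.all(np.isfinite(positions), axis=2)
    if zero_is_gap:
        gap_mask |= np.all(positions == 0.0, axis=2)
    return TrajectorySet(
        marker_labels=labels,
        positions=positions,
        sample_rate=rate if rate > 0 else 150.0,
        gap_mask=gap_mask,
    )


def write_markers(traj: TrajectorySet, path, dialect: str = "tsv") -> None:
    """Write a trajectory as a TSV/CSV marker table (gaps as blank cells).

    Round-trips through :func:`read_markers` to full float64 precision.
    """
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unsupported write dialect {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    header = ["frame"]
    for label in traj.marker_labels:
        header += [f"{label}_{ax}" for ax in "xyz"]
    lines = [
        "# units: mm",
        f"# sample_rate: {traj.sample_rate:g}",
        sep.join(header),
    ]
    flat = traj.positions.reshape(traj.n_frames, -1)
    for row, fi in zip(flat, traj.frame_index):
        cells = [str(int(fi))]
        cells += ["" if not np.isfinite(v) else f"{v:.17g}" for v in row]
        lines.append(sep.join(cells))
    Path(path).write_text("\n".join(lines) + "\n")


def interpolate_gaps(traj: TrajectorySet, max_gap_frames: int) -> TrajectorySet:
    """Fill short gaps by per-coordinate linear interpolation.

    Gap runs of length <= ``max_gap_frames`` that have valid samples on
    both sides are filled linearly; longer runs and leading/trailing
    gaps stay masked. Unmasked samples are never altered. Returns a new
    TrajectorySet; the input is untouched.
    """
    if max_gap_frames < 0:
        raise ValueError("max_gap_frames must be >= 0")
    out = traj.copy()
    if max_gap_frames == 0 or not out.gap_mask.any():
        return out
    for m in range(out.n_markers):
        mask = out.gap_mask[:, m]
        if not mask.any():
            continue
        # enumerate gap runs
        padded = np.concatenate(([False], mask, [False]))
        starts = np.flatnonzero(~padded[:-1] & padded[1:])
        ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # exclusive
        for s, e in zip(starts, ends):
            if e - s > max_gap_frames:
                continue
            if s == 0 or e == out.n_frames:  # no flank on one side
                continue
            left = out.positions[s - 1, m]
            right = out.positions[e, m]
            t = np.arange(1, e - s + 1) / (e - s + 1)
            out.positions[s:e, m] = left + t[:, None] * (right - left)
            out.gap_mask[s:e, m] = False
    return out
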