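"""Per-frame kinematic analysis of a marker trajectory.

For each frame, both curvature measures are computed on the proximal and
distal three-marker segments, the two local coordinate systems are
built, and the three relative-orientation angles (flexion/extension,
abduction/adduction, external/internal rotation) are extracted. Frames
with unfilled gaps, colinear segments or the singular axis configuration
are carried through with missing values rather than aborting the run.

Postures are labelled with configurable thresholds (degrees):

* ``nearly_straight`` — both segment chord angles k_b below
  ``straight_kb_max`` (default 15): the arm is close to a line and the
  bend planes, hence the angles, are barely defined.
* ``complex_bending`` — max(|beta|, |gamma|) above ``nonplanar_min``
  (default 30): the segments curve in clearly different planes.
* ``simple_bending`` — both k_b at or above ``straight_kb_max`` and the
  non-planar angles within ``nonplanar_min``: substantial curvature,
  approximately one plane.
* ``unclassified`` — anything else (including frames without angles that
  are not nearly straight).

The defaults were chosen so that published exemplar postures for this
kind of data fall in the intended classes; postures in the source
studies were identified visually, so the numeric taxonomy is a
convenience, not a claim of equivalence, and every threshold is exposed
in the configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .curvature import CurvatureSample, SegmentTriple, compute_kb, compute_ko
from .errors import DegenerateGeometryError, SchemaError
from .markers import TrajectorySet
from .orientation import OrientationAngles, build_local_frame, relative_orientation
from .config import Thresholds

__all__ = [
    "PostureResult",
    "analyze_trajectory",
    "classify_posture",
    "summarize",
    "results_to_frame",
    "find_extreme_posture",
    "LABELS",
]

LABELS = ("nearly_straight", "simple_bending", "complex_bending", "unclassified")


@dataclass
class PostureResult:
    """Curvatures, orientation angles and posture label for one frame."""

    frame: int
    proximal: Optional[CurvatureSample]
    distal: Optional[CurvatureSample]
    angles: Optional[OrientationAngles]
    label: str = "unclassified"


def classify_posture(
    result: PostureResult, thresholds: Thresholds = Thresholds()
) -> str:
    """Assign a posture label from a frame's curvatures and angles.

    Checks run in order: nearly straight (curvatures only), then complex
    bending (non-planar angles), then simple bending. Raising
    ``straight_kb_max`` therefore never moves a frame out of
    ``nearly_straight``.
    """
    if result.proximal is None or result.distal is None:
        return "unclassified"
    kb_p, kb_d = result.proximal.k_b, result.distal.k_b
    if kb_p < thresholds.straight_kb_max and kb_d < thresholds.straight_kb_max:
        return "nearly_straight"
    if result.angles is None:
        return "unclassified"
    nonplanar = max(abs(result.angles.beta), abs(result.angles.gamma))
    if nonplanar > thresholds.nonplanar_min:
        return "complex_bending"
    if kb_p >= thresholds.straight_kb_max and kb_d >= thresholds.straight_kb_max:
        return "simple_bending"
    return "unclassified"


def _smooth_positions(traj: TrajectorySet, window: int) -> np.ndarray:
    """Centered moving average over valid samples; gaps stay NaN."""
    if window in (0, 1):
        return traj.positions
    if window % 2 == 0:
        raise ValueError(f"smoothing window must be odd, got {window}")
    n_frames = traj.n_frames
    flat = traj.positions.reshape(n_frames, -1)
    smoothed = (
        pd.DataFrame(flat)
        .rolling(window, center=True, min_periods=1)
        .mean()
        .to_numpy()
        .reshape(traj.positions.shape)
    )
    smoothed[traj.gap_mask] = np.nan
    return smoothed


def analyze_trajectory(
    traj: TrajectorySet,
    proximal: SegmentTriple = SegmentTriple(0, 1, 2),
    distal: SegmentTriple = SegmentTriple(2, 3, 4),
    smoothing_window: int = 0,
    thresholds: Thresholds = Thresholds(),
) -> list[PostureResult]:
    """Run the full per-frame analysis over a trajectory.

    Each frame's result depends only on that frame's (optionally
    smoothed) positions. Frames with gaps in any needed marker, or with
    degenerate geometry, yield missing curvatures/angles and the
    ``unclassified`` label.
    """
    n = traj.n_markers
    for t in (proximal, distal):
        if t.i3 >= n:
            raise SchemaError(
                f"segment indices {t.indices} out of range for {n} markers"
            )
    positions = _smooth_positions(traj, smoothing_window)
    results: list[PostureResult] = []
    for f in range(traj.n_frames):
        frame_no = int(traj.frame_index[f])
        needed = set(proximal.indices) | set(distal.indices)
        if any(traj.gap_mask[f, m] for m in needed):
            results.append(
                PostureResult(frame_no, None, None, None, "unclassified")
            )
            continue
        pts = positions[f]
        prox_c = _segment_curvature(pts, proximal, frame_no)
        dist_c = _segment_curvature(pts, distal, frame_no)
        angles = None
        if prox_c is not None and dist_c is not None:
            try:
                frame_p = build_local_frame(*(pts[i] for i in proximal.indices))
                frame_d = build_local_frame(*(pts[i] for i in distal.indices))
                angles = relative_orientation(frame_p, frame_d)
            except DegenerateGeometryError:
                angles = None
        result = PostureResult(frame_no, prox_c, dist_c, angles)
        result.label = classify_posture(result, thresholds)
        results.append(result)
    return results


def _segment_curvature(
    pts: np.ndarray, triple: SegmentTriple, frame_no: int
) -> Optional[CurvatureSample]:
    p1, p2, p3 = (pts[i] for i in triple.indices)
    try:
        return CurvatureSample(
            k_o=compute_ko(p1, p2, p3),
            k_b=compute_kb(p1, p2, p3),
            segment=triple,
            frame=frame_no,
        )
    except DegenerateGeometryError:
        return None


def results_to_frame(
    results: Sequence[PostureResult], sample_rate: float = 150.0
) -> pd.DataFrame:
    """Tidy per-frame table: one row per frame, NaN for missing values."""
    rows = []
    for r in results:
        rows.append(
            {
                "frame": r.frame,
                "time_s": r.frame / sample_rate,
                "k_o_prox": r.proximal.k_o if r.proximal else np.nan,
                "k_b_prox": r.proximal.k_b if r.proximal else np.nan,
                "k_o_dist": r.distal.k_o if r.distal else np.nan,
                "k_b_dist": r.distal.k_b if r.distal else np.nan,
                "alpha": r.angles.alpha if r.angles else np.nan,
                "beta": r.angles.beta if r.angles else np.nan,
                "gamma": r.angles.gamma if r.angles else np.nan,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)


_SUMMARY_COLUMNS = ["k_b_prox", "k_b_dist", "alpha", "beta", "gamma"]


def summarize(
    results: Sequence[PostureResult] | pd.DataFrame,
    group_by: str = "label",
) -> pd.DataFrame:
    """Per-label mean and sample standard deviation of k_b and (α, β, γ).

    Mirrors the group-average tables of this kind of study: one row per
    posture label present in the data, columns ``<quantity>_mean`` /
    ``<quantity>_sd`` plus the group size ``n``. Groups of one frame
    report sd 0. Empty groups are absent, never zero-filled.
    """
    df = (
        results
        if isinstance(results, pd.DataFrame)
        else results_to_frame(results)
    )
    if df.empty:
        raise ValueError("no results to summarize")
    out_rows = {}
    for label, group in df.groupby(group_by, sort=False):
        row: dict[str, float] = {"n": len(group)}
        for col in _SUMMARY_COLUMNS:
            values = group[col].dropna()
            row[f"{col}_mean"] = values.mean() if len(values) else np.nan
            sd = values.std(ddof=1) if len(values) > 1 else 0.0
            row[f"{col}_sd"] = sd if len(values) else np.nan
        out_rows[label] = row
    out = pd.DataFrame.from_dict(out_rows, orient="index")
    out.index.name = group_by
    out["n"] = out["n"].astype(int)
    return out


def find_extreme_posture(
    results: Sequence[PostureResult], mode: str = "min"
) -> Optional[PostureResult]:
    """Frame minimizing ("min") or maximizing ("max") overall curvature.

    Overall curvature is the larger of the two segment chord angles —
    the scalar used to pick the straightest (min) or most bent (max)
    posture out of a recording, as done by eye in the source studies.
    Frames without both curvatures are ignored; returns None if none
    qualify.
    """
    if mode not in ("min", "max"):
        raise ValueError("mode must be 'min' or 'max'")
    scored = [
        (max(r.proximal.k_b, r.distal.k_b), r)
        for r in results
        if r.proximal is not None and r.distal is not None
    ]
    if not scored:
        return None
    key = min if mode == "min" else max
    return key(scored, key=lambda t: t[0])[1]
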