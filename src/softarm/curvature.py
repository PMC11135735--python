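"""Discrete curvature of a three-marker segment.

Two measures are computed for every ordered triple of markers
(proximal, middle, distal):

``k_o``
    Circumradius curvature, the inverse of the radius ``R`` of the circle
    through the three points, obtained from the triangle side lengths via
    Heron's formula::

        k_o = 4 * sqrt(s (s-a) (s-b) (s-c)) / (a b c) = 1 / R

    Units mm^-1. Because ``R`` scales with the segment, ``k_o`` is
    sensitive to marker spacing.

``k_b``
    Chord-angle curvature, the angle between the two consecutive chord
    vectors v1 = p2 - p1 and v2 = p3 - p2::

        k_b = arccos(v1 . v2 / (|v1| |v2|))

    Units degrees, in [0, 180). For equally spaced markers on a circle,
    k_b equals the angular spacing between consecutive markers (exterior
    angle), independent of the radius.

Both are zero exactly when the three markers are colinear.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import DegenerateGeometryError

__all__ = ["SegmentTriple", "CurvatureSample", "compute_ko", "compute_kb"]


@dataclass(frozen=True)
class SegmentTriple:
    """Ordered triple of marker indices defining one arm segment.

    Indices run proximal to distal and must be distinct and strictly
    increasing. The canonical 5-marker arm uses (0, 1, 2) for the
    proximal segment and (2, 3, 4) for the distal; they share marker 2.
    """

    i1: int
    i2: int
    i3: int

    def __post_init__(self) -> None:
        if not (self.i1 < self.i2 < self.i3):
            raise ValueError(
                f"segment indices must be strictly increasing, got "
                f"({self.i1}, {self.i2}, {self.i3})"
            )

    @property
    def indices(self) -> tuple[int, int, int]:
        return (self.i1, self.i2, self.i3)


@dataclass(frozen=True)
class CurvatureSample:
    """Both curvature measures for one segment in one frame."""

    k_o: float  # circumradius curvature, mm^-1
    k_b: float  # chord angle, degrees
    segment: Optional[SegmentTriple] = None
    frame: Optional[int] = None


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (3,):
        raise ValueError(f"expected a 3D point, got shape {a.shape}")
    if not np.all(np.isfinite(a)):
        raise ValueError("point coordinates must be finite")
    return a


def compute_ko(p1, p2, p3) -> float:
    """Circumradius curvature 1/R of the circle through three points, mm^-1.

    Returns exactly 0.0 for colinear points (the Heron square-root
    argument is clamped at zero to absorb floating-point negatives).

    Raises
    ------
    DegenerateGeometryError
        If two or more points coincide; the circumradius is undefined.
    """
    p1, p2, p3 = _as_point(p1), _as_point(p2), _as_point(p3)
    a = float(np.linalg.norm(p2 - p3))
    b = float(np.linalg.norm(p1 - p3))
    c = float(np.linalg.norm(p1 - p2))
    if a == 0.0 or b == 0.0 or c == 0.0:
        raise DegenerateGeometryError(
            "coincident markers: circumradius undefined"
        )
    s = 0.5 * (a + b + c)
    # Heron: 16 * area^2 = 16 s (s-a)(s-b)(s-c); clamp for near-colinear
    heron = max(s * (s - a) * (s - b) * (s - c), 0.0)
    return 4.0 * np.sqrt(heron) / (a * b * c)


def compute_kb(p1, p2, p3) -> float:
    """Angle between consecutive chords (p2-p1) and (p3-p2), degrees.

    0 deg for colinear points in the same direction, 90 deg for a right
    angle, approaching 180 deg as the path doubles back.

    Raises
    ------
    DegenerateGeometryError
        If either chord has zero length.
    """
    p1, p2, p3 = _as_point(p1), _as_point(p2), _as_point(p3)
    v1 = p2 - p1
    v2 = p3 - p2
    n1 = float(np.linalg.norm(v1))
    n2 = float(np.linalg.norm(v2))
    if n1 == 0.0 or n2 == 0.0:
        raise DegenerateGeometryError(
            "zero-length chord: chord angle undefined"
        )
    cos_angle = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(cos_angle)))
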