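"""Relative planar orientation of two arm segments (joint coordinate system).

Each three-marker segment carries a right-handed local coordinate system
(LCS) in the style of Grood & Suntay's joint coordinate system, adapted
to a soft body with no joint centres:

* long axis ``K_hat = (P1 - P3) / |P1 - P3|`` — the direction the segment
  would have if straight, pointing distal -> proximal;
* bend normal ``I_hat = (P2 - P3) x K_hat``, normalised — normal to the
  plane of the bend;
* completing axis ``J_hat = K_hat x I_hat``.

Between a proximal frame (I, J, K) and a distal frame (i, j, k), two
fixed body axes and one floating axis are defined::

    e1 = I_hat          (proximal bend normal)
    e3 = k_hat          (distal long axis)
    e2 = e3 x e1 / |e3 x e1|

and three angles, in degrees, describe the distal segment relative to
the proximal:

* alpha — flexion(-)/extension(+): ``sin(alpha) = -e2 . K_hat``,
  principal range [-90, +90];
* beta  — abduction(+)/adduction(-): ``cos(beta + 90 deg) = e1 . e3``,
  inverted directly to ``beta = arccos(e1 . e3) - 90`` in [-90, +90];
* gamma — external(+)/internal(-) long-axis rotation, computed with a
  two-argument tangent so the full 360 deg span is resolved::

      gamma = atan2((e2 x j_hat) . e3,  e2 . j_hat)   in (-180, +180].

  Sine and cosine alone fold rotations beyond +-90 deg back into the
  principal range; the atan2 form, with the signed sine taken along the
  distal long axis e3, does not.

Signs follow the right-side-of-body convention. When e1 and e3 are
parallel the floating axis is undefined (the gimbal-lock analogue) and a
:class:`~softarm.errors.SingularConfigurationError` is raised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ColinearityError, SingularConfigurationError

__all__ = [
    "LocalFrame",
    "FloatingAxes",
    "OrientationAngles",
    "build_local_frame",
    "floating_axes",
    "relative_orientation",
]

#: dimensionless colinearity threshold: |u x v| / (|u| |v|) below this
#: means the three markers define no bend plane
COLINEARITY_TOL = 1e-10

#: |e3 x e1| below this is treated as the singular (parallel) configuration
SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class LocalFrame:
    """Right-handed orthonormal triad attached to a three-marker segment.

    ``origin`` is the segment's shared (middle-of-arm) marker, kept for
    reporting only; the axes are position-independent.
    """

    I_hat: np.ndarray
    J_hat: np.ndarray
    K_hat: np.ndarray
    origin: np.ndarray


@dataclass(frozen=True)
class FloatingAxes:
    """Fixed body axes e1 (proximal I), e3 (distal k) and floating e2."""

    e1: np.ndarray
    e2: np.ndarray
    e3: np.ndarray


@dataclass(frozen=True)
class OrientationAngles:
    """The three relative-orientation angles, degrees.

    alpha: flexion(-)/extension(+), in [-90, +90].
    beta:  abduction(+)/adduction(-), in [-90, +90].
    gamma: external(+)/internal(-) rotation, in (-180, +180].
    """

    alpha: float
    beta: float
    gamma: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def build_local_frame(p1, p2, p3) -> LocalFrame:
    """Construct the segment local coordinate system from three markers.

    Parameters are the segment's markers in proximal -> distal order.

    Raises
    ------
    ColinearityError
        If the markers are (numerically) colinear: the bend-plane normal
        is the zero vector and no frame exists.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)

    u = p1 - p3
    v1 = p2 - p3
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v1)
    if nu == 0.0 or nv == 0.0:
        raise ColinearityError("coincident markers: no local frame")
    K_hat = u / nu

    cross = np.cross(v1, K_hat)
    # scale-free colinearity test
    if np.linalg.norm(cross) / nv < COLINEARITY_TOL:
        raise ColinearityError(
            "colinear markers: bend plane undefined, no local frame"
        )
    I_hat = _unit(cross)
    J_hat = _unit(np.cross(K_hat, I_hat))
    return LocalFrame(I_hat=I_hat, J_hat=J_hat, K_hat=K_hat, origin=p3.copy())


def floating_axes(proximal: LocalFrame, distal: LocalFrame) -> FloatingAxes:
    """Fixed body axes and the floating axis between two segment frames.

    e1 is the proximal bend normal, e3 the distal long axis, and
    e2 = (e3 x e1), normalised.

    Raises
    ------
    SingularConfigurationError
        If e1 and e3 are parallel (|e3 x e1| < SINGULAR_TOL); the
        message reports the angle between them.
    """
    e1 = proximal.I_hat
    e3 = distal.K_hat
    cross = np.cross(e3, e1)
    norm = np.linalg.norm(cross)
    if norm < SINGULAR_TOL:
        angle = np.degrees(np.arccos(np.clip(abs(np.dot(e1, e3)), -1.0, 1.0)))
        raise SingularConfigurationError(angle)
    return FloatingAxes(e1=e1, e2=cross / norm, e3=e3)


def relative_orientation(
    proximal: LocalFrame, distal: LocalFrame
) -> OrientationAngles:
    """The three angles of the distal frame relative to the proximal.

    See the module docstring for definitions and sign conventions.
    Propagates :class:`SingularConfigurationError` from the floating-axis
    construction.
    """
    axes = floating_axes(proximal, distal)
    e1, e2, e3 = axes.e1, axes.e2, axes.e3

    alpha = np.degrees(np.arcsin(np.clip(-np.dot(e2, proximal.K_hat), -1.0, 1.0)))
    beta = np.degrees(np.arccos(np.clip(np.dot(e1, e3), -1.0, 1.0))) - 90.0

    j_hat = distal.J_hat
    sin_g = np.dot(np.cross(e2, j_hat), e3)
    cos_g = np.dot(e2, j_hat)
    gamma = np.degrees(np.arctan2(sin_g, cos_g))
    if gamma <= -180.0:  # map -180 to +180 for the (-180, 180] interval
        gamma += 360.0
    return OrientationAngles(alpha=float(alpha), beta=float(beta), gamma=float(gamma))
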