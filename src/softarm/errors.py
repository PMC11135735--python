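"""Exception hierarchy for softarm.

All geometry failures derive from :class:`DegenerateGeometryError` so a
pipeline can catch one class; data-layer problems derive from
:class:`SchemaError`.
"""


class SoftarmError(Exception):
    """Base class for all softarm errors."""


class SchemaError(SoftarmError):
    """Marker table does not conform to the expected layout."""


class ParameterError(SoftarmError, ValueError):
    """A generator or configuration parameter is out of its valid range."""


class DegenerateGeometryError(SoftarmError, ValueError):
    """Marker geometry does not admit the requested computation."""


class ColinearityError(DegenerateGeometryError):
    """Three markers are colinear: no bend plane, no local frame.

    A colinear triple has a well-defined curvature (zero) but no local
    coordinate system, because the plane normal is the zero vector.
    """


class SingularConfigurationError(DegenerateGeometryError):
    """Fixed body axes e1 and e3 are parallel (gimbal lock).

    The floating axis e2 = e3 x e1 / |e3 x e1| is undefined, so the
    flexion and long-axis rotation angles cannot be separated.
    """

    def __init__(self, angle_deg: float):
        self.angle_deg = float(angle_deg)
        super().__init__(
            f"fixed axes e1 and e3 are parallel (angle between them "
            f"{angle_deg:.3g} deg); floating axis undefined"
        )
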