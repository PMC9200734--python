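"""Short-axis-area-based quantities and the two SAX+length comparator
methods (area-length and truncated ellipsoid).

The mean wall thickness ``t`` is the difference of equivalent-circle radii
of the epicardial (A1) and endocardial (A2) traced areas:

    t = sqrt(A1/pi) - sqrt(A2/pi)

and the cavity minor semi-axis is ``b = sqrt(A2/pi)``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .core_types import RecordValidationError, SaxTrace, Violation

#: Myocardial density used for mass conversion (g/ml).
DENSITY_G_PER_ML = 1.05


@dataclass(frozen=True)
class LongAxisSplit:
    """Long-axis length split at the SAX plane.

    ``a_cm``: apex to SAX plane; ``d_cm``: SAX plane to mitral plane.
    """

    a_cm: float
    d_cm: float

    def __post_init__(self) -> None:
        v: list[Violation] = []
        if not self.a_cm > 0:
            v.append(Violation("a_cm", "must be > 0"))
        if self.d_cm < 0:
            v.append(Violation("d_cm", "must be >= 0"))
        if v:
            raise RecordValidationError(v)


def mean_wall_thickness(s: SaxTrace) -> float:
    """t = sqrt(A1/pi) - sqrt(A2/pi), in cm (>= 0 by the A1 >= A2 invariant)."""
    return math.sqrt(s.a1_cm2 / math.pi) - math.sqrt(s.a2_cm2 / math.pi)


def minor_semi_axis(s: SaxTrace) -> float:
    """Equivalent-circle cavity radius b = sqrt(A2/pi), in cm."""
    return math.sqrt(s.a2_cm2 / math.pi)


def area_length_lvm(s: SaxTrace, L: LongAxisSplit, density: float = DENSITY_G_PER_ML) -> float:
    """Area-length LV mass (g).

    LVM = density * (5/6) * [A1 * (a + d + t) - A2 * (a + d)]
    with t = mean_wall_thickness(s).
    """
    t = mean_wall_thickness(s)
    return density * (5.0 / 6.0) * (s.a1_cm2 * (L.a_cm + L.d_cm + t) - s.a2_cm2 * (L.a_cm + L.d_cm))


def truncated_ellipsoid_lvm(
    s: SaxTrace, L: LongAxisSplit, density: float = DENSITY_G_PER_ML
) -> float:
    """Truncated-ellipsoid LV mass (g).

    LVM = density * pi * { (b+t)^2 * [ (2/3)(a+t) + d - d^3 / (3 (a+t)^2) ]
                           -  b^2  * [ (2/3) a    + d - d^3 / (3 a^2) ] }
    """
    a, d = L.a_cm, L.d_cm
    if d > a:
        warnings.warn(
            "truncated ellipsoid with d > a: SAX plane lies below the ellipsoid "
            "equator; result may be unreliable",
            stacklevel=2,
        )
    b = minor_semi_axis(s)
    t = mean_wall_thickness(s)

    def half_shape(semi_minor: float, semi_major: float) -> float:
        return semi_minor**2 * (
            (2.0 / 3.0) * semi_major + d - d**3 / (3.0 * semi_major**2)
        )

    return density * math.pi * (half_shape(b + t, a + t) - half_shape(b, a))
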