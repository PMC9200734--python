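"""Biplane model of discs (modified Simpson rule).

The cavity is modelled as a base->apex stack of elliptical discs whose two
semi-axes come from the 4-chamber and 2-chamber delineations.  Chords are
sampled at disc mid-levels (midpoint rule, second-order accurate) at the
same fractional positions of each view's own long-axis length; the stack
height is the effective length (max of the two views) divided by the disc
count.
"""

from __future__ import annotations

import math

import numpy as np
from shapely.geometry import LineString, Polygon

from .core_types import DiscStack, PlanarContour
from .sax_methods import DENSITY_G_PER_ML

DEFAULT_N_DISCS = 30


class GeometryError(ValueError):
    """Degenerate or inconsistent geometry."""


def _axis_frame(c: PlanarContour) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    base = np.asarray(c.base_mid, dtype=float)
    apex = np.asarray(c.apex, dtype=float)
    axis = apex - base
    length = float(np.hypot(*axis))
    if length <= 0:
        raise GeometryError("apex coincides with the base midpoint")
    u = axis / length
    normal = np.array([-u[1], u[0]])
    return base, u, normal, length


def chord_semi_axes(c: PlanarContour, fractions: np.ndarray) -> np.ndarray:
    """Half chord widths perpendicular to the long axis at the given
    fractional levels (0 = base midpoint, 1 = apex) of this view."""
    base, u, normal, length = _axis_frame(c)
    poly = Polygon(c.points)
    if not poly.is_valid:
        poly = poly.buffer(0)
    # reach far enough to cross the contour at every level
    minx, miny, maxx, maxy = poly.bounds
    reach = 2.0 * (abs(maxx - minx) + abs(maxy - miny)) + 1.0
    semi = np.empty(len(fractions))
    for i, f in enumerate(fractions):
        p = base + f * length * u
        probe = LineString([p - reach * normal, p + reach * normal])
        cut = probe.intersection(poly)
        semi[i] = 0.5 * cut.length
    return semi


def contours_to_discstack(
    c4: PlanarContour, c2: PlanarContour, n: int = DEFAULT_N_DISCS
) -> DiscStack:
    """Slice a pair of apical contours into an n-disc stack.

    Semi-axis i of a disc is half the contour chord width at the disc's
    mid-level, measured perpendicular to the long axis of that view.
    """
    if n < 1:
        raise ValueError("disc count must be >= 1")
    _, _, _, len4 = _axis_frame(c4)
    _, _, _, len2 = _axis_frame(c2)
    fractions = (np.arange(n) + 0.5) / n
    a = chord_semi_axes(c4, fractions)
    b = chord_semi_axes(c2, fractions)
    return DiscStack(
        semi_axes=tuple(zip(a.tolist(), b.tolist())),
        length_4ch_cm=len4,
        length_2ch_cm=len2,
    )


def biplane_edv(d: DiscStack) -> float:
    """Stack volume (ml): sum over discs of pi * a_i * b_i * h."""
    h = d.disc_height_cm
    return float(sum(math.pi * a * b * h for a, b in d.semi_axes))


def bp_lvm(endo: DiscStack, epi: DiscStack, density: float = DENSITY_G_PER_ML) -> float:
    """Conventional biplane mass: density * (epi volume - endo volume).

    Both stacks must have the same disc count; the epicardial volume must
    not be smaller than the endocardial one.
    """
    if endo.n_discs != epi.n_discs:
        raise GeometryError(
            f"disc counts differ: endo {endo.n_discs} vs epi {epi.n_discs}"
        )
    v_endo = biplane_edv(endo)
    v_epi = biplane_edv(epi)
    if v_epi < v_endo:
        raise GeometryError(
            f"epicardial volume {v_epi:.2f} ml smaller than endocardial {v_endo:.2f} ml"
        )
    return density * (v_epi - v_endo)
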