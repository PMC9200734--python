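"""Analytic LV phantoms with closed-form ground truth.

Three shape families, all with uniform wall thickness ``wall_cm`` unless a
focal bulge is requested:

``hemi_ellipsoid``
    Cavity is a half ellipsoid with long semi-axis ``endo_long_cm`` (apex
    to base) and short semi-axes ``endo_b_cm`` (4CH direction) and
    ``endo_c_cm`` (2CH direction); the epicardial surface is the
    concentric half ellipsoid with each semi-axis enlarged by the wall.

``cylinder_flat_cap``
    Elliptical cylinder cavity closed by a flat apical cap of thickness
    equal to the wall.

``septal_bulge``
    Circular ``cylinder_flat_cap`` plus a smooth cosine-tapered focal wall
    thickening on the septal (4CH, +x) side, centred at the SAX level.
    The bulge adds ``bulge_extra_cm`` of wall thickness at its centre and
    tapers to zero over a half-extent of ``bulge_theta_rad`` radians
    circumferentially and ``bulge_halflen_cm`` cm longitudinally; its
    integrated extra volume is closed-form.

Axial coordinate ``z`` runs from the base plane (z = 0) to the endocardial
apex (z = cavity length); the SAX plane sits at
``sax_level_fraction * length`` from the base ("chordae level" mapped to
0.4 by default).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from enum import Enum

import numpy as np
import pandas as pd

from .core_types import (
    DiscStack,
    LinearMeasurements,
    PlanarContour,
    SaxLevel,
    SaxTrace,
)
from .sax_methods import DENSITY_G_PER_ML, LongAxisSplit


class Shape(str, Enum):
    HEMI_ELLIPSOID = "hemi_ellipsoid"
    CYLINDER_FLAT_CAP = "cylinder_flat_cap"
    SEPTAL_BULGE = "septal_bulge"


class PhantomGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class PhantomSpec:
    shape: Shape = Shape.HEMI_ELLIPSOID
    endo_long_cm: float = 8.0
    endo_b_cm: float = 2.5
    endo_c_cm: float = 2.5
    wall_cm: float = 1.0
    bulge_extra_cm: float = 0.0
    bulge_theta_rad: float = 1.0
    bulge_halflen_cm: float = 2.0
    sax_level_fraction: float = 0.4

    def __post_init__(self) -> None:
        if min(self.endo_long_cm, self.endo_b_cm, self.endo_c_cm) <= 0:
            raise PhantomGeometryError("cavity dimensions must be > 0")
        if self.wall_cm < 0:
            raise PhantomGeometryError("wall thickness must be >= 0")
        if not 0 < self.sax_level_fraction < 1:
            raise PhantomGeometryError("sax_level_fraction must lie in (0, 1)")
        if self.shape is Shape.SEPTAL_BULGE:
            if abs(self.endo_b_cm - self.endo_c_cm) > 1e-12:
                raise PhantomGeometryError("septal_bulge requires a circular cavity (b == c)")
            z_c = self.sax_level_fraction * self.endo_long_cm
            if z_c - self.bulge_halflen_cm < 0 or z_c + self.bulge_halflen_cm > self.endo_long_cm:
                raise PhantomGeometryError("bulge extends beyond the cavity length")

    def to_json(self) -> str:
        d = {k: (v.value if isinstance(v, Enum) else v) for k, v in self.__dict__.items()}
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        d = json.loads(text)
        d["shape"] = Shape(d["shape"])
        return cls(**d)


@dataclass(frozen=True)
class NoiseModel:
    """Independent Gaussian measurement noise (a stand-in error model, not
    an estimate of real sonographer error).

    ``trace_segments`` is the effective number of independent boundary
    segments in an area trace: a traced area averages its boundary-
    localization error around the circumference, so its realized relative
    SD is ``area_rel_sd / sqrt(trace_segments)``.  The default of 1 treats
    the whole trace as one coherent measurement (like a caliper).
    """

    linear_sd_cm: float = 0.0
    area_rel_sd: float = 0.0
    contour_rel_sd: float = 0.0
    trace_segments: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.linear_sd_cm, self.area_rel_sd, self.contour_rel_sd) < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.trace_segments < 1:
            raise ValueError("trace_segments must be >= 1")


@dataclass(frozen=True)
class RenderedMeasurements:
    """Everything the quantification methods consume, rendered noiselessly
    (or perturbed) from one phantom."""

    linear: LinearMeasurements
    sax: SaxTrace
    disc_stack: DiscStack
    long_axis: LongAxisSplit
    contour_4ch: PlanarContour | None = None
    contour_2ch: PlanarContour | None = None


# ---------------------------------------------------------------------------
# closed-form truth

# cosine taper w(x) = (1 + cos(pi x / X)) / 2 on [-X, X]:
#   integral of w = X, integral of w^2 = 3X/4
_TAPER_I1 = 1.0
_TAPER_I2 = 0.75


def _bulge_extra_volume(p: PhantomSpec) -> float:
    if p.shape is not Shape.SEPTAL_BULGE or p.bulge_extra_cm == 0:
        return 0.0
    r_epi = p.endo_b_cm + p.wall_cm
    e = p.bulge_extra_cm
    i_theta1 = _TAPER_I1 * p.bulge_theta_rad
    i_theta2 = _TAPER_I2 * p.bulge_theta_rad
    i_z1 = _TAPER_I1 * p.bulge_halflen_cm
    i_z2 = _TAPER_I2 * p.bulge_halflen_cm
    return r_epi * e * i_theta1 * i_z1 + 0.5 * e**2 * i_theta2 * i_z2


def analytic_truth(p: PhantomSpec, density: float = DENSITY_G_PER_ML) -> tuple[float, float]:
    """Closed-form (cavity EDV in ml, myocardial mass in g)."""
    b, c, length, t = p.endo_b_cm, p.endo_c_cm, p.endo_long_cm, p.wall_cm
    if p.shape is Shape.HEMI_ELLIPSOID:
        edv = (2.0 / 3.0) * math.pi * b * c * length
        myo = (2.0 / 3.0) * math.pi * ((b + t) * (c + t) * (length + t) - b * c * length)
    else:
        edv = math.pi * b * c * length
        shell = math.pi * ((b + t) * (c + t) - b * c) * length
        cap = math.pi * (b + t) * (c + t) * t
        myo = shell + cap + _bulge_extra_volume(p)
    return edv, density * myo


# ---------------------------------------------------------------------------
# rendering


def _bulge_axial_taper(p: PhantomSpec, z: float) -> float:
    z_c = p.sax_level_fraction * p.endo_long_cm
    x = (z - z_c) / p.bulge_halflen_cm
    if abs(x) >= 1.0:
        return 0.0
    return 0.5 * (1.0 + math.cos(math.pi * x))


def _half_ellipse_contour(b: float, length: float, n_arc: int = 256) -> PlanarContour:
    phi = np.linspace(0.0, math.pi, n_arc)
    pts = [(b * math.cos(a), length * math.sin(a)) for a in phi]
    return PlanarContour(
        points=tuple(pts),
        base_left=(-b, 0.0),
        base_right=(b, 0.0),
        apex=(0.0, length),
    )


def _rectangle_contour(b: float, length: float) -> PlanarContour:
    return PlanarContour(
        points=((b, 0.0), (b, length), (-b, length), (-b, 0.0)),
        base_left=(-b, 0.0),
        base_right=(b, 0.0),
        apex=(0.0, length),
    )


def exact_disc_stack(p: PhantomSpec, n: int = 30) -> DiscStack:
    """Midpoint-sampled true endocardial semi-axes (bypasses contour slicing)."""
    fr = (np.arange(n) + 0.5) / n
    if p.shape is Shape.HEMI_ELLIPSOID:
        g = np.sqrt(1.0 - fr**2)
        semi = tuple(zip((p.endo_b_cm * g).tolist(), (p.endo_c_cm * g).tolist()))
    else:
        semi = tuple((p.endo_b_cm, p.endo_c_cm) for _ in range(n))
    return DiscStack(
        semi_axes=semi, length_4ch_cm=p.endo_long_cm, length_2ch_cm=p.endo_long_cm
    )


def render_measurements(p: PhantomSpec, n_discs: int = 30) -> RenderedMeasurements:
    """Noiseless measurements consistent with the phantom geometry.

    SAX areas are true cross-sections at the SAX plane, contours the true
    meridional sections, LVID the endocardial diameter at the SAX plane and
    IVS/PWT the in-plane radial wall thickness there (including any bulge).
    """
    b, c, length, t = p.endo_b_cm, p.endo_c_cm, p.endo_long_cm, p.wall_cm
    z = p.sax_level_fraction * length

    if p.shape is Shape.HEMI_ELLIPSOID:
        g2 = 1.0 - (z / length) ** 2
        if g2 <= 0:
            raise PhantomGeometryError("SAX plane outside the cavity")
        g_epi2 = 1.0 - (z / (length + t)) ** 2
        r2x = b * math.sqrt(g2)
        r1x = (b + t) * math.sqrt(g_epi2)
        a2 = math.pi * b * c * g2
        a1 = math.pi * (b + t) * (c + t) * g_epi2
        c4 = _half_ellipse_contour(b, length)
        c2 = _half_ellipse_contour(c, length)
    else:
        r2x = b
        r1x = b + t
        a2 = math.pi * b * c
        a1 = math.pi * (b + t) * (c + t)
        if p.shape is Shape.SEPTAL_BULGE and p.bulge_extra_cm > 0:
            u = _bulge_axial_taper(p, z)
            e = p.bulge_extra_cm * u
            r_epi = b + t
            # extra cross-sectional area of the tapered thickening
            a1 += r_epi * e * _TAPER_I1 * p.bulge_theta_rad
            a1 += 0.5 * e**2 * _TAPER_I2 * p.bulge_theta_rad
            r1x = r1x + e  # septal (+x) side carries the bulge
        c4 = _rectangle_contour(b, length)
        c2 = _rectangle_contour(c, length)

    linear = LinearMeasurements(ivs_cm=r1x - r2x, lvid_cm=2.0 * r2x, pwt_cm=(b + t) - b)
    if p.shape is Shape.HEMI_ELLIPSOID:
        # posterior wall mirrors the septal one (no bulge possible here)
        linear = LinearMeasurements(ivs_cm=r1x - r2x, lvid_cm=2.0 * r2x, pwt_cm=r1x - r2x)
    sax = SaxTrace(a1_cm2=a1, a2_cm2=a2, level=SaxLevel.CHORDAE)
    split = LongAxisSplit(a_cm=length - z, d_cm=z)
    stack = exact_disc_stack(p, n_discs)
    return RenderedMeasurements(
        linear=linear, sax=sax, disc_stack=stack, long_axis=split, contour_4ch=c4, contour_2ch=c2
    )


# ---------------------------------------------------------------------------
# noise


def perturb(
    m: RenderedMeasurements, nm: NoiseModel, rng: np.random.Generator | None = None
) -> RenderedMeasurements:
    """Apply the noise model; reproducible given the seed, identity when all
    SDs are zero.  Chord noise is applied to the disc-stack semi-axes (the
    carriers of the chord half-widths); contours are left untouched."""
    if rng is None:
        rng = np.random.default_rng(nm.seed)

    lin = m.linear
    if nm.linear_sd_cm > 0:
        noise = rng.normal(0.0, nm.linear_sd_cm, size=3)
        lin = LinearMeasurements(
            ivs_cm=max(lin.ivs_cm + noise[0], 0.0),
            lvid_cm=max(lin.lvid_cm + noise[1], 0.0),
            pwt_cm=max(lin.pwt_cm + noise[2], 0.0),
        )

    sax = m.sax
    if nm.area_rel_sd > 0:
        eff_sd = nm.area_rel_sd / math.sqrt(nm.trace_segments)
        f1, f2 = 1.0 + rng.normal(0.0, eff_sd, size=2)
        a1 = max(sax.a1_cm2 * f1, 0.0)
        a2 = max(sax.a2_cm2 * f2, 0.0)
        sax = SaxTrace(a1_cm2=max(a1, a2), a2_cm2=a2, level=sax.level)

    stack = m.disc_stack
    if nm.contour_rel_sd > 0:
        sa = np.asarray(stack.semi_axes)
        factors = 1.0 + rng.normal(0.0, nm.contour_rel_sd, size=sa.shape)
        sa = np.clip(sa * factors, 0.0, None)
        stack = replace(stack, semi_axes=tuple(map(tuple, sa.tolist())))

    return replace(m, linear=lin, sax=sax, disc_stack=stack)


# ---------------------------------------------------------------------------
# cohorts


def simulate_cohort(
    specs: list[PhantomSpec],
    nm: NoiseModel = NoiseModel(),
    sessions: int = 1,
    n_discs: int = 30,
) -> pd.DataFrame:
    """Tidy per-subject x session table of method inputs + analytic truth.

    Deterministic given the noise-model seed; each (subject, session) cell
    gets an independent RNG stream.
    """
    if not specs:
        raise ValueError("need at least one phantom spec")
    rows = []
    for i, spec in enumerate(specs):
        edv, lvm = analytic_truth(spec)
        clean = render_measurements(spec, n_discs=n_discs)
        for sess in range(sessions):
            rng = np.random.default_rng([nm.seed, i, sess])
            m = perturb(clean, nm, rng=rng)
            rows.append(
                {
                    "subject": f"P{i:03d}",
                    "session": sess + 1,
                    "shape": spec.shape.value,
                    "age_years": 50.0,
                    "sex": "M" if i % 2 == 0 else "F",
                    "bsa_m2": 1.9,
                    "ivs_cm": m.linear.ivs_cm,
                    "lvid_cm": m.linear.lvid_cm,
                    "pwt_cm": m.linear.pwt_cm,
                    "a1_cm2": m.sax.a1_cm2,
                    "a2_cm2": m.sax.a2_cm2,
                    "sax_level": m.sax.level.value,
                    "a_cm": m.long_axis.a_cm,
                    "d_cm": m.long_axis.d_cm,
                    "n_discs": m.disc_stack.n_discs,
                    "length_4ch_cm": m.disc_stack.length_4ch_cm,
                    "length_2ch_cm": m.disc_stack.length_2ch_cm,
                    "semi_axes_4ch": json.dumps([a for a, _ in m.disc_stack.semi_axes]),
                    "semi_axes_2ch": json.dumps([b for _, b in m.disc_stack.semi_axes]),
                    "truth_edv_ml": edv,
                    "truth_lvm_g": lvm,
                }
            )
    return pd.DataFrame(rows)


def cohort_row_to_measurements(row: "pd.Series | dict") -> RenderedMeasurements:
    """Rebuild the method inputs from one cohort-table row."""
    a4 = json.loads(row["semi_axes_4ch"])
    a2c = json.loads(row["semi_axes_2ch"])
    stack = DiscStack(
        semi_axes=tuple(zip(a4, a2c)),
        length_4ch_cm=float(row["length_4ch_cm"]),
        length_2ch_cm=float(row["length_2ch_cm"]),
    )
    return RenderedMeasurements(
        linear=LinearMeasurements(
            ivs_cm=float(row["ivs_cm"]),
            lvid_cm=float(row["lvid_cm"]),
            pwt_cm=float(row["pwt_cm"]),
        ),
        sax=SaxTrace(
            a1_cm2=float(row["a1_cm2"]),
            a2_cm2=float(row["a2_cm2"]),
            level=SaxLevel(row.get("sax_level", "chordae")),
        ),
        disc_stack=stack,
        long_axis=LongAxisSplit(a_cm=float(row["a_cm"]), d_cm=float(row["d_cm"])),
    )
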