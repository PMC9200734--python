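"""Shared domain types and record validation.

Unit conventions used throughout the package: lengths in cm, areas in
cm**2, volumes in ml (== cm**3), masses in g.  Input files may declare
``"units": "mm"`` and are converted on read (lengths / 10, areas / 100).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence


class SaxLevel(str, Enum):
    """Short-axis measurement level along the LV long axis."""

    MITRAL = "mitral"
    CHORDAE = "chordae"
    MID_PAPILLARY = "mid_papillary"


class Sex(str, Enum):
    M = "M"
    F = "F"


class Method(str, Enum):
    """Identifiers for the implemented mass/volume methods."""

    NOVEL = "NOVEL"
    BP = "BP"
    TE = "TE"
    AL = "AL"
    DEV = "DEV"
    TEICHHOLZ_EDV = "TEICHHOLZ_EDV"
    BIPLANE_EDV = "BIPLANE_EDV"


class Violation:
    """A single validation failure: which field, and why."""

    __slots__ = ("field", "message")

    def __init__(self, field: str, message: str) -> None:
        self.field = field
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Violation({self.field!r}, {self.message!r})"

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Violation)
            and other.field == self.field
            and other.message == self.message
        )


class RecordValidationError(ValueError):
    """Raised when a measurement record violates a type invariant.

    Carries the full structured list of violations so callers can report
    every problem at once.
    """

    def __init__(self, violations: Sequence[Violation]):
        self.violations = list(violations)
        detail = "; ".join(f"{v.field}: {v.message}" for v in self.violations)
        super().__init__(f"invalid measurement record: {detail}")


def _require(cond: bool, field_name: str, message: str, out: list[Violation]) -> None:
    if not cond:
        out.append(Violation(field_name, message))


@dataclass(frozen=True)
class LinearMeasurements:
    """End-diastolic 1D parasternal long-axis measurements (cm).

    ``ivs_cm``: septal wall thickness, ``lvid_cm``: internal diameter,
    ``pwt_cm``: posterior wall thickness.
    """

    ivs_cm: float
    lvid_cm: float
    pwt_cm: float

    def __post_init__(self) -> None:
        v: list[Violation] = []
        _require(self.ivs_cm >= 0, "ivs_cm", "must be >= 0", v)
        _require(self.lvid_cm >= 0, "lvid_cm", "must be >= 0", v)
        _require(self.pwt_cm >= 0, "pwt_cm", "must be >= 0", v)
        if v:
            raise RecordValidationError(v)


@dataclass(frozen=True)
class SaxTrace:
    """Traced epicardial (``a1_cm2``) and endocardial (``a2_cm2``) short-axis
    areas at a named LV level (chordae by default)."""

    a1_cm2: float
    a2_cm2: float
    level: SaxLevel = SaxLevel.CHORDAE

    def __post_init__(self) -> None:
        v: list[Violation] = []
        _require(self.a2_cm2 >= 0, "a2_cm2", "must be >= 0", v)
        _require(self.a1_cm2 >= 0, "a1_cm2", "must be >= 0", v)
        if self.a1_cm2 >= 0 and self.a2_cm2 >= 0:
            _require(
                self.a1_cm2 >= self.a2_cm2,
                "a1_cm2",
                "epicardial area smaller than endocardial (a1_cm2 < a2_cm2)",
                v,
            )
        if v:
            raise RecordValidationError(v)


def _orientation(p: tuple[float, float], q: tuple[float, float], r: tuple[float, float]) -> int:
    val = (q[0] - p[0]) * (r[1] - p[1]) - (q[1] - p[1]) * (r[0] - p[0])
    if abs(val) < 1e-12:
        return 0
    return 1 if val > 0 else -1


def _segments_cross(a, b, c, d) -> bool:
    # proper intersection only; shared endpoints of adjacent edges don't count
    o1, o2 = _orientation(a, b, c), _orientation(a, b, d)
    o3, o4 = _orientation(c, d, a), _orientation(c, d, b)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


@dataclass(frozen=True)
class PlanarContour:
    """An ordered endocardial (or epicardial) border in one apical view.

    ``points`` are (x_cm, y_cm) vertices; ``base_left``/``base_right`` are
    the mitral-annulus endpoints and ``apex`` the apical point.  The long
    axis runs from the base midpoint to the apex.
    """

    points: tuple[tuple[float, float], ...]
    base_left: tuple[float, float]
    base_right: tuple[float, float]
    apex: tuple[float, float]

    def __post_init__(self) -> None:
        v: list[Violation] = []
        pts = tuple((float(x), float(y)) for x, y in self.points)
        object.__setattr__(self, "points", pts)
        _require(len(pts) >= 3, "points", "need at least 3 vertices", v)
        if len(pts) >= 3 and self._self_intersects(pts):
            v.append(Violation("points", "contour is self-intersecting"))
        bl, br, ap = self.base_left, self.base_right, self.apex
        if _orientation(bl, br, ap) == 0:
            v.append(Violation("apex", "apex lies on the base segment"))
        if v:
            raise RecordValidationError(v)

    @staticmethod
    def _self_intersects(pts: tuple[tuple[float, float], ...]) -> bool:
        n = len(pts)
        edges = [(pts[i], pts[(i + 1) % n]) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if j == i + 1 or (i == 0 and j == n - 1):
                    continue  # adjacent edges share a vertex
                if _segments_cross(*edges[i], *edges[j]):
                    return True
        return False

    @property
    def base_mid(self) -> tuple[float, float]:
        return (
            0.5 * (self.base_left[0] + self.base_right[0]),
            0.5 * (self.base_left[1] + self.base_right[1]),
        )


@dataclass(frozen=True)
class DiscStack:
    """Per-disc semi-axis pairs ordered base -> apex.

    ``semi_axes[i] = (a_i_cm, b_i_cm)`` gives the elliptical disc semi-axes
    from the 4CH and 2CH delineations.  The disc height is the effective
    long-axis length (max of the two views) divided by ``n_discs``.
    """

    semi_axes: tuple[tuple[float, float], ...]
    length_4ch_cm: float
    length_2ch_cm: float

    def __post_init__(self) -> None:
        v: list[Violation] = []
        sa = tuple((float(a), float(b)) for a, b in self.semi_axes)
        object.__setattr__(self, "semi_axes", sa)
        _require(len(sa) >= 1, "semi_axes", "need at least one disc", v)
        if any(a < 0 or b < 0 for a, b in sa):
            v.append(Violation("semi_axes", "all semi-axes must be >= 0"))
        _require(self.length_4ch_cm > 0, "length_4ch_cm", "must be > 0", v)
        _require(self.length_2ch_cm > 0, "length_2ch_cm", "must be > 0", v)
        if v:
            raise RecordValidationError(v)

    @property
    def n_discs(self) -> int:
        return len(self.semi_axes)

    @property
    def effective_length_cm(self) -> float:
        return max(self.length_4ch_cm, self.length_2ch_cm)

    @property
    def disc_height_cm(self) -> float:
        return self.effective_length_cm / self.n_discs


@dataclass(frozen=True)
class Subject:
    id: str
    age_years: float
    sex: Sex
    bsa_m2: float

    def __post_init__(self) -> None:
        v: list[Violation] = []
        _require(self.bsa_m2 > 0, "bsa_m2", "must be > 0", v)
        if v:
            raise RecordValidationError(v)
        if self.age_years < 18:
            warnings.warn(
                f"subject {self.id!r}: age {self.age_years} < 18 is outside the "
                "adult population the thresholds were derived for",
                stacklevel=2,
            )


@dataclass(frozen=True)
class MethodResult:
    """Output of one quantification method on one record."""

    method: Method
    lvm_g: float | None = None
    edv_ml: float | None = None
    indexed_g_per_m2: float | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        v: list[Violation] = []
        if self.lvm_g is not None:
            _require(self.lvm_g >= 0, "lvm_g", "must be >= 0", v)
        if self.edv_ml is not None:
            _require(self.edv_ml >= 0, "edv_ml", "must be >= 0", v)
        if v:
            raise RecordValidationError(v)

    def to_dict(self) -> dict:
        d: dict = {"method": self.method.value}
        if self.lvm_g is not None:
            d["lvm_g"] = self.lvm_g
        if self.edv_ml is not None:
            d["edv_ml"] = self.edv_ml
        if self.indexed_g_per_m2 is not None:
            d["indexed_g_per_m2"] = self.indexed_g_per_m2
        if self.provenance:
            d["provenance"] = self.provenance
        return d


@dataclass(frozen=True)
class Record:
    """A validated per-subject measurement record (any subset of inputs)."""

    subject: Subject | None = None
    linear: LinearMeasurements | None = None
    sax: SaxTrace | None = None
    long_axis: "LongAxisSplitLike | None" = None
    disc_stack: DiscStack | None = None
    disc_stack_epi: DiscStack | None = None
    contour_4ch: PlanarContour | None = None
    contour_2ch: PlanarContour | None = None


# sax_methods defines the real LongAxisSplit; keep the reference loose here
# to avoid a circular import.
LongAxisSplitLike = object


# ---------------------------------------------------------------------------
# record (de)serialization


_LENGTH_SCALE = {"cm": 1.0, "mm": 0.1}


def _scale_lengths(obj, s: float):
    if isinstance(obj, dict):
        return {k: _scale_lengths(v, s) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_scale_lengths(v, s) for v in obj]
    if isinstance(obj, (int, float)) and not isinstance(obj, bool):
        return obj * s
    return obj


def validate_record(raw: dict) -> Record:
    """Validate a parsed measurement record and normalize units to cm/cm2.

    Returns a typed :class:`Record`; raises :class:`RecordValidationError`
    carrying the full list of violations otherwise.
    """
    from .sax_methods import LongAxisSplit  # deferred: avoids import cycle

    units = raw.get("units", "cm")
    if units not in _LENGTH_SCALE:
        raise RecordValidationError([Violation("units", f"unknown unit {units!r}")])
    s = _LENGTH_SCALE[units]

    violations: list[Violation] = []
    parts: dict = {}

    def build(key, ctor, fields, scales):
        if key not in raw or raw[key] is None:
            return None
        block = raw[key]
        kwargs = {}
        for f_name, scale in zip(fields, scales):
            if f_name in block:
                val = block[f_name]
                kwargs[f_name] = _scale_lengths(val, scale) if scale != 1.0 else val
        try:
            return ctor(**kwargs)
        except RecordValidationError as e:
            violations.extend(Violation(f"{key}.{v.field}", v.message) for v in e.violations)
        except TypeError as e:
            violations.append(Violation(key, str(e)))
        return None

    parts["linear"] = build(
        "linear", LinearMeasurements, ("ivs_cm", "lvid_cm", "pwt_cm"), (s, s, s)
    )
    parts["sax"] = build("sax", _sax_from_dict, ("a1_cm2", "a2_cm2", "level"), (s * s, s * s, 1.0))
    parts["long_axis"] = build("long_axis", LongAxisSplit, ("a_cm", "d_cm"), (s, s))
    for key in ("disc_stack", "disc_stack_epi"):
        parts[key] = build(
            key,
            _stack_from_dict,
            ("semi_axes", "length_4ch_cm", "length_2ch_cm"),
            (s, s, s),
        )
    parts["subject"] = build("subject", _subject_from_dict, ("id", "age_years", "sex", "bsa_m2"), (1.0,) * 4)
    for key, attr in (("contour_4ch", "contour_4ch"), ("contour_2ch", "contour_2ch")):
        parts[attr] = build(
            key, _contour_from_dict, ("points", "base_left", "base_right", "apex"), (s,) * 4
        )

    if violations:
        raise RecordValidationError(violations)
    return Record(**parts)


def _sax_from_dict(a1_cm2, a2_cm2, level="chordae"):
    return SaxTrace(a1_cm2=a1_cm2, a2_cm2=a2_cm2, level=SaxLevel(level))


def _subject_from_dict(id, age_years, sex, bsa_m2):
    return Subject(id=str(id), age_years=age_years, sex=Sex(sex), bsa_m2=bsa_m2)


def _stack_from_dict(semi_axes, length_4ch_cm, length_2ch_cm):
    return DiscStack(
        semi_axes=tuple((a, b) for a, b in semi_axes),
        length_4ch_cm=length_4ch_cm,
        length_2ch_cm=length_2ch_cm,
    )


def _contour_from_dict(points, base_left, base_right, apex):
    return PlanarContour(
        points=tuple((x, y) for x, y in points),
        base_left=tuple(base_left),
        base_right=tuple(base_right),
        apex=tuple(apex),
    )


def record_to_dict(rec: Record) -> dict:
    """Canonical plain-dict form (always cm units) of a validated record."""
    out: dict = {"units": "cm"}
    if rec.subject is not None:
        out["subject"] = {
            "id": rec.subject.id,
            "age_years": rec.subject.age_years,
            "sex": rec.subject.sex.value,
            "bsa_m2": rec.subject.bsa_m2,
        }
    if rec.linear is not None:
        out["linear"] = {
            "ivs_cm": rec.linear.ivs_cm,
            "lvid_cm": rec.linear.lvid_cm,
            "pwt_cm": rec.linear.pwt_cm,
        }
    if rec.sax is not None:
        out["sax"] = {
            "a1_cm2": rec.sax.a1_cm2,
            "a2_cm2": rec.sax.a2_cm2,
            "level": rec.sax.level.value,
        }
    if rec.long_axis is not None:
        out["long_axis"] = {"a_cm": rec.long_axis.a_cm, "d_cm": rec.long_axis.d_cm}
    for key, stack in (("disc_stack", rec.disc_stack), ("disc_stack_epi", rec.disc_stack_epi)):
        if stack is not None:
            out[key] = {
                "semi_axes": [[a, b] for a, b in stack.semi_axes],
                "length_4ch_cm": stack.length_4ch_cm,
                "length_2ch_cm": stack.length_2ch_cm,
            }
    for key, attr in (("contour_4ch", rec.contour_4ch), ("contour_2ch", rec.contour_2ch)):
        if attr is not None:
            out[key] = {
                "points": [[x, y] for x, y in attr.points],
                "base_left": list(attr.base_left),
                "base_right": list(attr.base_right),
                "apex": list(attr.apex),
            }
    return out


def record_to_json(rec: Record) -> str:
    """Deterministic JSON serialization (sorted keys, fixed separators)."""
    return json.dumps(record_to_dict(rec), sort_keys=True, separators=(",", ":"))


def record_from_json(text: str) -> Record:
    return validate_record(json.loads(text))
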