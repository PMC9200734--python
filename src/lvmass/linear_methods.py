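"""One-dimensional ("linear") methods: Teichholz EDV and the cube-formula
LVM with the Devereux correction.

Both operate on :class:`~lvmass.core_types.LinearMeasurements` (cm) and
return ml / g.
"""

from __future__ import annotations

from .core_types import LinearMeasurements, Method, MethodResult

#: Devereux-corrected cube formula constants: regression slope, myocardial
#: density (g/ml) and additive offset (g).
DEVEREUX_SLOPE = 0.8
MYOCARDIAL_DENSITY_G_PER_ML = 1.04
DEVEREUX_OFFSET_G = 0.6


def teichholz_edv(m: LinearMeasurements) -> float:
    """End-diastolic volume (ml) from the internal diameter alone.

    EDV = 7.0 / (2.4 + LVID) * LVID**3, with LVID in cm.
    """
    if m.lvid_cm <= 0:
        raise ValueError("teichholz_edv requires lvid_cm > 0")
    return 7.0 / (2.4 + m.lvid_cm) * m.lvid_cm**3


def devereux_lvm(m: LinearMeasurements) -> float:
    """Cube-formula LV mass (g) with the Devereux correction.

    LVM = 0.8 * 1.04 * [(IVS + LVID + PWT)**3 - LVID**3] + 0.6 g
    """
    if m.lvid_cm <= 0:
        raise ValueError("devereux_lvm requires lvid_cm > 0")
    outer = (m.ivs_cm + m.lvid_cm + m.pwt_cm) ** 3
    inner = m.lvid_cm**3
    return DEVEREUX_SLOPE * MYOCARDIAL_DENSITY_G_PER_ML * (outer - inner) + DEVEREUX_OFFSET_G


def devereux_result(m: LinearMeasurements) -> MethodResult:
    return MethodResult(method=Method.DEV, lvm_g=devereux_lvm(m))


def teichholz_result(m: LinearMeasurements) -> MethodResult:
    return MethodResult(method=Method.TEICHHOLZ_EDV, edv_ml=teichholz_edv(m))
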