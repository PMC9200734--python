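"""Disc-expansion LV mass method.

Pipeline: (1) mean wall thickness ``t`` from a single SAX trace;
(2) endocardial biplane disc stack, optionally rescaled by a calibration
factor ``k``; (3) each disc expanded by ``t`` on both semi-axes and a half
prolate-ellipsoid apical cap of height ``t`` added, giving the epicardial
volume; (4) mass = density * (EDV_EPI - EDV_ENDO).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from .biplane import biplane_edv
from .core_types import DiscStack, Method, MethodResult, SaxTrace
from .sax_methods import DENSITY_G_PER_ML, mean_wall_thickness


class KMode(str, Enum):
    """How the EDV calibration factor k is applied to the endocardial stack.

    ``volume_scale`` multiplies every semi-axis by sqrt(k) so the stack
    volume scales exactly by k; ``radial_scale`` multiplies semi-axes by k.
    """

    VOLUME_SCALE = "volume_scale"
    RADIAL_SCALE = "radial_scale"


class CapShape(str, Enum):
    HALF_PROLATE_ELLIPSOID = "half_prolate_ellipsoid"
    NONE = "none"


#: k implied by the study's printed mean CMR vs biplane EDVs (197/151).
#: Offered as a preset only; the default is the uncalibrated k = 1.
K_PRESET_CMR_MEANS = 197.0 / 151.0


@dataclass(frozen=True)
class NovelConfig:
    k: float = 1.0
    k_mode: KMode = KMode.VOLUME_SCALE
    cap: CapShape = CapShape.HALF_PROLATE_ELLIPSOID
    density_g_per_ml: float = DENSITY_G_PER_ML

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError("k must be > 0")
        if not self.density_g_per_ml > 0:
            raise ValueError("density must be > 0")


def apply_k(endo: DiscStack, cfg: NovelConfig) -> DiscStack:
    """Rescale the endocardial stack by the calibration factor k."""
    if cfg.k == 1.0:
        return endo
    r = math.sqrt(cfg.k) if cfg.k_mode is KMode.VOLUME_SCALE else cfg.k
    return DiscStack(
        semi_axes=tuple((a * r, b * r) for a, b in endo.semi_axes),
        length_4ch_cm=endo.length_4ch_cm,
        length_2ch_cm=endo.length_2ch_cm,
    )


def expand_discs(endo: DiscStack, t_cm: float) -> DiscStack:
    """Add the wall thickness to both semi-axes of every disc."""
    if t_cm < 0:
        raise ValueError("wall thickness must be >= 0")
    return DiscStack(
        semi_axes=tuple((a + t_cm, b + t_cm) for a, b in endo.semi_axes),
        length_4ch_cm=endo.length_4ch_cm,
        length_2ch_cm=endo.length_2ch_cm,
    )


def apical_cap_volume(expanded: DiscStack, t_cm: float) -> float:
    """Half prolate-ellipsoid cap of height t over the most-apical disc:
    V = (2/3) * pi * a_apex * b_apex * t  (ml)."""
    if t_cm < 0:
        raise ValueError("wall thickness must be >= 0")
    a_apex, b_apex = expanded.semi_axes[-1]
    return (2.0 / 3.0) * math.pi * a_apex * b_apex * t_cm


def novel_lvm(endo: DiscStack, s: SaxTrace, cfg: NovelConfig = NovelConfig()) -> MethodResult:
    """Run the full disc-expansion pipeline and return a MethodResult with
    both EDV_ENDO (ml) and the mass (g)."""
    t = mean_wall_thickness(s)
    stack = apply_k(endo, cfg)
    edv_endo = biplane_edv(stack)
    expanded = expand_discs(stack, t)
    cap = apical_cap_volume(expanded, t) if cfg.cap is CapShape.HALF_PROLATE_ELLIPSOID else 0.0
    edv_epi = biplane_edv(expanded) + cap
    lvm = cfg.density_g_per_ml * (edv_epi - edv_endo)
    return MethodResult(
        method=Method.NOVEL,
        lvm_g=lvm,
        edv_ml=edv_endo,
        provenance={
            "t_cm": t,
            "k": cfg.k,
            "k_mode": cfg.k_mode.value,
            "cap": cfg.cap.value,
            "edv_epi_ml": edv_epi,
            "cap_ml": cap,
            "n_discs": endo.n_discs,
            "density_g_per_ml": cfg.density_g_per_ml,
        },
    )
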