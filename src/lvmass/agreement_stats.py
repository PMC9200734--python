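"""Agreement and reproducibility statistics: Bland-Altman, coefficient of
variation, ICC(2,1), hypertrophy classification against indexed-mass
cutoffs, and 2x2 diagnostic performance."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_types import Method, Sex, Subject

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairedSeries:
    """Equal-length paired measurements in the same units.

    Rows with missing entries are dropped (count logged) by
    :meth:`from_arrays`.
    """

    values_x: tuple[float, ...]
    values_y: tuple[float, ...]
    label_x: str = "x"
    label_y: str = "y"

    def __post_init__(self) -> None:
        if len(self.values_x) != len(self.values_y):
            raise ValueError("paired series must have equal length")
        if len(self.values_x) < 2:
            raise ValueError("need at least 2 pairs")

    @classmethod
    def from_arrays(cls, x, y, label_x: str = "x", label_y: str = "y") -> "PairedSeries":
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape:
            raise ValueError("paired series must have equal length")
        keep = ~(np.isnan(x) | np.isnan(y))
        dropped = int((~keep).sum())
        if dropped:
            log.info("dropped %d pairs with missing entries", dropped)
        return cls(tuple(x[keep]), tuple(y[keep]), label_x, label_y)

    @property
    def n(self) -> int:
        return len(self.values_x)

    def diffs(self) -> np.ndarray:
        return np.asarray(self.values_y) - np.asarray(self.values_x)

    def means(self) -> np.ndarray:
        return 0.5 * (np.asarray(self.values_x) + np.asarray(self.values_y))


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float
    prop_bias_slope: float
    p_value: float
    sd_diff: float
    n: int


#: conventional 95% limits-of-agreement multiplier
LOA_MULTIPLIER = 1.96


def bland_altman(p: PairedSeries) -> BlandAltmanResult:
    """Bias (mean of y - x), 1.96-SD limits of agreement, proportional-bias
    slope (differences regressed on pair means) and paired-t p-value."""
    d = p.diffs()
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    if p.n >= 3 and np.ptp(p.means()) > 0:
        slope = float(stats.linregress(p.means(), d).slope)
    else:
        slope = math.nan
    if sd > 0:
        p_value = float(stats.ttest_rel(p.values_y, p.values_x).pvalue)
    else:
        p_value = math.nan if bias == 0 else 0.0
    return BlandAltmanResult(
        bias=bias,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        prop_bias_slope=slope,
        p_value=p_value,
        sd_diff=sd,
        n=p.n,
    )


class CVConvention(str, Enum):
    #: SD of paired differences over the grand mean
    SD_DIFF = "sd_diff"
    #: within-subject SD (SD of differences / sqrt(2)) over the grand mean
    WITHIN_SUBJECT = "within_subject"


@dataclass(frozen=True)
class CVResult:
    cv_percent: float
    convention: CVConvention


def cv_percent(p: PairedSeries, convention: CVConvention = CVConvention.SD_DIFF) -> CVResult:
    """Coefficient of variation of the paired differences, in percent of the
    grand mean of all measurements."""
    grand = float(np.mean(np.concatenate([p.values_x, p.values_y])))
    if grand <= 0:
        raise ValueError("grand mean must be > 0 for a coefficient of variation")
    sd = float(np.std(p.diffs(), ddof=1))
    if convention is CVConvention.WITHIN_SUBJECT:
        sd = sd / math.sqrt(2.0)
    return CVResult(cv_percent=100.0 * sd / grand, convention=convention)


class ICCForm(str, Enum):
    #: two-way random effects, absolute agreement, single measures
    ICC2_1 = "ICC(2,1)"


@dataclass(frozen=True)
class ICCResult:
    value: float
    form: ICCForm
    defined: bool


def icc(p: PairedSeries, form: ICCForm = ICCForm.ICC2_1) -> ICCResult:
    """Intraclass correlation, default ICC(2,1) (two-way random, absolute
    agreement, single measures), computed with pingouin.

    Zero total variance makes the coefficient undefined; the result is then
    flagged with ``defined=False`` and a NaN value.
    """
    if form is not ICCForm.ICC2_1:  # pragma: no cover - single supported form
        raise ValueError(f"unsupported ICC form {form}")
    if p.n < 3:
        raise ValueError("ICC needs at least 3 pairs")
    total_var = float(np.var(np.concatenate([p.values_x, p.values_y])))
    if total_var == 0:
        return ICCResult(value=math.nan, form=form, defined=False)
    import pingouin as pg  # deferred: heavy import

    frame = pd.DataFrame(
        {
            "target": list(range(p.n)) * 2,
            "rater": [p.label_x] * p.n + [p.label_y] * p.n,
            "rating": list(p.values_x) + list(p.values_y),
        }
    )
    table = pg.intraclass_corr(frame, targets="target", raters="rater", ratings="rating")
    # pingouin labels two-way random / absolute agreement / single measures
    # either "ICC2" (Shrout-Fleiss) or "ICC(A,1)" (McGraw-Wong)
    mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
    value = float(table.loc[mask, "ICC"].iloc[0])
    return ICCResult(value=value, form=form, defined=math.isfinite(value))


# ---------------------------------------------------------------------------
# hypertrophy classification


@dataclass(frozen=True)
class CutoffRow:
    group: str
    sex: Sex
    age_min: float  # inclusive
    age_max: float  # exclusive
    threshold: float  # g/m2 (or ml/m2 for the dilatation table)

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be > 0")


@dataclass(frozen=True)
class CutoffTable:
    rows: tuple[CutoffRow, ...]

    def threshold(self, group: str, sex: Sex, age_years: float) -> float:
        for r in self.rows:
            if r.group == group and r.sex == sex and r.age_min <= age_years < r.age_max:
                return r.threshold
        raise KeyError(
            f"no cutoff for group={group!r}, sex={sex.value}, age={age_years}"
        )

    @classmethod
    def from_records(cls, records: Sequence[dict]) -> "CutoffTable":
        return cls(
            rows=tuple(
                CutoffRow(
                    group=r["group"],
                    sex=Sex(r["sex"]),
                    age_min=float(r.get("age_min", 0.0)),
                    age_max=float(r.get("age_max", math.inf)),
                    threshold=float(r["threshold"]),
                )
                for r in records
            )
        )


#: cutoff group names
GROUP_CMR = "cmr_mass"  # NOVEL, BP (and 3DE) indexed-mass thresholds
GROUP_2D = "echo_2d_mass"  # TE, A-L
GROUP_LINEAR = "echo_linear_mass"  # DEV
GROUP_CMR_DILATATION = "cmr_edv"  # indexed-EDV dilatation thresholds

_INF = math.inf

#: Sex- and age-stratified indexed thresholds (g/m2; ml/m2 for the EDV group).
BUILTIN_CUTOFFS = CutoffTable(
    rows=(
        CutoffRow(GROUP_CMR, Sex.M, 0, 60, 92.0),
        CutoffRow(GROUP_CMR, Sex.M, 60, _INF, 91.0),
        CutoffRow(GROUP_CMR, Sex.F, 0, 60, 78.0),
        CutoffRow(GROUP_CMR, Sex.F, 60, _INF, 79.0),
        CutoffRow(GROUP_2D, Sex.M, 0, _INF, 103.0),
        CutoffRow(GROUP_2D, Sex.F, 0, _INF, 89.0),
        CutoffRow(GROUP_LINEAR, Sex.M, 0, _INF, 116.0),
        CutoffRow(GROUP_LINEAR, Sex.F, 0, _INF, 96.0),
        CutoffRow(GROUP_CMR_DILATATION, Sex.M, 0, 60, 101.0),
        CutoffRow(GROUP_CMR_DILATATION, Sex.M, 60, _INF, 95.0),
        CutoffRow(GROUP_CMR_DILATATION, Sex.F, 0, 60, 96.0),
        CutoffRow(GROUP_CMR_DILATATION, Sex.F, 60, _INF, 87.0),
    )
)

METHOD_CUTOFF_GROUP = {
    Method.NOVEL: GROUP_CMR,
    Method.BP: GROUP_CMR,
    Method.TE: GROUP_2D,
    Method.AL: GROUP_2D,
    Method.DEV: GROUP_LINEAR,
}


def classify_hypertrophy(
    lvm_g: float,
    subj: Subject,
    method: Method,
    cuts: CutoffTable = BUILTIN_CUTOFFS,
) -> bool:
    """True iff lvm_g / BSA meets or exceeds the method group's threshold
    for the subject's sex and age stratum."""
    group = METHOD_CUTOFF_GROUP.get(method)
    if group is None:
        raise KeyError(f"no cutoff group for method {method}")
    try:
        thr = cuts.threshold(group, subj.sex, subj.age_years)
    except KeyError as e:
        raise KeyError(f"cutoff table incomplete: {e}") from e
    return lvm_g / subj.bsa_m2 >= thr


@dataclass(frozen=True)
class DiagnosticPerformance:
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    counts: dict = field(default_factory=dict)


def diagnostic_performance(pred: Sequence[bool], truth: Sequence[bool]) -> DiagnosticPerformance:
    """Standard 2x2 proportions in percent; entries with an empty
    denominator come back as NaN."""
    pred = np.asarray(pred, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth must have equal length")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else math.nan

    return DiagnosticPerformance(
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        counts={"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    )
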