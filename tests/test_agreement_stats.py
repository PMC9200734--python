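import math

import numpy as np
import pytest
from scipy import stats

from lvmass.agreement_stats import (
    BUILTIN_CUTOFFS,
    CutoffTable,
    CVConvention,
    PairedSeries,
    bland_altman,
    classify_hypertrophy,
    cv_percent,
    diagnostic_performance,
    icc,
)
from lvmass.core_types import Method, Sex, Subject


def _subject(sex="M", age=45.0, bsa=2.0):
    return Subject(id="s", age_years=age, sex=Sex(sex), bsa_m2=bsa)


class TestBlandAltman:
    def test_identity(self):
        p = PairedSeries((1.0, 2.0, 3.0), (1.0, 2.0, 3.0))
        r = bland_altman(p)
        assert r.bias == 0.0
        assert (r.loa_low, r.loa_high) == (0.0, 0.0)

    def test_constant_offset(self):
        p = PairedSeries((1.0, 2.0, 3.0), (6.0, 7.0, 8.0))
        r = bland_altman(p)
        assert r.bias == pytest.approx(5.0)
        assert r.loa_low == pytest.approx(5.0)
        assert r.loa_high == pytest.approx(5.0)
        assert r.prop_bias_slope == pytest.approx(0.0, abs=1e-12)

    def test_three_pair_fixture(self):
        p = PairedSeries((100.0, 150.0, 200.0), (110.0, 150.0, 210.0))
        r = bland_altman(p)
        sd = np.std([10.0, 0.0, 10.0], ddof=1)
        assert r.bias == pytest.approx(20.0 / 3.0)
        assert r.loa_low == pytest.approx(20.0 / 3.0 - 1.96 * sd)
        assert r.loa_high == pytest.approx(20.0 / 3.0 + 1.96 * sd)

    def test_bias_and_p_match_t_distribution_oracle(self):
        rng = np.random.default_rng(3)
        x = rng.normal(150.0, 30.0, size=25)
        y = x + rng.normal(5.0, 10.0, size=25)
        r = bland_altman(PairedSeries(tuple(x), tuple(y)))
        d = y - x
        bias = d.mean()
        t_stat = bias / (d.std(ddof=1) / math.sqrt(len(d)))
        p_oracle = 2.0 * stats.t.sf(abs(t_stat), len(d) - 1)
        assert r.bias == pytest.approx(bias, abs=1e-10)
        assert r.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            PairedSeries((1.0,), (2.0,))

    def test_missing_pairs_dropped(self):
        p = PairedSeries.from_arrays([1.0, 2.0, np.nan, 4.0], [1.5, np.nan, 3.0, 4.5])
        assert p.n == 2


class TestCV:
    def test_identical_pairs(self):
        p = PairedSeries((100.0, 150.0), (100.0, 150.0))
        assert cv_percent(p).cv_percent == 0.0

    def test_three_pair_fixture(self):
        # diffs (10, 0, 10), sd = 5.7735, grand mean = 153.33 -> 3.77%
        p = PairedSeries((100.0, 150.0, 200.0), (110.0, 150.0, 210.0))
        r = cv_percent(p, CVConvention.SD_DIFF)
        assert r.cv_percent == pytest.approx(3.77, abs=0.01)
        assert r.convention is CVConvention.SD_DIFF

    def test_within_subject_convention(self):
        p = PairedSeries((100.0, 150.0, 200.0), (110.0, 150.0, 210.0))
        r = cv_percent(p, CVConvention.WITHIN_SUBJECT)
        assert r.cv_percent == pytest.approx(3.77 / math.sqrt(2), abs=0.01)

    def test_scale_invariance(self):
        p = PairedSeries((100.0, 150.0, 200.0), (110.0, 150.0, 210.0))
        p2 = PairedSeries((200.0, 300.0, 400.0), (220.0, 300.0, 420.0))
        assert cv_percent(p2).cv_percent == pytest.approx(cv_percent(p).cv_percent, rel=1e-12)

    def test_nonpositive_grand_mean(self):
        with pytest.raises(ValueError):
            cv_percent(PairedSeries((-1.0, 1.0), (-1.0, 1.0)))


def _icc21_oracle(x, y):
    """Textbook two-way random, absolute agreement, single measures ICC via
    the ANOVA decomposition (k = 2 raters)."""
    x, y = np.asarray(x), np.asarray(y)
    n, k = len(x), 2
    data = np.stack([x, y], axis=1)
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_pairs_with_spread(self):
        x = (100.0, 120.0, 140.0, 160.0, 180.0)
        r = icc(PairedSeries(x, x))
        assert r.value == pytest.approx(1.0, abs=1e-9)

    def test_antithetic_is_nonpositive(self):
        x = (-2.0, -1.0, 0.0, 1.0, 2.0)
        y = tuple(-v for v in x)
        assert icc(PairedSeries(x, y)).value <= 0.0

    def test_six_pair_fixture_matches_anova_oracle(self):
        x = (100.0, 150.0, 200.0, 120.0, 170.0, 90.0)
        y = (110.0, 145.0, 215.0, 118.0, 180.0, 95.0)
        r = icc(PairedSeries(x, y))
        assert r.defined
        assert r.value == pytest.approx(_icc21_oracle(x, y), abs=1e-10)

    def test_random_fixtures_match_anova_oracle(self):
        rng = np.random.default_rng(8)
        for n in (3, 5, 10):
            x = rng.normal(150, 40, size=n)
            y = x + rng.normal(0, 15, size=n)
            r = icc(PairedSeries(tuple(x), tuple(y)))
            assert r.value == pytest.approx(_icc21_oracle(x, y), abs=1e-10)

    def test_zero_variance_flagged_undefined(self):
        r = icc(PairedSeries((5.0, 5.0, 5.0), (5.0, 5.0, 5.0)))
        assert not r.defined
        assert math.isnan(r.value)


class TestClassifyHypertrophy:
    def test_novel_man_45_at_100(self):
        assert classify_hypertrophy(200.0, _subject("M", 45), Method.NOVEL)

    def test_novel_woman_50_at_75(self):
        assert not classify_hypertrophy(150.0, _subject("F", 50), Method.NOVEL)

    def test_dev_man_45_at_115(self):
        assert not classify_hypertrophy(230.0, _subject("M", 45), Method.DEV)

    @pytest.mark.parametrize(
        "method,sex,age,threshold",
        [
            (Method.NOVEL, "M", 45, 92.0),
            (Method.NOVEL, "M", 70, 91.0),
            (Method.NOVEL, "F", 45, 78.0),
            (Method.NOVEL, "F", 70, 79.0),
            (Method.BP, "M", 45, 92.0),
            (Method.TE, "M", 45, 103.0),
            (Method.TE, "F", 45, 89.0),
            (Method.AL, "M", 70, 103.0),
            (Method.AL, "F", 70, 89.0),
            (Method.DEV, "M", 45, 116.0),
            (Method.DEV, "F", 45, 96.0),
        ],
    )
    def test_every_threshold_boundary(self, method, sex, age, threshold):
        subj = _subject(sex, age, bsa=1.0)
        assert classify_hypertrophy(threshold + 0.1, subj, method)
        assert classify_hypertrophy(threshold, subj, method)  # >= is inclusive
        assert not classify_hypertrophy(threshold - 0.1, subj, method)

    def test_monotone_in_mass_antitone_in_bsa(self):
        subj_small = _subject("M", 45, bsa=1.8)
        subj_large = _subject("M", 45, bsa=2.4)
        lvm_lo, lvm_hi = 160.0, 230.0
        assert not classify_hypertrophy(lvm_lo, subj_small, Method.NOVEL)
        assert classify_hypertrophy(lvm_hi, subj_small, Method.NOVEL)
        # same mass, larger BSA -> never flips from negative to positive
        assert not classify_hypertrophy(lvm_lo, subj_large, Method.NOVEL)

    def test_missing_stratum_raises(self):
        empty = CutoffTable(rows=())
        with pytest.raises(KeyError):
            classify_hypertrophy(200.0, _subject(), Method.NOVEL, empty)

    def test_builtin_table_complete(self):
        for sex in (Sex.M, Sex.F):
            for age in (45.0, 70.0):
                for method in (Method.NOVEL, Method.BP, Method.TE, Method.AL, Method.DEV):
                    classify_hypertrophy(100.0, _subject(sex.value, age), method, BUILTIN_CUTOFFS)


class TestDiagnosticPerformance:
    def test_perfect(self):
        truth = [True, False, True, False]
        r = diagnostic_performance(truth, truth)
        assert (r.sensitivity, r.specificity, r.ppv, r.npv) == (100.0, 100.0, 100.0, 100.0)

    def test_counts_fixture(self):
        # TP=2, FP=1, FN=1, TN=6
        pred = [True, True, True, False, False, False, False, False, False, False]
        truth = [True, True, False, True, False, False, False, False, False, False]
        r = diagnostic_performance(pred, truth)
        assert r.sensitivity == pytest.approx(66.7, abs=0.05)
        assert r.specificity == pytest.approx(85.7, abs=0.05)
        assert r.ppv == pytest.approx(66.7, abs=0.05)
        assert r.npv == pytest.approx(85.7, abs=0.05)

    def test_all_positive_predictor(self):
        pred = [True] * 6
        truth = [True, True, True, False, False, False]
        r = diagnostic_performance(pred, truth)
        assert r.sensitivity == 100.0
        assert r.specificity == 0.0
        assert math.isnan(r.npv)

    def test_empty_truth_class_flagged(self):
        r = diagnostic_performance([True, False], [False, False])
        assert math.isnan(r.sensitivity)
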