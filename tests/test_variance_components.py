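import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from relex import (
    DegenerateDataError,
    TestRetestData,
    TestRetestSummary,
    UnbalancedDesignError,
    VarianceComponents,
    classify_reliability,
    icc_a1,
    icc_from_sem,
    sdd_group,
    sdd_individual,
    sem_from_icc,
    sigma_e_from_sd_of_differences,
    within_subject_error,
    wscv,
)

from _oracles import loopwise_icc_a1, loopwise_sigma_e


def _data_from_matrix(y):
    records = [(i + 1, j + 1, y[i][j])
               for i in range(len(y)) for j in range(len(y[0]))]
    return TestRetestData.from_records(records)


balanced_matrices = st.integers(2, 10).flatmap(
    lambda n: st.integers(2, 4).flatmap(
        lambda k: st.lists(
            st.lists(st.floats(-50, 50), min_size=k, max_size=k),
            min_size=n, max_size=n)))


class TestIccA1:
    def test_perfect_agreement_gives_one(self):
        y = [[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]]
        icc, anova = icc_a1(_data_from_matrix(y))
        assert icc == 1.0
        assert anova.ms_error == 0.0
        assert anova.ms_cols == 0.0

    def test_no_between_subject_variance_gives_nonpositive(self):
        y = [[0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0]]
        icc, _ = icc_a1(_data_from_matrix(y))
        assert icc <= 0.0

    @given(balanced_matrices)
    def test_matches_loopwise_anova_oracle(self, y):
        data = _data_from_matrix(y)
        try:
            icc, _ = icc_a1(data)
        except DegenerateDataError:
            assert np.ptp(np.asarray(y)) == 0
            return
        assert icc == pytest.approx(loopwise_icc_a1(y), abs=1e-10)
        assert icc <= 1.0 + 1e-12

    def test_matches_pingouin_icc2(self, paired_records):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        data = TestRetestData.from_records(paired_records)
        icc, _ = icc_a1(data)
        table = pingouin.intraclass_corr(
            data=data.frame, targets="subject", raters="occasion",
            ratings="value")
        reference = float(table.set_index("Type").loc["ICC(A,1)", "ICC"])
        assert icc == pytest.approx(reference, abs=1e-10)

    def test_shift_invariance_and_scaling(self, paired_records):
        data = TestRetestData.from_records(paired_records)
        icc, _ = icc_a1(data)
        sigma = within_subject_error(data)
        shifted = TestRetestData.from_records(
            [(s, o, v + 1234.5) for s, o, v in paired_records])
        scaled = TestRetestData.from_records(
            [(s, o, 3.0 * v) for s, o, v in paired_records])
        assert icc_a1(shifted)[0] == pytest.approx(icc, abs=1e-9)
        assert icc_a1(scaled)[0] == pytest.approx(icc, abs=1e-9)
        assert within_subject_error(scaled) == pytest.approx(3.0 * sigma,
                                                             rel=1e-12)

    def test_unbalanced_design_names_offender(self):
        records = [(1, 1, 0.5), (1, 2, 0.7), (2, 1, 1.0)]
        data = TestRetestData.from_records(records)
        with pytest.raises(UnbalancedDesignError, match="2"):
            icc_a1(data)

    def test_complete_cases_drops_offenders(self):
        records = [(1, 1, 0.5), (1, 2, 0.7), (2, 1, 1.0),
                   (3, 1, 2.0), (3, 2, 2.2)]
        data = TestRetestData.from_records(records).complete_cases()
        assert data.n_subjects == 2
        icc_a1(data)  # no longer raises

    def test_duplicate_occasions_rejected(self):
        with pytest.raises(UnbalancedDesignError, match="duplicate"):
            TestRetestData.from_records([(1, 1, 0.5), (1, 1, 0.7)])

    def test_constant_data_is_degenerate(self):
        y = [[3.0, 3.0], [3.0, 3.0]]
        with pytest.raises(DegenerateDataError, match="degenerate"):
            icc_a1(_data_from_matrix(y))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            TestRetestData.from_records([(1, 1, float("nan")), (1, 2, 1.0)])


class TestWithinSubjectError:
    def test_zero_for_perfect_retest(self):
        y = [[1.0, 1.0], [2.0, 2.0]]
        assert within_subject_error(_data_from_matrix(y)) == 0.0

    def test_hand_computed_example(self):
        # subjects (0,2) and (10,12): each deviates +-1 from its mean,
        # so MS_W = 4/2 and sigma_e = sqrt(2)
        y = [[0.0, 2.0], [10.0, 12.0]]
        assert within_subject_error(_data_from_matrix(y)) == pytest.approx(
            math.sqrt(2.0), abs=1e-12)

    @given(balanced_matrices)
    def test_matches_loopwise_oracle(self, y):
        if np.ptp(np.asarray(y)) == 0:
            return
        data = _data_from_matrix(y)
        assert within_subject_error(data) == pytest.approx(
            loopwise_sigma_e(y), abs=1e-12)


class TestSemIccConversions:
    @pytest.mark.parametrize("sd,icc,expected", [
        (1.0, 1.0, 0.0),
        (1.0, 0.5, 0.7071067811865476),
        (2.0, 0.75, 1.0),
    ])
    def test_sem_from_icc_closed_form(self, sd, icc, expected):
        assert sem_from_icc(sd, icc) == pytest.approx(expected, abs=1e-12)

    def test_negative_icc_truncated_with_warning(self):
        with pytest.warns(UserWarning, match="truncated"):
            assert sem_from_icc(1.0, -0.3) == 1.0

    @pytest.mark.parametrize("sd,sem,expected", [
        (1.0, 0.0, 1.0),
        (1.0, 1.0, 0.0),
        (2.0, 1.0, 0.75),
    ])
    def test_icc_from_sem_closed_form(self, sd, sem, expected):
        assert icc_from_sem(sd, sem) == pytest.approx(expected, abs=1e-12)

    def test_icc_from_sem_requires_positive_sd(self):
        with pytest.raises(ValueError):
            icc_from_sem(0.0, 1.0)

    @pytest.mark.parametrize("icc", [0.0, 0.3, 0.9])
    @pytest.mark.parametrize("sd", [0.5, 1.0, 7.3])
    def test_round_trip_identity(self, sd, icc):
        assert icc_from_sem(sd, sem_from_icc(sd, icc)) == pytest.approx(
            icc, abs=1e-12)


class TestWscvAndSdd:
    def test_wscv_values_and_round_trip(self):
        assert wscv(0.0, 5.0) == 0.0
        assert wscv(0.1, 2.0) == pytest.approx(0.05)
        assert wscv(0.1, -2.0) == pytest.approx(0.05)
        cv = wscv(0.37, 1.6)
        assert cv * abs(1.6) == pytest.approx(0.37, abs=1e-15)
        with pytest.raises(ValueError):
            wscv(0.1, 0.0)

    def test_sdd_individual_values(self):
        assert sdd_individual(0.0) == 0.0
        assert sdd_individual(1.0, conf=0.95) == pytest.approx(2.7718, abs=2e-4)

    def test_sdd_from_sd_of_differences(self):
        # SD of test-retest differences 7.3 (percent units)
        sigma_e = sigma_e_from_sd_of_differences(7.3)
        assert sdd_individual(sigma_e) == pytest.approx(14.31, abs=0.005)
        assert sdd_group(sigma_e, 2) == pytest.approx(10.12, abs=0.005)

    def test_sdd_group_properties(self):
        assert sdd_group(1.3, 1) == sdd_individual(1.3)
        values = [sdd_group(1.3, n) for n in range(1, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_invalid_confidence(self):
        with pytest.raises(ValueError):
            sdd_individual(1.0, conf=1.0)


class TestClassification:
    @pytest.mark.parametrize("icc,scheme,label", [
        (0.8, "koo_li", "good"),
        (0.3, "koo_li", "poor"),
        (0.6, "koo_li", "poor to moderate"),
        (0.95, "koo_li", "excellent (clinical)"),
        (0.95, "nunnally", "adequate (applied settings)"),
        (0.92, "nunnally", "minimum (applied settings)"),
        (0.85, "nunnally", "adequate (basic research)"),
        (0.72, "nunnally", "lowest acceptable (basic research)"),
        (0.5, "nunnally", "insufficient"),
        (0.39, "cicchetti", "poor"),
        (0.4, "cicchetti", "fair"),
        (0.65, "cicchetti", "good"),
        (0.8, "cicchetti", "excellent"),
        (0.39, "fleiss", "poor"),
        (0.75, "fleiss", "good"),
        (0.76, "fleiss", "excellent"),
    ])
    def test_band_labels(self, icc, scheme, label):
        assert classify_reliability(icc, scheme) == label

    def test_unknown_scheme_lists_valid_ones(self):
        with pytest.raises(ValueError, match="koo_li"):
            classify_reliability(0.8, "made_up")


class TestTypes:
    def test_variance_components_identities(self):
        vc = VarianceComponents(var_true=4.0, var_error=1.0)
        assert vc.var_total == 5.0
        assert vc.reliability == pytest.approx(0.8)
        back = VarianceComponents.from_reliability(0.8, 5.0)
        assert back.var_true == pytest.approx(4.0)
        with pytest.raises(ValueError):
            VarianceComponents(var_true=-1.0, var_error=1.0)

    def test_summary_derives_missing_piece(self):
        s = TestRetestSummary(mean=1.6, sd=2.0, icc=0.75)
        assert s.sem_effective == pytest.approx(1.0)
        s2 = TestRetestSummary(mean=1.6, sd=2.0, sem=1.0)
        assert s2.icc == pytest.approx(0.75)

    def test_explicit_sem_wins_and_is_reported(self):
        s = TestRetestSummary(mean=0.0, sd=2.0, icc=0.75, sem=1.5)
        assert s.sem_effective == 1.5
        assert "explicit sem" in s.consistency_note()
        consistent = TestRetestSummary(mean=0.0, sd=2.0, icc=0.75, sem=1.0)
        assert consistent.consistency_note() is None

    def test_negative_icc_is_flagged_not_rejected(self):
        s = TestRetestSummary(mean=-12.0, sd=10.0, sem=10.32)
        assert s.icc < 0
        assert any("negative" in f for f in s.flags)
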