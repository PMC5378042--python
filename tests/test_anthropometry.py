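"""Age arithmetic, the LMS transform, and weight-status classification."""

import datetime as dt
import math

import pytest
from hypothesis import given, strategies as st

from pedcds import anthropometry as anth
from pedcds import reference_data as rd
from pedcds.errors import ConfigurationError, CoverageError, DomainError


class TestComputeAge:
    def test_exact_anniversary(self):
        assert anth.compute_age(dt.date(2005, 3, 7), dt.date(2015, 3, 7)) == (10, 120.0)

    def test_same_day_is_zero(self):
        assert anth.compute_age(dt.date(2005, 3, 7), dt.date(2005, 3, 7)) == (0, 0.0)

    def test_month_end_rolls_at_short_months(self):
        # born Jan 31: the February anniversary clamps to Feb 28, so on Mar 1
        # one month is complete plus 1 day of the 31-day Feb 28 -> Mar 31 span
        years, months = anth.compute_age(dt.date(2005, 1, 31), dt.date(2005, 3, 1))
        assert years == 0
        assert months == pytest.approx(1 + 1 / 31, abs=1e-12)

    def test_encounter_before_birth_rejected(self):
        with pytest.raises(DomainError):
            anth.compute_age(dt.date(2010, 1, 1), dt.date(2009, 12, 31))

    @given(st.dates(min_value=dt.date(1990, 1, 1), max_value=dt.date(2020, 1, 1)),
           st.integers(min_value=0, max_value=9000))
    def test_exact_months_monotone_in_encounter_date(self, dob, offset):
        d1 = dob + dt.timedelta(days=offset)
        d2 = d1 + dt.timedelta(days=1)
        assert anth.compute_age(dob, d1)[1] < anth.compute_age(dob, d2)[1]


class TestBmiAndLms:
    def test_bmi_arithmetic(self):
        assert anth.compute_bmi(50, 1.5) == pytest.approx(50 / 2.25, abs=1e-12)
        assert anth.compute_bmi(16, 1.0) == 16.0
        with pytest.raises(DomainError):
            anth.compute_bmi(0, 1.5)

    def test_z_is_zero_at_median(self):
        row = rd.LMSRow("male", 100.5, L=-1.3, M=17.2, S=0.09)
        assert anth.lms_z(row.M, row) == 0.0

    def test_log_branch_identity(self):
        row = rd.LMSRow("male", 100.5, L=0.0, M=16.0, S=0.1)
        assert anth.lms_z(16.0 * math.exp(0.1), row) == pytest.approx(1.0, abs=1e-12)

    def test_power_branch_against_direct_evaluation(self):
        # ((18/16)^-2 - 1) / (-2 * 0.1) evaluated exactly: (64/81 - 1) / -0.2
        row = rd.LMSRow("male", 100.5, L=-2.0, M=16.0, S=0.1)
        expected = (64.0 / 81.0 - 1.0) / (-0.2)
        assert expected == pytest.approx(1.0493827160493827, abs=1e-15)
        assert anth.lms_z(18.0, row) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(10.0, 30.0), st.floats(12.0, 22.0), st.floats(0.02, 0.3))
    def test_branches_continuous_at_l_zero(self, x, M, S):
        near = rd.LMSRow("male", 30.5, L=1e-8, M=M, S=S)
        at = rd.LMSRow("male", 30.5, L=0.0, M=M, S=S)
        assert abs(anth.lms_z(x, near) - anth.lms_z(x, at)) < 1e-6

    @given(st.floats(-3.0, 3.0), st.floats(-2.5, 2.5, exclude_min=True))
    def test_z_value_round_trip(self, L, z):
        row = rd.LMSRow("female", 60.5, L=L if abs(L) > 1e-3 else 0.0, M=16.0, S=0.08)
        x = anth.lms_value_from_z(z, row)
        assert anth.lms_z(x, row) == pytest.approx(z, abs=1e-9)

    def test_percentile_mapping(self):
        assert anth.z_to_percentile(0.0) == 50.0
        assert anth.z_to_percentile(1.6449) == pytest.approx(95.0, abs=1e-3)

    @given(st.floats(-5, 5))
    def test_percentiles_of_opposite_z_sum_to_100(self, z):
        assert anth.z_to_percentile(z) + anth.z_to_percentile(-z) == pytest.approx(100.0)


class TestClassification:
    @pytest.mark.parametrize("percentile,category", [
        (84.999, "normal"), (85.0, "overweight"), (94.999, "overweight"),
        (95.0, "obese"), (99.9, "obese"), (0.001, "normal"),
    ])
    def test_inclusive_upward_boundaries(self, percentile, category):
        assert anth.classify_weight_status(percentile, (85.0, 95.0)) == category

    def test_unordered_thresholds_rejected(self):
        with pytest.raises(ConfigurationError):
            anth.classify_weight_status(50.0, (95.0, 85.0))

    @given(st.floats(0.001, 99.999))
    def test_classification_partitions_the_percentile_axis(self, percentile):
        cats = [anth.classify_weight_status(percentile, (85.0, 95.0))]
        assert cats[0] in ("normal", "overweight", "obese")


class TestBmiAssessmentChain:
    DOB = dt.date(2006, 4, 2)
    ENC = dt.date(2016, 8, 20)

    def test_median_weight_maps_to_50th_percentile(self, library):
        _, months = anth.compute_age(self.DOB, self.ENC)
        row = library.lms_row_for("female", months)
        res = anth.bmi_assessment(self.DOB, self.ENC, "female",
                                  height=1.0, weight=row.M, library=library)
        assert res.percentile == pytest.approx(50.0, abs=1e-9)
        assert res.category == "normal"

    def test_age_outside_coverage_names_bounds(self, library):
        with pytest.raises(CoverageError, match=r"\(24, 252\)"):
            anth.bmi_assessment(dt.date(1990, 1, 1), dt.date(2016, 1, 1), "male",
                                height=1.8, weight=80.0, library=library)

    def test_chain_equals_stepwise_recomputation(self, library):
        res = anth.bmi_assessment(self.DOB, self.ENC, "male",
                                  height=1.38, weight=44.5, library=library)
        _, months = anth.compute_age(self.DOB, self.ENC)
        row = library.lms_row_for("male", months)
        bmi = 44.5 / 1.38**2
        z = anth.lms_z(bmi, row)
        assert res.bmi == pytest.approx(bmi, abs=1e-9)
        assert res.z == pytest.approx(z, abs=1e-9)
        assert res.percentile == pytest.approx(anth.z_to_percentile(z), abs=1e-9)

    @given(st.floats(30.0, 70.0), st.floats(30.0, 70.0))
    def test_percentile_strictly_monotone_in_weight(self, library, w1, w2):
        if w1 == w2:
            return
        lo, hi = sorted((w1, w2))
        r_lo = anth.bmi_assessment(self.DOB, self.ENC, "male", 1.4, lo, library)
        r_hi = anth.bmi_assessment(self.DOB, self.ENC, "male", 1.4, hi, library)
        assert r_lo.percentile < r_hi.percentile
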