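"""Age, BMI, LMS z-scores/percentiles and weight-status classification.

The LMS method expresses an age-varying reference distribution through three
parameters — Box-Cox power L, median M, coefficient of variation S — and maps
a measurement ``x`` to a z-score::

    z = ((x / M)**L - 1) / (L * S)      for L != 0
    z = ln(x / M) / S                   for L == 0

The two branches agree in the limit L -> 0; the implementation uses ``expm1``
so the power branch stays accurate for |L| near zero.  Percentiles are
``100 * Phi(z)`` with Phi the standard normal CDF.

Weight-status cutpoints (overweight at the 85th percentile, obese at the
95th by the pediatric guideline) are *rulebase data*, passed in by the
caller — this module contains no clinical constants.
"""

from __future__ import annotations

import calendar
import datetime as dt
import math
from dataclasses import dataclass

from scipy.special import ndtr, ndtri

from .errors import ConfigurationError, CoverageError, DomainError
from .reference_data import LMSRow, ReferenceLibrary, normalize_sex

__all__ = [
    "compute_age",
    "compute_bmi",
    "lms_z",
    "lms_value_from_z",
    "z_to_percentile",
    "percentile_to_z",
    "classify_weight_status",
    "bmi_assessment",
    "PercentileResult",
    "BMI_CHANGE_CATEGORIES",
]

#: User-entered (never inferred) categorization of the change in BMI.
BMI_CHANGE_CATEGORIES = ("stable", "improvement", "increase", "excessive_increase",
                         "no_improvement", "unknown")


def _anniversary(dob: dt.date, year: int, month: int) -> dt.date:
    """dob's day-of-month in (year, month), clamped to that month's length."""
    day = min(dob.day, calendar.monthrange(year, month)[1])
    return dt.date(year, month, day)


def compute_age(dob: dt.date, encounter_date: dt.date) -> tuple[int, float]:
    """Completed years and exact age in months at the encounter.

    Exact months = completed calendar months plus the fraction of the current
    month elapsed (days since the last monthly anniversary over the length of
    the anniversary-to-anniversary interval).  When the birth day-of-month
    exceeds the length of a month, the anniversary rolls to that month's last
    day, so ages stay monotone through short months.
    """
    if encounter_date < dob:
        raise DomainError(f"encounter date {encounter_date} precedes date of birth {dob}")
    months = (encounter_date.year - dob.year) * 12 + (encounter_date.month - dob.month)
    if encounter_date.day < _anniversary(dob, encounter_date.year, encounter_date.month).day:
        months -= 1
    y, m = divmod(dob.month - 1 + months, 12)
    last = _anniversary(dob, dob.year + y, m + 1)
    y2, m2 = divmod(dob.month - 1 + months + 1, 12)
    nxt = _anniversary(dob, dob.year + y2, m2 + 1)
    fraction = (encounter_date - last).days / (nxt - last).days
    exact_months = months + fraction
    years = (encounter_date.year - dob.year) - (
        (encounter_date.month, encounter_date.day) <
        (dob.month, _anniversary(dob, encounter_date.year, dob.month).day))
    return years, exact_months


def compute_bmi(weight: float, height: float) -> float:
    """Body-mass index in kg/m^2; inputs in kilograms and meters, unrounded."""
    if not weight > 0:
        raise DomainError(f"weight must be > 0 kg, got {weight}")
    if not height > 0:
        raise DomainError(f"height must be > 0 m, got {height}")
    return weight / height**2


def lms_z(x: float, row: LMSRow) -> float:
    """Z-score of measurement ``x`` under an LMS row (log branch at L = 0)."""
    if not x > 0:
        raise DomainError(f"measurement must be > 0, got {x}")
    log_ratio = math.log(x / row.M)
    if row.L == 0.0:
        return log_ratio / row.S
    # expm1 keeps ((x/M)**L - 1) accurate as L -> 0, so the branches meet
    return math.expm1(row.L * log_ratio) / (row.L * row.S)


def lms_value_from_z(z: float, row: LMSRow) -> float:
    """Inverse of :func:`lms_z`: the measurement at a given z-score."""
    if row.L == 0.0:
        return row.M * math.exp(row.S * z)
    base = 1.0 + row.L * row.S * z
    if base <= 0:
        raise DomainError(f"z={z} outside the support of the Box-Cox transform (L={row.L})")
    return row.M * base ** (1.0 / row.L)


def z_to_percentile(z: float) -> float:
    """``100 * Phi(z)``, strictly increasing in z."""
    return 100.0 * float(ndtr(z))


def percentile_to_z(percentile: float) -> float:
    if not 0 < percentile < 100:
        raise DomainError(f"percentile must lie in (0, 100), got {percentile}")
    return float(ndtri(percentile / 100.0))


def classify_weight_status(percentile: float, thresholds: tuple[float, float]) -> str:
    """Classify a BMI-for-age percentile against (overweight_at, obese_at).

    The boundary convention is inclusive upward: a percentile exactly at a
    threshold belongs to the more severe category.
    """
    overweight_at, obese_at = thresholds
    if not overweight_at < obese_at:
        raise ConfigurationError(
            f"weight-status thresholds must be ordered, got {thresholds}")
    if percentile >= obese_at:
        return "obese"
    if percentile >= overweight_at:
        return "overweight"
    return "normal"


@dataclass(frozen=True)
class PercentileResult:
    """Outcome of a BMI-for-age assessment."""

    bmi: float
    z: float
    percentile: float  # = 100 * Phi(z)
    category: str
    age_years: int
    exact_months: float
    reference_row: LMSRow


def bmi_assessment(dob: dt.date, encounter_date: dt.date, sex: str,
                   height: float, weight: float,
                   library: ReferenceLibrary,
                   thresholds: tuple[float, float] = (85.0, 95.0)) -> PercentileResult:
    """Full BMI chain: age -> reference row -> z -> percentile -> category.

    Raises :class:`CoverageError` when the exact age in months falls outside
    the loaded BMI reference, naming the coverage bounds.
    """
    sex = normalize_sex(sex)
    years, exact_months = compute_age(dob, encounter_date)
    bounds = library.lms_coverage("bmi")
    if bounds is None or not bounds[0] <= exact_months < bounds[1]:
        raise CoverageError(
            f"age {exact_months:.1f} months outside BMI reference coverage {bounds}",
            bounds=bounds)
    row = library.lms_row_for(sex, exact_months, "bmi")
    bmi = compute_bmi(weight, height)
    z = lms_z(bmi, row)
    percentile = z_to_percentile(z)
    return PercentileResult(bmi=bmi, z=z, percentile=percentile,
                            category=classify_weight_status(percentile, thresholds),
                            age_years=years, exact_months=exact_months, reference_row=row)
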