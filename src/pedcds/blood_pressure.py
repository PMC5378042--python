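"""Blood-pressure averaging and percentile inversion.

The pediatric BP reference is tabulated at percentile knots per (sex, age in
completed years, height-percentile column).  An observed pressure is turned
into a percentile by piecewise-linear inversion of the monotone knot function;
values outside the knot span are *censored* (flagged ``below_range`` /
``above_range``), never extrapolated, because the tables say nothing about
tail shape.

Up to three readings per visit are averaged per channel.  A patient's height
percentile is computed from a stature LMS reference and snapped to the nearest
height column available in the BP table (ties resolve toward the 50th).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from . import anthropometry
from .errors import ConfigurationError, CoverageError, DomainError
from .reference_data import BPReferenceRow, LMSRow, ReferenceLibrary, normalize_sex

__all__ = [
    "BPEntry",
    "BPPercentileResult",
    "BELOW_RANGE",
    "ABOVE_RANGE",
    "average_readings",
    "height_percentile_for_lookup",
    "bp_percentile",
    "bp_assessment",
    "BP_METHODS",
]

BP_METHODS = ("auscultation", "oscillometry", "unknown")

#: Censoring flags returned when an observed value falls outside the knot span.
BELOW_RANGE = "below_range"
ABOVE_RANGE = "above_range"


@dataclass
class BPEntry:
    """Blood-pressure data entered at one visit: method plus 1-3 readings."""

    readings: list[tuple[float, float]] = field(default_factory=list)
    method: str = "unknown"
    height: float | None = None  # meters, for height-percentile lookup

    def __post_init__(self):
        if self.method not in BP_METHODS:
            raise DomainError(f"BP method must be one of {BP_METHODS}, got {self.method!r}")
        self.readings = [tuple(map(float, r)) for r in self.readings]
        _validate_readings(self.readings)

    @property
    def mean_systolic(self) -> float:
        return average_readings(self.readings)[0]

    @property
    def mean_diastolic(self) -> float:
        return average_readings(self.readings)[1]


def _validate_readings(readings) -> None:
    if len(readings) < 1:
        raise DomainError("at least one BP reading required")
    if len(readings) > 3:
        raise DomainError(f"at most 3 BP readings per visit, got {len(readings)}")
    for s, d in readings:
        if not (s > 0 and d > 0):
            raise DomainError(f"BP readings must be positive, got ({s}, {d})")
        if not s > d:
            raise DomainError(f"systolic must exceed diastolic, got ({s}, {d})")


def average_readings(readings) -> tuple[float, float]:
    """Arithmetic mean per channel over 1-3 (systolic, diastolic) pairs."""
    readings = [tuple(map(float, r)) for r in readings]
    _validate_readings(readings)
    sys_mean = sum(r[0] for r in readings) / len(readings)
    dia_mean = sum(r[1] for r in readings) / len(readings)
    return sys_mean, dia_mean


def height_percentile_for_lookup(height: float, dob: dt.date, encounter_date: dt.date,
                                 sex: str, stature_reference: tuple[LMSRow, ...],
                                 knots: tuple[float, ...]) -> float:
    """Patient height percentile snapped to the nearest BP-table height column.

    The percentile comes from the stature LMS reference at the patient's exact
    age; it is then snapped to the nearest knot in ``knots``, with distance
    ties resolved toward the 50th percentile.
    """
    if not stature_reference:
        raise ConfigurationError(
            "no stature reference available; supply the height percentile directly")
    sex = normalize_sex(sex)
    _, exact_months = anthropometry.compute_age(dob, encounter_date)
    index = {(r.sex, r.age_months): r for r in stature_reference}
    midpoint = float(int(exact_months)) + 0.5
    row = index.get((sex, midpoint))
    if row is None:
        raise CoverageError(
            f"stature reference does not cover sex={sex} at {exact_months:.1f} months",
            key=(sex, midpoint))
    pct = anthropometry.z_to_percentile(anthropometry.lms_z(height, row))
    return snap_to_knot(pct, knots)


def snap_to_knot(percentile: float, knots) -> float:
    """Nearest knot; on an exact distance tie, the knot closer to 50."""
    knots = sorted(float(k) for k in knots)
    if not knots:
        raise ConfigurationError("empty height-knot set")
    return min(knots, key=lambda k: (abs(k - percentile), abs(k - 50.0)))


def bp_percentile(observed: float, row: BPReferenceRow, channel: str) -> float | str:
    """Invert the knot function for one channel.

    Returns the percentile from piecewise-linear interpolation between knots,
    exact at every knot; ``below_range`` / ``above_range`` outside the span.
    """
    idx = {"systolic": 1, "diastolic": 2}
    if channel not in idx:
        raise DomainError(f"channel must be systolic or diastolic, got {channel!r}")
    values = [k[idx[channel]] for k in row.knots]
    percentiles = [k[0] for k in row.knots]
    if observed < values[0]:
        return BELOW_RANGE
    if observed > values[-1]:
        return ABOVE_RANGE
    return float(np.interp(observed, values, percentiles))


@dataclass(frozen=True)
class BPPercentileResult:
    """Per-channel percentile (or censoring flag) plus the reference row used."""

    mean_systolic: float
    mean_diastolic: float
    systolic_percentile: float | None
    diastolic_percentile: float | None
    systolic_flag: str | None
    diastolic_flag: str | None
    reference_row_key: tuple[str, int, float]

    def __post_init__(self):
        for v, f in ((self.systolic_percentile, self.systolic_flag),
                     (self.diastolic_percentile, self.diastolic_flag)):
            if (v is None) == (f is None):
                raise DomainError("exactly one of percentile and censoring flag per channel")


def _channel_result(observed: float, row: BPReferenceRow, channel: str):
    out = bp_percentile(observed, row, channel)
    return (None, out) if isinstance(out, str) else (out, None)


def bp_assessment(dob: dt.date, encounter_date: dt.date, sex: str, entry: BPEntry,
                  library: ReferenceLibrary,
                  height: float | None = None,
                  height_percentile: float | None = None) -> BPPercentileResult:
    """Average the readings and look both channels up in the BP reference.

    The height column is chosen from, in order of preference: an explicitly
    supplied ``height_percentile``, or the stature-reference percentile of
    ``height`` (falling back to ``entry.height``).  Age is truncated to
    completed years for table lookup, mirroring the reference's granularity.
    """
    sex = normalize_sex(sex)
    years, _ = anthropometry.compute_age(dob, encounter_date)
    cov = library.bp_age_coverage()
    if cov is None or not cov[0] <= years <= cov[1]:
        raise CoverageError(
            f"age {years} years outside BP reference coverage {cov}",
            key=(sex, years), bounds=cov)
    knots = library.height_knots(sex, years)
    if height_percentile is not None:
        hknot = snap_to_knot(height_percentile, knots)
    else:
        h = height if height is not None else entry.height
        if h is None:
            raise ConfigurationError("height or height_percentile required for BP lookup")
        hknot = height_percentile_for_lookup(h, dob, encounter_date, sex,
                                             library.lms_stature, knots)
    row = library.bp_row_for(sex, years, hknot)
    mean_sys, mean_dia = average_readings(entry.readings)
    sys_pct, sys_flag = _channel_result(mean_sys, row, "systolic")
    dia_pct, dia_flag = _channel_result(mean_dia, row, "diastolic")
    return BPPercentileResult(
        mean_systolic=mean_sys, mean_diastolic=mean_dia,
        systolic_percentile=sys_pct, diastolic_percentile=dia_pct,
        systolic_flag=sys_flag, diastolic_flag=dia_flag,
        reference_row_key=row.key)
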