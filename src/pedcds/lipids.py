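"""Lipid panel capture, derived analytes and category assignment.

The panel mirrors what a pediatric visit records: sample type (fasting,
nonfasting or unknown) and any subset of total cholesterol, LDL-C, HDL-C,
triglycerides and non-HDL cholesterol, in mg/dL.  Non-HDL is derivable as
TC - HDL and is the analyte of choice for nonfasting samples.

Cutpoints (acceptable / borderline / high bands) are guideline content and
live in the rulebase, not here: :func:`categorize_analyte` takes them as
data.  The uniform boundary convention is "inclusive toward the worse
category": a value exactly at a bound gets the more severe label, whichever
direction severity runs for that analyte.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

from . import anthropometry
from .errors import ConfigurationError, MissingInputError, ValidationError
from .reference_data import ReferenceLibrary

__all__ = [
    "LipidPanel",
    "LipidAssessment",
    "derive_non_hdl",
    "categorize_analyte",
    "categorize_panel",
    "lipid_assessment",
    "SAMPLE_TYPES",
    "ANALYTES",
]

SAMPLE_TYPES = ("fasting", "nonfasting", "unknown")
ANALYTES = ("total_cholesterol", "ldl", "hdl", "triglycerides", "non_hdl")


@dataclass(frozen=True)
class LipidPanel:
    """One lipid draw; any analyte may be absent (None)."""

    sample_type: str = "unknown"
    total_cholesterol: float | None = None
    ldl: float | None = None
    hdl: float | None = None
    triglycerides: float | None = None
    non_hdl: float | None = None

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise ValidationError(
                f"sample_type must be one of {SAMPLE_TYPES}, got {self.sample_type!r}")
        for name in ANALYTES:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0 mg/dL, got {v}")
        if (self.total_cholesterol is not None and self.hdl is not None
                and self.hdl > self.total_cholesterol):
            raise ValidationError(
                f"HDL ({self.hdl}) cannot exceed total cholesterol ({self.total_cholesterol})")


def derive_non_hdl(panel: LipidPanel) -> LipidPanel:
    """Fill in non-HDL = TC - HDL when both are present and non-HDL absent.

    An explicitly entered non-HDL value is never overwritten; the operation is
    idempotent.
    """
    if panel.non_hdl is not None:
        return panel
    if panel.total_cholesterol is None or panel.hdl is None:
        return panel
    return replace(panel, non_hdl=panel.total_cholesterol - panel.hdl)


def categorize_analyte(value: float, cutpoints, direction: str = "high_is_bad") -> str:
    """Label a value against ordered (label, upper_bound) cutpoints.

    ``cutpoints`` partition [0, inf): each entry gives a label and the upper
    bound of its band; the last bound must be None (unbounded).  For
    ``high_is_bad`` analytes, bands are half-open ``[lo, hi)`` so a value at a
    bound falls in the *upper* (worse) band.  For ``low_is_bad`` analytes
    (HDL), severity runs downward, so bands are ``(lo, hi]`` and a value at a
    bound falls in the *lower* (worse) band.
    """
    if direction not in ("high_is_bad", "low_is_bad"):
        raise ConfigurationError(f"unknown direction {direction!r}")
    labels = [c[0] for c in cutpoints]
    bounds = [c[1] for c in cutpoints]
    if len(cutpoints) < 1 or bounds[-1] is not None:
        raise ConfigurationError("cutpoints must end with an unbounded (label, None) band")
    finite = bounds[:-1]
    if any(b is None for b in finite) or any(a >= b for a, b in zip(finite, finite[1:])):
        raise ConfigurationError(f"cutpoint bounds must be strictly increasing: {bounds}")
    for label, bound in zip(labels, finite):
        if (direction == "high_is_bad" and value < bound) or \
           (direction == "low_is_bad" and value <= bound):
            return label
    return labels[-1]


def categorize_panel(panel: LipidPanel, cutpoint_table: dict) -> dict[str, str]:
    """Category label per present analyte, per the rulebase cutpoint table.

    ``cutpoint_table`` maps analyte name to ``{"direction": ..., "bands":
    [[label, upper_bound_or_None], ...]}`` — the structure the rulebase's
    ``lipid_cutpoints`` section parses into.  Analytes absent from the panel
    or from the table are skipped.
    """
    panel = derive_non_hdl(panel)
    out = {}
    for name in ANALYTES:
        value = getattr(panel, name)
        spec = cutpoint_table.get(name)
        if value is None or spec is None:
            continue
        out[name] = categorize_analyte(value, [tuple(b) for b in spec["bands"]],
                                       spec.get("direction", "high_is_bad"))
    return out


@dataclass(frozen=True)
class LipidAssessment:
    """Validated panel plus its categories and, when computable, the BMI block."""

    panel: LipidPanel
    categories: dict[str, str]
    bmi_block: anthropometry.PercentileResult | None


def lipid_assessment(panel: LipidPanel, dob: dt.date, encounter_date: dt.date, sex: str,
                     cutpoint_table: dict,
                     height: float | None = None, weight: float | None = None,
                     library: ReferenceLibrary | None = None,
                     bmi_thresholds: tuple[float, float] = (85.0, 95.0)) -> LipidAssessment:
    """Validate the panel, derive non-HDL, categorize, and add the BMI block.

    The lipid module mirrors the other calculators in also reporting BMI when
    height and weight are on hand; the BMI block is omitted (not an error)
    when they are not.
    """
    if dob is None or sex is None:
        raise MissingInputError("dob" if dob is None else "sex")
    if panel.sample_type is None:
        raise MissingInputError("sample_type")
    panel = derive_non_hdl(panel)
    categories = categorize_panel(panel, cutpoint_table)
    bmi_block = None
    if height is not None and weight is not None and library is not None:
        bmi_block = anthropometry.bmi_assessment(dob, encounter_date, sex, height, weight,
                                                 library, bmi_thresholds)
    return LipidAssessment(panel=panel, categories=categories, bmi_block=bmi_block)
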