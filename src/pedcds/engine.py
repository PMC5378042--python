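"""The executable layer: sessions, three-valued trigger evaluation, assembly.

A :class:`PatientSession` holds everything entered for the current patient
across the four tools (integrated screener, BMI, BP, lipid) — data carries
over between tools and is cleared in one action, mirroring a
single-current-patient workflow.  From the session the engine derives a flat
``facts`` mapping (variable id -> value) that the rulebase's triggers are
evaluated against.

Evaluation is Kleene three-valued: an atomic predicate over an absent or
"unknown" value is *indeterminate* (unless the comparator is ``is_unknown``),
and indeterminacy propagates through conjunction/disjunction by the Kleene
truth tables.  Only a definite *fire* emits a recommendation — clinical
advice is never triggered off missing answers; rules that should react to
missingness say so explicitly with ``is_unknown``.

Fired rules are deduplicated per recommendation (supportive actions unioned
in first-seen order, contributing rule ids accumulated) and ordered by the
fixed risk-domain order, then rule id, so output is deterministic down to the
byte.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field, replace

from . import anthropometry, blood_pressure, lipids
from .blood_pressure import BPEntry
from .errors import ContradictionError, DuplicateEntryError, EvaluationError, MissingInputError
from .knowledge import (DOMAIN_ORDER, NUMERIC_OPS, TOOL_CONTEXTS, Atom, Rule, Rulebase,
                        TriggerNode)
from .lipids import LipidPanel
from .reference_data import ReferenceLibrary

__all__ = [
    "FIRE",
    "NO_FIRE",
    "INDETERMINATE",
    "eval_atom",
    "eval_trigger",
    "rule_applies",
    "run_assessment",
    "dedup",
    "clear_session",
    "Anthropometrics",
    "RiskFactorProfile",
    "PatientSession",
    "FiredRecommendation",
    "AssessmentResult",
    "CONDITIONS",
    "ACTIVITY_LEVELS",
]

FIRE = "fire"
NO_FIRE = "no_fire"
INDETERMINATE = "indeterminate"

CONDITIONS = ("hypertension", "dyslipidemia", "t1dm", "t2dm")
ACTIVITY_LEVELS = ("sedentary", "moderate_to_vigorous", "vigorous", "unknown")
TRAJECTORIES = ("improving", "not_improving", "unknown")
TRI = ("yes", "no", "unknown")


# ---------------------------------------------------------------------------
# Session data
# ---------------------------------------------------------------------------

@dataclass
class Anthropometrics:
    """Demographics and body measurements shared by every tool."""

    dob: dt.date | None = None
    encounter_date: dt.date | None = None
    sex: str | None = None
    height: float | None = None  # meters
    weight: float | None = None  # kilograms
    bmi_change_category: str | None = None  # user-entered, never inferred

    def __post_init__(self):
        if self.height is not None and not self.height > 0:
            raise ContradictionError(f"height must be > 0 m, got {self.height}")
        if self.weight is not None and not self.weight > 0:
            raise ContradictionError(f"weight must be > 0 kg, got {self.weight}")
        if (self.dob is not None and self.encounter_date is not None
                and self.encounter_date < self.dob):
            raise ContradictionError("encounter date precedes date of birth")
        if (self.bmi_change_category is not None
                and self.bmi_change_category not in anthropometry.BMI_CHANGE_CATEGORIES):
            raise ContradictionError(
                f"bmi_change_category must be one of {anthropometry.BMI_CHANGE_CATEGORIES}")


def _check_tri(name, value):
    if value is not None and value not in TRI:
        raise ContradictionError(f"{name} must be yes/no/unknown, got {value!r}")


@dataclass
class RiskFactorProfile:
    """Screener answers beyond the calculators: conditions, lifestyle, family."""

    conditions: tuple[str, ...] | None = None  # subset of CONDITIONS, or none/unknown
    condition_trajectories: dict[str, str] = field(default_factory=dict)
    other_risk_conditions: str | None = None
    activity_level: str | None = None
    activity_decrease: str | None = None
    smokes: str | None = None
    smoke_free_home: str | None = None
    parent_obese: str | None = None
    parent_dyslipidemia: str | None = None
    mother_tc: float | str | None = None  # mg/dL or "unknown"
    father_tc: float | str | None = None
    family_history_cvd: str | None = None

    def __post_init__(self):
        if self.conditions is not None:
            conds = tuple(self.conditions)
            real = [c for c in conds if c in CONDITIONS]
            markers = [c for c in conds if c in ("none", "unknown")]
            bad = [c for c in conds if c not in CONDITIONS + ("none", "unknown")]
            if bad:
                raise ContradictionError(f"unknown condition(s): {bad}")
            if markers and real:
                raise ContradictionError(
                    f"'{markers[0]}' cannot be combined with a named condition {real}")
            if len(markers) > 1:
                raise ContradictionError("conditions cannot be both 'none' and 'unknown'")
            self.conditions = conds
        for c, t in self.condition_trajectories.items():
            if c not in CONDITIONS or t not in TRAJECTORIES:
                raise ContradictionError(f"bad condition trajectory {c!r}: {t!r}")
        if self.activity_level is not None and self.activity_level not in ACTIVITY_LEVELS:
            raise ContradictionError(
                f"activity_level must be one of {ACTIVITY_LEVELS}, got {self.activity_level!r}")
        for name in ("other_risk_conditions", "activity_decrease", "smokes",
                     "smoke_free_home", "parent_obese", "parent_dyslipidemia",
                     "family_history_cvd"):
            _check_tri(name, getattr(self, name))


@dataclass
class PatientSession:
    """All data entered for the current patient, carried over between tools."""

    anthropometrics: Anthropometrics = field(default_factory=Anthropometrics)
    bp: BPEntry | None = None
    lipid_panel: LipidPanel | None = None
    risk: RiskFactorProfile = field(default_factory=RiskFactorProfile)
    #: single systolic/diastolic pair from the integrated screener; treated as
    #: one reading and superseded by the BP tool's up-to-3 readings.
    screener_bp: tuple[float, float] | None = None

    def enter(self, **fields) -> "PatientSession":
        """Record values, enforcing enter-at-most-once per variable."""
        for name, value in fields.items():
            if hasattr(self.anthropometrics, name):
                if getattr(self.anthropometrics, name) is not None:
                    raise DuplicateEntryError(f"{name} already entered this session")
                self.anthropometrics = replace(self.anthropometrics, **{name: value})
            elif hasattr(self.risk, name):
                if getattr(self.risk, name) is not None:
                    raise DuplicateEntryError(f"{name} already entered this session")
                self.risk = replace(self.risk, **{name: value})
            elif name in ("bp", "lipid_panel", "screener_bp"):
                if getattr(self, name) is not None:
                    raise DuplicateEntryError(f"{name} already entered this session")
                setattr(self, name, value)
            else:
                raise KeyError(f"unknown session field {name!r}")
        return self

    def clear(self) -> "PatientSession":
        """The trashcan: drop every entered value (idempotent)."""
        self.anthropometrics = Anthropometrics()
        self.bp = None
        self.lipid_panel = None
        self.risk = RiskFactorProfile()
        self.screener_bp = None
        return self

    # -- serialization (explicit session files for the CLI) ---------------
    def to_dict(self) -> dict:
        a, r = self.anthropometrics, self.risk
        doc: dict = {}
        if a.dob:
            doc["dob"] = a.dob.isoformat()
        if a.encounter_date:
            doc["encounter_date"] = a.encounter_date.isoformat()
        for k in ("sex", "height", "weight", "bmi_change_category"):
            if getattr(a, k) is not None:
                doc[k] = getattr(a, k)
        if self.screener_bp is not None:
            doc["screener_bp"] = list(self.screener_bp)
        if self.bp is not None:
            doc["bp"] = {"method": self.bp.method,
                         "readings": [list(x) for x in self.bp.readings],
                         **({"height": self.bp.height} if self.bp.height else {})}
        if self.lipid_panel is not None:
            p = self.lipid_panel
            doc["lipids"] = {k: v for k, v in (
                ("sample_type", p.sample_type), ("total_cholesterol", p.total_cholesterol),
                ("ldl", p.ldl), ("hdl", p.hdl), ("triglycerides", p.triglycerides),
                ("non_hdl", p.non_hdl)) if v is not None}
        rf = {k: getattr(r, k) for k in (
            "other_risk_conditions", "activity_level", "activity_decrease", "smokes",
            "smoke_free_home", "parent_obese", "parent_dyslipidemia", "mother_tc",
            "father_tc", "family_history_cvd") if getattr(r, k) is not None}
        if r.conditions is not None:
            rf["conditions"] = list(r.conditions)
        if r.condition_trajectories:
            rf["condition_trajectories"] = dict(r.condition_trajectories)
        if rf:
            doc["risk_factors"] = rf
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "PatientSession":
        a = Anthropometrics(
            dob=dt.date.fromisoformat(doc["dob"]) if "dob" in doc else None,
            encounter_date=(dt.date.fromisoformat(doc["encounter_date"])
                            if "encounter_date" in doc else None),
            sex=doc.get("sex"), height=doc.get("height"), weight=doc.get("weight"),
            bmi_change_category=doc.get("bmi_change_category"))
        bp = None
        if "bp" in doc:
            bp = BPEntry(readings=[tuple(x) for x in doc["bp"]["readings"]],
                         method=doc["bp"].get("method", "unknown"),
                         height=doc["bp"].get("height"))
        panel = LipidPanel(**doc["lipids"]) if "lipids" in doc else None
        rf = dict(doc.get("risk_factors", {}))
        if "conditions" in rf:
            rf["conditions"] = tuple(rf["conditions"])
        risk = RiskFactorProfile(**rf)
        screener_bp = tuple(doc["screener_bp"]) if "screener_bp" in doc else None
        return cls(anthropometrics=a, bp=bp, lipid_panel=panel, risk=risk,
                   screener_bp=screener_bp)

    # -- fact derivation ---------------------------------------------------
    def facts(self, library: ReferenceLibrary | None = None,
              rulebase: Rulebase | None = None) -> dict:
        """Flatten entered data plus derived quantities into a fact mapping.

        Derived facts (age, BMI, percentiles, lipid categories) are recomputed
        on every call, so they always reflect the current inputs.  Facts that
        cannot be derived (missing inputs, censored percentiles, ages outside
        reference coverage) are simply absent.
        """
        a, r = self.anthropometrics, self.risk
        facts: dict = {}
        if a.sex is not None:
            facts["sex"] = a.sex
        if a.dob is not None and a.encounter_date is not None:
            years, months = anthropometry.compute_age(a.dob, a.encounter_date)
            facts["age_years"] = years
            facts["age_months"] = months
        for k in ("height", "weight", "bmi_change_category"):
            if getattr(a, k) is not None:
                facts[k] = getattr(a, k)
        if a.height is not None and a.weight is not None:
            facts["bmi"] = anthropometry.compute_bmi(a.weight, a.height)
        thresholds = rulebase.bmi_thresholds() if rulebase else (85.0, 95.0)
        if (library is not None and "bmi" in facts and "age_months" in facts
                and a.sex is not None):
            try:
                res = anthropometry.bmi_assessment(a.dob, a.encounter_date, a.sex,
                                                   a.height, a.weight, library, thresholds)
            except Exception:
                pass
            else:
                facts["bmi_percentile"] = res.percentile
                facts["bmi_category"] = res.category

        entry = self.bp
        if entry is None and self.screener_bp is not None:
            entry = BPEntry(readings=[self.screener_bp])
        if entry is not None:
            mean_sys, mean_dia = blood_pressure.average_readings(entry.readings)
            facts["mean_systolic"] = mean_sys
            facts["mean_diastolic"] = mean_dia
            facts["bp_method"] = entry.method
            if library is not None and a.dob is not None and a.sex is not None \
                    and a.encounter_date is not None:
                try:
                    res = blood_pressure.bp_assessment(
                        a.dob, a.encounter_date, a.sex, entry, library, height=a.height)
                except Exception:
                    pass
                else:
                    if res.systolic_percentile is not None:
                        facts["systolic_bp_percentile"] = res.systolic_percentile
                    else:
                        facts["systolic_bp_range"] = res.systolic_flag
                    if res.diastolic_percentile is not None:
                        facts["diastolic_bp_percentile"] = res.diastolic_percentile
                    else:
                        facts["diastolic_bp_range"] = res.diastolic_flag

        if self.lipid_panel is not None:
            panel = lipids.derive_non_hdl(self.lipid_panel)
            facts["sample_type"] = panel.sample_type
            for name in lipids.ANALYTES:
                v = getattr(panel, name)
                if v is not None:
                    facts[name] = v
            if rulebase is not None:
                table = rulebase.lipid_cutpoint_table(facts.get("age_months"))
                for name, label in lipids.categorize_panel(panel, table).items():
                    facts[f"{name}_category"] = label

        if r.conditions is not None:
            if "unknown" in r.conditions:
                status = {c: "unknown" for c in CONDITIONS}
            else:  # explicit 'none', or a named subset (unselected -> no)
                status = {c: ("yes" if c in r.conditions else "no") for c in CONDITIONS}
            for c, v in status.items():
                facts[f"has_{c}"] = v
        for c, t in r.condition_trajectories.items():
            facts[f"{c}_trend"] = t
        for k in ("other_risk_conditions", "activity_level", "activity_decrease",
                  "smokes", "smoke_free_home", "parent_obese", "parent_dyslipidemia",
                  "mother_tc", "father_tc", "family_history_cvd"):
            v = getattr(r, k)
            if v is not None:
                facts[k] = v
        return facts


def clear_session(session: PatientSession) -> PatientSession:
    """Clear all data for the current patient (the app's trashcan action)."""
    return session.clear()


# ---------------------------------------------------------------------------
# Three-valued trigger evaluation
# ---------------------------------------------------------------------------

def eval_atom(atom: Atom, facts: dict, rule_id: str | None = None) -> bool | None:
    """Evaluate one predicate; None encodes *indeterminate*.

    Absent facts and the literal value "unknown" are both treated as unknown:
    they satisfy only ``is_unknown`` and make every other comparator
    indeterminate.
    """
    value = facts.get(atom.var)
    unknown = value is None or value == "unknown"
    if atom.op == "is_unknown":
        return unknown
    if unknown:
        return None
    if atom.op in NUMERIC_OPS:
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise EvaluationError(
                f"rule {rule_id}: numeric comparator {atom.op!r} on non-numeric value "
                f"{value!r} of {atom.var!r}", rule_id=rule_id, variable=atom.var)
        t = atom.value
        return {"lt": value < t, "le": value <= t,
                "gt": value > t, "ge": value >= t}[atom.op]
    if atom.op == "eq":
        return value == atom.value
    if atom.op == "ne":
        return value != atom.value
    if atom.op == "in_set":
        return value in atom.value
    raise EvaluationError(f"rule {rule_id}: unknown comparator {atom.op!r}",
                          rule_id=rule_id, variable=atom.var)


def _eval_expr(expr, facts: dict, rule_id: str | None) -> bool | None:
    if isinstance(expr, Atom):
        return eval_atom(expr, facts, rule_id)
    results = [_eval_expr(c, facts, rule_id) for c in expr.children]
    if expr.kind == "all":
        if any(r is False for r in results):
            return False
        return None if any(r is None for r in results) else True
    if any(r is True for r in results):  # any
        return True
    return None if any(r is None for r in results) else False


def eval_trigger(trigger, facts: dict, rule_id: str | None = None) -> str:
    """Kleene evaluation of a trigger tree -> fire / no_fire / indeterminate."""
    out = _eval_expr(trigger, facts, rule_id)
    return FIRE if out is True else NO_FIRE if out is False else INDETERMINATE


def rule_applies(rule: Rule, facts: dict, context: str = "screener") -> bool:
    """Age-band and tool-context filter applied before trigger evaluation."""
    if context != "screener" and context not in TOOL_CONTEXTS[rule.domain]:
        return False
    age = facts.get("age_months")
    if age is None:
        return False
    return rule.age_band.contains(age)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FiredRecommendation:
    recommendation_id: str
    text: str
    grade: str
    supportive_actions: tuple[tuple[str, str], ...]  # (id, text), first-seen order
    rule_ids: tuple[str, ...]


@dataclass(frozen=True)
class AssessmentResult:
    """Patient summary plus the ordered, deduplicated fired recommendations."""

    patient_summary: dict
    fired: tuple[FiredRecommendation, ...]
    context: str

    def recommendation_ids(self) -> tuple[str, ...]:
        return tuple(f.recommendation_id for f in self.fired)

    def to_dict(self) -> dict:
        return {
            "context": self.context,
            "patient_summary": self.patient_summary,
            "recommendations": [
                {"id": f.recommendation_id, "text": f.text, "grade": f.grade,
                 "supportive_actions": [{"id": i, "text": t}
                                        for i, t in f.supportive_actions],
                 "rules": list(f.rule_ids)}
                for f in self.fired],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, separators=(",", ":"),
                          default=_json_default)

    def to_text(self) -> str:
        lines = ["PATIENT SUMMARY"]
        for k in sorted(self.patient_summary):
            lines.append(f"  {k}: {self.patient_summary[k]}")
        lines.append(f"RECOMMENDATIONS ({len(self.fired)})")
        for f in self.fired:
            lines.append(f"  [{f.grade}] {f.recommendation_id}: {f.text}")
            for _, t in f.supportive_actions:
                lines.append(f"      - {t}")
            lines.append(f"      (rules: {', '.join(f.rule_ids)})")
        return "\n".join(lines)


def _json_default(o):
    if isinstance(o, (dt.date, dt.datetime)):
        return o.isoformat()
    raise TypeError(f"not JSON serializable: {o!r}")


def dedup(hits: list[Rule], rulebase: Rulebase) -> tuple[FiredRecommendation, ...]:
    """Collapse rule hits to one entry per recommendation id.

    Supportive actions are unioned preserving first-seen order; contributing
    rule ids accumulate; the grade is the first-seen (hits arrive already in
    domain order).  Idempotent by construction.
    """
    order: list[str] = []
    merged: dict[str, dict] = {}
    for rule in hits:
        rid = rule.recommendation_id
        if rid not in merged:
            order.append(rid)
            merged[rid] = {"grade": rule.grade, "actions": [], "rules": []}
        entry = merged[rid]
        for a in rule.actions:
            if a not in entry["actions"]:
                entry["actions"].append(a)
        if rule.rule_id not in entry["rules"]:
            entry["rules"].append(rule.rule_id)
    return tuple(
        FiredRecommendation(
            recommendation_id=rid,
            text=rulebase.recommendations[rid],
            grade=merged[rid]["grade"],
            supportive_actions=tuple((a, rulebase.actions[a]) for a in merged[rid]["actions"]),
            rule_ids=tuple(merged[rid]["rules"]))
        for rid in order)


_DOMAIN_RANK = {d: i for i, d in enumerate(DOMAIN_ORDER)}


def run_assessment(session_or_facts, rulebase: Rulebase,
                   library: ReferenceLibrary | None = None,
                   context: str = "screener") -> AssessmentResult:
    """Evaluate every applicable rule against the session and assemble output.

    ``session_or_facts`` may be a :class:`PatientSession` (facts are derived)
    or an already-flat fact mapping.  ``context`` scopes the rule set to one
    tool; the integrated screener sees every domain.
    """
    if isinstance(session_or_facts, PatientSession):
        facts = session_or_facts.facts(library, rulebase)
    else:
        facts = dict(session_or_facts)
    if "age_months" not in facts:
        raise MissingInputError("age_months", "session age is not computable (need dob "
                                "and encounter_date, or an age_months fact)")
    hits = [r for r in sorted(rulebase.rules,
                              key=lambda r: (_DOMAIN_RANK[r.domain], r.rule_id))
            if rule_applies(r, facts, context)
            and eval_trigger(r.trigger, facts, r.rule_id) == FIRE]
    return AssessmentResult(patient_summary=facts, fired=dedup(hits, rulebase),
                            context=context)
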