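"""The knowledge layers: rulebase schema, parser, validator, trigger matrix.

Guideline content is declarative data, not code.  A rulebase file (YAML) has
five sections:

* ``meta`` — name, declared age coverage in months;
* ``thresholds`` / ``lipid_cutpoints`` — numeric guideline cutpoints consumed
  by the calculators (weight-status percentiles, lipid category bands);
* ``data_elements`` — the typed dictionary of every variable a trigger may
  reference (numeric, enumerated, tri-state yes/no/unknown, date);
* ``supportive_actions`` and ``recommendations`` — patient-specific guidance
  text, keyed by token;
* ``rules`` — one trigger -> recommendation unit each, with a half-open age
  band in months, an evidence grade A-F and supportive-action references.

Triggers are conjunction/disjunction trees over atomic predicates
``(variable, comparator, constant)`` with comparators
``eq ne lt le gt ge in_set is_unknown``.  The parser resolves and checks
every cross-reference; a shipped schema document
(``data/rulebase.schema.json``) records the same contract for authors.

Age bands are half-open ``[lower, upper)`` by design: the guideline's own
age categories overlapped at the infant-to-3 / 3-to-11 seam, and half-open
bands in months make such overlaps detectable and fixable
(:func:`validate_age_bands`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import FormatError, ValidationError

__all__ = [
    "DOMAINS",
    "DOMAIN_ORDER",
    "TOOL_CONTEXTS",
    "GRADES",
    "COMPARATORS",
    "AgeBand",
    "Atom",
    "TriggerNode",
    "Rule",
    "DataElement",
    "Rulebase",
    "parse_rulebase",
    "serialize_rulebase",
    "packaged_rulebase_path",
    "packaged_rulebase",
    "validate_age_bands",
    "AgeBandReport",
    "build_trigger_matrix",
    "trigger_atoms",
]

#: Risk domains, in the presentation order used for recommendation output.
DOMAIN_ORDER = (
    "family_history",
    "nutrition_diet",
    "physical_activity",
    "tobacco_exposure",
    "lipids",
    "overweight_obesity",
    "blood_pressure",
    "other_risk_condition",
)
DOMAINS = frozenset(DOMAIN_ORDER)
GRADES = ("A", "B", "C", "D", "E", "F")
COMPARATORS = ("eq", "ne", "lt", "le", "gt", "ge", "in_set", "is_unknown")
KINDS = ("numeric", "enumerated", "tri_state", "date")
NUMERIC_OPS = frozenset({"lt", "le", "gt", "ge"})

#: Which tools exercise each domain's rules.  Every domain appears in the
#: integrated screener; the BMI calculator also reports weight status and its
#: diet/activity guidance; the lipid tool includes the BMI block.
TOOL_CONTEXTS = {
    "family_history": ("screener",),
    "nutrition_diet": ("screener", "bmi"),
    "physical_activity": ("screener", "bmi"),
    "tobacco_exposure": ("screener",),
    "lipids": ("screener", "lipid"),
    "overweight_obesity": ("screener", "bmi", "lipid"),
    "blood_pressure": ("screener", "bp"),
    "other_risk_condition": ("screener",),
}
TOOLS = ("screener", "bmi", "bp", "lipid")


@dataclass(frozen=True, order=True)
class AgeBand:
    """Half-open applicability interval [lower, upper) in months."""

    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValidationError(f"age band must satisfy lower < upper, got {self!r}")

    def contains(self, months: float) -> bool:
        return self.lower <= months < self.upper

    def intersection(self, other: "AgeBand") -> "AgeBand | None":
        lo, hi = max(self.lower, other.lower), min(self.upper, other.upper)
        return AgeBand(lo, hi) if lo < hi else None


@dataclass(frozen=True)
class Atom:
    """One predicate (variable, comparator, constant)."""

    var: str
    op: str
    value: object = None


@dataclass(frozen=True)
class TriggerNode:
    """Conjunction ('all') or disjunction ('any') over child expressions."""

    kind: str
    children: tuple


@dataclass(frozen=True)
class DataElement:
    id: str
    kind: str
    units: str | None = None
    allowed: tuple[str, ...] | None = None


@dataclass(frozen=True)
class Rule:
    rule_id: str
    domain: str
    age_band: AgeBand
    trigger: object  # Atom | TriggerNode
    recommendation_id: str
    grade: str
    actions: tuple[str, ...] = ()
    raw_trigger: dict = field(default=None, compare=False, repr=False)


@dataclass
class Rulebase:
    meta: dict
    elements: dict[str, DataElement]
    recommendations: dict[str, str]
    actions: dict[str, str]
    thresholds: dict
    lipid_cutpoints: dict
    rules: tuple[Rule, ...]

    @property
    def age_coverage(self) -> AgeBand:
        lo, hi = self.meta["age_coverage_months"]
        return AgeBand(float(lo), float(hi))

    def bmi_thresholds(self) -> tuple[float, float]:
        return (float(self.thresholds["bmi_overweight_percentile"]),
                float(self.thresholds["bmi_obese_percentile"]))

    def lipid_cutpoint_table(self, age_months: float | None = None) -> dict:
        """Cutpoint table with any age-split entries resolved for this age."""
        out = {}
        for analyte, spec in self.lipid_cutpoints.items():
            if "by_age" in spec:
                if age_months is None:
                    continue
                for part in spec["by_age"]:
                    lo, hi = part["age_band"]
                    if lo <= age_months < hi:
                        out[analyte] = {"direction": spec.get("direction", "high_is_bad"),
                                        "bands": part["bands"]}
                        break
            else:
                out[analyte] = spec
        return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_expr(node, rule_id: str, elements: dict[str, DataElement]):
    if not isinstance(node, dict):
        raise FormatError(f"rule {rule_id}: trigger node must be a mapping, got {node!r}")
    if "all" in node or "any" in node:
        if len(node) != 1:
            raise FormatError(f"rule {rule_id}: composite node must have exactly one key")
        kind, body = next(iter(node.items()))
        if not isinstance(body, list) or not body:
            raise FormatError(f"rule {rule_id}: '{kind}' needs a nonempty child list")
        return TriggerNode(kind=kind, children=tuple(
            _parse_expr(c, rule_id, elements) for c in body))
    if "var" not in node or "op" not in node:
        raise FormatError(f"rule {rule_id}: atom needs 'var' and 'op' keys, got {node!r}")
    var, op, value = node["var"], node["op"], node.get("value")
    if var not in elements:
        raise ValidationError(f"rule {rule_id}: trigger references undeclared variable {var!r}")
    if op not in COMPARATORS:
        raise ValidationError(f"rule {rule_id}: unknown comparator {op!r} on {var!r}")
    el = elements[var]
    if op in NUMERIC_OPS:
        if el.kind != "numeric":
            raise ValidationError(
                f"rule {rule_id}: numeric comparator {op!r} on non-numeric variable {var!r}")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            raise ValidationError(f"rule {rule_id}: {op!r} on {var!r} needs a numeric constant")
    elif op == "is_unknown":
        if value is not None:
            raise ValidationError(f"rule {rule_id}: is_unknown takes no constant ({var!r})")
    elif op == "in_set":
        if not isinstance(value, list) or not value:
            raise ValidationError(f"rule {rule_id}: in_set on {var!r} needs a nonempty list")
        _check_enum_constants(rule_id, el, value)
        value = tuple(value)
    else:  # eq / ne
        if value is None:
            raise ValidationError(f"rule {rule_id}: {op!r} on {var!r} needs a constant")
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            _check_enum_constants(rule_id, el, [value])
    return Atom(var=var, op=op, value=value)


def _check_enum_constants(rule_id: str, el: DataElement, values) -> None:
    allowed = el.allowed
    if el.kind == "tri_state":
        allowed = ("yes", "no", "unknown")
    if allowed is not None:
        for v in values:
            if v not in allowed:
                raise ValidationError(
                    f"rule {rule_id}: constant {v!r} not an allowed value of {el.id!r}")


def parse_rulebase(source) -> Rulebase:
    """Parse and validate a rulebase from a path, YAML string or mapping."""
    if isinstance(source, dict):
        doc = source
    else:
        text = Path(source).read_text() if not str(source).lstrip().startswith(
            ("meta:", "{")) else str(source)
        doc = yaml.safe_load(text)
    if not isinstance(doc, dict):
        raise FormatError("rulebase document must be a mapping")
    for section in ("meta", "data_elements", "recommendations", "rules"):
        if section not in doc:
            raise FormatError(f"rulebase missing required section {section!r}")
    meta = dict(doc["meta"])
    if "age_coverage_months" not in meta:
        raise FormatError("meta.age_coverage_months is required")

    elements: dict[str, DataElement] = {}
    for rec in doc["data_elements"]:
        eid = rec.get("id")
        if eid is None:
            raise FormatError(f"data element without id: {rec!r}")
        if eid in elements:
            raise ValidationError(f"duplicate data element id {eid!r}")
        kind = rec.get("kind")
        if kind not in KINDS:
            raise ValidationError(f"data element {eid!r}: unknown kind {kind!r}")
        allowed = rec.get("allowed")
        if kind == "enumerated":
            if not allowed:
                raise ValidationError(f"enumerated data element {eid!r} needs 'allowed'")
            allowed = tuple(allowed)
        elif allowed is not None:
            allowed = tuple(allowed)
        elements[eid] = DataElement(id=eid, kind=kind, units=rec.get("units"), allowed=allowed)

    actions = {}
    for rec in doc.get("supportive_actions", []):
        if rec["id"] in actions:
            raise ValidationError(f"duplicate supportive action id {rec['id']!r}")
        if not rec.get("text"):
            raise ValidationError(f"supportive action {rec['id']!r} has empty text")
        actions[rec["id"]] = rec["text"]

    recommendations = {}
    for rec in doc["recommendations"]:
        if rec["id"] in recommendations:
            raise ValidationError(f"duplicate recommendation id {rec['id']!r}")
        if not rec.get("text"):
            raise ValidationError(f"recommendation {rec['id']!r} has empty text")
        recommendations[rec["id"]] = rec["text"]

    rules = []
    seen = set()
    for rec in doc["rules"]:
        rid = rec.get("id")
        if rid is None:
            raise FormatError(f"rule without id: {rec!r}")
        if rid in seen:
            raise ValidationError(f"duplicate rule id {rid!r}")
        seen.add(rid)
        domain = rec.get("domain")
        if domain not in DOMAINS:
            raise ValidationError(f"rule {rid}: unknown domain {domain!r}")
        band = rec.get("age_band")
        if not (isinstance(band, list) and len(band) == 2):
            raise FormatError(f"rule {rid}: age_band must be [lower, upper] in months")
        rec_id = rec.get("recommendation")
        if rec_id not in recommendations:
            raise ValidationError(f"rule {rid}: unknown recommendation id {rec_id!r}")
        grade = rec.get("grade")
        if grade not in GRADES:
            raise ValidationError(f"rule {rid}: malformed evidence grade {grade!r}")
        for a in rec.get("actions", []):
            if a not in actions:
                raise ValidationError(f"rule {rid}: unknown supportive action {a!r}")
        trigger = _parse_expr(rec["trigger"], rid, elements)
        rules.append(Rule(rule_id=rid, domain=domain,
                          age_band=AgeBand(float(band[0]), float(band[1])),
                          trigger=trigger, recommendation_id=rec_id, grade=grade,
                          actions=tuple(rec.get("actions", [])),
                          raw_trigger=rec["trigger"]))

    return Rulebase(meta=meta, elements=elements, recommendations=recommendations,
                    actions=actions, thresholds=dict(doc.get("thresholds", {})),
                    lipid_cutpoints=dict(doc.get("lipid_cutpoints", {})),
                    rules=tuple(rules))


def _expr_to_dict(expr):
    if isinstance(expr, TriggerNode):
        return {expr.kind: [_expr_to_dict(c) for c in expr.children]}
    d = {"var": expr.var, "op": expr.op}
    if expr.value is not None:
        d["value"] = list(expr.value) if isinstance(expr.value, tuple) else expr.value
    return d


def serialize_rulebase(rb: Rulebase) -> dict:
    """Plain mapping that re-parses to an equal rulebase (round-trip identity)."""
    return {
        "meta": dict(rb.meta),
        "thresholds": dict(rb.thresholds),
        "lipid_cutpoints": dict(rb.lipid_cutpoints),
        "data_elements": [
            {k: v for k, v in (("id", e.id), ("kind", e.kind), ("units", e.units),
                               ("allowed", list(e.allowed) if e.allowed else None))
             if v is not None}
            for e in rb.elements.values()],
        "supportive_actions": [{"id": k, "text": v} for k, v in rb.actions.items()],
        "recommendations": [{"id": k, "text": v} for k, v in rb.recommendations.items()],
        "rules": [
            {"id": r.rule_id, "domain": r.domain,
             "age_band": [r.age_band.lower, r.age_band.upper],
             "trigger": _expr_to_dict(r.trigger),
             "recommendation": r.recommendation_id, "grade": r.grade,
             **({"actions": list(r.actions)} if r.actions else {})}
            for r in rb.rules],
    }


def packaged_rulebase_path() -> Path:
    return Path(importlib.resources.files("pedcds") / "data" / "rulebase.yaml")


def packaged_rulebase() -> Rulebase:
    """The rulebase shipped with the package (representative guideline encoding)."""
    return parse_rulebase(packaged_rulebase_path())


# ---------------------------------------------------------------------------
# Age-band validation and the trigger matrix
# ---------------------------------------------------------------------------

@dataclass
class AgeBandReport:
    """Overlaps between same-trigger rules and coverage gaps, per group."""

    overlaps: list  # (rule_id_a, rule_id_b, AgeBand)
    gaps: list      # (domain, recommendation_id, AgeBand)

    @property
    def ok(self) -> bool:
        return not self.overlaps

    def to_text(self) -> str:
        lines = []
        for a, b, band in self.overlaps:
            lines.append(f"OVERLAP {a} / {b}: [{band.lower:g}, {band.upper:g}) months")
        for domain, rec, band in self.gaps:
            lines.append(f"GAP {domain}/{rec}: [{band.lower:g}, {band.upper:g}) months")
        return "\n".join(lines) if lines else "age bands: no overlaps, no gaps"

    def to_dict(self) -> dict:
        return {
            "overlaps": [{"rules": [a, b], "band": [x.lower, x.upper]}
                         for a, b, x in self.overlaps],
            "gaps": [{"domain": d, "recommendation": r, "band": [x.lower, x.upper]}
                     for d, r, x in self.gaps],
        }


def validate_age_bands(rules, coverage: AgeBand | None = None,
                       strict: bool = False) -> AgeBandReport:
    """Detect intersecting age bands among same-trigger rules, and coverage gaps.

    Two rules conflict when they share (domain, recommendation, trigger) but
    their half-open bands intersect — the failure mode the half-open-band
    convention exists to prevent.  Gaps are reported per (domain,
    recommendation) group as the complement of the group's band union within
    the declared coverage.  With ``strict=True`` any overlap raises.
    """
    groups: dict = {}
    for r in rules:
        groups.setdefault((r.domain, r.recommendation_id), []).append(r)
    overlaps = []
    gaps = []
    for (domain, rec_id), members in sorted(groups.items()):
        members = sorted(members, key=lambda r: (r.age_band, r.rule_id))
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                if a.trigger == b.trigger:
                    inter = a.age_band.intersection(b.age_band)
                    if inter is not None:
                        overlaps.append((a.rule_id, b.rule_id, inter))
        if coverage is not None:
            cursor = coverage.lower
            for band in sorted(r.age_band for r in members):
                if band.lower > cursor:
                    gaps.append((domain, rec_id, AgeBand(cursor, min(band.lower, coverage.upper))))
                cursor = max(cursor, band.upper)
                if cursor >= coverage.upper:
                    break
            if cursor < coverage.upper:
                gaps.append((domain, rec_id, AgeBand(cursor, coverage.upper)))
    report = AgeBandReport(overlaps=overlaps, gaps=gaps)
    if strict and overlaps:
        raise ValidationError("age-band overlaps found:\n" + report.to_text())
    return report


def trigger_atoms(expr):
    """Yield every atomic predicate in a trigger tree, left to right."""
    if isinstance(expr, Atom):
        yield expr
    else:
        for child in expr.children:
            yield from trigger_atoms(child)


def build_trigger_matrix(rules) -> pd.DataFrame:
    """Variable x recommendation incidence matrix.

    ``matrix.loc[v, r]`` is True iff variable ``v`` appears in the trigger of
    some rule recommending ``r``.
    """
    variables = sorted({a.var for r in rules for a in trigger_atoms(r.trigger)})
    recs = sorted({r.recommendation_id for r in rules})
    m = pd.DataFrame(False, index=variables, columns=recs)
    for r in rules:
        for a in trigger_atoms(r.trigger):
            m.loc[a.var, r.recommendation_id] = True
    m.index.name = "variable"
    return m
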