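"""Validation harness: boundary cases, single-expression tests, scenarios.

The harness reproduces a three-part validation methodology for guideline
rule sets:

1. **Boundary cases** — for every numeric boundary in the rulebase (trigger
   comparators *and* the two edges of each rule's age band) generate probes
   one whole unit below, at, and above the threshold, with every sibling
   condition held at a satisfying value, and record whether the rule must
   fire.  Cases are duplicated per tool context (a weight boundary is probed
   in the BMI tool, the lipid tool and the integrated screener alike).
2. **Single-expression runs** — execute each case through the real engine and
   require (a) the target rule's firing to match the recorded expectation and
   (b) no recommendation beyond those implied by the satisfying context.
3. **Scenarios** — full multi-domain sessions with an expected fired set that
   was computed once by the brute-force oracle and frozen to disk, so any
   behavioral drift in the engine is a reportable diff.

The brute-force oracle (:func:`oracle_fired_rules`) re-evaluates triggers by
explicit Kleene truth tables over raw trigger dictionaries, sharing no code
with the engine's evaluator; engine-vs-oracle equivalence over random
sessions is the package's core correctness property.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import importlib.resources
import numpy as np

from .engine import FIRE, run_assessment
from .errors import ValidationError
from .knowledge import (TOOL_CONTEXTS, Atom, Rule, Rulebase, TriggerNode, parse_rulebase,
                        serialize_rulebase, trigger_atoms)

__all__ = [
    "BoundaryCase",
    "Scenario",
    "Report",
    "generate_boundary_cases",
    "run_single_expression_tests",
    "generate_scenarios",
    "run_scenarios",
    "packaged_scenarios",
    "oracle_fired_rules",
    "random_session_facts",
    "numeric_boundary_census",
    "mutate_rulebase",
    "comparator_mutations",
]


# ---------------------------------------------------------------------------
# Brute-force oracle (independent of the engine)
# ---------------------------------------------------------------------------

# Kleene truth tables over {True, False, None}; evaluated by table lookup.
_K_AND = {(True, True): True, (True, False): False, (False, True): False,
          (False, False): False, (True, None): None, (None, True): None,
          (False, None): False, (None, False): False, (None, None): None}
_K_OR = {(True, True): True, (True, False): True, (False, True): True,
         (False, False): False, (True, None): True, (None, True): True,
         (False, None): None, (None, False): None, (None, None): None}


def _oracle_atom(node: dict, facts: dict):
    value = facts.get(node["var"])
    if node["op"] == "is_unknown":
        return value is None or value == "unknown"
    if value is None or value == "unknown":
        return None
    t = node.get("value")
    if node["op"] == "lt":
        return value < t
    if node["op"] == "le":
        return value <= t
    if node["op"] == "gt":
        return value > t
    if node["op"] == "ge":
        return value >= t
    if node["op"] == "eq":
        return value == t
    if node["op"] == "ne":
        return value != t
    if node["op"] == "in_set":
        return value in t
    raise ValidationError(f"oracle: unknown comparator {node['op']!r}")


def _oracle_expr(node: dict, facts: dict):
    if "all" in node:
        out = True
        for child in node["all"]:
            out = _K_AND[(out, _oracle_expr(child, facts))]
        return out
    if "any" in node:
        out = False
        for child in node["any"]:
            out = _K_OR[(out, _oracle_expr(child, facts))]
        return out
    return _oracle_atom(node, facts)


def oracle_fired_rules(facts: dict, rulebase: Rulebase,
                       context: str = "screener") -> set[str]:
    """Rule ids that definitively fire, by independent truth-table evaluation."""
    fired = set()
    age = facts.get("age_months")
    for rule in rulebase.rules:
        if context != "screener" and context not in TOOL_CONTEXTS[rule.domain]:
            continue
        if age is None or not (rule.age_band.lower <= age < rule.age_band.upper):
            continue
        if _oracle_expr(rule.raw_trigger, facts) is True:
            fired.add(rule.rule_id)
    return fired


def oracle_fired_recommendations(facts: dict, rulebase: Rulebase,
                                 context: str = "screener") -> set[str]:
    by_rule = {r.rule_id: r.recommendation_id for r in rulebase.rules}
    return {by_rule[rid] for rid in oracle_fired_rules(facts, rulebase, context)}


# ---------------------------------------------------------------------------
# Satisfying-context synthesis
# ---------------------------------------------------------------------------

def _satisfying_value(atom: Atom, rulebase: Rulebase, step: float):
    """A minimal value making one atom definitively true (None = leave absent)."""
    if atom.op == "is_unknown":
        return None
    if atom.op in ("ge", "le"):
        return atom.value
    if atom.op == "gt":
        return atom.value + step
    if atom.op == "lt":
        return atom.value - step
    if atom.op == "eq":
        return atom.value
    if atom.op == "in_set":
        return atom.value[0]
    if atom.op == "ne":
        el = rulebase.elements[atom.var]
        allowed = el.allowed or (("yes", "no", "unknown") if el.kind == "tri_state" else ())
        for v in allowed:
            if v != atom.value and v != "unknown":
                return v
        raise ValidationError(f"cannot satisfy ne on {atom.var!r}")
    raise ValidationError(f"unsupported comparator {atom.op!r}")


def _required_atoms(expr, target: Atom | None):
    """Atoms that must hold for the rule to fire through ``target``.

    All children of 'all' nodes on (or beside) the path are required; of an
    'any' node, only the branch containing the target (or the first branch,
    when the target lies elsewhere) is descended.  Returns None for branches
    not containing the target.
    """
    def contains(e, t):
        if e is t:
            return True
        return isinstance(e, TriggerNode) and any(contains(c, t) for c in e.children)

    def collect(e):
        if isinstance(e, Atom):
            return [e]
        if e.kind == "all":
            out = []
            for c in e.children:
                out.extend(collect(c))
            return out
        # 'any': descend only the target's branch, else the first child
        branch = next((c for c in e.children if target is not None and contains(c, target)),
                      e.children[0])
        return collect(branch)

    return collect(expr)


def satisfying_facts(rule: Rule, rulebase: Rulebase, step: float = 1.0,
                     target: Atom | None = None) -> dict:
    """Session facts under which the rule definitively fires.

    The probe atom (``target``) is included at its satisfying value; callers
    overwrite it with the probe value afterwards.  Age is pinned to the band's
    lower edge (its minimal satisfying value).
    """
    facts = {"age_months": float(rule.age_band.lower)}
    for atom in _required_atoms(rule.trigger, target):
        v = _satisfying_value(atom, rulebase, step)
        if v is not None:
            facts[atom.var] = v
    return facts


# ---------------------------------------------------------------------------
# Boundary-case generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoundaryCase:
    """One auto-generated single-expression probe."""

    case_id: str
    rule_id: str
    context: str
    variable: str
    probe: float
    provenance: str  # below_boundary / at_boundary / above_boundary
    expectation: str  # fire / no_fire
    facts: dict = field(compare=False)
    implied_recommendations: tuple[str, ...] = field(compare=False, default=())

    def to_dict(self) -> dict:
        return {"case_id": self.case_id, "rule_id": self.rule_id, "context": self.context,
                "variable": self.variable, "probe": self.probe,
                "provenance": self.provenance, "expectation": self.expectation,
                "facts": self.facts,
                "implied_recommendations": list(self.implied_recommendations)}


# expectation at (threshold - step, threshold, threshold + step) per comparator
_EXPECT = {
    "ge": (False, True, True),
    "gt": (False, False, True),
    "le": (True, True, False),
    "lt": (True, False, False),
}
_PROVENANCE = ("below_boundary", "at_boundary", "above_boundary")


def _numeric_probes(rule: Rule):
    """(label, variable, comparator, threshold) for every numeric boundary.

    Trigger atoms with numeric comparators, plus the age band's two edges
    (lower behaves like ``ge age_months``, upper like ``lt age_months``).
    """
    probes = []
    for i, atom in enumerate(trigger_atoms(rule.trigger)):
        if atom.op in _EXPECT:
            probes.append((f"t{i}", atom, atom.var, atom.op, float(atom.value)))
    probes.append(("band_lo", None, "age_months", "ge", rule.age_band.lower))
    probes.append(("band_hi", None, "age_months", "lt", rule.age_band.upper))
    return probes


def numeric_boundary_census(rulebase: Rulebase) -> int:
    """Number of (numeric boundary x applicable tool context) pairs.

    ``generate_boundary_cases`` emits exactly three cases per pair.
    """
    return sum(len(_numeric_probes(r)) * len(TOOL_CONTEXTS[r.domain])
               for r in rulebase.rules)


def generate_boundary_cases(rulebase: Rulebase, step: float = 1.0) -> list[BoundaryCase]:
    """At/below/above probes for every numeric boundary, per tool context.

    Deterministic given the rulebase and step policy.  The expectation is
    derived from comparator semantics alone (inclusive-upward convention);
    the recommendations implied by the satisfying context are frozen from the
    brute-force oracle so the single-expression runner can detect spurious
    extra firings.
    """
    cases = []
    for rule in rulebase.rules:
        for label, atom, var, op, threshold in _numeric_probes(rule):
            base = satisfying_facts(rule, rulebase, step, target=atom)
            expectations = _EXPECT[op]
            for provenance, offset, expected in zip(
                    _PROVENANCE, (-step, 0.0, step), expectations):
                probe = threshold + offset
                facts = dict(base)
                facts[var] = probe
                for context in TOOL_CONTEXTS[rule.domain]:
                    implied = sorted(oracle_fired_recommendations(facts, rulebase, context)
                                     - {rule.recommendation_id})
                    cases.append(BoundaryCase(
                        case_id=f"{rule.rule_id}:{label}:{provenance}:{context}",
                        rule_id=rule.rule_id, context=context, variable=var,
                        probe=probe, provenance=provenance,
                        expectation=FIRE if expected else "no_fire",
                        facts=facts, implied_recommendations=tuple(implied)))
    return cases


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

@dataclass
class Report:
    """Outcome of a validation run; renders as text or JUnit-style XML."""

    kind: str
    total: int
    failures: list = field(default_factory=list)
    skipped: int = 0

    @property
    def passed(self) -> int:
        return self.total - len(self.failures)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_text(self) -> str:
        lines = [f"{self.kind}: {self.passed}/{self.total} passed"
                 + (f", {self.skipped} skipped" if self.skipped else "")]
        for f in self.failures:
            lines.append(f"  FAIL {f['id']}: {f['detail']}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"kind": self.kind, "total": self.total, "passed": self.passed,
                "skipped": self.skipped, "failures": self.failures}

    def to_junit_xml(self) -> str:
        suite = ET.Element("testsuite", name=self.kind, tests=str(self.total),
                           failures=str(len(self.failures)), skipped=str(self.skipped))
        failed = {f["id"]: f["detail"] for f in self.failures}
        for f_id, detail in failed.items():
            case = ET.SubElement(suite, "testcase", name=f_id)
            ET.SubElement(case, "failure", message=detail)
        return ET.tostring(suite, encoding="unicode")


def run_single_expression_tests(rulebase: Rulebase, cases: list[BoundaryCase]) -> Report:
    """Execute each boundary case through the engine and check it.

    A case passes iff the target rule's firing matches the recorded
    expectation and no non-target recommendation fires beyond those the
    satisfying context implies.
    """
    report = Report(kind="single_expression", total=len(cases))
    for case in cases:
        result = run_assessment(case.facts, rulebase, context=case.context)
        fired_rules = {rid for f in result.fired for rid in f.rule_ids}
        target_fired = case.rule_id in fired_rules
        expected_fired = case.expectation == FIRE
        detail = None
        if target_fired != expected_fired:
            detail = (f"rule {case.rule_id} {'fired' if target_fired else 'did not fire'} "
                      f"at {case.variable}={case.probe} ({case.provenance}); expected "
                      f"{case.expectation}")
        else:
            target_rec = next(r.recommendation_id for r in rulebase.rules
                              if r.rule_id == case.rule_id)
            allowed = set(case.implied_recommendations) | {target_rec}
            extra = set(result.recommendation_ids()) - allowed
            if extra:
                detail = f"unexpected recommendations beyond context: {sorted(extra)}"
        if detail:
            report.failures.append({"id": case.case_id, "detail": detail})
    return report


# ---------------------------------------------------------------------------
# Random sessions and scenarios
# ---------------------------------------------------------------------------

def _numeric_ranges(rulebase: Rulebase) -> dict[str, tuple[float, float]]:
    """Sampling range per numeric variable: thresholds widened by 20 units."""
    ranges: dict[str, list[float]] = {}
    for rule in rulebase.rules:
        for atom in trigger_atoms(rule.trigger):
            if atom.op in _EXPECT:
                ranges.setdefault(atom.var, []).append(float(atom.value))
    return {var: (max(0.0, min(v) - 20.0), max(v) + 20.0) for var, v in ranges.items()}


def random_session_facts(rulebase: Rulebase, rng: np.random.Generator,
                         p_missing: float = 0.35) -> dict:
    """One random session spanning the rulebase's whole trigger space.

    Each declared variable is independently missing with probability
    ``p_missing``; numeric values are drawn around the thresholds the rules
    actually use (with a point mass on the exact thresholds so boundaries are
    exercised), enumerated and tri-state values uniformly over their allowed
    sets including "unknown".
    """
    lo, hi = rulebase.age_coverage.lower, rulebase.age_coverage.upper
    facts = {"age_months": float(np.round(rng.uniform(lo, hi), 2))}
    ranges = _numeric_ranges(rulebase)
    thresholds = {var: sorted({float(a.value) for r in rulebase.rules
                               for a in trigger_atoms(r.trigger)
                               if a.var == var and a.op in _EXPECT})
                  for var in ranges}
    for el in rulebase.elements.values():
        if el.id in ("age_months", "age_years", "dob", "encounter_date"):
            continue
        if rng.random() < p_missing:
            continue
        if el.kind == "numeric":
            if el.id not in ranges:
                continue
            a, b = ranges[el.id]
            if rng.random() < 0.15:  # probe an exact threshold
                facts[el.id] = float(rng.choice(thresholds[el.id]))
            else:
                facts[el.id] = float(np.round(rng.uniform(a, b), 1))
        elif el.kind == "tri_state":
            facts[el.id] = str(rng.choice(["yes", "no", "unknown"]))
        elif el.kind == "enumerated":
            facts[el.id] = str(rng.choice(list(el.allowed)))
    return facts


@dataclass(frozen=True)
class Scenario:
    """A full multi-domain session with a frozen expected fired set."""

    scenario_id: str
    facts: dict
    expected_recommendations: tuple[str, ...]

    def to_dict(self) -> dict:
        return {"scenario_id": self.scenario_id, "facts": self.facts,
                "expected_recommendations": list(self.expected_recommendations)}

    @classmethod
    def from_dict(cls, d: dict) -> "Scenario":
        return cls(scenario_id=d["scenario_id"], facts=dict(d["facts"]),
                   expected_recommendations=tuple(d["expected_recommendations"]))


def _handcrafted_scenarios() -> list[dict]:
    return [
        {"scenario_id": "HC-all-unknown", "facts": {"age_months": 96.0}},
        {"scenario_id": "HC-obese-adolescent-smoker",
         "facts": {"age_months": 180.0, "sex": "male", "bmi_percentile": 96.5,
                   "bmi_change_category": "excessive_increase", "smokes": "yes",
                   "smoke_free_home": "no", "activity_level": "sedentary"}},
        {"scenario_id": "HC-dyslipidemia-fasting-panel",
         "facts": {"age_months": 150.0, "sex": "female", "sample_type": "fasting",
                   "total_cholesterol": 215.0, "ldl": 141.0, "hdl": 38.0,
                   "non_hdl": 177.0, "triglycerides": 180.0,
                   "has_dyslipidemia": "yes", "dyslipidemia_trend": "not_improving"}},
        {"scenario_id": "HC-stage2-bp-obesity",
         "facts": {"age_months": 130.0, "sex": "male", "systolic_bp_percentile": 99.2,
                   "diastolic_bp_percentile": 96.0, "bmi_percentile": 97.5,
                   "mean_systolic": 132.0, "mean_diastolic": 88.0}},
        {"scenario_id": "HC-family-history-screen",
         "facts": {"age_months": 110.0, "sex": "female", "family_history_cvd": "yes",
                   "parent_dyslipidemia": "yes", "mother_tc": 244.0,
                   "father_tc": 205.0, "bmi_percentile": 88.0}},
    ]


def generate_scenarios(rulebase: Rulebase, n_random: int = 70, seed: int = 7) -> list[Scenario]:
    """Handcrafted plus seeded-random scenarios with oracle-frozen expectations."""
    rng = np.random.default_rng(seed)
    docs = list(_handcrafted_scenarios())
    for i in range(n_random):
        docs.append({"scenario_id": f"RS-{i:03d}",
                     "facts": random_session_facts(rulebase, rng)})
    out = []
    for doc in docs:
        expected = sorted(oracle_fired_recommendations(doc["facts"], rulebase, "screener"))
        out.append(Scenario(scenario_id=doc["scenario_id"], facts=doc["facts"],
                            expected_recommendations=tuple(expected)))
    return out


def run_scenarios(rulebase: Rulebase, scenarios: list[Scenario]) -> Report:
    """Engine fired set vs each scenario's frozen expected set."""
    report = Report(kind="scenarios", total=len(scenarios))
    for sc in scenarios:
        result = run_assessment(sc.facts, rulebase, context="screener")
        got = set(result.recommendation_ids())
        expected = set(sc.expected_recommendations)
        if got != expected:
            report.failures.append({
                "id": sc.scenario_id,
                "detail": f"missing={sorted(expected - got)} extra={sorted(got - expected)}"})
    return report


def packaged_scenarios() -> list[Scenario]:
    """The frozen scenario suite shipped with the package."""
    path = importlib.resources.files("pedcds") / "data" / "scenarios.json"
    return [Scenario.from_dict(d) for d in json.loads(path.read_text())]


def save_scenarios(scenarios: list[Scenario], path) -> None:
    with open(path, "w") as fh:
        for i, s in enumerate(scenarios):  # one compact line per scenario
            fh.write(("[" if i == 0 else ",\n") +
                     json.dumps(s.to_dict(), sort_keys=True, separators=(",", ":")))
        fh.write("]\n")


# ---------------------------------------------------------------------------
# Mutation testing
# ---------------------------------------------------------------------------

_COMPARATOR_SWAP = {"ge": "gt", "gt": "ge", "le": "lt", "lt": "le"}


def comparator_mutations(rulebase: Rulebase):
    """All single mutations: comparator swap, boundary +1, boundary -1.

    Yields (rule_id, atom_index, mutation_label, mutated_rulebase_dict) for
    every numeric trigger atom.
    """
    for rule in rulebase.rules:
        for i, atom in enumerate(trigger_atoms(rule.trigger)):
            if atom.op not in _COMPARATOR_SWAP:
                continue
            yield (rule.rule_id, i, f"{atom.op}->{_COMPARATOR_SWAP[atom.op]}",
                   mutate_rulebase(rulebase, rule.rule_id, i, op=_COMPARATOR_SWAP[atom.op]))
            for delta in (1.0, -1.0):
                yield (rule.rule_id, i, f"boundary{delta:+g}",
                       mutate_rulebase(rulebase, rule.rule_id, i, value=atom.value + delta))


def mutate_rulebase(rulebase: Rulebase, rule_id: str, atom_index: int,
                    op: str | None = None, value=None) -> Rulebase:
    """A copy of the rulebase with one atom's comparator or threshold changed."""
    doc = serialize_rulebase(rulebase)
    for rec in doc["rules"]:
        if rec["id"] != rule_id:
            continue
        counter = [0]

        def visit(node):
            if "all" in node or "any" in node:
                kind = "all" if "all" in node else "any"
                for child in node[kind]:
                    visit(child)
                return
            if counter[0] == atom_index:
                if op is not None:
                    node["op"] = op
                if value is not None:
                    node["value"] = value
            counter[0] += 1

        visit(rec["trigger"])
    return parse_rulebase(doc)
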