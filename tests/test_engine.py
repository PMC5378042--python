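"""Three-valued evaluation, session carry-over, dedup and determinism."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, strategies as st

from pedcds import engine, validation
from pedcds.blood_pressure import BPEntry
from pedcds.errors import ContradictionError, DuplicateEntryError, MissingInputError
from pedcds.knowledge import Atom
from pedcds.lipids import LipidPanel


class TestKleeneAtoms:
    def test_definite_match_fires(self):
        assert engine.eval_atom(Atom("smokes", "eq", "yes"), {"smokes": "yes"}) is True

    def test_unknown_value_is_indeterminate(self):
        assert engine.eval_atom(Atom("smokes", "eq", "yes"), {"smokes": "unknown"}) is None
        assert engine.eval_atom(Atom("smokes", "eq", "yes"), {}) is None

    def test_is_unknown_targets_missingness(self):
        atom = Atom("smokes", "is_unknown")
        assert engine.eval_atom(atom, {}) is True
        assert engine.eval_atom(atom, {"smokes": "unknown"}) is True
        assert engine.eval_atom(atom, {"smokes": "no"}) is False

    def test_trigger_levels(self, rulebase):
        rule = next(r for r in rulebase.rules if r.rule_id == "TB-002")
        assert engine.eval_trigger(rule.trigger, {"smokes": "yes"}) == engine.FIRE
        assert engine.eval_trigger(rule.trigger, {"smokes": "no"}) == engine.NO_FIRE
        assert engine.eval_trigger(rule.trigger, {}) == engine.INDETERMINATE


class TestRunAssessment:
    def test_single_matching_rule_fires_alone(self, rulebase):
        result = engine.run_assessment(
            {"age_months": 50.0, "other_risk_conditions": "yes"}, rulebase)
        (rec,) = result.fired
        assert rec.recommendation_id == "R-RC-OTHER"
        assert rec.grade == "C"
        assert rec.rule_ids == ("RC-003",)

    def test_age_outside_every_band_fires_nothing(self, rulebase):
        result = engine.run_assessment(
            {"age_months": 400.0, "smokes": "yes", "bmi_percentile": 99.0}, rulebase)
        assert result.fired == ()

    def test_age_is_required(self, rulebase):
        with pytest.raises(MissingInputError):
            engine.run_assessment({"smokes": "yes"}, rulebase)

    def test_unknowns_never_fire_definite_rules(self, rulebase):
        facts = {"age_months": 150.0,
                 **{el: "unknown" for el in ("smokes", "smoke_free_home", "parent_obese",
                                             "family_history_cvd", "activity_level")}}
        assert engine.run_assessment(facts, rulebase).fired == ()

    def test_domain_order_then_rule_id(self, rulebase):
        facts = {"age_months": 150.0, "smokes": "yes", "bmi_percentile": 96.0,
                 "family_history_cvd": "yes", "systolic_bp_percentile": 99.5}
        result = engine.run_assessment(facts, rulebase)
        domains = []
        rank = {d: i for i, d in enumerate(
            ("family_history", "nutrition_diet", "physical_activity", "tobacco_exposure",
             "lipids", "overweight_obesity", "blood_pressure", "other_risk_condition"))}
        by_rule = {r.rule_id: r.domain for r in rulebase.rules}
        for rec in result.fired:
            domains.append(min(rank[by_rule[rid]] for rid in rec.rule_ids))
        assert domains == sorted(domains)

    def test_byte_identical_json_for_identical_sessions(self, rulebase, library):
        session = _full_session()
        a = engine.run_assessment(session, rulebase, library).to_json()
        b = engine.run_assessment(_full_session(), rulebase, library).to_json()
        assert a == b

    def test_module_context_filters_domains(self, rulebase):
        facts = {"age_months": 150.0, "smokes": "yes", "bmi_percentile": 96.0}
        screener = engine.run_assessment(facts, rulebase, context="screener")
        bmi_only = engine.run_assessment(facts, rulebase, context="bmi")
        assert set(bmi_only.recommendation_ids()) <= set(screener.recommendation_ids())
        assert "R-TB-QUIT" in screener.recommendation_ids()
        assert "R-TB-QUIT" not in bmi_only.recommendation_ids()

    def test_fact_addition_never_retracts_unrelated_firing(self, rulebase, rng):
        """Adding a fact flips only rules whose triggers mention it."""
        for _ in range(100):
            facts = validation.random_session_facts(rulebase, rng)
            fired_before = validation.oracle_fired_rules(facts, rulebase)
            new_var = "other_risk_conditions"
            facts2 = dict(facts)
            facts2[new_var] = "yes"
            fired_after = {rid for f in engine.run_assessment(facts2, rulebase).fired
                           for rid in f.rule_ids}
            from pedcds.knowledge import trigger_atoms
            for rule in rulebase.rules:
                mentions = any(a.var == new_var for a in trigger_atoms(rule.trigger))
                if not mentions and rule.rule_id in fired_before:
                    assert rule.rule_id in fired_after


class TestDedup:
    def test_actions_union_preserves_first_seen_order(self, rulebase):
        rules = [r for r in rulebase.rules if r.rule_id in ("OB-002", "ND-002")]
        facts = {"age_months": 60.0, "bmi_percentile": 96.0}
        result = engine.run_assessment(facts, rulebase)
        obese = next(f for f in result.fired if f.recommendation_id == "R-OB-OBESE")
        assert obese.rule_ids == ("OB-002",)
        assert [a for a, _ in obese.supportive_actions] == \
            ["SA-WEIGHT-PROGRAM", "SA-FOLLOWUP-6MO"]

    def test_same_recommendation_from_two_rules_collapses(self, rulebase):
        facts = {"age_months": 60.0, "mother_tc": 250.0, "father_tc": 250.0}
        result = engine.run_assessment(facts, rulebase)
        (rec,) = [f for f in result.fired if f.recommendation_id == "R-FH-PARENT-TC"]
        assert rec.rule_ids == ("FH-003", "FH-004")

    def test_idempotent_and_matches_group_by(self, rulebase, rng):
        rules = list(rulebase.rules)
        for _ in range(300):
            hits = [rules[i] for i in rng.integers(0, len(rules),
                                                   size=rng.integers(0, 12))]
            out = engine.dedup(hits, rulebase)
            again = engine.dedup(
                [r for f in out for r in rules if r.rule_id in f.rule_ids], rulebase)
            assert [f.recommendation_id for f in again] == \
                [f.recommendation_id for f in out]
            # brute-force group-by oracle
            seen, order = {}, []
            for h in hits:
                if h.recommendation_id not in seen:
                    seen[h.recommendation_id] = []
                    order.append(h.recommendation_id)
                if h.rule_id not in seen[h.recommendation_id]:
                    seen[h.recommendation_id].append(h.rule_id)
            assert [f.recommendation_id for f in out] == order
            assert {f.recommendation_id: list(f.rule_ids) for f in out} == seen


def _full_session():
    return engine.PatientSession(
        anthropometrics=engine.Anthropometrics(
            dob=dt.date(2004, 4, 2), encounter_date=dt.date(2016, 5, 10), sex="male",
            height=1.52, weight=62.0, bmi_change_category="excessive_increase"),
        bp=BPEntry(readings=[(128, 83), (126, 81)], method="oscillometry"),
        lipid_panel=LipidPanel(sample_type="fasting", total_cholesterol=212,
                               hdl=39, ldl=138, triglycerides=145),
        risk=engine.RiskFactorProfile(conditions=("none",), activity_level="sedentary",
                                      smokes="no", smoke_free_home="no",
                                      parent_obese="yes", family_history_cvd="yes"))


class TestSession:
    def test_enter_once_enforced(self):
        s = engine.PatientSession()
        s.enter(sex="male")
        with pytest.raises(DuplicateEntryError):
            s.enter(sex="female")

    def test_none_of_these_contradicts_named_condition(self):
        with pytest.raises(ContradictionError):
            engine.RiskFactorProfile(conditions=("none", "t1dm"))

    def test_condition_subset_derives_tristate_facts(self, rulebase):
        s = engine.PatientSession(risk=engine.RiskFactorProfile(conditions=("t1dm",)))
        s.anthropometrics = engine.Anthropometrics(
            dob=dt.date(2010, 1, 1), encounter_date=dt.date(2016, 1, 1))
        facts = s.facts()
        assert facts["has_t1dm"] == "yes"
        assert facts["has_t2dm"] == "no"

    def test_screener_pair_counts_as_one_reading_until_superseded(self):
        s = engine.PatientSession(screener_bp=(118.0, 76.0))
        facts = s.facts()
        assert facts["mean_systolic"] == 118.0
        s.bp = BPEntry(readings=[(120, 78), (124, 82)])
        assert s.facts()["mean_systolic"] == 122.0

    def test_clear_then_reenter_reproduces_result(self, rulebase, library):
        s = _full_session()
        first = engine.run_assessment(s, rulebase, library).to_json()
        engine.clear_session(s)
        assert s.facts(library, rulebase) == {}
        assert s.to_dict() == {}
        s2 = _full_session()
        assert engine.run_assessment(s2, rulebase, library).to_json() == first

    def test_clear_is_idempotent(self):
        s = engine.PatientSession()
        assert engine.clear_session(engine.clear_session(s)).to_dict() == {}

    def test_round_trip_through_dict(self, rulebase, library):
        s = _full_session()
        back = engine.PatientSession.from_dict(s.to_dict())
        assert back.facts(library, rulebase) == s.facts(library, rulebase)
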