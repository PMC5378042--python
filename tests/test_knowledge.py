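"""Rulebase parsing, age-band validation and the trigger matrix."""

import itertools

import pytest

from pedcds import knowledge as kn
from pedcds.errors import ValidationError


def minimal_doc(**overrides):
    doc = {
        "meta": {"name": "mini", "age_coverage_months": [0, 252]},
        "data_elements": [{"id": "smokes", "kind": "tri_state"},
                          {"id": "bmi_percentile", "kind": "numeric", "units": "percentile"}],
        "recommendations": [{"id": "R1", "text": "Counsel the patient."}],
        "rules": [{"id": "T-001", "domain": "tobacco_exposure", "age_band": [0, 252],
                   "trigger": {"var": "smokes", "op": "eq", "value": "yes"},
                   "recommendation": "R1", "grade": "B"}],
    }
    doc.update(overrides)
    return doc


class TestParsing:
    def test_minimal_rulebase_parses(self):
        rb = kn.parse_rulebase(minimal_doc())
        assert len(rb.rules) == 1
        assert rb.rules[0].grade == "B"

    def test_undeclared_variable_named_in_error(self):
        doc = minimal_doc()
        doc["rules"][0]["trigger"] = {"var": "vaping", "op": "eq", "value": "yes"}
        with pytest.raises(ValidationError, match="T-001.*'vaping'"):
            kn.parse_rulebase(doc)

    def test_unknown_recommendation_rejected(self):
        doc = minimal_doc()
        doc["rules"][0]["recommendation"] = "R9"
        with pytest.raises(ValidationError, match="R9"):
            kn.parse_rulebase(doc)

    def test_malformed_grade_rejected(self):
        doc = minimal_doc()
        doc["rules"][0]["grade"] = "Z"
        with pytest.raises(ValidationError, match="grade"):
            kn.parse_rulebase(doc)

    def test_numeric_comparator_on_enumerated_variable_rejected(self):
        doc = minimal_doc()
        doc["rules"][0]["trigger"] = {"var": "smokes", "op": "ge", "value": 1}
        with pytest.raises(ValidationError, match="non-numeric"):
            kn.parse_rulebase(doc)

    def test_round_trip_is_identity_on_shipped_rulebase(self, rulebase):
        again = kn.parse_rulebase(kn.serialize_rulebase(rulebase))
        assert again.rules == rulebase.rules
        assert again.elements == rulebase.elements
        assert again.recommendations == rulebase.recommendations


class TestShippedRulebase:
    def test_every_domain_and_comparator_represented(self, rulebase):
        assert len(rulebase.rules) >= 40
        assert {r.domain for r in rulebase.rules} == set(kn.DOMAIN_ORDER)
        ops = {a.op for r in rulebase.rules for a in kn.trigger_atoms(r.trigger)}
        assert {"eq", "lt", "le", "gt", "ge", "in_set", "is_unknown"} <= ops

    @pytest.mark.parametrize("element,options", [
        ("bmi_change_category", ("stable", "improvement", "increase",
                                 "excessive_increase", "no_improvement", "unknown")),
        ("activity_level", ("sedentary", "moderate_to_vigorous", "vigorous", "unknown")),
        ("bp_method", ("auscultation", "oscillometry", "unknown")),
        ("sample_type", ("fasting", "nonfasting", "unknown")),
    ])
    def test_screener_response_options_declared(self, rulebase, element, options):
        assert rulebase.elements[element].allowed == options

    def test_no_age_band_overlaps(self, rulebase):
        report = kn.validate_age_bands(rulebase.rules, rulebase.age_coverage)
        assert report.overlaps == []


def make_rule(rule_id, band, trigger_value="yes", rec="R1"):
    return kn.parse_rulebase(minimal_doc(rules=[
        {"id": rule_id, "domain": "tobacco_exposure", "age_band": list(band),
         "trigger": {"var": "smokes", "op": "eq", "value": trigger_value},
         "recommendation": rec, "grade": "B"}])).rules[0]


class TestAgeBands:
    def test_touching_half_open_bands_do_not_overlap(self):
        rules = [make_rule("A", (0, 36)), make_rule("B", (36, 132))]
        assert kn.validate_age_bands(rules).overlaps == []

    def test_same_trigger_intersection_reported(self):
        rules = [make_rule("A", (0, 38)), make_rule("B", (36, 132))]
        (a, b, band), = kn.validate_age_bands(rules).overlaps
        assert {a, b} == {"A", "B"}
        assert (band.lower, band.upper) == (36, 38)

    def test_different_triggers_do_not_conflict(self):
        rules = [make_rule("A", (0, 38)), make_rule("B", (36, 132), trigger_value="no")]
        assert kn.validate_age_bands(rules).overlaps == []

    def test_gap_within_declared_coverage_reported(self):
        rules = [make_rule("A", (0, 36)), make_rule("B", (48, 252))]
        report = kn.validate_age_bands(rules, kn.AgeBand(0, 252))
        (domain, rec, band), = report.gaps
        assert (band.lower, band.upper) == (36, 48)

    def test_strict_mode_escalates_overlaps(self):
        rules = [make_rule("A", (0, 38)), make_rule("B", (36, 132))]
        with pytest.raises(ValidationError):
            kn.validate_age_bands(rules, strict=True)

    def test_matches_pairwise_brute_force_on_random_band_sets(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 10))
            rules = []
            for i in range(n):
                lo = float(rng.integers(0, 240))
                hi = lo + float(rng.integers(1, 60))
                rules.append(make_rule(f"R{i:02d}", (lo, hi)))
            got = {frozenset((a, b)) for a, b, _ in kn.validate_age_bands(rules).overlaps}
            expected = set()
            for a, b in itertools.combinations(rules, 2):
                if max(a.age_band.lower, b.age_band.lower) < \
                        min(a.age_band.upper, b.age_band.upper):
                    expected.add(frozenset((a.rule_id, b.rule_id)))
            assert got == expected


class TestTriggerMatrix:
    def test_single_rule_single_cell(self):
        rb = kn.parse_rulebase(minimal_doc())
        m = kn.build_trigger_matrix(rb.rules)
        assert m.loc["smokes", "R1"]
        assert m.values.sum() == 1

    def test_conjunction_marks_both_variables(self):
        doc = minimal_doc()
        doc["rules"][0]["trigger"] = {"all": [
            {"var": "smokes", "op": "eq", "value": "yes"},
            {"var": "bmi_percentile", "op": "ge", "value": 85}]}
        m = kn.build_trigger_matrix(kn.parse_rulebase(doc).rules)
        assert m.loc["smokes", "R1"] and m.loc["bmi_percentile", "R1"]

    def test_matrix_equals_brute_force_tree_walk(self, rulebase):
        m = kn.build_trigger_matrix(rulebase.rules)
        for var in m.index:
            for rec in m.columns:
                expected = any(
                    any(a.var == var for a in kn.trigger_atoms(r.trigger))
                    for r in rulebase.rules if r.recommendation_id == rec)
                assert bool(m.loc[var, rec]) == expected
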