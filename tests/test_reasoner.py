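"""Reasoner tests: normalization worked examples, fixture inferences,
equivalence with the naive fixpoint oracle, and the soundness /
monotonicity / idempotence properties."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from muscle_logic import (
    Curie,
    Existential,
    Named,
    NoEntailmentError,
    Ontology,
    OntologyClass,
    SubClassOf,
    classify,
    entails,
    explain,
    loads_obo,
)
from muscle_logic.fixture import ARCH2, DEVELOPS_FROM, INNERVATED_BY, TRIGEMINAL_NERVE
from muscle_logic.model import ObjectProperty, conjunction_of, EquivalentTo
from muscle_logic.obo import dumps_obo
from muscle_logic.reasoner import NF1, NF2, NF3, NF4, normalize, saturate

from .ontgen import random_ontology
from .oracles import (
    graph_transitive_closure,
    naive_saturate,
    package_subsumers,
    replay_trace,
)


def _ontology_with(axioms, n_classes=4, n_props=2, transitive=()):
    onto = Ontology()
    for i in range(n_classes):
        onto.add_class(OntologyClass(Curie("C", str(i)), f"c{i}"))
    for i in range(n_props):
        onto.add_property(
            ObjectProperty(Curie("P", str(i)), f"p{i}", is_transitive=i in transitive)
        )
    onto.axioms.extend(axioms)
    onto.validate()
    return onto


class TestNormalize:
    def test_named_subclass_is_already_normal(self):
        onto = _ontology_with([SubClassOf(Named(Curie("C", "0")), Named(Curie("C", "1")))])
        assert normalize(onto) == [NF1(Curie("C", "0"), Curie("C", "1"))]

    def test_three_existential_definition_yields_eight_normal_axioms(self, fixture_onto):
        """A definition ≡ ∃r1.A ⊓ ∃r2.B ⊓ ∃r2.C normalizes to 3 NF3
        (necessary direction), 3 NF4 introducing fresh names, and 2 NF2
        binarizing the conjunction back (hand-derived count)."""
        styl = fixture_onto.resolve_label("styloglossus muscle")
        defs = [
            a
            for a in fixture_onto.axioms
            if isinstance(a, EquivalentTo) and a.cls == styl
        ]
        onto = Ontology(
            classes=fixture_onto.classes,
            properties=fixture_onto.properties,
            axioms=defs,
        )
        normal = normalize(onto)
        kinds = sorted(type(a).__name__ for a in normal)
        assert kinds == ["NF2", "NF2", "NF3", "NF3", "NF3", "NF4", "NF4", "NF4"]

    def test_gci_splits_into_nf4_plus_nf3_with_one_fresh_name(self):
        """∃innervated_by.N ⊑ ∃develops_from.A becomes NF4 then NF3
        through a single fresh intermediate (hand-derived)."""
        onto = _ontology_with(
            [
                SubClassOf(
                    Existential(Curie("P", "0"), Named(Curie("C", "0"))),
                    Existential(Curie("P", "1"), Named(Curie("C", "1"))),
                )
            ]
        )
        normal = normalize(onto)
        assert len(normal) == 2
        nf4 = next(a for a in normal if isinstance(a, NF4))
        nf3 = next(a for a in normal if isinstance(a, NF3))
        assert nf4.prop == Curie("P", "0") and nf4.filler == Curie("C", "0")
        assert nf3.prop == Curie("P", "1") and nf3.filler == Curie("C", "1")
        assert nf4.sup == nf3.sub and nf4.sup.prefix == "_"  # the fresh name

    def test_output_is_deterministic(self, fixture_onto):
        assert normalize(fixture_onto) == normalize(fixture_onto)


class TestSaturate:
    def test_no_axioms_gives_reflexive_top_only(self):
        onto = _ontology_with([])
        sat = classify(onto)
        for cls in onto.classes:
            assert sat.subsumers_of(cls) == frozenset({cls})
        assert all(not pairs for pairs in sat.role_pairs.values())

    def test_epiphysis_of_digit_is_classified_under_epiphysis_of_hand(
        self, fixture_onto, fixture_sat
    ):
        eod = fixture_onto.resolve_label("epiphysis of digit")
        eoh = fixture_onto.resolve_label("epiphysis of hand")
        assert fixture_sat.is_entailed(eod, eoh)
        # and the nested case: distal phalanx under digit
        eop = fixture_onto.resolve_label("epiphysis of distal phalanx")
        assert fixture_sat.is_entailed(eop, eod)

    def test_posterior_digastric_develops_from_arch_2_via_innervation(
        self, fixture_onto
    ):
        pd = fixture_onto.resolve_label("posterior digastric muscle")
        assert entails(
            fixture_onto, Named(pd), Existential(DEVELOPS_FROM, Named(ARCH2))
        )
        # the facial-nerve innervation is the only route: no direct axiom
        direct = [
            a
            for a in fixture_onto.axioms
            if isinstance(a, SubClassOf)
            and a.sub == Named(pd)
            and isinstance(a.sup, Existential)
            and a.sup.prop == DEVELOPS_FROM
        ]
        assert direct == []

    def test_anterior_digastric_is_a_trigeminal_muscle_but_geniohyoid_is_not(
        self, fixture_onto, fixture_sat
    ):
        tm = fixture_onto.resolve_label("trigeminal muscle")
        ad = fixture_onto.resolve_label("anterior digastric muscle")
        gh = fixture_onto.resolve_label("geniohyoid muscle")
        assert fixture_sat.is_entailed(ad, tm)
        assert not fixture_sat.is_entailed(gh, tm)

    def test_identical_definitions_share_an_equivalence_group(self):
        body = Existential(Curie("P", "0"), Named(Curie("C", "2")))
        onto = _ontology_with(
            [
                EquivalentTo(Curie("C", "0"), body),
                EquivalentTo(Curie("C", "1"), body),
            ]
        )
        sat = classify(onto)
        assert sat.group_of(Curie("C", "0")) == frozenset(
            {Curie("C", "0"), Curie("C", "1")}
        )

    def test_transitive_role_closure_matches_graph_closure(self, fixture_sat):
        """For a transitive property the reported pairs over original
        classes equal the graph-transitive closure of the one-step pairs."""
        from muscle_logic.fixture import PART_OF

        pairs = fixture_sat.role_closure(PART_OF)
        assert pairs == graph_transitive_closure(pairs)
        assert len(pairs) > 0


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(40))
    def test_subsumers_match_naive_fixpoint(self, seed):
        onto = random_ontology(seed)
        assert package_subsumers(onto) == naive_saturate(onto)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(min_value=1000, max_value=10**6))
    def test_subsumers_match_naive_fixpoint_hypothesis(self, seed):
        onto = random_ontology(seed)
        assert package_subsumers(onto) == naive_saturate(onto)


class TestProperties:
    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10**6))
    def test_monotonicity_adding_an_axiom_never_removes_subsumptions(self, seed):
        onto = random_ontology(seed, max_axioms=30)
        before = package_subsumers(onto)
        import random as _random

        rng = _random.Random(seed ^ 0xBEEF)
        classes = sorted(onto.classes, key=str)
        onto.axioms.append(
            SubClassOf(Named(rng.choice(classes)), Named(rng.choice(classes)))
        )
        after = package_subsumers(onto)
        for cls, subsumers in before.items():
            assert subsumers <= after[cls]

    @pytest.mark.parametrize("seed", [3, 11, 42])
    def test_idempotence_reclassifying_serialized_closure_is_stable(self, seed):
        """Materializing every entailed is_a pair and reclassifying the
        serialized result reports the same subsumer sets."""
        onto = random_ontology(seed, max_axioms=30)
        sat = classify(onto)
        flat = Ontology(classes=dict(onto.classes), properties=dict(onto.properties))
        for cls in onto.classes:
            for sup in sat.subsumers_of(cls, reflexive=False):
                flat.axioms.append(SubClassOf(Named(cls), Named(sup)))
        reread = loads_obo(dumps_obo(flat))
        sat2 = classify(reread)
        for cls in onto.classes:
            assert sat2.subsumers_of(cls) == sat.subsumers_of(cls)


class TestExplain:
    def test_asserted_subsumption_has_single_rule_application(self):
        onto = _ontology_with([SubClassOf(Named(Curie("C", "0")), Named(Curie("C", "1")))])
        sat = classify(onto)
        trace = explain(sat, Curie("C", "0"), Curie("C", "1"))
        assert trace.rule == "R1"
        assert replay_trace(trace, set(sat.axioms), onto.properties)

    def test_epiphysis_trace_contains_a_transitivity_step(
        self, fixture_onto, fixture_sat
    ):
        eod = fixture_onto.resolve_label("epiphysis of digit")
        eoh = fixture_onto.resolve_label("epiphysis of hand")
        trace = explain(fixture_sat, eod, eoh)
        assert "R5" in trace.rules_used()
        assert replay_trace(trace, set(fixture_sat.axioms), fixture_onto.properties)

    def test_not_entailed_raises(self, fixture_onto, fixture_sat):
        a = fixture_onto.resolve_label("geniohyoid muscle")
        b = fixture_onto.resolve_label("trigeminal muscle")
        with pytest.raises(NoEntailmentError):
            explain(fixture_sat, a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_every_reported_subsumption_replays(self, seed):
        """Soundness: every entailment in a random ontology has a
        derivation that replays to its conclusion."""
        onto = random_ontology(seed, max_classes=15, max_axioms=30)
        sat = classify(onto)
        axiom_set = set(sat.axioms)
        for cls in onto.classes:
            for sup in sat.subsumers_of(cls):
                trace = explain(sat, cls, sup)
                assert trace.conclusion == ("S", cls, sup)
                assert replay_trace(trace, axiom_set, onto.properties)
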