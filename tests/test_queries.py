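"""Query patterns: worked-example answers, open-world semantics, oracle checks."""

from __future__ import annotations

import pytest

from ctxquery import (
    ABSENT,
    PRESENT,
    Cohort,
    Patient,
    PhenotypeAssertion,
    QueryError,
    QuerySpec,
    VariantObservation,
    cohort_frequency,
    evaluate,
    mean_attribute,
    mean_interval,
    trait_frequency,
    traits_for_variant,
    variant_trait_partition,
    variants_never_associated,
    variants_with_all_traits,
    variants_with_trait,
)
from ctxquery.synthetic import (
    GeneratorConfig,
    PATIENT_564385_1,
    VARIANT_C844,
    VARIANT_Q230X,
    VARIANT_Q525X,
    VARIANT_R395C,
    VARIANT_R405W,
    VARIANT_T343R,
    generate_random_cohort,
)

import oracle

COCD = "ChildhoodOnsetChronicDiarrhea"


class TestWorkedExample:
    """The childhood-onset chronic diarrhea mini-scenario."""

    def test_variants_with_presence(self, figure1, ctx_ontology):
        assert variants_with_trait(figure1, COCD, PRESENT, ctx_ontology) == {
            VARIANT_Q230X, VARIANT_R395C, VARIANT_R405W, VARIANT_T343R,
        }

    def test_variants_with_asserted_absence(self, figure1, ctx_ontology):
        assert variants_with_trait(figure1, COCD, ABSENT, ctx_ontology) == {
            VARIANT_R395C,
        }

    def test_uninformative_carriers_answer_do_not_know(self, figure1, ctx_ontology):
        never, do_not_know = variants_never_associated(figure1, COCD, ctx_ontology)
        assert never == set()
        assert {VARIANT_C844, VARIANT_Q525X} <= do_not_know

    def test_closed_world_turns_blanks_into_absence(self, figure1, ctx_ontology):
        never_ow, _ = variants_never_associated(figure1, COCD, ctx_ontology)
        never_cw, dnk_cw = variants_never_associated(
            figure1, COCD, ctx_ontology, closed_world=True
        )
        assert dnk_cw == set()
        assert never_ow <= never_cw
        assert {VARIANT_C844, VARIANT_Q525X} <= never_cw

    def test_absence_patient_is_the_named_one(self, figure1):
        p = figure1.patient(PATIENT_564385_1)
        assert p.carries(VARIANT_R395C)


class TestOpenWorldSemantics:
    def test_empty_cohort_yields_empty_set(self, ctx_ontology):
        assert variants_with_trait(Cohort([]), COCD, PRESENT, ctx_ontology) == set()

    def test_empty_cohort_frequency_is_empty_denominator(self, ctx_ontology):
        out = cohort_frequency(Cohort([]), "Epilepsy", PRESENT, ctx_ontology)
        assert out.note == "empty-denominator" and out.value is None

    def test_unknown_variant_traits_note_do_not_know(self, figure1, ctx_ontology):
        traits, note = traits_for_variant(figure1, "p.NOSUCH", "Phenotype", ctx_ontology)
        assert traits == set() and note == "do-not-know"

    def test_zero_carrier_frequency_is_empty_denominator(self, figure1, ctx_ontology):
        out = trait_frequency(figure1, "p.NOSUCH", COCD, ctx_ontology)
        assert out.note == "empty-denominator" and out.value is None

    def test_no_qualifying_patient_mean_is_empty_denominator(self, figure1, ctx_ontology):
        out = mean_attribute(
            figure1, "age_at_diagnosis", [("variant", VARIANT_Q525X)], ctx_ontology
        )
        assert out.note == "empty-denominator"

    def test_open_world_stability(self, figure1, ctx_ontology):
        """An assertion-free patient changes no variant-set answer, only
        cohort-frequency denominators."""
        extended = Cohort(
            figure1.patients + [Patient("blank", "fb", [VariantObservation("p.NEW")], [], {})],
            enriched=True,
        )
        for polarity in (PRESENT, ABSENT):
            assert variants_with_trait(
                figure1, COCD, polarity, ctx_ontology
            ) == variants_with_trait(extended, COCD, polarity, ctx_ontology)
        base = cohort_frequency(figure1, COCD, PRESENT, ctx_ontology)
        ext = cohort_frequency(extended, COCD, PRESENT, ctx_ontology)
        assert ext.numerator == base.numerator
        assert ext.denominator == base.denominator + 1


class TestAggregateConventions:
    def test_percent_uses_floor_not_rounding(self, ctx_ontology):
        # 4 of 7 = 57.14 -> 57 (floor), not 57.1 or 58
        patients = [
            Patient(f"p{i}", f"f{i}", [VariantObservation("v")],
                    [PhenotypeAssertion("Ataxia", PRESENT)] if i < 4 else [], {})
            for i in range(7)
        ]
        out = trait_frequency(Cohort(patients, enriched=True), "v", "Ataxia", ctx_ontology)
        assert out.value == 57.0 and (out.numerator, out.denominator) == (4, 7)

    def test_all_carriers_count_in_denominator(self, ctx_ontology):
        """Unknown-status carriers dilute the frequency (open world keeps
        them in the denominator)."""
        patients = [
            Patient("a", "fa", [VariantObservation("v")],
                    [PhenotypeAssertion("Ataxia", PRESENT)], {}),
            Patient("b", "fb", [VariantObservation("v")], [], {}),
        ]
        out = trait_frequency(Cohort(patients, enriched=True), "v", "Ataxia", ctx_ontology)
        assert (out.numerator, out.denominator, out.value) == (1, 2, 50.0)

    def test_mean_rounds_half_up_at_tenth(self, ctx_ontology):
        patients = [
            Patient(f"p{i}", f"f{i}", [], [], {"age_at_diagnosis": v})
            for i, v in enumerate([1.2, 1.3])
        ]
        out = mean_attribute(Cohort(patients, enriched=True), "age_at_diagnosis",
                             [], ctx_ontology)
        assert out.value == 1.3  # 1.25 rounds up

    def test_single_patient_mean_and_interval(self, ctx_ontology):
        p = Patient("p", "f", [], [], {"diarrhea_onset_age": 3.0,
                                       "neurological_symptom_onset_age": 10.0})
        c = Cohort([p], enriched=True)
        assert mean_attribute(c, "diarrhea_onset_age", [], ctx_ontology).value == 3.0
        assert mean_interval(c, "diarrhea_onset_age",
                             "neurological_symptom_onset_age", [], ctx_ontology).value == 7.0

    def test_negative_intervals_still_count(self, ctx_ontology):
        patients = [
            Patient("a", "fa", [], [], {"s": 10.0, "e": 5.0}),
            Patient("b", "fb", [], [], {"s": 1.0, "e": 10.0}),
        ]
        out = mean_interval(Cohort(patients, enriched=True), "s", "e", [], ctx_ontology)
        assert out.value == 2.0 and out.denominator == 2

    def test_single_term_combination_equals_with_trait(self, figure1, ctx_ontology):
        assert variants_with_all_traits(figure1, [COCD], ctx_ontology) == (
            variants_with_trait(figure1, COCD, PRESENT, ctx_ontology)
        )


def _random_case(seed):
    config = GeneratorConfig(
        seed=seed,
        n_patients=(seed % 10) + 1,
        n_variants=(seed % 6) + 1,
        prevalence={
            "Ataxia": 0.4, "Epilepsy": 0.3, "Diarrhea": 0.5,
            "TendonXanthomas": 0.3, "Dementia": 0.25, "Cataract": 0.2,
        },
        missingness=0.1 if seed % 3 == 0 else 0.0,
        absence_rate=0.35,
    )
    return config


QUERY_TERMS = (
    "Ataxia", "AbnormalityOfTheCerebellum", "Epilepsy", "Diarrhea",
    "AbnormalityOfTheDigestiveSystem", "Xanthoma", "Phenotype",
    "AbnormalityOfTheNervousSystem", "Dementia", "Cataract",
    "ExtraNeurologicalManifestation", "TendonXanthomas",
    "AbnormalityOfTheCentralNervousSystem", "ChronicDiarrhea", "Osteoporosis",
)


class TestOracleEquivalence:
    """Every pattern equals an independent nested-loop evaluator."""

    @pytest.mark.parametrize("seed", range(40))
    def test_patterns_match_brute_force(self, ctx_ontology, seed):
        cohort = generate_random_cohort(_random_case(seed), ctx_ontology)
        cohort.enriched = True  # compare engines on the raw facts
        parents = oracle.parent_map(ctx_ontology)
        variants = sorted(cohort.variant_ids()) or ["p.RND001"]
        for term in QUERY_TERMS[: 5 + seed % 10]:
            for polarity in (PRESENT, ABSENT):
                assert variants_with_trait(
                    cohort, term, polarity, ctx_ontology
                ) == oracle.naive_variants_with_trait(parents, cohort, term, polarity)
            assert variant_trait_partition(
                cohort, term, ctx_ontology
            ) == oracle.naive_partition(parents, cohort, term)
            freq = cohort_frequency(cohort, term, PRESENT, ctx_ontology)
            assert freq.value == oracle.naive_cohort_frequency(
                parents, cohort, term, PRESENT
            )
            for v in variants[:3]:
                got = trait_frequency(cohort, v, term, ctx_ontology)
                expected = oracle.naive_trait_frequency(parents, cohort, v, term)
                if expected is None:
                    assert got.note == "empty-denominator"
                else:
                    assert (got.value, got.numerator, got.denominator) == expected
                assert traits_for_variant(cohort, v, term, ctx_ontology)[0] == (
                    oracle.naive_traits_for_variant(parents, cohort, v, term)
                )
        assert variants_with_all_traits(
            cohort, ["Ataxia", "Diarrhea"], ctx_ontology
        ) == oracle.naive_variants_with_all_traits(parents, cohort, ["Ataxia", "Diarrhea"])
        filters = [("term", "Ataxia", PRESENT), ("variant", variants[0])]
        for flt in ([], filters[:1], filters):
            got = mean_attribute(cohort, "age_at_diagnosis", flt, ctx_ontology)
            expected = oracle.naive_mean_attribute(parents, cohort, "age_at_diagnosis", flt)
            assert got.value == expected or (expected is None and got.value is None)
            got = mean_interval(cohort, "diarrhea_onset_age",
                                "neurological_symptom_onset_age", flt, ctx_ontology)
            expected = oracle.naive_mean_interval(
                parents, cohort, "diarrhea_onset_age",
                "neurological_symptom_onset_age", flt)
            assert got.value == expected or (expected is None and got.value is None)

    @pytest.mark.parametrize("seed", range(12))
    def test_hierarchy_superset_property(self, ctx_ontology, seed):
        """A presence query on a class covers every child's answer."""
        cohort = generate_random_cohort(_random_case(seed + 100), ctx_ontology)
        cohort.enriched = True
        for term in ("AbnormalityOfTheCerebellum", "Diarrhea",
                     "ExtraNeurologicalManifestation", "Phenotype"):
            parent_hits = variants_with_trait(cohort, term, PRESENT, ctx_ontology)
            for child in ctx_ontology.descendants(term):
                assert variants_with_trait(
                    cohort, child, PRESENT, ctx_ontology
                ) <= parent_hits

    @pytest.mark.parametrize("seed", range(12))
    def test_partition_property(self, ctx_ontology, seed):
        """always/never/mixed/do-not-know partition the carried variants."""
        cohort = generate_random_cohort(_random_case(seed + 200), ctx_ontology)
        cohort.enriched = True
        for term in ("Ataxia", "Diarrhea", "Xanthoma"):
            parts = variant_trait_partition(cohort, term, ctx_ontology)
            names = ["always", "never", "mixed", "do-not-know"]
            union = set().union(*(parts[n] for n in names))
            assert union == cohort.variant_ids()
            total = sum(len(parts[n]) for n in names)
            assert total == len(union)  # pairwise disjoint
            assert parts["always"].isdisjoint(parts["never"])


class TestDispatch:
    def test_variants_with_trait_table(self, figure1, ctx_ontology, ctx_ruleset):
        table = evaluate(
            QuerySpec(pattern="variants_with_trait", term_ids=(COCD,)),
            figure1, ctx_ontology, ctx_ruleset,
        )
        assert table.column_names == ["GeneMutation"]
        assert [r[0] for r in table.rows] == sorted(
            [VARIANT_Q230X, VARIANT_R395C, VARIANT_R405W, VARIANT_T343R]
        )
        assert table.note == "ok"

    def test_rules_applied_exactly_once_before_evaluation(
        self, ctx_ontology, ctx_ruleset
    ):
        raw = Cohort([
            Patient("p1", "f1", [VariantObservation("v")],
                    [PhenotypeAssertion("Diarrhea", PRESENT, "extra-neurological",
                                        2.0, 8.0)],
                    {"diarrhea_onset_age": 2.0, "diarrhea_duration_weeks": 8.0}),
        ])
        table = evaluate(
            QuerySpec(pattern="variants_with_trait", term_ids=(COCD,)),
            raw, ctx_ontology, ctx_ruleset,
        )
        assert table.rows == [("v",)]
        assert not raw.enriched  # input untouched

    def test_unknown_pattern_lists_available(self, figure1, ctx_ontology):
        with pytest.raises(QueryError, match="variants_with_trait"):
            evaluate(QuerySpec(pattern="nope"), figure1, ctx_ontology)

    def test_arity_errors(self, figure1, ctx_ontology):
        with pytest.raises(QueryError):
            evaluate(QuerySpec(pattern="trait_frequency", term_ids=(COCD,)),
                     figure1, ctx_ontology)
        with pytest.raises(QueryError):
            evaluate(QuerySpec(pattern="variants_with_trait",
                               term_ids=("Ataxia", "Epilepsy")),
                     figure1, ctx_ontology)

    def test_every_pattern_smoke_on_fixture(self, enriched):
        cohort, ontology, _, _ = enriched
        specs = [
            QuerySpec(pattern="variants_with_trait", term_ids=(COCD,)),
            QuerySpec(pattern="variants_with_all_traits",
                      term_ids=("Epilepsy", "Dementia")),
            QuerySpec(pattern="variants_always_associated", term_ids=(COCD,)),
            QuerySpec(pattern="variants_never_associated", term_ids=(COCD,)),
            QuerySpec(pattern="traits_for_variant", variant_id=VARIANT_R395C,
                      scope_class="AbnormalityOfTheCerebellum"),
            QuerySpec(pattern="trait_frequency", variant_id=VARIANT_R395C,
                      term_ids=("Ataxia",)),
            QuerySpec(pattern="cohort_frequency", term_ids=("Epilepsy",)),
            QuerySpec(pattern="mean_attribute",
                      attribute="neurological_symptom_onset_age",
                      filters=(("term", "Xanthoma", PRESENT),)),
            QuerySpec(pattern="mean_interval",
                      start_attribute="diarrhea_onset_age",
                      end_attribute="neurological_symptom_onset_age",
                      filters=(("variant", VARIANT_R395C),)),
        ]
        for spec in specs:
            table = evaluate(spec, cohort, ontology)
            assert table.note == "ok"
            assert all(len(r) == len(table.column_names) for r in table.rows)
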