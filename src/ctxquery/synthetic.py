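"""Synthetic cohorts: the canonical CTX reference fixture and random cohorts.

The original 25-patient CTX study dataset is not publicly deposited; what
the study prints are *aggregates* (frequencies, variant sets, mean onset
ages). This module builds a deterministic synthetic cohort of 25 patients /
19 families / 14 CYP27A1 variants whose aggregate structure satisfies every
one of those printed facts simultaneously — the fixture is the single
witness that they are mutually consistent, and :func:`verify_constraints`
machine-checks each one through the query engine. Record-level details the
aggregates leave open (which patient carries which placeholder variant,
individual onset ages) are fixed by an arbitrary but documented choice; any
constraint-satisfying choice reproduces the same aggregates.

Placeholder variants use an unmistakably synthetic namespace
(``p.SYN001``..``p.SYN006``) so no fabricated HGVS label can be mistaken
for a published one.

:func:`generate_random_cohort` additionally provides seeded random cohorts
(independent per-term draws, optional asserted absence, optional
missingness) for property-based and oracle-equivalence testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .cohort import (
    ABSENT,
    PRESENT,
    Cohort,
    Patient,
    PhenotypeAssertion,
    VariantObservation,
)
from .ontology import Ontology, load_ctx_ontology
from .queries import (
    cohort_frequency,
    mean_attribute,
    mean_interval,
    trait_frequency,
    traits_for_variant,
    variant_trait_partition,
    variants_with_all_traits,
    variants_with_trait,
)
from .rules import RuleSet, apply_rules, load_ctx_ruleset

__all__ = [
    "VARIANT_C844",
    "VARIANT_Q525X",
    "VARIANT_Q230X",
    "VARIANT_R395C",
    "VARIANT_R405W",
    "VARIANT_T343R",
    "VARIANT_N403K",
    "VARIANT_T339M",
    "PLACEHOLDER_VARIANTS",
    "PATIENT_564385_1",
    "Constraint",
    "ConstraintReport",
    "FixtureError",
    "CANONICAL_CONSTRAINTS",
    "build_canonical_fixture",
    "build_figure1_scenario",
    "verify_constraints",
    "GeneratorConfig",
    "generate_random_cohort",
]

# The eight variant labels named in the study (canonical HGVS spelling),
# plus six clearly-synthetic placeholders to reach the study's 14.
VARIANT_C844 = "c.844+1G>T"
VARIANT_Q525X = "p.Q525X"
VARIANT_Q230X = "p.Q230X"
VARIANT_R395C = "p.R395C"
VARIANT_R405W = "p.R405W"
VARIANT_T343R = "p.T343R"
VARIANT_N403K = "p.N403K"
VARIANT_T339M = "p.T339M"
PLACEHOLDER_VARIANTS = tuple(f"p.SYN{i:03d}" for i in range(1, 7))

#: the one patient id the study prints (ASCII hyphen spelling)
PATIENT_564385_1 = "564385-1"

_NEURO = "neurological"
_EXTRA = "extra-neurological"
_DIAG = "diagnostic-study"


def _present(term, group, onset=None, duration=None):
    return PhenotypeAssertion(term, PRESENT, group, onset, duration)


def _absent(term, group):
    return PhenotypeAssertion(term, ABSENT, group)


def _patient(pid, fam, variants, assertions, attributes):
    return Patient(
        patient_id=pid,
        family_id=fam,
        variants=[VariantObservation(v) for v in variants],
        assertions=assertions,
        attributes=attributes,
    )


def _canonical_patients() -> list[Patient]:
    """The 25 reference patients.

    Raw records only: childhood-onset chronic diarrhea is never asserted
    present — presences must be derivable from the low-level diarrhea
    fields by the abstraction rules. Asserted absences of the composite
    concept are allowed (they are data, not abstraction).
    """
    P = _patient
    pts: list[Patient] = []

    # --- p.R395C carriers (7): the variant seen with BOTH polarities of
    # childhood-onset chronic diarrhea, 4/7 with ataxia, 5 with xanthomas
    # (neuro onset 19,21,23,25,29 -> mean 23.4) and 2 with asserted absence
    # of xanthomas (12.0, 13.4 -> mean 12.7).
    pts.append(P("CTX-P01", "FAM-01", [VARIANT_R395C], [
        _present("Diarrhea", _EXTRA, onset=12.0, duration=10.0),
        _present("Dementia", _NEURO, onset=30.0),
        _present("Ataxia", _NEURO, onset=19.0),
        _present("TendonXanthomas", _EXTRA, onset=17.0),
    ], {"diarrhea_onset_age": 12.0, "diarrhea_duration_weeks": 10.0,
        "neurological_symptom_onset_age": 19.0, "xanthoma_onset_age": 17.0,
        "age_at_diagnosis": 34.0}))
    pts.append(P("CTX-P02", "FAM-01", [VARIANT_R395C], [
        _present("Diarrhea", _EXTRA, onset=14.0, duration=8.0),
        _present("Dementia", _NEURO, onset=33.0),
        _present("Ataxia", _NEURO, onset=21.0),
        _present("TendonXanthomas", _EXTRA, onset=18.0),
    ], {"diarrhea_onset_age": 14.0, "diarrhea_duration_weeks": 8.0,
        "neurological_symptom_onset_age": 21.0, "xanthoma_onset_age": 18.0}))
    pts.append(P("CTX-P03", "FAM-02", [VARIANT_R395C], [
        _present("Epilepsy", _NEURO, onset=23.0),
        _present("Dementia", _NEURO, onset=35.0),
        _present("Ataxia", _NEURO, onset=24.0),
        _present("TendonXanthomas", _EXTRA, onset=20.0),
    ], {"neurological_symptom_onset_age": 23.0, "xanthoma_onset_age": 20.0}))
    pts.append(P("CTX-P04", "FAM-02", [VARIANT_R395C], [
        _present("Dementia", _NEURO, onset=38.0),
        _present("Ataxia", _NEURO, onset=25.0),
        _present("Xanthoma", _EXTRA, onset=22.0),
    ], {"neurological_symptom_onset_age": 25.0, "xanthoma_onset_age": 22.0}))
    pts.append(P("CTX-P05", "FAM-03", [VARIANT_R395C], [
        _present("ArnoldChiariTypeI", _NEURO, onset=29.0),
        _present("Xanthoma", _EXTRA, onset=26.0),
    ], {"neurological_symptom_onset_age": 29.0, "xanthoma_onset_age": 26.0}))
    # the one patient the study names: asserted absence of childhood-onset
    # chronic diarrhea, carries p.R395C
    pts.append(P(PATIENT_564385_1, "FAM-04", [VARIANT_R395C], [
        _absent("ChildhoodOnsetChronicDiarrhea", _EXTRA),
        _absent("Xanthoma", _EXTRA),
        _present("PeripheralNeuropathy", _NEURO, onset=12.0),
    ], {"neurological_symptom_onset_age": 12.0}))
    pts.append(P("CTX-P07", "FAM-03", [VARIANT_R395C], [
        _absent("Xanthoma", _EXTRA),
        _present("PyramidalSigns", _NEURO, onset=13.4),
    ], {"neurological_symptom_onset_age": 13.4}))

    # --- p.R405W carriers: two with xanthomas, neuro onsets 29 and 33
    # (mean 31.0); a third carrier (compound het with a placeholder) of
    # unknown xanthoma status appears below as CTX-P24.
    pts.append(P("CTX-P08", "FAM-05", [VARIANT_R405W], [
        _present("Diarrhea", _EXTRA, onset=5.0, duration=26.0),
        _present("Epilepsy", _NEURO, onset=29.0),
        _present("Dementia", _NEURO, onset=40.0),
        _present("Xanthoma", _EXTRA, onset=24.0),
    ], {"diarrhea_onset_age": 5.0, "diarrhea_duration_weeks": 26.0,
        "neurological_symptom_onset_age": 29.0, "xanthoma_onset_age": 24.0}))
    pts.append(P("CTX-P09", "FAM-05", [VARIANT_R405W], [
        _present("Diarrhea", _EXTRA, onset=3.0, duration=52.0),
        _present("Dementia", _NEURO, onset=45.0),
        _present("Xanthoma", _EXTRA, onset=28.0),
    ], {"diarrhea_onset_age": 3.0, "diarrhea_duration_weeks": 52.0,
        "neurological_symptom_onset_age": 33.0, "xanthoma_onset_age": 28.0}))

    # --- p.T343R carriers
    pts.append(P("CTX-P10", "FAM-06", [VARIANT_T343R], [
        _present("Diarrhea", _EXTRA, onset=2.0, duration=8.0),
        _present("Epilepsy", _NEURO, onset=10.0),
        _present("Dementia", _NEURO, onset=28.0),
        _present("Xanthoma", _EXTRA, onset=15.0),
    ], {"diarrhea_onset_age": 2.0, "diarrhea_duration_weeks": 8.0,
        "neurological_symptom_onset_age": 10.0, "xanthoma_onset_age": 15.0}))
    pts.append(P("CTX-P15", "FAM-06", [VARIANT_T343R], [
        _present("Diarrhea", _EXTRA, onset=3.5, duration=16.0),
        _present("Dementia", _NEURO, onset=36.0),
    ], {"diarrhea_onset_age": 3.5, "diarrhea_duration_weeks": 16.0,
        "neurological_symptom_onset_age": 22.0}))
    pts.append(P("CTX-P25", "FAM-07", [VARIANT_T343R], [
        _present("PsychiatricDisturbance", _NEURO, onset=27.0),
        _present("ElevatedPlasmaCholestanol", _DIAG),
    ], {}))

    # --- p.Q230X carriers (epilepsy without dementia, so the variant stays
    # out of the epilepsy-and-dementia combination answer)
    pts.append(P("CTX-P11", "FAM-08", [VARIANT_Q230X], [
        _present("Diarrhea", _EXTRA, onset=4.5, duration=12.0),
        _present("Epilepsy", _NEURO, onset=18.6),
        _absent("Xanthoma", _EXTRA),
    ], {"diarrhea_onset_age": 4.5, "diarrhea_duration_weeks": 12.0,
        "neurological_symptom_onset_age": 18.6}))
    pts.append(P("CTX-P16", "FAM-08", [VARIANT_Q230X], [
        _present("Diarrhea", _EXTRA, onset=0.5, duration=30.0),
    ], {"diarrhea_onset_age": 0.5, "diarrhea_duration_weeks": 30.0}))

    # --- single-carrier named variants
    pts.append(P("CTX-P12", "FAM-09", [VARIANT_N403K], [
        _present("Diarrhea", _EXTRA, onset=1.0, duration=6.0),
        _present("Epilepsy", _NEURO, onset=16.0),
        _present("Dementia", _NEURO, onset=39.0),
        _present("Xanthoma", _EXTRA, onset=19.0),
    ], {"diarrhea_onset_age": 1.0, "diarrhea_duration_weeks": 6.0,
        "neurological_symptom_onset_age": 16.0, "xanthoma_onset_age": 19.0}))
    pts.append(P("CTX-P13", "FAM-10", [VARIANT_T339M], [
        _present("Diarrhea", _EXTRA, onset=6.0, duration=20.0),
        _present("Epilepsy", _NEURO, onset=25.0),
        _present("Dementia", _NEURO, onset=42.0),
        _present("Xanthoma", _EXTRA, onset=21.0),
    ], {"diarrhea_onset_age": 6.0, "diarrhea_duration_weeks": 20.0,
        "neurological_symptom_onset_age": 25.0, "xanthoma_onset_age": 21.0}))
    pts.append(P("CTX-P14", "FAM-11", [VARIANT_C844], [
        _present("Diarrhea", _EXTRA, onset=2.5, duration=10.0),
        _present("Epilepsy", _NEURO, onset=20.0),
        _present("Dementia", _NEURO, onset=37.0),
        _absent("Xanthoma", _EXTRA),
    ], {"diarrhea_onset_age": 2.5, "diarrhea_duration_weeks": 10.0,
        "neurological_symptom_onset_age": 20.0}))

    # --- p.Q525X: never associated with childhood-onset chronic diarrhea;
    # the carrier asserts absence of diarrhea altogether, from which the
    # absence rule derives absence of the composite concept.
    pts.append(P("CTX-P20", "FAM-12", [VARIANT_Q525X], [
        _absent("Diarrhea", _EXTRA),
        _present("Cataract", _EXTRA, onset=9.0),
    ], {"age_at_diagnosis": 41.0}))

    # --- placeholder-variant carriers: no information either way about
    # childhood-onset chronic diarrhea (the "do not know" pool).
    pts.append(P("CTX-P17", "FAM-13", [PLACEHOLDER_VARIANTS[0]], [
        _present("Epilepsy", _NEURO, onset=14.0),
    ], {}))
    pts.append(P("CTX-P18", "FAM-14", [PLACEHOLDER_VARIANTS[1]], [
        _present("Dementia", _NEURO, onset=48.0),
    ], {}))
    pts.append(P("CTX-P19", "FAM-15", [PLACEHOLDER_VARIANTS[2]], [
        _present("Dementia", _NEURO, onset=51.0),
    ], {}))
    pts.append(P("CTX-P21", "FAM-16", [PLACEHOLDER_VARIANTS[0]], [
        _present("JuvenileCataracts", _EXTRA, onset=7.0),
    ], {}))
    pts.append(P("CTX-P22", "FAM-17", [PLACEHOLDER_VARIANTS[4]], [
        _present("ElevatedPlasmaCholestanol", _DIAG),
    ], {}))
    pts.append(P("CTX-P23", "FAM-18", [PLACEHOLDER_VARIANTS[5]], [
        _present("PeripheralNeuropathy", _NEURO, onset=31.0),
    ], {}))
    # compound heterozygote: a named variant plus a placeholder
    pts.append(P("CTX-P24", "FAM-19", [VARIANT_R405W, PLACEHOLDER_VARIANTS[3]], [
        _present("Cataract", _EXTRA, onset=11.0),
    ], {"age_at_diagnosis": 38.0}))

    return pts


# ---------------------------------------------------------------------------
# Constraints: the printed aggregates, machine-checked via the query engine
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Constraint:
    name: str
    description: str
    expected: object
    compute: Callable[[Cohort, Ontology, RuleSet], object]


@dataclass(frozen=True)
class ConstraintResult:
    name: str
    expected: object
    computed: object
    passed: bool


@dataclass(frozen=True)
class ConstraintReport:
    results: tuple[ConstraintResult, ...]

    @property
    def passed(self) -> bool:
        return all(r.passed for r in self.results)

    def failures(self) -> list[ConstraintResult]:
        return [r for r in self.results if not r.passed]


class FixtureError(RuntimeError):
    """Raised when the canonical fixture violates one of its constraints."""


_COCD = "ChildhoodOnsetChronicDiarrhea"
_SIX_COMBINATION_VARIANTS = frozenset(
    {VARIANT_C844, VARIANT_N403K, VARIANT_R395C, VARIANT_R405W,
     VARIANT_T339M, VARIANT_T343R}
)


def _freq(term, polarity=PRESENT):
    def compute(c, o, r):
        return cohort_frequency(c, term, polarity, o).value
    return compute


CANONICAL_CONSTRAINTS: tuple[Constraint, ...] = (
    Constraint("n-patients", "study size", 25, lambda c, o, r: len(c)),
    Constraint("n-families", "distinct families", 19,
               lambda c, o, r: len(c.family_ids())),
    Constraint("n-variants", "distinct CYP27A1 variants", 14,
               lambda c, o, r: len(c.variant_ids())),
    Constraint("cocd-frequency", "childhood-onset chronic diarrhea in 44% of patients",
               44.0, _freq(_COCD)),
    Constraint("cocd-cases", "11 of 25 patients", 11,
               lambda c, o, r: cohort_frequency(c, _COCD, PRESENT, o).numerator),
    Constraint("cocd-variants", "7 of the 14 variants associated with presence", 7,
               lambda c, o, r: len(variants_with_trait(c, _COCD, PRESENT, o))),
    Constraint("cocd-variants-include-figure1",
               "the four variants named in the worked example are associated", True,
               lambda c, o, r: {VARIANT_Q230X, VARIANT_R395C, VARIANT_R405W,
                                VARIANT_T343R}
               <= variants_with_trait(c, _COCD, PRESENT, o)),
    Constraint("cocd-mixed-variant", "exactly one variant with both polarities",
               frozenset({VARIANT_R395C}),
               lambda c, o, r: frozenset(
                   variant_trait_partition(c, _COCD, o)["mixed"])),
    Constraint("cocd-never-variant", "only p.Q525X never associated",
               frozenset({VARIANT_Q525X}),
               lambda c, o, r: frozenset(
                   variant_trait_partition(c, _COCD, o)["never"])),
    Constraint("epilepsy-frequency", "epilepsy in 32% of patients", 32.0,
               _freq("Epilepsy")),
    Constraint("dementia-frequency", "dementia in 52% of patients", 52.0,
               _freq("Dementia")),
    Constraint("epilepsy-dementia-variants",
               "six variants associated with epilepsy and dementia together",
               _SIX_COMBINATION_VARIANTS,
               lambda c, o, r: frozenset(
                   variants_with_all_traits(c, ["Epilepsy", "Dementia"], o))),
    Constraint("r395c-carriers", "p.R395C carried by 7 patients", 7,
               lambda c, o, r: len(c.carriers(VARIANT_R395C))),
    Constraint("r395c-ataxia-frequency", "p.R395C with ataxia in 57% of carriers",
               57.0,
               lambda c, o, r: trait_frequency(c, VARIANT_R395C, "Ataxia", o).value),
    Constraint("r395c-cerebellar-traits",
               "cerebellar-scope traits of p.R395C carriers",
               frozenset({"Ataxia", "ArnoldChiariTypeI"}),
               lambda c, o, r: frozenset(
                   traits_for_variant(c, VARIANT_R395C,
                                      "AbnormalityOfTheCerebellum", o)[0])),
    Constraint("neuro-onset-xanthoma-present",
               "mean neurological onset, xanthomas present", 23.0,
               lambda c, o, r: mean_attribute(
                   c, "neurological_symptom_onset_age",
                   [("term", "Xanthoma", PRESENT)], o).value),
    Constraint("neuro-onset-xanthoma-absent",
               "mean neurological onset, xanthomas absent", 16.0,
               lambda c, o, r: mean_attribute(
                   c, "neurological_symptom_onset_age",
                   [("term", "Xanthoma", ABSENT)], o).value),
    Constraint("neuro-onset-xp-r405w",
               "mean neurological onset, xanthomas present and p.R405W", 31.0,
               lambda c, o, r: mean_attribute(
                   c, "neurological_symptom_onset_age",
                   [("term", "Xanthoma", PRESENT), ("variant", VARIANT_R405W)],
                   o).value),
    Constraint("neuro-onset-xp-r395c",
               "mean neurological onset, xanthomas present and p.R395C", 23.4,
               lambda c, o, r: mean_attribute(
                   c, "neurological_symptom_onset_age",
                   [("term", "Xanthoma", PRESENT), ("variant", VARIANT_R395C)],
                   o).value),
    Constraint("neuro-onset-xa-r395c",
               "mean neurological onset, xanthomas absent and p.R395C", 12.7,
               lambda c, o, r: mean_attribute(
                   c, "neurological_symptom_onset_age",
                   [("term", "Xanthoma", ABSENT), ("variant", VARIANT_R395C)],
                   o).value),
    Constraint("diarrhea-to-neuro-r395c",
               "mean years from diarrhea onset to neurological onset, p.R395C",
               7.0,
               lambda c, o, r: mean_interval(
                   c, "diarrhea_onset_age", "neurological_symptom_onset_age",
                   [("variant", VARIANT_R395C)], o).value),
)


def verify_constraints(
    cohort: Cohort,
    ontology: Ontology,
    ruleset: RuleSet,
    constraints: Sequence[Constraint] = CANONICAL_CONSTRAINTS,
) -> ConstraintReport:
    """Check each constraint against the (rule-enriched) cohort.

    The cohort is enriched here if it is not already; an empty constraint
    sequence passes vacuously.
    """
    if not cohort.enriched:
        cohort, _ = apply_rules(cohort, ruleset, ontology)
    results = []
    for c in constraints:
        computed = c.compute(cohort, ontology, ruleset)
        results.append(
            ConstraintResult(c.name, c.expected, computed, computed == c.expected)
        )
    return ConstraintReport(tuple(results))


def build_canonical_fixture() -> tuple[Cohort, Ontology, RuleSet]:
    """Build and verify the canonical 25-patient CTX reference cohort.

    Returns the *raw* cohort (rules not applied), the shipped ontology and
    the shipped ruleset. Every canonical constraint is checked against the
    enriched cohort before returning; a violation raises
    :class:`FixtureError` naming the failed constraint, guarding against
    regressions in the fixture, the rules or the query engine.
    """
    ontology = load_ctx_ontology()
    ruleset = load_ctx_ruleset()
    cohort = Cohort(
        _canonical_patients(),
        provenance="synthetic CTX reference cohort (constraint-built; "
        "aggregate-level fidelity to the published study, record-level "
        "details are constructed)",
    )
    report = verify_constraints(cohort, ontology, ruleset)
    if not report.passed:
        failed = ", ".join(
            f"{r.name} (expected {r.expected!r}, computed {r.computed!r})"
            for r in report.failures()
        )
        raise FixtureError(f"canonical fixture violates constraint(s): {failed}")
    return cohort, ontology, ruleset


def build_figure1_scenario() -> Cohort:
    """The worked mini-example: seven patients, seven informative rows.

    Four patients with raw diarrhea records from which childhood-onset
    chronic diarrhea is derivable (variants p.Q230X, p.R395C, p.R405W,
    p.T343R), one patient (564385-1) with asserted absence, and two
    carriers of c.844+1G>T and p.Q525X about whom nothing is recorded —
    the "do not know" answers under the open world.
    """
    mk = _patient
    return Cohort([
        mk("FIG1-A", "FIG1-FA", [VARIANT_Q230X],
           [_present("Diarrhea", _EXTRA, onset=2.0, duration=8.0)],
           {"diarrhea_onset_age": 2.0, "diarrhea_duration_weeks": 8.0}),
        mk("FIG1-B", "FIG1-FB", [VARIANT_R395C],
           [_present("Diarrhea", _EXTRA, onset=3.0, duration=12.0)],
           {"diarrhea_onset_age": 3.0, "diarrhea_duration_weeks": 12.0}),
        mk("FIG1-C", "FIG1-FC", [VARIANT_R405W],
           [_present("Diarrhea", _EXTRA, onset=5.0, duration=6.0)],
           {"diarrhea_onset_age": 5.0, "diarrhea_duration_weeks": 6.0}),
        mk("FIG1-D", "FIG1-FD", [VARIANT_T343R],
           [_present("Diarrhea", _EXTRA, onset=1.5, duration=20.0)],
           {"diarrhea_onset_age": 1.5, "diarrhea_duration_weeks": 20.0}),
        mk(PATIENT_564385_1, "FIG1-FE", [VARIANT_R395C],
           [_absent("ChildhoodOnsetChronicDiarrhea", _EXTRA)], {}),
        mk("FIG1-F", "FIG1-FF", [VARIANT_C844], [], {}),
        mk("FIG1-G", "FIG1-FG", [VARIANT_Q525X], [], {}),
    ], provenance="worked-example scenario (synthetic)")


# ---------------------------------------------------------------------------
# Random cohorts for property-based testing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Seeded random-cohort recipe.

    ``prevalence`` maps leaf phenotype term ids to per-patient presence
    probabilities (independent draws per term; no comorbidity structure).
    A non-case is asserted absent with probability ``absence_rate``,
    otherwise left unknown; a case is omitted (left unknown) with
    probability ``missingness`` before being asserted present.
    """

    seed: int
    n_patients: int = 25
    n_variants: int = 6
    prevalence: dict[str, float] = field(default_factory=dict)
    missingness: float = 0.0
    absence_rate: float = 0.3
    attribute_rate: float = 0.7

    def __post_init__(self) -> None:
        probs = [self.missingness, self.absence_rate, self.attribute_rate,
                 *self.prevalence.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_patients < 0 or self.n_variants < 1:
            raise ValueError("n_patients must be >= 0 and n_variants >= 1")


_GENERATOR_ATTRIBUTES = (
    "diarrhea_onset_age",
    "neurological_symptom_onset_age",
    "xanthoma_onset_age",
    "age_at_diagnosis",
)


def generate_random_cohort(config: GeneratorConfig, ontology: Ontology) -> Cohort:
    """Seeded, reproducible random cohort (same config => identical cohort).

    Each patient draws 1-2 variants uniformly from a synthetic pool, then
    per prevalence-listed term: present with its prevalence (onset age
    uniform 0.5-60.0 years at 0.1 resolution, duration uniform 1-104
    weeks), else asserted absent with ``absence_rate``, else unknown.
    """
    for term in config.prevalence:
        ontology._require(term)
    rng = np.random.default_rng(config.seed)
    pool = [f"p.RND{i:03d}" for i in range(1, config.n_variants + 1)]
    patients = []
    for i in range(config.n_patients):
        n_var = min(len(pool), 1 + int(rng.random() < 0.2))
        variants = list(rng.choice(pool, size=n_var, replace=False))
        assertions = []
        attributes = {}
        for term in sorted(config.prevalence):
            p_term = config.prevalence[term]
            if rng.random() < p_term:
                if rng.random() < config.missingness:
                    continue  # true case lost to missingness -> unknown
                onset = round(float(rng.uniform(0.5, 60.0)), 1)
                duration = round(float(rng.uniform(1.0, 104.0)), 1)
                assertions.append(
                    PhenotypeAssertion(term, PRESENT, "other", onset, duration)
                )
            elif rng.random() < config.absence_rate:
                assertions.append(PhenotypeAssertion(term, ABSENT, "other"))
        for name in _GENERATOR_ATTRIBUTES:
            if rng.random() < config.attribute_rate:
                attributes[name] = round(float(rng.uniform(0.5, 60.0)), 1)
        patients.append(
            Patient(f"RND-{i:03d}", f"RNDFAM-{i:03d}",
                    [VariantObservation(v) for v in variants],
                    assertions, attributes)
        )
    return Cohort(patients, provenance=f"random cohort (seed={config.seed})")
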