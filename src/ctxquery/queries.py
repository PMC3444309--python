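"""Bidirectional phenotype-genotype query patterns with SQWRL-style aggregates.

The patterns answer competency questions in both directions — *which
variants go with this trait?* and *which traits go with this variant?* —
over an enriched cohort (abstraction rules already applied). Evidence is
read under the open-world assumption: a variant is associated with the
*absence* of a trait only through an explicitly asserted negative; carriers
about whom nothing is asserted surface in a separate "do not know" list,
never as silent negatives. An optional closed-world mode reads blanks as
absence instead.

Conventions shared by all aggregate patterns:

* percentages are reported as floor (truncation) to an integer percent;
* means are reported in years at 0.1 precision, round-half-up;
* an empty denominator is a distinct outcome (``empty-denominator``), never
  0 and never an exception — "do not know" must stay distinguishable from
  "0 %".
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional, Sequence

from .cohort import ABSENT, PRESENT, UNKNOWN, Cohort, Patient, status
from .ontology import Ontology
from .rules import RuleSet, apply_rules

__all__ = [
    "QuerySpec",
    "ResultTable",
    "AggregateOutcome",
    "QueryError",
    "variants_with_trait",
    "variants_with_all_traits",
    "variants_always_associated",
    "variants_never_associated",
    "variant_trait_partition",
    "traits_for_variant",
    "trait_frequency",
    "cohort_frequency",
    "mean_attribute",
    "mean_interval",
    "evaluate",
    "PATTERNS",
]

NOTE_OK = "ok"
NOTE_DO_NOT_KNOW = "do-not-know"
NOTE_EMPTY_DENOMINATOR = "empty-denominator"


class QueryError(ValueError):
    """Raised for malformed query specifications."""


@dataclass(frozen=True)
class QuerySpec:
    """A parameterised query pattern (the CLI's wire format)."""

    pattern: str
    term_ids: tuple[str, ...] = ()
    polarity: str = PRESENT
    variant_id: Optional[str] = None
    scope_class: Optional[str] = None
    filters: tuple[tuple, ...] = ()  # ("term", id, polarity) | ("variant", id)
    hierarchy: bool = True
    closed_world: bool = False
    attribute: Optional[str] = None
    start_attribute: Optional[str] = None
    end_attribute: Optional[str] = None


@dataclass
class ResultTable:
    column_names: list[str]
    rows: list[tuple]
    note: str = NOTE_OK
    do_not_know: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        arity = len(self.column_names)
        assert all(len(r) == arity for r in self.rows)


@dataclass(frozen=True)
class AggregateOutcome:
    value: Optional[float]
    numerator: int
    denominator: int
    unit: str  # "percent" | "years" | "count"
    note: str = NOTE_OK


# ---------------------------------------------------------------------------
# Variant-set patterns (trait -> variants)
# ---------------------------------------------------------------------------

def variants_with_trait(
    cohort: Cohort,
    term_id: str,
    polarity: str,
    ontology: Ontology,
    hierarchy: bool = True,
    closed_world: bool = False,
) -> set[str]:
    """Distinct variants carried by at least one patient with the given status.

    For ``polarity="absent"`` only literal absence assertions count
    (open world), unless ``closed_world`` reads blanks as absence.
    """
    ontology._require(term_id)
    found: set[str] = set()
    for p in cohort.patients:
        if status(p, term_id, ontology, hierarchy, closed_world) == polarity:
            found.update(v.variant_id for v in p.variants)
    return found


def variants_with_all_traits(
    cohort: Cohort,
    term_ids: Sequence[str],
    ontology: Ontology,
    hierarchy: bool = True,
) -> set[str]:
    """Variants carried by a patient presenting EVERY listed trait.

    Co-occurrence is within the same patient: a variant whose carriers show
    the traits only separately does not qualify.
    """
    if not term_ids:
        raise QueryError("variants_with_all_traits needs at least one term")
    for t in term_ids:
        ontology._require(t)
    found: set[str] = set()
    for p in cohort.patients:
        if all(status(p, t, ontology, hierarchy) == PRESENT for t in term_ids):
            found.update(v.variant_id for v in p.variants)
    return found


def variant_trait_partition(
    cohort: Cohort,
    term_id: str,
    ontology: Ontology,
    hierarchy: bool = True,
    closed_world: bool = False,
) -> dict[str, set[str]]:
    """Partition carried variants by their evidence for a trait.

    ``always``: >=1 carrier present, no carrier absent. ``never``: >=1
    carrier absent, no carrier present. ``mixed``: both polarities among
    carriers. ``do-not-know``: carriers exist but none has an assertion
    either way. The four sets partition the variants with >=1 carrier.
    """
    ontology._require(term_id)
    present: set[str] = set()
    absent: set[str] = set()
    carried: set[str] = set()
    for p in cohort.patients:
        vids = {v.variant_id for v in p.variants}
        carried |= vids
        st = status(p, term_id, ontology, hierarchy, closed_world)
        if st == PRESENT:
            present |= vids
        elif st == ABSENT:
            absent |= vids
    return {
        "always": present - absent,
        "never": absent - present,
        "mixed": present & absent,
        "do-not-know": carried - present - absent,
    }


def variants_always_associated(
    cohort: Cohort, term_id: str, ontology: Ontology, hierarchy: bool = True
) -> set[str]:
    """Variants every informative carrier of which presents the trait
    (>=1 presence, zero asserted absences)."""
    return variant_trait_partition(cohort, term_id, ontology, hierarchy)["always"]


def variants_never_associated(
    cohort: Cohort,
    term_id: str,
    ontology: Ontology,
    hierarchy: bool = True,
    closed_world: bool = False,
) -> tuple[set[str], set[str]]:
    """(never-associated variants, do-not-know variants).

    Never-associated needs positive evidence of absence: >=1 carrier with an
    asserted absence and none with presence. Variants whose carriers are all
    uninformative land in the do-not-know set (empty under closed world).
    """
    parts = variant_trait_partition(cohort, term_id, ontology, hierarchy, closed_world)
    return parts["never"], parts["do-not-know"]


# ---------------------------------------------------------------------------
# Variant -> traits
# ---------------------------------------------------------------------------

def traits_for_variant(
    cohort: Cohort,
    variant_id: str,
    scope_class: str,
    ontology: Ontology,
) -> tuple[set[str], str]:
    """Present traits of the variant's carriers within a scope class.

    Returns (set of term ids asserted/derived present on some carrier and
    subsumed by ``scope_class``, note). An unknown variant yields an empty
    set with a do-not-know note; an unknown scope class is an error.
    """
    ontology._require(scope_class)
    carriers = cohort.carriers(variant_id)
    if not carriers:
        return set(), NOTE_DO_NOT_KNOW
    traits: set[str] = set()
    for p in carriers:
        for a in p.assertions:
            if (
                a.polarity == PRESENT
                and a.term_id in ontology
                and ontology.subsumes(scope_class, a.term_id)
            ):
                traits.add(a.term_id)
    return traits, NOTE_OK


# ---------------------------------------------------------------------------
# Aggregates
# ---------------------------------------------------------------------------

def _floor_percent(numerator: int, denominator: int) -> int:
    return (100 * numerator) // denominator


def _round_mean(values: Sequence[float]) -> float:
    total = sum(Decimal(str(v)) for v in values)
    mean = (total / len(values)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(mean)


def trait_frequency(
    cohort: Cohort,
    variant_id: str,
    term_id: str,
    ontology: Ontology,
    hierarchy: bool = True,
) -> AggregateOutcome:
    """How often a variant's carriers present a trait (floor percent).

    The denominator is ALL carriers, including those of unknown status —
    uninformative carriers dilute the frequency rather than vanish.
    """
    ontology._require(term_id)
    carriers = cohort.carriers(variant_id)
    if not carriers:
        return AggregateOutcome(None, 0, 0, "percent", NOTE_EMPTY_DENOMINATOR)
    numerator = sum(
        1 for p in carriers if status(p, term_id, ontology, hierarchy) == PRESENT
    )
    return AggregateOutcome(
        float(_floor_percent(numerator, len(carriers))),
        numerator,
        len(carriers),
        "percent",
    )


def cohort_frequency(
    cohort: Cohort,
    term_id: str,
    polarity: str,
    ontology: Ontology,
    hierarchy: bool = True,
    closed_world: bool = False,
) -> AggregateOutcome:
    """Share of all patients with the given status for a term (floor percent)."""
    ontology._require(term_id)
    if not cohort.patients:
        return AggregateOutcome(None, 0, 0, "percent", NOTE_EMPTY_DENOMINATOR)
    numerator = sum(
        1
        for p in cohort.patients
        if status(p, term_id, ontology, hierarchy, closed_world) == polarity
    )
    return AggregateOutcome(
        float(_floor_percent(numerator, len(cohort.patients))),
        numerator,
        len(cohort.patients),
        "percent",
    )


def _passes_filters(
    patient: Patient,
    filters: Sequence[tuple],
    ontology: Ontology,
    hierarchy: bool,
) -> bool:
    for f in filters:
        if f[0] == "term":
            _, term_id, polarity = f
            if status(patient, term_id, ontology, hierarchy) != polarity:
                return False
        elif f[0] == "variant":
            if not patient.carries(f[1]):
                return False
        else:
            raise QueryError(f"unknown filter kind {f[0]!r}")
    return True


def mean_attribute(
    cohort: Cohort,
    attribute_name: str,
    filters: Sequence[tuple],
    ontology: Ontology,
    hierarchy: bool = True,
) -> AggregateOutcome:
    """Mean of a clinical attribute over patients passing all filters.

    Term filters evaluate three-valued status (hierarchy-aware); variant
    filters require carriage. Patients lacking the attribute are excluded
    from numerator and denominator alike.
    """
    for f in filters:
        if f[0] == "term":
            ontology._require(f[1])
    values = [
        p.attributes[attribute_name]
        for p in cohort.patients
        if attribute_name in p.attributes
        and _passes_filters(p, filters, ontology, hierarchy)
    ]
    if not values:
        return AggregateOutcome(None, 0, 0, "years", NOTE_EMPTY_DENOMINATOR)
    return AggregateOutcome(_round_mean(values), len(values), len(values), "years")


def mean_interval(
    cohort: Cohort,
    start_attribute: str,
    end_attribute: str,
    filters: Sequence[tuple],
    ontology: Ontology,
    hierarchy: bool = True,
) -> AggregateOutcome:
    """Mean of (end - start) ages over patients having BOTH attributes.

    Individual intervals may be negative (end preceding start); such
    patients still count in the denominator.
    """
    for f in filters:
        if f[0] == "term":
            ontology._require(f[1])
    diffs = []
    for p in cohort.patients:
        if start_attribute in p.attributes and end_attribute in p.attributes:
            if _passes_filters(p, filters, ontology, hierarchy):
                diffs.append(
                    float(
                        Decimal(str(p.attributes[end_attribute]))
                        - Decimal(str(p.attributes[start_attribute]))
                    )
                )
    if not diffs:
        return AggregateOutcome(None, 0, 0, "years", NOTE_EMPTY_DENOMINATOR)
    return AggregateOutcome(_round_mean(diffs), len(diffs), len(diffs), "years")


# ---------------------------------------------------------------------------
# Dispatch
# ---------------------------------------------------------------------------

def _require_spec(condition: bool, message: str) -> None:
    if not condition:
        raise QueryError(message)


def evaluate(
    spec: QuerySpec,
    cohort: Cohort,
    ontology: Ontology,
    ruleset: Optional[RuleSet] = None,
) -> ResultTable:
    """Dispatch a :class:`QuerySpec` to its pattern and tabulate the result.

    Abstraction rules are applied first (exactly once — an already-enriched
    cohort is not re-derived). Rows are sorted lexicographically on the
    first column so output is deterministic and byte-comparable.
    """
    if not cohort.enriched and ruleset is not None:
        cohort, _ = apply_rules(cohort, ruleset, ontology)

    p = spec.pattern
    if p == "variants_with_trait":
        _require_spec(len(spec.term_ids) == 1, "variants_with_trait takes one term")
        hits = variants_with_trait(
            cohort, spec.term_ids[0], spec.polarity, ontology,
            spec.hierarchy, spec.closed_world,
        )
        return ResultTable(["GeneMutation"], sorted((v,) for v in hits))
    if p == "variants_with_all_traits":
        _require_spec(len(spec.term_ids) >= 1, "variants_with_all_traits takes >=1 term")
        hits = variants_with_all_traits(cohort, spec.term_ids, ontology, spec.hierarchy)
        return ResultTable(["GeneMutation"], sorted((v,) for v in hits))
    if p == "variants_always_associated":
        _require_spec(len(spec.term_ids) == 1, "variants_always_associated takes one term")
        hits = variants_always_associated(cohort, spec.term_ids[0], ontology, spec.hierarchy)
        return ResultTable(["GeneMutation"], sorted((v,) for v in hits))
    if p == "variants_never_associated":
        _require_spec(len(spec.term_ids) == 1, "variants_never_associated takes one term")
        never, dnk = variants_never_associated(
            cohort, spec.term_ids[0], ontology, spec.hierarchy, spec.closed_world
        )
        return ResultTable(
            ["GeneMutation"], sorted((v,) for v in never),
            note=NOTE_OK, do_not_know=sorted(dnk),
        )
    if p == "traits_for_variant":
        _require_spec(spec.variant_id is not None, "traits_for_variant needs --variant")
        scope = spec.scope_class or "Phenotype"
        traits, note = traits_for_variant(cohort, spec.variant_id, scope, ontology)
        return ResultTable(
            ["Trait", "Polarity"], sorted((t, PRESENT) for t in traits), note=note
        )
    if p == "trait_frequency":
        _require_spec(
            spec.variant_id is not None and len(spec.term_ids) == 1,
            "trait_frequency needs --variant and exactly one term",
        )
        out = trait_frequency(cohort, spec.variant_id, spec.term_ids[0], ontology, spec.hierarchy)
        return _aggregate_table(out, "Percent")
    if p == "cohort_frequency":
        _require_spec(len(spec.term_ids) == 1, "cohort_frequency takes one term")
        out = cohort_frequency(
            cohort, spec.term_ids[0], spec.polarity, ontology,
            spec.hierarchy, spec.closed_world,
        )
        return _aggregate_table(out, "Percent")
    if p == "mean_attribute":
        _require_spec(spec.attribute is not None, "mean_attribute needs --attribute")
        out = mean_attribute(cohort, spec.attribute, spec.filters, ontology, spec.hierarchy)
        return _aggregate_table(out, "MeanYears")
    if p == "mean_interval":
        _require_spec(
            spec.start_attribute is not None and spec.end_attribute is not None,
            "mean_interval needs --start-attribute and --end-attribute",
        )
        out = mean_interval(
            cohort, spec.start_attribute, spec.end_attribute, spec.filters,
            ontology, spec.hierarchy,
        )
        return _aggregate_table(out, "MeanYears")
    raise QueryError(
        f"unknown pattern {p!r}; available: {', '.join(PATTERNS)}"
    )


def _aggregate_table(out: AggregateOutcome, value_name: str) -> ResultTable:
    if out.note == NOTE_EMPTY_DENOMINATOR:
        return ResultTable(
            [value_name, "Numerator", "Denominator"], [], note=NOTE_EMPTY_DENOMINATOR
        )
    return ResultTable(
        [value_name, "Numerator", "Denominator"],
        [(out.value, out.numerator, out.denominator)],
        note=out.note,
    )


PATTERNS = (
    "variants_with_trait",
    "variants_with_all_traits",
    "variants_always_associated",
    "variants_never_associated",
    "traits_for_variant",
    "trait_frequency",
    "cohort_frequency",
    "mean_attribute",
    "mean_interval",
)
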