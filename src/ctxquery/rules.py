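"""Horn-rule abstraction engine with provenance.

Clinical records store low-level fields (diarrhea onset age, duration);
genetic catalogs speak in abstract phenotype descriptions (childhood-onset
chronic diarrhea). The gap is bridged by Horn-like rules: a conjunction of
positive conditions over one patient implying a single phenotype assertion.
Forward chaining such rules to fixpoint is monotone (only adds assertions),
terminates (the Herbrand base is |patients| x |terms| x 2), and the fixpoint
is independent of rule application order.

The rule language is deliberately a small fragment: conjunctive antecedents
over a single patient, no variables ranging over several patients, and no
negation-as-failure — an absence condition reads asserted negatives only,
preserving the open-world reading of blanks.

Atom kinds
----------
``status-check``
    the patient's three-valued status for a term equals a required polarity
    (presence propagates up the hierarchy; absence is literal).
``attribute-comparison``
    a named clinical attribute compared against a numeric threshold
    (``<, <=, =, >=, >``); thresholds may be named parameters resolved from
    the rule file's ``parameters:`` block. Comparisons are exact decimal
    comparisons — thresholds are policy values, not measurements.
``class-membership``
    the patient has some *present* assertion on a term subsumed by the
    subject class (used for the property-group link rules).
"""

from __future__ import annotations

import copy
import io
from dataclasses import dataclass, field
from typing import Optional, TextIO

import yaml

from .cohort import (
    ABSENT,
    PRESENT,
    Cohort,
    Patient,
    PhenotypeAssertion,
    status,
)
from .ontology import Ontology

__all__ = [
    "Atom",
    "Rule",
    "RuleSet",
    "DerivationRecord",
    "RuleParseError",
    "RuleApplicationError",
    "parse_rules",
    "load_ctx_ruleset",
    "apply_rules",
    "explain",
]

STATUS_CHECK = "status-check"
ATTRIBUTE_COMPARISON = "attribute-comparison"
CLASS_MEMBERSHIP = "class-membership"

_COMPARATORS = {
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "=": lambda a, b: a == b,
    ">=": lambda a, b: a >= b,
    ">": lambda a, b: a > b,
}


class RuleParseError(ValueError):
    """Raised when the rule file is malformed; names the offending rule."""


class RuleApplicationError(ValueError):
    """Raised before any derivation if a ruleset cannot apply to an ontology."""


@dataclass(frozen=True)
class Atom:
    kind: str
    subject: str
    comparator: Optional[str] = None
    threshold: Optional[float] = None
    required_polarity: Optional[str] = None

    def __post_init__(self) -> None:
        has_cmp = self.comparator is not None or self.threshold is not None
        if (self.kind == ATTRIBUTE_COMPARISON) != has_cmp:
            raise RuleParseError(
                "comparator/threshold are set iff kind is attribute-comparison"
            )


@dataclass(frozen=True)
class Rule:
    rule_id: str
    antecedent: tuple[Atom, ...]
    consequent_term: str
    consequent_polarity: str
    consequent_group: str = "other"

    def __post_init__(self) -> None:
        if not self.antecedent:
            raise RuleParseError(f"rule {self.rule_id!r}: antecedent must be non-empty")


@dataclass
class RuleSet:
    rules: list[Rule] = field(default_factory=list)
    parameters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [r.rule_id for r in self.rules]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise RuleParseError(f"duplicate rule id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.rules)


@dataclass(frozen=True)
class MatchedFact:
    """One antecedent match backing a derivation (for explanation)."""

    atom_kind: str
    detail: str
    term_id: Optional[str] = None
    via_rule_id: Optional[str] = None  # set when the matched fact was itself derived


@dataclass(frozen=True)
class DerivationRecord:
    patient_id: str
    term_id: str
    polarity: str
    rule_id: str
    matched: tuple[MatchedFact, ...]


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _resolve_threshold(value, parameters: dict[str, float], rule_id: str) -> float:
    if isinstance(value, (int, float)) and not isinstance(value, bool):
        return float(value)
    if isinstance(value, str):
        if value not in parameters:
            raise RuleParseError(f"rule {rule_id!r}: undefined parameter {value!r}")
        return float(parameters[value])
    raise RuleParseError(f"rule {rule_id!r}: bad threshold {value!r}")


def _parse_atom(raw: dict, parameters: dict[str, float], rule_id: str) -> Atom:
    check = raw.get("check")
    if check == "status":
        polarity = raw.get("polarity")
        if polarity not in (PRESENT, ABSENT):
            raise RuleParseError(f"rule {rule_id!r}: status atom missing polarity")
        return Atom(STATUS_CHECK, raw["term"], required_polarity=polarity)
    if check == "attribute":
        op = raw.get("op")
        if op not in _COMPARATORS:
            raise RuleParseError(f"rule {rule_id!r}: bad comparator {op!r}")
        return Atom(
            ATTRIBUTE_COMPARISON,
            raw["attribute"],
            comparator=op,
            threshold=_resolve_threshold(raw.get("value"), parameters, rule_id),
        )
    if check == "class":
        return Atom(CLASS_MEMBERSHIP, raw["term"])
    raise RuleParseError(f"rule {rule_id!r}: unknown atom kind {check!r}")


def parse_rules(source: str | TextIO) -> RuleSet:
    """Parse a YAML rule file into a :class:`RuleSet`.

    The file has a ``parameters:`` mapping of named numeric thresholds and a
    ``rules:`` list; each rule carries ``id``, ``when`` (list of atoms) and
    ``then`` (term, polarity, group). Named thresholds are resolved at parse
    time; referencing an undefined parameter is an error.
    """
    stream = io.StringIO(source) if isinstance(source, str) else source
    try:
        payload = yaml.safe_load(stream)
    except yaml.YAMLError as exc:
        raise RuleParseError(f"rule file is not valid YAML: {exc}") from exc
    if not isinstance(payload, dict) or "rules" not in payload:
        raise RuleParseError("rule file must contain a top-level 'rules' list")
    parameters = {
        str(k): float(v) for k, v in (payload.get("parameters") or {}).items()
    }
    rules = []
    for raw in payload["rules"]:
        rule_id = raw.get("id")
        if not rule_id:
            raise RuleParseError("rule without an id")
        then = raw.get("then") or {}
        if then.get("polarity") not in (PRESENT, ABSENT):
            raise RuleParseError(f"rule {rule_id!r}: consequent polarity missing")
        if not then.get("term"):
            raise RuleParseError(f"rule {rule_id!r}: consequent term missing")
        atoms = tuple(
            _parse_atom(a, parameters, rule_id) for a in (raw.get("when") or [])
        )
        rules.append(
            Rule(
                rule_id=rule_id,
                antecedent=atoms,
                consequent_term=then["term"],
                consequent_polarity=then["polarity"],
                consequent_group=then.get("group", "other"),
            )
        )
    return RuleSet(rules=rules, parameters=parameters)


def load_ctx_ruleset() -> RuleSet:
    """Load the representative CTX abstraction ruleset shipped with the package."""
    from importlib import resources

    ref = resources.files("ctxquery.data").joinpath("ctx_rules.yaml")
    return parse_rules(ref.read_text(encoding="utf-8"))


# ---------------------------------------------------------------------------
# Forward chaining
# ---------------------------------------------------------------------------

def _match_atom(atom: Atom, patient: Patient, ontology: Ontology):
    """Return a MatchedFact if the atom holds for the patient, else None."""
    if atom.kind == STATUS_CHECK:
        if status(patient, atom.subject, ontology) == atom.required_polarity:
            backing = None
            for a in patient.assertions:
                if a.polarity == atom.required_polarity and (
                    a.term_id == atom.subject
                    or (
                        atom.required_polarity == PRESENT
                        and a.term_id in ontology
                        and ontology.subsumes(atom.subject, a.term_id)
                    )
                ):
                    backing = a
                    break
            return MatchedFact(
                STATUS_CHECK,
                f"status({atom.subject}) == {atom.required_polarity}",
                term_id=backing.term_id if backing else atom.subject,
                via_rule_id=backing.rule_id if backing and backing.derived else None,
            )
        return None
    if atom.kind == ATTRIBUTE_COMPARISON:
        value = patient.attributes.get(atom.subject)
        if value is not None and _COMPARATORS[atom.comparator](value, atom.threshold):
            return MatchedFact(
                ATTRIBUTE_COMPARISON,
                f"{atom.subject}={value} {atom.comparator} {atom.threshold}",
            )
        return None
    if atom.kind == CLASS_MEMBERSHIP:
        for a in patient.assertions:
            if (
                a.polarity == PRESENT
                and a.term_id in ontology
                and ontology.subsumes(atom.subject, a.term_id)
            ):
                return MatchedFact(
                    CLASS_MEMBERSHIP,
                    f"{a.term_id} is-a {atom.subject}, present",
                    term_id=a.term_id,
                    via_rule_id=a.rule_id if a.derived else None,
                )
        return None
    raise AssertionError(f"unreachable atom kind {atom.kind}")


def apply_rules(
    cohort: Cohort, ruleset: RuleSet, ontology: Ontology
) -> tuple[Cohort, list[DerivationRecord]]:
    """Forward-chain ``ruleset`` over ``cohort`` to fixpoint.

    Returns a new, enriched cohort (the input is not mutated) plus one
    :class:`DerivationRecord` per successful (patient, rule) application.
    Derived assertions are marked ``derived=True`` with the rule id. A rule
    whose consequent would contradict an existing assertion (opposite
    polarity on the same term) does not fire. Re-application adds nothing.
    """
    for rule in ruleset.rules:
        if rule.consequent_term not in ontology:
            raise RuleApplicationError(
                f"rule {rule.rule_id!r}: consequent term "
                f"{rule.consequent_term!r} not in ontology"
            )
    enriched = copy.deepcopy(cohort)
    enriched.enriched = True
    records: list[DerivationRecord] = []
    recorded: set[tuple[str, str]] = set()  # (patient_id, rule_id)
    changed = True
    while changed:
        changed = False
        for patient in enriched.patients:
            polarities = {
                (a.term_id, a.polarity) for a in patient.assertions
            }
            for rule in ruleset.rules:
                key = (patient.patient_id, rule.rule_id)
                if key in recorded:
                    continue
                matched = []
                for atom in rule.antecedent:
                    m = _match_atom(atom, patient, ontology)
                    if m is None:
                        break
                    matched.append(m)
                else:
                    recorded.add(key)
                    records.append(
                        DerivationRecord(
                            patient_id=patient.patient_id,
                            term_id=rule.consequent_term,
                            polarity=rule.consequent_polarity,
                            rule_id=rule.rule_id,
                            matched=tuple(matched),
                        )
                    )
                    target = (rule.consequent_term, rule.consequent_polarity)
                    opposite = (
                        rule.consequent_term,
                        ABSENT if rule.consequent_polarity == PRESENT else PRESENT,
                    )
                    if target not in polarities and opposite not in polarities:
                        patient.assertions.append(
                            PhenotypeAssertion(
                                term_id=rule.consequent_term,
                                polarity=rule.consequent_polarity,
                                property_group=rule.consequent_group,
                                derived=True,
                                rule_id=rule.rule_id,
                            )
                        )
                        polarities.add(target)
                        changed = True
    return enriched, records


def explain(
    records: list[DerivationRecord], patient_id: str, term_id: str
) -> list[list[DerivationRecord]]:
    """Every rule-application chain ending in an assertion on ``term_id``.

    Each chain is ordered from the final derivation backwards through the
    derived facts its antecedent matched. Returns an empty list if the
    assertion was asserted rather than derived (or never made).
    """
    by_key: dict[tuple[str, str], list[DerivationRecord]] = {}
    for r in records:
        by_key.setdefault((r.patient_id, r.rule_id), []).append(r)

    def expand(record: DerivationRecord) -> list[DerivationRecord]:
        chain = [record]
        for fact in record.matched:
            if fact.via_rule_id:
                for upstream in by_key.get((record.patient_id, fact.via_rule_id), []):
                    chain.extend(expand(upstream))
        return chain

    return [
        expand(r)
        for r in records
        if r.patient_id == patient_id and r.term_id == term_id
    ]
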