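"""Patient model: variants, three-valued phenotype assertions, attributes.

A patient record is interpreted under the open-world assumption: a
phenotype is *present* or *absent* only if explicitly asserted (or derived
by a rule); anything else is *unknown*. A blank field in a source file is
missing information, never absence. Each phenotype is therefore split into
two possible asserted facts — presence and absence — and :func:`status`
returns one of exactly three values for any (patient, term) pair.

Presence propagates up the is-a hierarchy (a patient with ataxia has an
abnormality of the cerebellum); absence does not propagate in either
direction, except through explicit abstraction rules.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Literal, Optional, TextIO

import pandas as pd

from .ontology import Ontology, UnknownTermError

__all__ = [
    "VariantObservation",
    "PhenotypeAssertion",
    "Patient",
    "Cohort",
    "Issue",
    "CohortError",
    "read_cohort",
    "write_cohort_json",
    "write_cohort_csv",
    "validate_cohort",
    "status",
    "PRESENT",
    "ABSENT",
    "UNKNOWN",
]

PRESENT = "present"
ABSENT = "absent"
UNKNOWN = "unknown"
POLARITIES = (PRESENT, ABSENT)
PROPERTY_GROUPS = ("neurological", "extra-neurological", "diagnostic-study", "other")

#: clinical attributes used by the reference cohort; the attribute map is
#: open-ended, these are merely the conventional names.
KNOWN_ATTRIBUTES = (
    "diarrhea_onset_age",
    "diarrhea_duration_weeks",
    "neurological_symptom_onset_age",
    "xanthoma_onset_age",
    "age_at_diagnosis",
)


class CohortError(ValueError):
    """Raised when a cohort file cannot be parsed into a valid model."""


@dataclass(frozen=True)
class VariantObservation:
    """A genetic variant carried by a patient (HGVS-style label)."""

    variant_id: str
    gene: str = "CYP27A1"

    def __post_init__(self) -> None:
        if not self.variant_id:
            raise CohortError("variant_id must be non-empty")


@dataclass
class PhenotypeAssertion:
    """An explicit presence/absence statement about one ontology term.

    ``derived`` marks assertions produced by an abstraction rule;
    ``rule_id`` records which one.
    """

    term_id: str
    polarity: str
    property_group: str = "other"
    onset_age_years: Optional[float] = None
    duration_weeks: Optional[float] = None
    derived: bool = False
    rule_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.polarity not in POLARITIES:
            raise CohortError(
                f"polarity must be one of {POLARITIES}, got {self.polarity!r}"
            )
        if self.property_group not in PROPERTY_GROUPS:
            raise CohortError(
                f"property_group must be one of {PROPERTY_GROUPS}, "
                f"got {self.property_group!r}"
            )


@dataclass
class Patient:
    patient_id: str
    family_id: str
    variants: list[VariantObservation] = field(default_factory=list)
    assertions: list[PhenotypeAssertion] = field(default_factory=list)
    attributes: dict[str, float] = field(default_factory=dict)

    def carries(self, variant_id: str) -> bool:
        return any(v.variant_id == variant_id for v in self.variants)

    def assertions_on(self, term_id: str) -> list[PhenotypeAssertion]:
        return [a for a in self.assertions if a.term_id == term_id]


@dataclass
class Cohort:
    patients: list[Patient] = field(default_factory=list)
    provenance: str = ""
    enriched: bool = False  # set by the rule engine after forward chaining

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        dup = {i for i in ids if ids.count(i) > 1}
        if dup:
            raise CohortError(f"duplicate patient_id(s): {sorted(dup)}")

    def __len__(self) -> int:
        return len(self.patients)

    def __iter__(self):
        return iter(self.patients)

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def variant_ids(self) -> set[str]:
        return {v.variant_id for p in self.patients for v in p.variants}

    def carriers(self, variant_id: str) -> list[Patient]:
        return [p for p in self.patients if p.carries(variant_id)]

    def family_ids(self) -> set[str]:
        return {p.family_id for p in self.patients}


# ---------------------------------------------------------------------------
# Three-valued open-world status
# ---------------------------------------------------------------------------

def status(
    patient: Patient,
    term_id: str,
    ontology: Ontology,
    hierarchy: bool = True,
    closed_world: bool = False,
) -> str:
    """Status of ``patient`` for ``term_id``: present, absent or unknown.

    Present if the patient has a presence assertion on the term itself or
    (with ``hierarchy``) on any descendant; absent if there is an absence
    assertion literally on the term; otherwise unknown. Presence is checked
    before absence, so a (validator-flagged) conflict between propagated
    presence and literal absence resolves to present.

    With ``closed_world=True`` a blank is read as "not(term)": unknown
    becomes absent.
    """
    ontology._require(term_id)
    for a in patient.assertions:
        if a.polarity != PRESENT:
            continue
        if a.term_id == term_id or (
            hierarchy and a.term_id in ontology and ontology.subsumes(term_id, a.term_id)
        ):
            return PRESENT
    for a in patient.assertions:
        if a.polarity == ABSENT and a.term_id == term_id:
            return ABSENT
    return ABSENT if closed_world else UNKNOWN


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Issue:
    severity: str  # "error" | "warning"
    patient_id: Optional[str]
    kind: str
    message: str


def validate_cohort(cohort: Cohort, ontology: Ontology) -> list[Issue]:
    """Report structural problems; never raises.

    Error level: unknown term ids, contradictory presence+absence on the
    same term, negative ages/durations. Warning level: more than two
    variants for one patient, and literal absence on a term whose status is
    presence-propagated (presence wins, but the record is suspicious).
    """
    issues: list[Issue] = []
    for p in cohort.patients:
        if len(p.variants) > 2:
            issues.append(
                Issue("warning", p.patient_id, "variant-count",
                      f"{len(p.variants)} variants recorded; recessive disease "
                      "expects at most 2")
            )
        seen: dict[str, set[str]] = {}
        for a in p.assertions:
            if a.term_id not in ontology:
                issues.append(
                    Issue("error", p.patient_id, "unknown-term",
                          f"assertion references unknown term {a.term_id!r}")
                )
                continue
            seen.setdefault(a.term_id, set()).add(a.polarity)
            for label, value in (
                ("onset_age_years", a.onset_age_years),
                ("duration_weeks", a.duration_weeks),
            ):
                if value is not None and value < 0:
                    issues.append(
                        Issue("error", p.patient_id, "negative-value",
                              f"{label} < 0 on {a.term_id}")
                    )
        for term_id, polarities in seen.items():
            if polarities == {PRESENT, ABSENT}:
                issues.append(
                    Issue("error", p.patient_id, "contradiction",
                          f"both presence and absence asserted on {term_id}")
                )
        for name, value in p.attributes.items():
            if value < 0:
                issues.append(
                    Issue("error", p.patient_id, "negative-value",
                          f"attribute {name} < 0")
                )
        # literal absence shadowed by propagated presence
        for a in p.assertions:
            if (
                a.polarity == ABSENT
                and a.term_id in ontology
                and seen.get(a.term_id) != {PRESENT, ABSENT}
                and status(p, a.term_id, ontology) == PRESENT
            ):
                issues.append(
                    Issue("warning", p.patient_id, "shadowed-absence",
                          f"absence of {a.term_id} shadowed by presence of a "
                          "narrower term (presence wins)")
                )
    return issues


# ---------------------------------------------------------------------------
# Reading and writing
# ---------------------------------------------------------------------------

def _as_stream(source: str | TextIO) -> TextIO:
    return io.StringIO(source) if isinstance(source, str) else source


def _opt_float(value, where: str):
    if value is None:
        return None
    if isinstance(value, str):
        value = value.strip()
        if value == "":
            return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise CohortError(f"unparseable number {value!r} at {where}")


def _patient_from_dict(obj: dict) -> Patient:
    pid = obj["patient_id"]
    variants = [
        VariantObservation(v["variant_id"], v.get("gene", "CYP27A1"))
        for v in obj.get("variants", [])
    ]
    assertions = []
    for a in obj.get("assertions", []):
        if a.get("polarity") not in POLARITIES:
            raise CohortError(
                f"unparseable polarity {a.get('polarity')!r} for patient {pid}"
            )
        assertions.append(
            PhenotypeAssertion(
                term_id=a["term_id"],
                polarity=a["polarity"],
                property_group=a.get("property_group", "other"),
                onset_age_years=_opt_float(a.get("onset_age_years"), pid),
                duration_weeks=_opt_float(a.get("duration_weeks"), pid),
                derived=bool(a.get("derived", False)),
                rule_id=a.get("rule_id"),
            )
        )
    attributes = {
        k: _opt_float(v, f"{pid}.{k}")
        for k, v in obj.get("attributes", {}).items()
        if v is not None and v != ""
    }
    return Patient(pid, obj.get("family_id", pid), variants, assertions, attributes)


def read_cohort(
    source: str | TextIO,
    format: str = "json",
    attributes_source: str | TextIO | None = None,
) -> Cohort:
    """Read a cohort from JSON or long-form CSV.

    JSON is self-contained (one object per patient). CSV is one row per
    (patient, assertion) with columns ``patient_id, family_id, variant_ids,
    term_id, polarity, property_group, onset_age_years, duration_weeks``; a
    row with a blank ``term_id`` declares an assertion-free patient. Patient
    attributes come from a companion CSV (``patient_id, attribute, value``)
    passed as ``attributes_source``. Blank cells are missing information,
    not absence.
    """
    stream = _as_stream(source)
    if format == "json":
        payload = json.load(stream)
        patients = [_patient_from_dict(obj) for obj in payload.get("patients", [])]
        cohort = Cohort(patients, provenance=payload.get("provenance", ""),
                        enriched=bool(payload.get("enriched", False)))
        return cohort
    if format != "csv":
        raise ValueError(f"unknown cohort format: {format!r}")

    frame = pd.read_csv(stream, dtype=str).fillna("")
    required = {"patient_id", "family_id", "variant_ids", "term_id", "polarity"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortError(f"cohort CSV missing column(s): {sorted(missing)}")
    patients: dict[str, Patient] = {}
    for i, row in enumerate(frame.itertuples(index=False), start=2):
        pid = row.patient_id.strip()
        if not pid:
            raise CohortError(f"blank patient_id at row {i}")
        variant_ids = tuple(v for v in row.variant_ids.split(";") if v)
        if pid not in patients:
            patients[pid] = Patient(
                pid, row.family_id, [VariantObservation(v) for v in variant_ids], [], {}
            )
        else:
            p = patients[pid]
            if row.family_id != p.family_id:
                raise CohortError(f"conflicting family_id for patient {pid} at row {i}")
            if variant_ids and variant_ids != tuple(v.variant_id for v in p.variants):
                raise CohortError(f"conflicting variant_ids for patient {pid} at row {i}")
        term_id = row.term_id.strip()
        if not term_id:
            continue  # patient-declaring row without an assertion
        polarity = row.polarity.strip()
        if polarity not in POLARITIES:
            raise CohortError(f"unparseable polarity {polarity!r} at row {i}")
        patients[pid].assertions.append(
            PhenotypeAssertion(
                term_id=term_id,
                polarity=polarity,
                property_group=(getattr(row, "property_group", "") or "other"),
                onset_age_years=_opt_float(getattr(row, "onset_age_years", ""), f"row {i}"),
                duration_weeks=_opt_float(getattr(row, "duration_weeks", ""), f"row {i}"),
                derived=(getattr(row, "derived", "") in ("True", "true", "1")),
                rule_id=(getattr(row, "rule_id", "") or None),
            )
        )
    if attributes_source is not None:
        attr_frame = pd.read_csv(_as_stream(attributes_source), dtype=str).fillna("")
        for i, row in enumerate(attr_frame.itertuples(index=False), start=2):
            pid = row.patient_id.strip()
            if pid not in patients:
                raise CohortError(f"attribute row {i} references unknown patient {pid!r}")
            value = _opt_float(row.value, f"attributes row {i}")
            if value is not None:
                patients[pid].attributes[row.attribute.strip()] = value
    return Cohort(list(patients.values()))


def write_cohort_json(cohort: Cohort) -> str:
    payload = {
        "provenance": cohort.provenance,
        "enriched": cohort.enriched,
        "patients": [
            {
                "patient_id": p.patient_id,
                "family_id": p.family_id,
                "variants": [asdict(v) for v in p.variants],
                "assertions": [asdict(a) for a in p.assertions],
                "attributes": p.attributes,
            }
            for p in cohort.patients
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def write_cohort_csv(cohort: Cohort) -> tuple[str, str]:
    """Return (cohort CSV, attributes CSV) in the long form read_cohort expects."""
    rows = []
    attr_rows = []
    for p in cohort.patients:
        variant_ids = ";".join(v.variant_id for v in p.variants)
        if not p.assertions:
            rows.append(
                dict(patient_id=p.patient_id, family_id=p.family_id,
                     variant_ids=variant_ids, term_id="", polarity="",
                     property_group="", onset_age_years="", duration_weeks="",
                     derived="", rule_id="")
            )
        for a in p.assertions:
            rows.append(
                dict(
                    patient_id=p.patient_id,
                    family_id=p.family_id,
                    variant_ids=variant_ids,
                    term_id=a.term_id,
                    polarity=a.polarity,
                    property_group=a.property_group,
                    onset_age_years="" if a.onset_age_years is None else a.onset_age_years,
                    duration_weeks="" if a.duration_weeks is None else a.duration_weeks,
                    derived=str(a.derived),
                    rule_id=a.rule_id or "",
                )
            )
        for name, value in sorted(p.attributes.items()):
            attr_rows.append(dict(patient_id=p.patient_id, attribute=name, value=value))
    cohort_csv = pd.DataFrame(rows).to_csv(index=False)
    attr_csv = pd.DataFrame(attr_rows, columns=["patient_id", "attribute", "value"]).to_csv(index=False)
    return cohort_csv, attr_csv
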