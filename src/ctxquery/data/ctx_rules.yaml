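# Abstraction rules for the CTX cohort.
#
# Each rule is a Horn clause over a single patient: a conjunction of positive
# conditions (`when`) implying one phenotype assertion (`then`). Forward
# chaining these rules bridges the gap between low-level clinical record
# fields (onset ages, durations) and catalog-level phenotype descriptions
# (e.g. childhood-onset chronic diarrhea).
#
# This ruleset is representative, not exhaustive: it contains every
# derivation exercised by the reference CTX cohort. Thresholds are policy
# parameters, overridable here:
#   childhood_onset_max_age   -- strict upper bound (years) for "childhood
#                                onset"; 16 y covers paediatric-onset classes.
#   chronic_min_duration_weeks -- inclusive lower bound (weeks) for "chronic"
#                                diarrhea; 4 weeks is the standard clinical
#                                definition.

parameters:
  childhood_onset_max_age: 16.0
  chronic_min_duration_weeks: 4.0

rules:
  - id: childhood-chronic-diarrhea-presence
    when:
      - {check: status, term: Diarrhea, polarity: present}
      - {check: attribute, attribute: diarrhea_onset_age, op: "<", value: childhood_onset_max_age}
      - {check: attribute, attribute: diarrhea_duration_weeks, op: ">=", value: chronic_min_duration_weeks}
    then: {term: ChildhoodOnsetChronicDiarrhea, polarity: present, group: extra-neurological}

  # Downward absence for a defined composite concept: a patient asserted not
  # to have diarrhea at all cannot have childhood-onset chronic diarrhea.
  # Absence otherwise never propagates (open-world assumption).
  - id: childhood-chronic-diarrhea-absence
    when:
      - {check: status, term: Diarrhea, polarity: absent}
    then: {term: ChildhoodOnsetChronicDiarrhea, polarity: absent, group: extra-neurological}

  # Property-group link rules: materialise the "has ... manifestations" links
  # between a patient and the abstract manifestation classes.
  - id: extra-neurological-manifestation-link
    when:
      - {check: class, term: ExtraNeurologicalManifestation}
    then: {term: ExtraNeurologicalManifestation, polarity: present, group: extra-neurological}

  - id: neurological-manifestation-link
    when:
      - {check: class, term: AbnormalityOfTheNervousSystem}
    then: {term: AbnormalityOfTheNervousSystem, polarity: present, group: neurological}

  - id: diagnostic-finding-link
    when:
      - {check: class, term: DiagnosticStudyFinding}
    then: {term: DiagnosticStudyFinding, polarity: present, group: diagnostic-study}
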