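# Methods

## Scope and model

`ctxquery` represents a rare-disease cohort as three coupled structures:

1. **Ontology.** A DAG of phenotype classes under four hierarchy roots
   (Phenotype, Anatomical Structure, Diagnostic Study, Qualifier Value)
   related by `is_a`. Subsumption is the reflexive-transitive closure of
   the parent relation: `subsumes(G, S)` iff `G == S` or `G` is reachable
   from `S` via parent links. `ancestors`/`descendants` exclude the term
   itself; `subsumes` includes equality, matching the query semantics in
   which a class denotes itself plus its strict descendants. Multiple
   parents are allowed (reused HPO/SNOMED CT concepts are multi-parent);
   cycles, dangling parent references and duplicate ids are load-time
   errors. Synonyms are stored but never used in matching — terminology
   mapping is out of scope, and all references are exact term ids.

2. **Patients.** Each patient carries 1–2 HGVS-labelled variants (recessive
   disease; compound heterozygosity allowed), a list of explicit phenotype
   assertions, and a numeric attribute map (onset ages in decimal years at
   0.1 resolution, durations in weeks). An assertion pairs a term with a
   *polarity* — presence and absence are both asserted facts. The
   three-valued status function is:

   - **present** if a presence assertion exists on the term or (with
     hierarchy on, the default) on any descendant;
   - **absent** if an absence assertion exists literally on the term;
   - **unknown** otherwise.

   Presence is checked first, so a propagated presence overrides a literal
   ancestor-level absence; the validator flags such records as warnings
   rather than rejecting them. Absence never propagates in either
   direction — the open-world stance never manufactures new negatives —
   except through explicit abstraction rules. The optional closed-world
   mode maps unknown to absent at the point of reading, which is exactly
   the "a blank means not(X)" interpretation.

3. **Rules.** Horn clauses over a single patient: a conjunction of
   status checks (three-valued, hierarchy-aware for presence),
   attribute comparisons (exact decimal comparisons against named
   thresholds — thresholds are policy values, not measurements, so no
   tolerance) and class-membership checks (some present assertion under a
   class). The consequent is one assertion template. The fragment
   deliberately excludes negation-as-failure and cross-patient variables:
   it is monotone over a finite fact base (|patients| × |terms| × 2), so
   forward chaining terminates at a unique, order-independent fixpoint,
   which the test suite verifies by shuffling rule order. Derived
   assertions carry `derived=True` and the rule id; derivation records
   allow every conclusion to be explained back through chained rules. If
   a consequent contradicts an existing assertion (opposite polarity on
   the same term), the rule records its match but does not assert — the
   literal data stand. This case never arises in the reference cohort; the
   policy simply keeps enrichment from creating contradictions.

## Rule thresholds

The clinical literature, not the cohort, fixes the two parameters of the
diarrhea abstraction: *childhood onset* is onset strictly before 16.0
years (covering paediatric-onset classes), *chronic* is duration ≥ 4.0
weeks (the standard chronic-diarrhea definition). Both live in the rule
file's `parameters:` block and can be overridden without code changes.

## Query conventions

- Percentages are floored to an integer percent (100·4/7 → 57), matching
  the convention of the aggregates being reproduced; means are reported at
  0.1-year precision, round half up (exact decimal arithmetic, not float
  rounding).
- `trait_frequency` divides by *all* carriers of the variant, including
  unknown-status carriers: uninformative records dilute a frequency, they
  do not disappear from it.
- Combination queries require co-occurrence in the same patient.
- "Never associated" requires positive evidence of absence; variants whose
  carriers are all uninformative are routed to a separate do-not-know
  list. An empty denominator is a distinct outcome (`empty-denominator`),
  never 0 and never an uncaught exception — "do not know" must stay
  distinguishable from "0 %".
- `traits_for_variant` collects literal (asserted or rule-derived) present
  assertions of the carriers, restricted by subsumption to a scope class;
  it does not report propagated ancestors as traits of their own.
- Patients are always counted individually, never per family. Patients
  carrying two variants contribute to both variants' carrier sets.

## The reference cohort

The 25-patient CTX study dataset behind the published aggregates is not
publicly deposited. The package therefore ships a *constraint-built*
synthetic cohort: 25 patients in 19 families carrying 14 CYP27A1 variants
(the eight labels the study names, plus six placeholders in an
unmistakably synthetic `p.SYN…` namespace). Twenty-one machine-checked
constraints — cohort frequencies, variant-set answers, mean onset ages and
the onset-interval — are verified through the query engine on every build;
a violation aborts the build naming the failed constraint. The cohort is
raw: presence of childhood-onset chronic diarrhea is never asserted, only
derivable from the low-level diarrhea fields, so the full
abstraction-then-query pipeline is exercised end to end.

Fidelity is aggregate-level, not record-level: which patient carries which
placeholder variant, individual onset ages and family structure are fixed
by an arbitrary deterministic choice, because any constraint-satisfying
choice yields the same aggregates. The one record-level fact the study
prints — patient 564385-1 carries p.R395C with asserted absence of
childhood-onset chronic diarrhea — is honoured literally. The
seven-patient worked-example scenario (four derivable presences, one
asserted absence, two uninformative carriers) is built separately by
`build_figure1_scenario`.

## Random cohort generator

`generate_random_cohort` emulates the statistical shape of such a study
for property-based testing: per patient, 1–2 variants drawn uniformly from
a synthetic pool; per listed leaf phenotype an independent presence draw
at its prevalence (onset uniform 0.5–60.0 years at 0.1 resolution,
duration uniform 1–104 weeks), otherwise an asserted absence with a
configurable rate, otherwise unknown; optional missingness deletes true
cases before assertion. Identical seeds give byte-identical cohorts. The
generator draws terms independently — no comorbidity correlation, no
penetrance model, no family structure — so passing property tests shows
engine correctness on arbitrary open-world fact patterns, not realism of
disease co-occurrence. Calibration is checked against the binomial: at
prevalence 0.5 and n = 400, the observed frequency falls within three
binomial standard errors of 50 % in at least 95 of 100 seeds.

## Verification strategy and problem sizes

Beyond unit tests, three independent-route checks anchor correctness:

- every query pattern is compared against a brute-force nested-loop
  evaluator (naive reachability over a plain parent map, exact rational
  arithmetic for means; no shared code) on 200 seeded random cohorts of
  ≤ 10 patients, ≤ 6 variants, ~15 query terms;
- reasoner invariants (fixpoint idempotence, rule-order independence,
  hierarchy-superset, open-world stability under adding an assertion-free
  patient) run on 50 random cohorts;
- ontology traversal is checked against exhaustive path enumeration on
  random 20-node DAGs, plus a hypothesis property test for the status
  function.

These sizes keep the whole suite under a few seconds while exhausting the
combinatorics that matter (multi-parent terms, mixed polarities,
missingness, 1-vs-2-variant carriers).

## Known limitations

- Temporal information is limited to onset ages and durations; no event
  timelines.
- No zygosity/phasing semantics; each (patient, variant) pair is treated
  independently.
- The shipped ruleset is representative of the abstraction style, not a
  reconstruction of any particular catalog's full rule inventory.
- No probabilistic rules or risk/odds estimation; associations are
  reported as evidence counts, and with 1–7 carriers per variant they are
  descriptive, not inferential.
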