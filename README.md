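# ctxquery

Open-world phenotype–genotype queries on rare-disease patient cohorts.

Clinicians and geneticists ask complementary questions of the same data:
*which genetic variants have been seen in patients with this combination of
traits?* and *which traits have been seen in carriers of this variant?*
Answering either on real clinical records runs into two obstacles. First,
records store low-level fields (diarrhea onset age, duration in weeks)
while catalogs speak in abstract phenotype descriptions (*childhood-onset
chronic diarrhea*). Second, clinical data are incomplete: a blank field
means *nobody recorded it*, not *the patient does not have it*.

`ctxquery` addresses both:

- **Phenotype ontology** — an is-a DAG of phenotype classes (a hand-curated
  subset for cerebrotendinous xanthomatosis, CTX, is shipped). Queries on a
  broad class (*Abnormality of the Cerebellum*) automatically cover
  narrower ones (*Ataxia*, *Arnold-Chiari type I malformation*).
- **Three-valued patient model** — every (patient, phenotype) pair has a
  status in {present, absent, unknown}. Absence must be asserted; it is
  never inferred from missing data (open-world assumption). A
  closed-world switch is available for the other reading.
- **Horn-rule abstraction** — forward chaining of conjunctive rules such as

  ```
  Diarrhea present ∧ diarrhea_onset_age < 16 ∧ diarrhea_duration_weeks ≥ 4
      ⟹ ChildhoodOnsetChronicDiarrhea present
  ```

  with full provenance (which rule, matched on which facts). The fragment
  is monotone, so the fixpoint is unique and order-independent.
- **Query engine** — bidirectional patterns (`variants_with_trait`,
  `variants_always_associated`, `variants_never_associated`,
  `traits_for_variant`, `trait_frequency`, `cohort_frequency`,
  `mean_attribute`, `mean_interval`, …) with SQWRL-style aggregates.
  Variants whose carriers are all uninformative are reported as
  *do not know*, kept distinct from a true negative and from 0 %.
- **Synthetic reference cohort** — the original 25-patient CTX study data
  are not deposited; the package constructs a deterministic synthetic
  cohort (25 patients, 19 families, 14 CYP27A1 variants) that satisfies
  every published aggregate simultaneously, and machine-checks all of them
  on every build.

## Worked example

```bash
$ ctxquery query --pattern trait_frequency --variant p.R395C --term Ataxia --format json
{
  "columns": ["Percent", "Numerator", "Denominator"],
  "rows": [[57.0, 4, 7]],
  "note": "ok",
  "do_not_know": []
}
```

Seven patients carry p.R395C; four of them have ataxia, and 100·4/7
truncates to 57 % (percentages use floor by convention). All carriers count
in the denominator, including those of unknown status.

```bash
$ ctxquery query --pattern variants_never_associated --term ChildhoodOnsetChronicDiarrhea
GeneMutation
p.Q525X
# do-not-know: p.SYN001
# do-not-know: p.SYN002
...
```

Only p.Q525X has positive evidence of *never*: one of its carriers is
asserted not to have diarrhea, and an abstraction rule derives absence of
the composite concept. The placeholder variants (`p.SYN…`) have carriers
with no information either way, so the open world answers *do not know*
instead of counting them as negatives.

The same engine is scriptable:

```python
from ctxquery import build_canonical_fixture, apply_rules, cohort_frequency

cohort, ontology, ruleset = build_canonical_fixture()
enriched, records = apply_rules(cohort, ruleset, ontology)
out = cohort_frequency(enriched, "ChildhoodOnsetChronicDiarrhea", "present", ontology)
print(out.value, out.numerator, out.denominator)   # 44.0 11 25
```

## Command-line interface

Subcommands: `validate` (ontology + cohort + rules; exit 0 iff clean),
`infer` (write the rule-enriched cohort and a provenance log), `query`
(evaluate one pattern; TSV or JSON), `fixture build` (write the reference
cohort, ontology, rules and constraint report) and `fixture random`
(seeded random cohort). Results go to stdout, logs to stderr; exit codes
are 0 (ok), 2 (validation) and 3 (query error).
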