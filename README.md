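# vocabprep

Tooling for making source-data vocabularies usable in the OMOP Common Data
Model (CDM) and for checking, against a claims-data extract, how well the
prepared vocabularies actually cover what sites document.

Many national code systems — German claims vocabularies such as the remedy
catalogs (HMK, HPNR), the outpatient billing standard (EBM), or charge-type
lists — are absent from the OHDSI vocabulary distribution (Athena). Sites
that want to analyse such data in the OMOP CDM must either map their codes
to existing *standard concepts* (typically via the OHDSI tool Usagi) or
create *custom concepts* in the concept-id range above 2,000,000,000 that is
reserved for local extensions. `vocabprep` implements that second path end
to end, plus the quality checks both paths need:

* **builder** — turns a curated code table (code, designations, parent code,
  validity period, replacement code) into a valid set of OMOP vocabulary
  tables (`vocabulary`, `concept_class`, `concept`,
  `concept_relationship`): consecutive concept ids above 2 billion,
  synthesized `OMOP<N>` codes for hierarchy nodes, default validity window
  1970-01-01..2099-12-31, reciprocal `Is a`/`Subsumes` and
  `Concept replaced by`/`Concept replaces` records.
* **validation** — exhaustive structural checking of assembled bundles
  (id range, secondary-key uniqueness of `(vocabulary_id, concept_code)`,
  date ordering, relationship reciprocity, replacement lifecycle).
* **stcm** — ingestion of Usagi-style mapping exports into
  `source_to_concept_map` tables, with target cross-checks against a
  reference concept list.
* **evaluation** — given a claims extract of `(source_code, event_date)`
  rows: *completeness* (is each code found in any supplied vocabulary
  source? unmatched codes resolve to concept_id 0) and *correctness* (does
  the event date lie inside the matched concept's validity period,
  inclusive on both ends? out-of-window dates are classified as before the
  start or after the end). Reported at unique-code/combination level and at
  record level, with the exact percentage-rendering rules evaluation
  reports use.
* **coverage** — the four-category availability score per vocabulary
  (available in Athena / Athena-ready / interim mapping / not available)
  and its percentage distribution.
* **synth** — a synthetic claims generator that injects manifest-tracked
  defects (transposed digits, deleted characters, zero-for-letter-"O"
  substitutions, out-of-window dates, missing fields), so every evaluator
  can be tested against exact ground truth.

## Worked example

`examples/evaluate_claims.py` generates a toy vocabulary of 80 codes,
builds it into a custom-concept bundle, draws a 5,000-row extract with
injected defects and evaluates it:

```
completeness (codes not found in the vocabulary):
  unique codes : 195/275 (70.91)
  records      : 257/4,942 (5.20)
correctness (dates outside the validity period):
  unique combos: 131/4,513 (2.90)
  records      : 131/4,639 (2.82)
  by side      : {'before_start': 103, 'after_end': 28}
  excluded (missing code/date): 104
manifest says  : {'unique_missing': 195, 'records_missing': 257, 'invalid_combos': 131, 'invalid_records': 131}
```

Reading the numbers: 257 of 4,942 records (5.20%) carry a code that is not
in the prepared vocabulary — corrupted codes are almost all distinct, which
is why they dominate the *unique*-code tally (195/275). Of the
code–date combinations whose code *was* found, 2.90% fall outside the
concept's validity window, most of them dated before its start. Every
tally equals the generator's ground-truth manifest exactly.

The other examples cover bundle construction
(`examples/build_vocabulary.py`), Usagi-export ingestion
(`examples/ingest_mapping.py`) and the coverage distribution
(`examples/coverage_report.py`). The same stages are available as shell
commands (`vocabprep simulate | build | validate | stcm-ingest |
eval-completeness | eval-correctness | coverage`); repeat `--vocab` to
search several vocabularies at once, as needed for charge-type codes that
may come from more than one code system.

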