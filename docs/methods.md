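# Methods

## Custom-concept construction

A source vocabulary arrives as a *code table*: one row per code with German
and English designations, an optional parent code, an optional validity
period, and an optional replacement code. Construction follows the OMOP
conventions for site-local ("2-billion") vocabulary extensions:

* Concept ids are consecutive integers starting at `concept_id_base`
  (default 2,000,000,001) and always above 2,000,000,000, the range
  reserved for local concepts. Allocation order is lexicographic by
  concept code — the convention the format itself does not fix, chosen so
  identical inputs always yield byte-identical outputs. Sites combining
  bundles from several sources should partition the 2-billion range via
  `concept_id_base` per vocabulary.
* Rows with an empty code (typically chapter/hierarchy nodes that exist in
  the printed catalog but carry no billing code) are given synthetic codes
  `OMOP1`, `OMOP2`, … numbered per vocabulary; a collision with a real
  source code aborts the build.
* Missing validity dates default to 1970-01-01 / 2099-12-31, the OMOP CDM
  default window.
* All custom concepts are nonstandard (`standard_concept` empty). Making
  local concepts standard would let them leak into cross-site analyses
  that expect normative concepts.
* Hierarchy edges are stored as reciprocal `Is a` (child→parent) /
  `Subsumes` (parent→child) pairs; these labels are the OMOP convention
  for hierarchical links and are an assumption of this package, not a
  property of the input format. Replacements are stored as
  `Concept replaced by` / `Concept replaces` pairs, only for directly
  stated successor links (no transitive closure). A bundle with `e` parent
  edges and `r` replacements therefore has exactly `2(e + r)` relationship
  rows.
* A replaced concept carries `invalid_reason = "U"` and a finite
  `valid_end_date`; if its row left the end date open, the build closes the
  window at its start date rather than emit a concept that is
  simultaneously "replaced" and "currently valid".

Validation (`validate_bundle`) re-checks all of this on any bundle,
including ones read from disk, and returns the complete list of violations
rather than stopping at the first. Relationship endpoints may resolve
against an optional external reference concept list, standing in for a full
Athena download, which is out of scope.

## Completeness and correctness

The evaluation mirrors a two-stage lookup pipeline over CSV inputs (no
database required):

1. **Completeness.** Each extract code is searched in the `concept_code`
   column of every supplied bundle and the `source_code` column of every
   supplied mapping table; a hit in *any* source counts as matched
   (charge-type codes, for instance, may legitimately come from either of
   two code systems). Unmatched codes resolve to concept_id 0. Tallies are
   kept at unique-code and at record level. Rows with an empty code cannot
   be looked up; they are excluded from the denominators and counted
   separately.
2. **Correctness.** Only matched codes are examined. Rows lacking a code
   or a date are excluded and counted. A (code, date) combination is valid
   iff some validity window of that code contains the date, bounds
   inclusive — "within the validity period" is read inclusively, matching
   the OMOP convention that `valid_end_date` is the last valid day. With
   several windows (multi-source matches) the union applies. Invalid
   combinations are classified `before_start` (date before every window)
   or `after_end` (date after every window); a date falling in a gap
   between windows is attributed to the nearer window boundary. If an
   extract's matched rows carry no dates at all (diagnosis-type or
   provider-specialty tables have no event date), the result is flagged
   *not evaluable* instead of reporting a vacuous 0%.

Matching is case- and whitespace-sensitive by default: strictness is what
surfaces documentation errors like a letter "O" written as a zero. A
`normalize` switch (strip + upper-case) is available for deliberately
lenient runs.

Percentages render the way evaluation reports print them: `100·n/N`
rounded half-up to two decimals, a bare `0` for a zero numerator, an em
dash for an empty denominator, and two significant digits for nonzero
shares below 0.01% (`0.0036`, `0.0074`) — at two decimals those would
round to a misleading `0.00`/`0.01`. Cross-vocabulary aggregation is
reported in two variants, summed (adding each vocabulary's n and N) and
deduplicated (each distinct code counted once), because the two differ
whenever vocabularies share codes and no single convention is canonical.

## Synthetic claims generator

The generator stands in for claims extracts that cannot be redistributed
(the motivating data were synthesized billing records of 10,000 insured
persons over six years, drawn from vocabularies of a few dozen to a few
thousand codes). Defaults: 100 codes in a 3-level hierarchy, 10,000
extract rows over a six-year date window (2015–2020), half the codes with
finite validity windows (6 months–4 years), 5% unknown-code rows, 2%
dates before the window start versus 0.5% after its end (out-of-window
dates skew early in billing data, e.g. payment dated after a code expired
is rarer than service dated before its introduction), 1% each missing
code and missing date, and an error mix of 40% transposed adjacent
digits, 40% deleted characters, 20% zero-for-"O" — the three
documentation-error classes observed in practice. These are study
conditions, not tuning knobs.

Per extract row exactly one defect class is drawn (mutual exclusivity
keeps the ground truth unambiguous; real data may stack defects, which
this generator deliberately does not model). Corrupted codes are
guaranteed absent from the vocabulary (bounded resampling, falling back
from an inapplicable operator to character deletion, and failing loudly if
every corruption collides). Defect dates land uniformly 1–365 days outside
the window on the assigned side; codes whose window is the full default
range cannot host a date defect and the row is demoted to a clean row with
a log notice. All randomness flows through one seeded numpy PCG64
generator, and only integer draws touch data values, so output is
reproducible bit-for-bit per seed across platforms.

The manifest records each row's defect class and original code; its
aggregates (unique/record-level missing counts, invalid combinations by
side, excluded rows) are recomputable from the rows and are the exact
expected evaluator output. Passing the ground-truth tests therefore shows
the evaluators count correctly under these generative assumptions — it
does not show that real claims data contain defects at these rates, nor
that mixed or systematic real-world errors behave like independent
per-row corruption.

## Coverage scoring

Each vocabulary is assigned to exactly one of four categories (available
in Athena, Athena-ready, available through interim mapping, not
available); the report is the one-hot count and percentage distribution.
The packaged 20-vocabulary assignment for German claims data reproduces
the published category counts (3/6/9/2); its per-vocabulary labels are a
synthetic reconstruction, since the original appendix-level assignment is
not part of the package, and users supply their own CSV for other data
sets. Deciding a vocabulary's category automatically would require
querying Athena's live contents and is out of scope.

## I/O and numerical choices

Two CSV dialects round-trip every table kind: comma + ISO dates (default)
and tab + compact `YYYYMMDD` dates ("athena"), the layout downstream OMOP
vocabulary loaders expect. Header checking is strict by default; a lenient
mode skips unknown extra columns but never tolerates missing ones. Date
parse failures are reported with their line number. Usagi exports are
ingested without silently dropping rows: data-row count always equals
ingested records plus reported row errors.

Known limitations: no German–English translation, no automatic
domain/class inference (both are curator inputs), no `Maps to`
self-relationships for custom concepts, no database loading, and no
reimplementation of Usagi's term-similarity ranking — its reviewed export
is treated as final.

## Problem sizes in the test suite

The packaged checks run the pipeline over 100 randomized generator
configurations of up to 10,000 extract rows each, cross-check the
evaluators against an independent per-record linear-scan reference up to
100,000 rows, and fuzz the builder over random code tables with
hierarchies up to depth 5 — sizes chosen to exercise every code path and
keep the whole suite comfortably within a coffee break on one CPU.
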