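"""Evaluate a synthetic claims extract for completeness and correctness.

The generator draws a toy vocabulary and an extract in which a known
fraction of rows carries one injected defect (corrupted code, date outside
the validity window, missing field), tracked in a ground-truth manifest.
The two evaluators must recover those defects exactly.
"""

from vocabprep import (
    BuildConfig,
    GeneratorConfig,
    assemble_bundle,
    assess_completeness,
    assess_correctness,
    format_fraction,
    generate_extract,
    generate_vocabulary,
)

cfg = GeneratorConfig(seed=7, n_codes=80, n_records=5000)
vocab = generate_vocabulary(cfg)
bundle = assemble_bundle(vocab, BuildConfig("SYN", "Synthetic vocabulary"))
extract, manifest = generate_extract(cfg, vocab)

comp = assess_completeness(extract, [bundle])
corr = assess_correctness(extract, comp, [bundle])
truth = manifest.aggregates()

print("completeness (codes not found in the vocabulary):")
print("  unique codes :", format_fraction(comp.unique_missing, comp.unique_total))
print("  records      :", format_fraction(comp.records_missing, comp.records_total))
print("correctness (dates outside the validity period):")
print("  unique combos:", format_fraction(corr.unique_invalid, corr.unique_total))
print("  records      :", format_fraction(corr.records_invalid, corr.records_total))
print("  by side      :", corr.invalid_by_side())
print("  excluded (missing code/date):", corr.excluded_missing_fields)
print("manifest says  :", {k: truth[k] for k in
      ("unique_missing", "records_missing", "invalid_combos", "invalid_records")})
# The evaluator tallies equal the manifest's injected-defect counts exactly;
# percentages are rendered the way the evaluation reports print them.
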