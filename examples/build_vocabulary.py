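"""Build a custom 2-billion-concept vocabulary from a curated code table.

A code table row carries the source code, its German and English
designations, the parent code, the validity period, and (for superseded
codes) the replacement code.  The builder allocates concept ids above
2,000,000,000, applies the default validity window 1970-01-01..2099-12-31
where none is given, and materializes reciprocal hierarchy and replacement
relationships.
"""

import datetime as dt

from vocabprep import BuildConfig, CodeTableRow, assemble_bundle, validate_bundle

rows = [
    CodeTableRow("", "Heilmittel", "Remedies", "", "Procedure", "Chapter"),
    CodeTableRow("1514", "Krankengymnastik", "Physiotherapy session",
                 parent_code="", domain_id="Procedure", concept_class_id="Item"),
    CodeTableRow("1515", "Krankengymnastik Gruppe", "Group physiotherapy",
                 parent_code="1514", domain_id="Procedure", concept_class_id="Item",
                 valid_start_date=dt.date(2005, 1, 1),
                 valid_end_date=dt.date(2020, 12, 31)),
]

config = BuildConfig(
    vocabulary_id="HPNR",
    vocabulary_name="Uniform item numbers for therapeutic services",
    vocabulary_version="example",
)
bundle = assemble_bundle(rows, config)

print(f"tables: vocabulary=1 concept_class={len(bundle.concept_classes)} "
      f"concept={len(bundle.concepts)} concept_relationship={len(bundle.relationships)}")
for c in bundle.concepts:
    print(f"  {c.concept_id}  {c.concept_code:<6} {c.concept_name:<24} "
          f"{c.valid_start_date}..{c.valid_end_date}")
print("violations:", validate_bundle(bundle))
# The synthesized chapter node received the code OMOP1; every concept id is in
# the site-specific range above 2 billion, and an empty violation list means
# the bundle satisfies all OMOP structural rules.
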