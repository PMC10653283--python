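"""Ingest a Usagi-style mapping export and validate its targets.

Vocabularies that map well onto existing standard concepts are not rebuilt
as custom concepts; instead the reviewed Usagi export becomes a
source_to_concept_map table.  Targets are cross-checked against a reference
concept list carrying the standard-concept flag.
"""

import io

from vocabprep import ingest_usagi_export, validate_targets

export = io.StringIO(
    "source_code,target_concept_id,source_code_description,matchScore\n"
    "115b,4128841,Outpatient specialist care item,0.91\n"
    "221a,4021107,Consultation,0.88\n"
    "999x,0,No suitable concept,0.12\n"
)
table = ingest_usagi_export(export, vocabulary_id="ASV")
print(f"ingested {len(table)} mapping records ({len(table.row_errors)} row errors)")

reference = [(4128841, "S"), (4021107, "")]
for v in validate_targets(table, reference):
    print(f"  {v.rule:<20} {v.key:<15} {v.message}")
# 4021107 exists but is not a standard concept; target 0 marks a source code
# the reviewers could not map and is reported informationally, not as an error.
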