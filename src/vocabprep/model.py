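"""Domain model for OMOP CDM vocabulary tables and bundle validation.

A custom ("2-billion") vocabulary is represented as a :class:`VocabularyBundle`
holding one row for the ``vocabulary`` table plus its ``concept_class``,
``concept`` and ``concept_relationship`` rows.  Custom concepts live in the
concept-id range above 2,000,000,000 reserved for site-specific extensions,
are nonstandard (empty ``standard_concept``), and obey the OMOP secondary-key
rule that ``(vocabulary_id, concept_code)`` is unique.

Validation never raises on bad data: :func:`validate_bundle` returns the full
list of rule violations so a caller can report all problems at once.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

TWO_BILLION = 2_000_000_000

#: Default OMOP CDM validity window applied when a source gives no dates.
DEFAULT_VALID_START = dt.date(1970, 1, 1)
DEFAULT_VALID_END = dt.date(2099, 12, 31)

#: Reciprocal relationship pairs stored for hierarchy and replacement links.
RECIPROCALS = {
    "Is a": "Subsumes",
    "Subsumes": "Is a",
    "Concept replaced by": "Concept replaces",
    "Concept replaces": "Concept replaced by",
}


@dataclass(frozen=True)
class ConceptRecord:
    """One row of the OMOP ``concept`` table."""

    concept_id: int
    concept_name: str
    domain_id: str
    vocabulary_id: str
    concept_class_id: str
    standard_concept: str  # "", "S" or "C"
    concept_code: str
    valid_start_date: dt.date
    valid_end_date: dt.date
    invalid_reason: str  # "", "D" (deprecated) or "U" (replaced)


@dataclass(frozen=True)
class VocabularyRecord:
    """One row of the OMOP ``vocabulary`` table."""

    vocabulary_id: str
    vocabulary_name: str
    vocabulary_reference: str
    vocabulary_version: str
    vocabulary_concept_id: int


@dataclass(frozen=True)
class ConceptClassRecord:
    """One row of the OMOP ``concept_class`` table."""

    concept_class_id: str
    concept_class_name: str
    concept_class_concept_id: int


@dataclass(frozen=True)
class ConceptRelationshipRecord:
    """One row of the OMOP ``concept_relationship`` table."""

    concept_id_1: int
    concept_id_2: int
    relationship_id: str
    valid_start_date: dt.date
    valid_end_date: dt.date
    invalid_reason: str = ""


@dataclass
class VocabularyBundle:
    """The four vocabulary tables for one custom vocabulary."""

    vocabulary: VocabularyRecord
    concept_classes: list[ConceptClassRecord] = field(default_factory=list)
    concepts: list[ConceptRecord] = field(default_factory=list)
    relationships: list[ConceptRelationshipRecord] = field(default_factory=list)

    def concept_by_code(self, code: str) -> Optional[ConceptRecord]:
        for c in self.concepts:
            if c.concept_code == code:
                return c
        return None


@dataclass(frozen=True)
class Violation:
    """A single broken validation rule, identified by rule id and row key."""

    rule: str
    key: str
    message: str


def _known_ids(
    bundle: VocabularyBundle, reference_concepts: Optional[Iterable[int]]
) -> set[int]:
    ids = {c.concept_id for c in bundle.concepts}
    if reference_concepts is not None:
        ids |= set(reference_concepts)
    return ids


def validate_bundle(
    bundle: VocabularyBundle,
    reference_concepts: Optional[Iterable[int]] = None,
) -> list[Violation]:
    """Check every structural invariant of a bundle; return all violations.

    ``reference_concepts`` optionally supplies external concept ids (e.g. from
    an Athena download) that relationship endpoints may legitimately point at.
    An empty return value means the bundle is structurally valid.
    """
    out: list[Violation] = []
    seen_ids: dict[int, str] = {}
    seen_codes: dict[tuple[str, str], str] = {}
    class_ids = {cc.concept_class_id for cc in bundle.concept_classes}
    vocab_id = bundle.vocabulary.vocabulary_id

    replaced_ids = {
        r.concept_id_1
        for r in bundle.relationships
        if r.relationship_id == "Concept replaced by"
    }

    for c in bundle.concepts:
        key = f"{c.vocabulary_id}/{c.concept_code}"
        if c.concept_id <= TWO_BILLION:
            out.append(
                Violation(
                    "concept_id_range",
                    key,
                    f"concept_id {c.concept_id} not above {TWO_BILLION}",
                )
            )
        if c.valid_start_date > c.valid_end_date:
            out.append(
                Violation(
                    "date_order",
                    key,
                    f"valid_start_date {c.valid_start_date} after "
                    f"valid_end_date {c.valid_end_date}",
                )
            )
        if c.standard_concept not in ("", None):
            out.append(
                Violation(
                    "nonstandard",
                    key,
                    "custom concepts must have an empty standard_concept flag",
                )
            )
        if c.invalid_reason not in ("", "D", "U"):
            out.append(
                Violation(
                    "invalid_reason_flag",
                    key,
                    f"invalid_reason {c.invalid_reason!r} not in {{'', 'D', 'U'}}",
                )
            )
        if c.concept_id in seen_ids:
            out.append(
                Violation(
                    "id_uniqueness",
                    key,
                    f"concept_id {c.concept_id} already used by "
                    f"{seen_ids[c.concept_id]}",
                )
            )
        else:
            seen_ids[c.concept_id] = key
        code_key = (c.vocabulary_id, c.concept_code)
        if code_key in seen_codes:
            out.append(
                Violation(
                    "code_uniqueness",
                    key,
                    f"(vocabulary_id, concept_code) {code_key} duplicated",
                )
            )
        else:
            seen_codes[code_key] = key
        if class_ids and c.concept_class_id not in class_ids:
            out.append(
                Violation(
                    "unknown_concept_class",
                    key,
                    f"concept_class_id {c.concept_class_id!r} not declared",
                )
            )
        if c.vocabulary_id != vocab_id:
            out.append(
                Violation(
                    "foreign_vocabulary",
                    key,
                    f"concept vocabulary_id {c.vocabulary_id!r} differs from "
                    f"bundle vocabulary {vocab_id!r}",
                )
            )
        if c.concept_id in replaced_ids:
            # OMOP lifecycle convention: a replaced concept is flagged "U"
            # and its validity window is closed.
            if c.invalid_reason != "U":
                out.append(
                    Violation(
                        "replacement_lifecycle",
                        key,
                        "concept with a 'Concept replaced by' link must carry "
                        "invalid_reason 'U'",
                    )
                )
            if c.valid_end_date >= DEFAULT_VALID_END:
                out.append(
                    Violation(
                        "replacement_lifecycle",
                        key,
                        "replaced concept must have a finite valid_end_date",
                    )
                )

    known = _known_ids(bundle, reference_concepts)
    rel_set = {
        (r.concept_id_1, r.concept_id_2, r.relationship_id)
        for r in bundle.relationships
    }
    for r in bundle.relationships:
        key = f"{r.concept_id_1}->{r.concept_id_2}:{r.relationship_id}"
        if r.concept_id_1 == r.concept_id_2:
            out.append(Violation("self_relationship", key, "self-relationship"))
        for endpoint in (r.concept_id_1, r.concept_id_2):
            if endpoint not in known:
                out.append(
                    Violation(
                        "unknown_endpoint",
                        key,
                        f"concept_id {endpoint} not in bundle or reference list",
                    )
                )
        if r.relationship_id not in RECIPROCALS:
            out.append(
                Violation(
                    "relationship_label",
                    key,
                    f"relationship_id {r.relationship_id!r} not supported",
                )
            )
        else:
            mirror = (
                r.concept_id_2,
                r.concept_id_1,
                RECIPROCALS[r.relationship_id],
            )
            if mirror not in rel_set:
                out.append(
                    Violation(
                        "missing_reciprocal",
                        key,
                        f"reciprocal {RECIPROCALS[r.relationship_id]!r} record "
                        "not stored",
                    )
                )
        if r.valid_start_date > r.valid_end_date:
            out.append(Violation("date_order", key, "relationship dates reversed"))
    return out
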