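"""Build a custom 2-billion-concept vocabulary bundle from a code table.

The input is the tabular summary a terminology curator assembles for one
vocabulary: one row per code carrying the German and English designations,
the parent code (hierarchy), the validity period, and — for codes that were
superseded — the replacement code.  Rows with an empty ``code`` stand for
synthesized hierarchy nodes and receive an ``OMOP<N>`` concept code.

Concept ids are allocated consecutively above ``concept_id_base`` in
lexicographic concept-code order, so identical inputs always produce the
identical bundle.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import (
    DEFAULT_VALID_END,
    DEFAULT_VALID_START,
    TWO_BILLION,
    ConceptClassRecord,
    ConceptRecord,
    ConceptRelationshipRecord,
    VocabularyBundle,
    VocabularyRecord,
)


class BuildError(ValueError):
    """Raised when a code table cannot be assembled into a valid bundle."""


@dataclass
class CodeTableRow:
    """One row of the machine-readable code table for a vocabulary."""

    code: str  # empty -> synthesized hierarchy node
    name_de: str
    name_en: str
    parent_code: str = ""
    domain_id: str = "Observation"
    concept_class_id: str = ""
    valid_start_date: Optional[dt.date] = None
    valid_end_date: Optional[dt.date] = None
    replaced_by_code: str = ""


@dataclass
class BuildConfig:
    vocabulary_id: str
    vocabulary_name: str
    vocabulary_reference: str = ""
    vocabulary_version: str = ""
    concept_id_base: int = TWO_BILLION + 1
    synthetic_code_start: int = 1
    concept_classes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concept_id_base <= TWO_BILLION:
            raise BuildError(
                f"concept_id_base must exceed {TWO_BILLION}, "
                f"got {self.concept_id_base}"
            )


def synthesize_concept_code(counter: int) -> str:
    """Concept code for a synthesized node: "OMOP" + decimal counter."""
    if counter < 1:
        raise BuildError(f"synthetic code counter must be >= 1, got {counter}")
    return f"OMOP{counter}"


def resolve_codes(rows: Sequence[CodeTableRow], config: BuildConfig) -> list[str]:
    """Assign synthetic codes to empty-code rows; return the code per row.

    Synthetic codes are numbered per vocabulary from
    ``config.synthetic_code_start``; a collision with a real source code is a
    build error.
    """
    real = {r.code for r in rows if r.code}
    codes: list[str] = []
    counter = config.synthetic_code_start
    for r in rows:
        if r.code:
            codes.append(r.code)
        else:
            code = synthesize_concept_code(counter)
            counter += 1
            if code in real:
                raise BuildError(
                    f"synthesized code {code!r} collides with a source code"
                )
            codes.append(code)
    return codes


def allocate_concept_ids(
    rows: Sequence[CodeTableRow], config: BuildConfig
) -> dict[str, int]:
    """Map each concept code to a consecutive id above the 2-billion base."""
    codes = resolve_codes(rows, config)
    seen: set[str] = set()
    for code in codes:
        if code in seen:
            raise BuildError(f"duplicate code {code!r} in code table")
        seen.add(code)
    return {
        code: config.concept_id_base + i for i, code in enumerate(sorted(codes))
    }


def build_concepts(
    rows: Sequence[CodeTableRow],
    ids: dict[str, int],
    config: BuildConfig,
) -> list[ConceptRecord]:
    codes = resolve_codes(rows, config)
    out: list[ConceptRecord] = []
    for row, code in zip(rows, codes):
        if not row.name_en:
            raise BuildError(f"row {code!r} has no English designation")
        # a class-less row falls back to a vocabulary-wide class so the
        # concept_class foreign key always resolves
        class_id = row.concept_class_id or config.vocabulary_id
        if config.concept_classes and class_id not in config.concept_classes:
            raise BuildError(
                f"row {code!r}: concept_class_id {class_id!r} "
                "not in the declared class list"
            )
        replaced = bool(row.replaced_by_code)
        end = row.valid_end_date or DEFAULT_VALID_END
        if replaced and end >= DEFAULT_VALID_END:
            # a superseded code cannot stay open-ended; close it at the
            # replacement boundary if the table gave no end date
            end = row.valid_start_date or DEFAULT_VALID_START
        out.append(
            ConceptRecord(
                concept_id=ids[code],
                concept_name=row.name_en,
                domain_id=row.domain_id,
                vocabulary_id=config.vocabulary_id,
                concept_class_id=class_id,
                standard_concept="",
                concept_code=code,
                valid_start_date=row.valid_start_date or DEFAULT_VALID_START,
                valid_end_date=end,
                invalid_reason="U" if replaced else "",
            )
        )
    return out


def _rel_pair(
    id_a: int, id_b: int, kind_ab: str, kind_ba: str, start: dt.date, end: dt.date
) -> list[ConceptRelationshipRecord]:
    return [
        ConceptRelationshipRecord(id_a, id_b, kind_ab, start, end),
        ConceptRelationshipRecord(id_b, id_a, kind_ba, start, end),
    ]


def build_hierarchy(
    rows: Sequence[CodeTableRow],
    ids: dict[str, int],
    config: Optional[BuildConfig] = None,
) -> list[ConceptRelationshipRecord]:
    """Materialize each parent edge as an "Is a"/"Subsumes" reciprocal pair."""
    config = config or BuildConfig("_", "_")
    codes = resolve_codes(rows, config)
    out: list[ConceptRelationshipRecord] = []
    for row, code in zip(rows, codes):
        if not row.parent_code:
            continue
        if row.parent_code == code:
            raise BuildError(f"row {code!r} is its own parent")
        if row.parent_code not in ids:
            raise BuildError(
                f"row {code!r} references unknown parent {row.parent_code!r}"
            )
        start = row.valid_start_date or DEFAULT_VALID_START
        end = row.valid_end_date or DEFAULT_VALID_END
        out.extend(
            _rel_pair(ids[code], ids[row.parent_code], "Is a", "Subsumes", start, end)
        )
    return out


def build_replacements(
    rows: Sequence[CodeTableRow],
    ids: dict[str, int],
    config: Optional[BuildConfig] = None,
) -> list[ConceptRelationshipRecord]:
    """Materialize each replacement as a "replaced by"/"replaces" pair.

    Only directly stated pairs are stored; chains are not transitively closed.
    """
    config = config or BuildConfig("_", "_")
    codes = resolve_codes(rows, config)
    out: list[ConceptRelationshipRecord] = []
    for row, code in zip(rows, codes):
        if not row.replaced_by_code:
            continue
        if row.replaced_by_code == code:
            raise BuildError(f"row {code!r} replaces itself")
        if row.replaced_by_code not in ids:
            raise BuildError(
                f"row {code!r} replaced by unknown code {row.replaced_by_code!r}"
            )
        start = row.valid_start_date or DEFAULT_VALID_START
        end = row.valid_end_date or DEFAULT_VALID_END
        out.extend(
            _rel_pair(
                ids[code],
                ids[row.replaced_by_code],
                "Concept replaced by",
                "Concept replaces",
                start,
                end,
            )
        )
    return out


def assemble_bundle(
    rows: Sequence[CodeTableRow], config: BuildConfig
) -> VocabularyBundle:
    """Full build: vocabulary row, classes, concepts, hierarchy, replacements."""
    if not rows:
        raise BuildError("empty_vocabulary: code table has no rows")
    ids = allocate_concept_ids(rows, config)
    concepts = build_concepts(rows, ids, config)
    relationships = build_hierarchy(rows, ids, config) + build_replacements(
        rows, ids, config
    )
    declared = dict(config.concept_classes) or {
        c.concept_class_id: c.concept_class_id for c in concepts
    }
    next_meta_id = config.concept_id_base + len(rows)
    classes = []
    for i, (class_id, class_name) in enumerate(sorted(declared.items())):
        classes.append(
            ConceptClassRecord(class_id, class_name, next_meta_id + i)
        )
    vocabulary = VocabularyRecord(
        vocabulary_id=config.vocabulary_id,
        vocabulary_name=config.vocabulary_name,
        vocabulary_reference=config.vocabulary_reference,
        vocabulary_version=config.vocabulary_version,
        vocabulary_concept_id=next_meta_id + len(classes),
    )
    return VocabularyBundle(
        vocabulary=vocabulary,
        concept_classes=classes,
        concepts=concepts,
        relationships=relationships,
    )
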