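"""CSV readers/writers for every table kind, in two dialects.

The default dialect is comma-separated with ISO dates (``2015-01-01``); the
"athena" dialect is tab-separated with compact dates (``20150101``), the
layout OMOP vocabulary loaders expect.  Reading and writing are inverse for
every table kind in both dialects; row order is preserved on write.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .builder import BuildConfig, CodeTableRow
from .coverage import CoverageAssignment
from .evaluation import ClaimsExtract, ClaimsExtractRow
from .model import (
    ConceptClassRecord,
    ConceptRecord,
    ConceptRelationshipRecord,
    VocabularyBundle,
    VocabularyRecord,
)
from .stcm import STCM_COLUMNS, FormatError, SourceToConceptMapRecord, SourceToConceptMapTable
from .synth import GroundTruthManifest, ManifestRow


@dataclass(frozen=True)
class CsvDialect:
    delimiter: str = ","
    date_format: str = "iso"  # "iso" -> YYYY-MM-DD, "compact" -> YYYYMMDD
    encoding: str = "utf-8"


DIALECTS = {
    "default": CsvDialect(),
    "athena": CsvDialect(delimiter="\t", date_format="compact"),
}


def _fmt_date(d: Optional[dt.date], dialect: CsvDialect) -> str:
    if d is None:
        return ""
    return d.strftime("%Y%m%d") if dialect.date_format == "compact" else d.isoformat()


def _parse_date(s: str, line: int, column: str) -> Optional[dt.date]:
    s = s.strip()
    if not s:
        return None
    try:
        if s.isdigit() and len(s) == 8:
            return dt.date(int(s[:4]), int(s[4:6]), int(s[6:]))
        return dt.date.fromisoformat(s)
    except ValueError as exc:
        raise FormatError(f"line {line}, column {column!r}: bad date {s!r}") from exc


def _int(s: str, default: int = 0) -> int:
    return int(s) if str(s).strip() else default


# column layout, serializer and deserializer per table kind
_SCHEMAS: dict[str, dict] = {}


def _register(kind, columns, to_row, from_row):
    _SCHEMAS[kind] = {"columns": columns, "to_row": to_row, "from_row": from_row}


_register(
    "concept",
    [
        "concept_id",
        "concept_name",
        "domain_id",
        "vocabulary_id",
        "concept_class_id",
        "standard_concept",
        "concept_code",
        "valid_start_date",
        "valid_end_date",
        "invalid_reason",
    ],
    lambda c, d: [
        c.concept_id,
        c.concept_name,
        c.domain_id,
        c.vocabulary_id,
        c.concept_class_id,
        c.standard_concept,
        c.concept_code,
        _fmt_date(c.valid_start_date, d),
        _fmt_date(c.valid_end_date, d),
        c.invalid_reason,
    ],
    lambda r, line: ConceptRecord(
        concept_id=_int(r["concept_id"]),
        concept_name=r["concept_name"],
        domain_id=r["domain_id"],
        vocabulary_id=r["vocabulary_id"],
        concept_class_id=r["concept_class_id"],
        standard_concept=r["standard_concept"],
        concept_code=r["concept_code"],
        valid_start_date=_parse_date(r["valid_start_date"], line, "valid_start_date"),
        valid_end_date=_parse_date(r["valid_end_date"], line, "valid_end_date"),
        invalid_reason=r["invalid_reason"],
    ),
)

_register(
    "vocabulary",
    [
        "vocabulary_id",
        "vocabulary_name",
        "vocabulary_reference",
        "vocabulary_version",
        "vocabulary_concept_id",
    ],
    lambda v, d: [
        v.vocabulary_id,
        v.vocabulary_name,
        v.vocabulary_reference,
        v.vocabulary_version,
        v.vocabulary_concept_id,
    ],
    lambda r, line: VocabularyRecord(
        vocabulary_id=r["vocabulary_id"],
        vocabulary_name=r["vocabulary_name"],
        vocabulary_reference=r["vocabulary_reference"],
        vocabulary_version=r["vocabulary_version"],
        vocabulary_concept_id=_int(r["vocabulary_concept_id"]),
    ),
)

_register(
    "concept_class",
    ["concept_class_id", "concept_class_name", "concept_class_concept_id"],
    lambda c, d: [c.concept_class_id, c.concept_class_name, c.concept_class_concept_id],
    lambda r, line: ConceptClassRecord(
        concept_class_id=r["concept_class_id"],
        concept_class_name=r["concept_class_name"],
        concept_class_concept_id=_int(r["concept_class_concept_id"]),
    ),
)

_register(
    "concept_relationship",
    [
        "concept_id_1",
        "concept_id_2",
        "relationship_id",
        "valid_start_date",
        "valid_end_date",
        "invalid_reason",
    ],
    lambda c, d: [
        c.concept_id_1,
        c.concept_id_2,
        c.relationship_id,
        _fmt_date(c.valid_start_date, d),
        _fmt_date(c.valid_end_date, d),
        c.invalid_reason,
    ],
    lambda r, line: ConceptRelationshipRecord(
        concept_id_1=_int(r["concept_id_1"]),
        concept_id_2=_int(r["concept_id_2"]),
        relationship_id=r["relationship_id"],
        valid_start_date=_parse_date(r["valid_start_date"], line, "valid_start_date"),
        valid_end_date=_parse_date(r["valid_end_date"], line, "valid_end_date"),
        invalid_reason=r["invalid_reason"],
    ),
)

_register(
    "source_to_concept_map",
    STCM_COLUMNS,
    lambda m, d: [
        m.source_code,
        m.source_concept_id,
        m.source_vocabulary_id,
        m.source_code_description,
        m.target_concept_id,
        m.target_vocabulary_id,
        _fmt_date(m.valid_start_date, d),
        _fmt_date(m.valid_end_date, d),
        m.invalid_reason,
    ],
    lambda r, line: SourceToConceptMapRecord(
        source_code=r["source_code"],
        source_concept_id=_int(r["source_concept_id"]),
        source_vocabulary_id=r["source_vocabulary_id"],
        source_code_description=r["source_code_description"],
        target_concept_id=_int(r["target_concept_id"]),
        target_vocabulary_id=r["target_vocabulary_id"],
        valid_start_date=_parse_date(r["valid_start_date"], line, "valid_start_date"),
        valid_end_date=_parse_date(r["valid_end_date"], line, "valid_end_date"),
        invalid_reason=r["invalid_reason"],
    ),
)

_register(
    "code_table",
    [
        "code",
        "name_de",
        "name_en",
        "parent_code",
        "domain_id",
        "concept_class_id",
        "valid_start_date",
        "valid_end_date",
        "replaced_by_code",
    ],
    lambda c, d: [
        c.code,
        c.name_de,
        c.name_en,
        c.parent_code,
        c.domain_id,
        c.concept_class_id,
        _fmt_date(c.valid_start_date, d),
        _fmt_date(c.valid_end_date, d),
        c.replaced_by_code,
    ],
    lambda r, line: CodeTableRow(
        code=r["code"],
        name_de=r["name_de"],
        name_en=r["name_en"],
        parent_code=r["parent_code"],
        domain_id=r["domain_id"],
        concept_class_id=r["concept_class_id"],
        valid_start_date=_parse_date(r["valid_start_date"], line, "valid_start_date"),
        valid_end_date=_parse_date(r["valid_end_date"], line, "valid_end_date"),
        replaced_by_code=r["replaced_by_code"],
    ),
)

_register(
    "extract",
    ["source_code", "event_date", "source_table"],
    lambda c, d: [c.source_code, _fmt_date(c.event_date, d), c.source_table],
    lambda r, line: ClaimsExtractRow(
        source_code=r["source_code"],
        event_date=_parse_date(r["event_date"], line, "event_date"),
        source_table=r["source_table"],
    ),
)

_register(
    "manifest",
    ["row_id", "defect", "original_code", "source_code", "event_date"],
    lambda c, d: [
        c.row_id,
        c.defect,
        c.original_code,
        c.source_code,
        _fmt_date(c.event_date, d),
    ],
    lambda r, line: ManifestRow(
        row_id=_int(r["row_id"]),
        defect=r["defect"],
        original_code=r["original_code"],
        source_code=r["source_code"],
        event_date=_parse_date(r["event_date"], line, "event_date"),
    ),
)

_register(
    "assignment",
    ["vocabulary_name", "category", "note"],
    lambda c, d: [c.vocabulary_name, c.category, c.note],
    lambda r, line: CoverageAssignment(
        vocabulary_name=r["vocabulary_name"],
        category=r["category"],
        note=r["note"],
    ),
)

TABLE_KINDS = tuple(_SCHEMAS)


def write_table(
    path, records: Sequence, kind: str, dialect: CsvDialect = CsvDialect()
) -> None:
    schema = _SCHEMAS[kind]
    rows = [schema["to_row"](rec, dialect) for rec in records]
    df = pd.DataFrame(rows, columns=schema["columns"])
    df.to_csv(path, sep=dialect.delimiter, index=False, encoding=dialect.encoding)


def read_table(
    path,
    kind: str,
    dialect: CsvDialect = CsvDialect(),
    strict: bool = True,
) -> list:
    """Parse a CSV into typed records; header checked against the table kind."""
    schema = _SCHEMAS[kind]
    df = pd.read_csv(
        path,
        sep=dialect.delimiter,
        dtype=str,
        keep_default_na=False,
        encoding=dialect.encoding,
    )
    expected = set(schema["columns"])
    found = set(df.columns)
    if strict and found != expected:
        raise FormatError(
            f"{path}: column mismatch for {kind!r}; expected "
            f"{sorted(expected)}, found {sorted(found)}"
        )
    if missing := expected - found:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)} for {kind!r}")
    out = []
    for i, (_, row) in enumerate(df.iterrows()):
        out.append(schema["from_row"](row, i + 2))
    return out


BUNDLE_FILES = ("vocabulary", "concept_class", "concept", "concept_relationship")


def write_bundle(
    directory, bundle: VocabularyBundle, dialect: CsvDialect = CsvDialect()
) -> None:
    """Write the four vocabulary tables as ``<kind>.csv`` in a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_table(directory / "vocabulary.csv", [bundle.vocabulary], "vocabulary", dialect)
    write_table(
        directory / "concept_class.csv", bundle.concept_classes, "concept_class", dialect
    )
    write_table(directory / "concept.csv", bundle.concepts, "concept", dialect)
    write_table(
        directory / "concept_relationship.csv",
        bundle.relationships,
        "concept_relationship",
        dialect,
    )


def read_bundle(directory, dialect: CsvDialect = CsvDialect()) -> VocabularyBundle:
    directory = Path(directory)
    vocab = read_table(directory / "vocabulary.csv", "vocabulary", dialect)
    if len(vocab) != 1:
        raise FormatError(
            f"{directory}: expected exactly one vocabulary row, found {len(vocab)}"
        )
    return VocabularyBundle(
        vocabulary=vocab[0],
        concept_classes=read_table(
            directory / "concept_class.csv", "concept_class", dialect
        ),
        concepts=read_table(directory / "concept.csv", "concept", dialect),
        relationships=read_table(
            directory / "concept_relationship.csv", "concept_relationship", dialect
        ),
    )


def read_extract(path, dialect: CsvDialect = CsvDialect(), name: str = "") -> ClaimsExtract:
    rows = read_table(path, "extract", dialect)
    return ClaimsExtract(rows=rows, name=name or Path(path).stem)


def write_stcm(
    path, table: SourceToConceptMapTable, dialect: CsvDialect = CsvDialect()
) -> None:
    write_table(path, table.records, "source_to_concept_map", dialect)


def read_stcm(
    path, dialect: CsvDialect = CsvDialect(), vocabulary_id: str = ""
) -> SourceToConceptMapTable:
    records = read_table(path, "source_to_concept_map", dialect)
    vocab = vocabulary_id or (records[0].source_vocabulary_id if records else "")
    return SourceToConceptMapTable(vocabulary_id=vocab, records=records)


def write_manifest(path, manifest: GroundTruthManifest, dialect: CsvDialect = CsvDialect()) -> None:
    write_table(path, manifest.rows, "manifest", dialect)


def read_manifest(path, dialect: CsvDialect = CsvDialect()) -> GroundTruthManifest:
    return GroundTruthManifest(rows=read_table(path, "manifest", dialect))


def read_build_configs(path) -> dict[str, BuildConfig]:
    """Build configuration: YAML mapping, one section per vocabulary id."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sections = raw.get("vocabularies", raw)
    out: dict[str, BuildConfig] = {}
    for vocab_id, params in sections.items():
        params = dict(params or {})
        params.setdefault("vocabulary_name", vocab_id)
        out[vocab_id] = BuildConfig(vocabulary_id=vocab_id, **params)
    return out
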