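"""Ingestion and validation of ``source_to_concept_map`` tables.

Vocabularies that can be expressed through existing standard concepts are
mapped with the OHDSI tool Usagi; its review export follows the OMOP CDM
``source_to_concept_map`` layout.  This module reads such exports (both the
minimal column set and Usagi's richer one), normalizes them into typed
records, and cross-checks mapping targets against a reference concept list.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .model import DEFAULT_VALID_END, DEFAULT_VALID_START, Violation

log = logging.getLogger(__name__)

STCM_COLUMNS = [
    "source_code",
    "source_concept_id",
    "source_vocabulary_id",
    "source_code_description",
    "target_concept_id",
    "target_vocabulary_id",
    "valid_start_date",
    "valid_end_date",
    "invalid_reason",
]

MANDATORY = ("source_code", "target_concept_id")


class FormatError(ValueError):
    """Input file does not match the expected column layout."""


@dataclass(frozen=True)
class SourceToConceptMapRecord:
    source_code: str
    source_concept_id: int
    source_vocabulary_id: str
    source_code_description: str
    target_concept_id: int
    target_vocabulary_id: str
    valid_start_date: dt.date
    valid_end_date: dt.date
    invalid_reason: str = ""


@dataclass
class RowError:
    line: int
    message: str


@dataclass
class SourceToConceptMapTable:
    vocabulary_id: str
    records: list[SourceToConceptMapRecord] = field(default_factory=list)
    row_errors: list[RowError] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)


def _parse_date(value, default: dt.date) -> dt.date:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return default
    s = str(value).strip()
    if not s:
        return default
    if s.isdigit() and len(s) == 8:  # compact YYYYMMDD
        return dt.date(int(s[:4]), int(s[4:6]), int(s[6:]))
    return dt.date.fromisoformat(s)


def ingest_usagi_export(
    path,
    vocabulary_id: Optional[str] = None,
    delimiter: str = ",",
) -> SourceToConceptMapTable:
    """Read a Usagi/STCM CSV export into a typed table.

    Rows are never silently dropped: input data rows = records + row errors.
    Columns beyond the STCM layout are ignored with a logged notice.
    """
    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False)
    for col in MANDATORY:
        if col not in df.columns:
            raise FormatError(f"mandatory column {col!r} missing from {path}")
    extra = [c for c in df.columns if c not in STCM_COLUMNS]
    if extra:
        log.info("ignoring %d extra column(s) in %s: %s", len(extra), path, extra)

    table = SourceToConceptMapTable(vocabulary_id=vocabulary_id or "")
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # 1-based, after the header
        get = lambda col, default="": getattr(row, col, default) if col in df.columns else default
        try:
            rec = SourceToConceptMapRecord(
                source_code=str(get("source_code")),
                source_concept_id=int(get("source_concept_id") or 0),
                source_vocabulary_id=str(
                    get("source_vocabulary_id") or table.vocabulary_id
                ),
                source_code_description=str(get("source_code_description")),
                target_concept_id=int(get("target_concept_id") or 0),
                target_vocabulary_id=str(get("target_vocabulary_id")),
                valid_start_date=_parse_date(
                    get("valid_start_date"), DEFAULT_VALID_START
                ),
                valid_end_date=_parse_date(get("valid_end_date"), DEFAULT_VALID_END),
                invalid_reason=str(get("invalid_reason")),
            )
        except (ValueError, TypeError) as exc:
            table.row_errors.append(RowError(line, str(exc)))
            continue
        table.records.append(rec)
    if not table.vocabulary_id and table.records:
        table.vocabulary_id = table.records[0].source_vocabulary_id
    pairs = [(r.source_code, r.target_concept_id) for r in table.records]
    if len(pairs) != len(set(pairs)):
        log.warning("duplicate (source_code, target_concept_id) pairs in %s", path)
    return table


def validate_targets(
    table: SourceToConceptMapTable,
    reference_concepts: Iterable[tuple[int, str]],
) -> list[Violation]:
    """Cross-check mapping targets against (concept_id, standard_concept) pairs.

    Target 0 is the OMOP convention for an unmappable source code; it is
    reported informationally as ``unmapped`` rather than as an error.
    """
    standard = {cid for cid, flag in reference_concepts if flag == "S"}
    known = standard | {cid for cid, _ in reference_concepts}
    out: list[Violation] = []
    for rec in table.records:
        key = f"{rec.source_code}->{rec.target_concept_id}"
        if rec.target_concept_id == 0:
            out.append(Violation("unmapped", key, "source code mapped to concept 0"))
        elif rec.target_concept_id not in known:
            out.append(
                Violation(
                    "unknown_target",
                    key,
                    f"target {rec.target_concept_id} absent from reference list",
                )
            )
        elif rec.target_concept_id not in standard:
            out.append(
                Violation(
                    "nonstandard_target",
                    key,
                    f"target {rec.target_concept_id} is not a standard concept",
                )
            )
    return out
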