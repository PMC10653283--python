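"""Completeness and correctness evaluation of claims extracts.

Given an extract of ``(source_code, event_date, source_table)`` rows pulled
from claims data and one or more prepared vocabulary sources (custom concept
bundles and/or source-to-concept-map tables), two questions are answered:

* **completeness** — is each source code present in any prepared vocabulary,
  i.e. does a lookup of the code in the ``concept_code`` (concept table) or
  ``source_code`` (source_to_concept_map) column yield a concept_id?  Codes
  with no hit resolve to concept_id 0 and are counted as missing, both at
  unique-code level and at record level.
* **correctness** — for the codes that *were* found, does the event date fall
  inside the concept's validity period ``[valid_start_date, valid_end_date]``
  (inclusive on both ends)?  Records with a missing code or date are excluded
  and counted.  Invalid combinations are classified as dated before the start
  or after the end of the validity window.

A code may match several concepts (e.g. when two candidate vocabularies must
be searched, as for outpatient charge types that are a selection of EBM
codes).  Matching then uses the union of validity windows: a date is valid if
any window contains it.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence, Union

import pandas as pd

from .model import VocabularyBundle
from .stcm import SourceToConceptMapTable

Source = Union[VocabularyBundle, SourceToConceptMapTable]


@dataclass(frozen=True)
class ClaimsExtractRow:
    source_code: str  # empty string = missing
    event_date: Optional[dt.date]  # None = missing
    source_table: str = ""


@dataclass
class ClaimsExtract:
    rows: list[ClaimsExtractRow] = field(default_factory=list)
    name: str = ""

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class CodeTally:
    matched: bool
    concept_id: int  # 0 when unmatched
    record_count: int


@dataclass
class ComboTally:
    valid: bool
    side: str  # "before_start", "after_end" or "none"
    record_count: int


@dataclass
class CompletenessResult:
    vocabulary: str
    per_code: dict[str, CodeTally]
    excluded_missing_code: int  # rows with an empty source code

    @property
    def unique_total(self) -> int:
        return len(self.per_code)

    @property
    def unique_missing(self) -> int:
        return sum(1 for t in self.per_code.values() if not t.matched)

    @property
    def records_total(self) -> int:
        return sum(t.record_count for t in self.per_code.values())

    @property
    def records_missing(self) -> int:
        return sum(t.record_count for t in self.per_code.values() if not t.matched)

    @property
    def pct_unique_missing(self) -> float:
        return 100.0 * self.unique_missing / self.unique_total if self.unique_total else float("nan")

    @property
    def pct_records_missing(self) -> float:
        return 100.0 * self.records_missing / self.records_total if self.records_total else float("nan")

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(matched, missing) DataFrames with occurrence counts, for CSV export."""
        rows = [
            {
                "source_code": code,
                "concept_id": t.concept_id,
                "occurrence_count": t.record_count,
            }
            for code, t in sorted(self.per_code.items())
        ]
        df = pd.DataFrame(rows, columns=["source_code", "concept_id", "occurrence_count"])
        return df[df.concept_id != 0].reset_index(drop=True), df[
            df.concept_id == 0
        ].reset_index(drop=True)


@dataclass
class CorrectnessResult:
    vocabulary: str
    per_combo: dict[tuple[str, dt.date], ComboTally]
    excluded_missing_fields: int  # matched-code rows lacking code or date
    concept_ids: dict[str, int] = field(default_factory=dict)
    evaluable: bool = True  # False when the source carries no usable dates

    @property
    def unique_total(self) -> int:
        return len(self.per_combo)

    @property
    def unique_invalid(self) -> int:
        return sum(1 for t in self.per_combo.values() if not t.valid)

    @property
    def records_total(self) -> int:
        return sum(t.record_count for t in self.per_combo.values())

    @property
    def records_invalid(self) -> int:
        return sum(t.record_count for t in self.per_combo.values() if not t.valid)

    def invalid_by_side(self) -> dict[str, int]:
        out = {"before_start": 0, "after_end": 0}
        for t in self.per_combo.values():
            if not t.valid:
                out[t.side] += 1
        return out

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(valid, invalid) DataFrames with occurrence counts, for CSV export."""
        rows = [
            {
                "source_code": code,
                "event_date": date.isoformat(),
                "concept_id": self.concept_ids.get(code, 0),
                "valid": t.valid,
                "side": t.side,
                "occurrence_count": t.record_count,
            }
            for (code, date), t in sorted(self.per_combo.items())
        ]
        cols = ["source_code", "event_date", "concept_id", "valid", "side", "occurrence_count"]
        df = pd.DataFrame(rows, columns=cols)
        return (
            df[df.valid].drop(columns="valid").reset_index(drop=True),
            df[~df.valid].drop(columns="valid").reset_index(drop=True),
        )


def _normalize(code: str, normalize: bool) -> str:
    return code.strip().upper() if normalize else code


def build_lookup(
    sources: Sequence[Source], normalize: bool = False
) -> dict[str, list[tuple[int, dt.date, dt.date]]]:
    """Index every source by code: code -> [(concept_id, start, end), ...].

    Bundle concepts contribute their concept validity window; mapping tables
    contribute the mapping record's window.  Matching is exact (case and
    whitespace sensitive) unless ``normalize`` is set.
    """
    lookup: dict[str, list[tuple[int, dt.date, dt.date]]] = {}
    for src in sources:
        if isinstance(src, VocabularyBundle):
            for c in src.concepts:
                lookup.setdefault(_normalize(c.concept_code, normalize), []).append(
                    (c.concept_id, c.valid_start_date, c.valid_end_date)
                )
        elif isinstance(src, SourceToConceptMapTable):
            for r in src.records:
                lookup.setdefault(_normalize(r.source_code, normalize), []).append(
                    (r.target_concept_id, r.valid_start_date, r.valid_end_date)
                )
        else:
            raise TypeError(f"unsupported source type {type(src).__name__}")
    return lookup


def assess_completeness(
    extract: ClaimsExtract,
    sources: Sequence[Source],
    normalize: bool = False,
) -> CompletenessResult:
    """Tally matched/missing source codes at unique-code and record level.

    A code is matched iff it is found in *any* supplied source (multi-
    vocabulary lookup).  Rows with an empty source code cannot be looked up
    and are excluded and counted separately.
    """
    if not sources:
        raise ValueError("at least one vocabulary source is required")
    lookup = build_lookup(sources, normalize)
    per_code: dict[str, CodeTally] = {}
    excluded = 0
    for row in extract.rows:
        if not row.source_code:
            excluded += 1
            continue
        code = _normalize(row.source_code, normalize)
        tally = per_code.get(code)
        if tally is None:
            hits = lookup.get(code)
            per_code[code] = CodeTally(
                matched=hits is not None,
                concept_id=hits[0][0] if hits else 0,
                record_count=1,
            )
        else:
            tally.record_count += 1
    return CompletenessResult(
        vocabulary=extract.name, per_code=per_code, excluded_missing_code=excluded
    )


def _classify(
    date: dt.date, windows: list[tuple[int, dt.date, dt.date]]
) -> tuple[bool, str]:
    if any(start <= date <= end for _, start, end in windows):
        return True, "none"
    starts = [w[1] for w in windows]
    ends = [w[2] for w in windows]
    if date < min(starts):
        return False, "before_start"
    if date > max(ends):
        return False, "after_end"
    # date falls in a gap between windows: attribute it to the side of the
    # nearest window boundary
    later_starts = [s for s in starts if s > date]
    earlier_ends = [e for e in ends if e < date]
    to_next = min(later_starts) - date if later_starts else None
    from_prev = date - max(earlier_ends) if earlier_ends else None
    if to_next is not None and (from_prev is None or to_next <= from_prev):
        return False, "before_start"
    return False, "after_end"


def assess_correctness(
    extract: ClaimsExtract,
    completeness: CompletenessResult,
    sources: Sequence[Source],
    normalize: bool = False,
) -> CorrectnessResult:
    """Check event dates against the validity windows of matched codes.

    Only codes the completeness step resolved to a concept_id are examined;
    records with a missing source code or missing date are excluded and
    counted.  A (code, date) combination is valid iff some validity window of
    the code contains the date (inclusive bounds).
    """
    if not sources:
        raise ValueError("at least one vocabulary source is required")
    lookup = build_lookup(sources, normalize)
    matched_codes = {c for c, t in completeness.per_code.items() if t.matched}
    for code in matched_codes:
        if code not in lookup:
            raise RuntimeError(
                f"internal inconsistency: matched code {code!r} absent from sources"
            )
    per_combo: dict[tuple[str, dt.date], ComboTally] = {}
    excluded = 0
    saw_matched_row = False
    for row in extract.rows:
        code = _normalize(row.source_code, normalize) if row.source_code else ""
        if code and code not in matched_codes:
            continue  # unmatched codes are outside the correctness scope
        if not code or row.event_date is None:
            excluded += 1
            continue
        saw_matched_row = True
        key = (code, row.event_date)
        tally = per_combo.get(key)
        if tally is None:
            valid, side = _classify(row.event_date, lookup[code])
            per_combo[key] = ComboTally(valid=valid, side=side, record_count=1)
        else:
            tally.record_count += 1
    concept_ids = {
        c: completeness.per_code[c].concept_id for c in matched_codes
    }
    return CorrectnessResult(
        vocabulary=extract.name,
        per_combo=per_combo,
        excluded_missing_fields=excluded,
        concept_ids=concept_ids,
        evaluable=saw_matched_row or excluded == 0,
    )


# --- reporting -------------------------------------------------------------

def format_percent(n: int, total: int) -> str:
    """Percentage 100*n/total as printed in evaluation reports.

    Rounded half-up to two decimal places; an exact zero numerator renders
    as "0"; a nonzero share below 0.01 percent is shown with two significant
    digits instead (e.g. "0.0036", "0.0074").  An undefined share
    (total = 0) renders as an em dash.
    """
    if total == 0:
        return "—"
    if n == 0:
        return "0"
    pct = Decimal(n) * 100 / Decimal(total)
    if pct < Decimal("0.01"):
        exponent = pct.adjusted()  # position of the leading significant digit
        rounded = pct.quantize(
            Decimal(1).scaleb(exponent - 1), rounding=ROUND_HALF_UP
        )
        return format(rounded, "f")
    return format(pct.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP), "f")


def format_fraction(n: int, total: int) -> str:
    """"n/N (pct)" with thousands separators, report style."""
    return f"{n:,}/{total:,} ({format_percent(n, total)})"


def render_report(
    result: Union[CompletenessResult, CorrectnessResult],
) -> list[tuple[str, int, int, str]]:
    """Rows (vocabulary, n, N, percent text) for the two-level report table."""
    if isinstance(result, CompletenessResult):
        return [
            (
                result.vocabulary,
                result.unique_missing,
                result.unique_total,
                format_percent(result.unique_missing, result.unique_total),
            ),
            (
                result.vocabulary,
                result.records_missing,
                result.records_total,
                format_percent(result.records_missing, result.records_total),
            ),
        ]
    if not result.evaluable:
        return [(result.vocabulary, 0, 0, "not evaluable")] * 2
    return [
        (
            result.vocabulary,
            result.unique_invalid,
            result.unique_total,
            format_percent(result.unique_invalid, result.unique_total),
        ),
        (
            result.vocabulary,
            result.records_invalid,
            result.records_total,
            format_percent(result.records_invalid, result.records_total),
        ),
    ]


def aggregate_completeness(
    results: Sequence[CompletenessResult],
) -> dict[str, tuple[int, int]]:
    """Cross-vocabulary totals, both summed and code-deduplicated.

    Summed totals add each vocabulary's n and N; the deduplicated variant
    counts each distinct source code once across all vocabularies (a code is
    missing only if it matched nowhere).
    """
    summed_n = sum(r.unique_missing for r in results)
    summed_total = sum(r.unique_total for r in results)
    matched: set[str] = set()
    seen: set[str] = set()
    for r in results:
        for code, t in r.per_code.items():
            seen.add(code)
            if t.matched:
                matched.add(code)
    return {
        "summed": (summed_n, summed_total),
        "deduplicated": (len(seen - matched), len(seen)),
        "summed_records": (
            sum(r.records_missing for r in results),
            sum(r.records_total for r in results),
        ),
    }
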