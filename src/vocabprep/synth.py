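"""Synthetic claims-data generator with a ground-truth defect manifest.

Real claims extracts and the licensed German vocabulary content cannot be
redistributed, so tests and examples run against a generated stand-in: a toy
hierarchical vocabulary (code table) plus a claims extract drawn from it in
which a configurable fraction of rows carries exactly one injected defect:

* ``unknown_code`` — the code was corrupted the way real documentation
  errors corrupt codes: transposed adjacent digits, a deleted character, or
  the digit zero written for the letter "O";
* ``date_before_start`` / ``date_after_end`` — the event date falls 1–365
  days outside the code's validity window on the stated side;
* ``missing_code`` / ``missing_date`` — the field is empty.

Every row's defect class and original code are recorded in a
:class:`GroundTruthManifest`, whose aggregates are the exact expected output
of the completeness and correctness evaluators on the generated extract.
Generation is fully deterministic per seed (numpy PCG64 generator).
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .builder import BuildConfig, CodeTableRow, allocate_concept_ids, build_concepts
from .evaluation import ClaimsExtract, ClaimsExtractRow
from .model import DEFAULT_VALID_END, DEFAULT_VALID_START

log = logging.getLogger(__name__)

DEFECT_CLASSES = (
    "none",
    "unknown_code",
    "date_before_start",
    "date_after_end",
    "missing_code",
    "missing_date",
)

ERROR_OPERATORS = ("transpose_digits", "delete_char", "zero_for_O")


class GeneratorError(RuntimeError):
    pass


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic run.

    Defaults emulate a mid-sized claims vocabulary (on the order of the
    remedy catalogs) observed over a six-year billing window, with a small
    minority of defective rows: unknown codes dominate the defects, dates
    before the validity start are more common than dates after its end, and
    missing fields are rare.
    """

    seed: int = 0
    n_codes: int = 100
    hierarchy_depth: int = 3
    n_records: int = 10_000
    p_unknown_code: float = 0.05
    error_mix: dict[str, float] = field(
        default_factory=lambda: {
            "transpose_digits": 0.4,
            "delete_char": 0.4,
            "zero_for_O": 0.2,
        }
    )
    p_date_before_start: float = 0.02
    p_date_after_end: float = 0.005
    p_missing_code: float = 0.01
    p_missing_date: float = 0.01
    date_window: tuple[dt.date, dt.date] = (dt.date(2015, 1, 1), dt.date(2020, 12, 31))
    p_finite_window: float = 0.5  # remaining codes keep the default window
    p_replaced: float = 0.04

    def __post_init__(self) -> None:
        fractions = (
            self.p_unknown_code,
            self.p_date_before_start,
            self.p_date_after_end,
            self.p_missing_code,
            self.p_missing_date,
        )
        if any(not 0 <= p <= 1 for p in fractions) or sum(fractions) > 1:
            raise GeneratorError(
                "defect fractions must each lie in [0, 1] and jointly sum to <= 1"
            )
        if self.n_codes < self.hierarchy_depth:
            raise GeneratorError(
                f"hierarchy depth {self.hierarchy_depth} infeasible with "
                f"{self.n_codes} codes"
            )
        if unknown := set(self.error_mix) - set(ERROR_OPERATORS):
            raise GeneratorError(f"unknown error operator(s): {sorted(unknown)}")

    @property
    def defect_probabilities(self) -> list[float]:
        ps = [
            self.p_unknown_code,
            self.p_date_before_start,
            self.p_date_after_end,
            self.p_missing_code,
            self.p_missing_date,
        ]
        return [1.0 - sum(ps)] + ps


@dataclass(frozen=True)
class ManifestRow:
    row_id: int
    defect: str
    original_code: str  # pre-corruption code; empty for missing_code rows
    source_code: str  # code as emitted into the extract
    event_date: Optional[dt.date]


@dataclass
class GroundTruthManifest:
    rows: list[ManifestRow] = field(default_factory=list)

    def aggregates(self) -> dict[str, int]:
        """Expected evaluator tallies, recomputed from the row labels."""
        unknown = [r for r in self.rows if r.defect == "unknown_code"]
        before = {
            (r.source_code, r.event_date)
            for r in self.rows
            if r.defect == "date_before_start"
        }
        after = {
            (r.source_code, r.event_date)
            for r in self.rows
            if r.defect == "date_after_end"
        }
        return {
            "records_missing": len(unknown),
            "unique_missing": len({r.source_code for r in unknown}),
            "invalid_records": sum(
                1 for r in self.rows if r.defect in ("date_before_start", "date_after_end")
            ),
            "invalid_combos": len(before) + len(after),
            "invalid_combos_before_start": len(before),
            "invalid_combos_after_end": len(after),
            "excluded_missing_fields": sum(
                1 for r in self.rows if r.defect in ("missing_code", "missing_date")
            ),
        }


def _sample_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


def _make_code(rng: np.random.Generator) -> str:
    code = str(int(rng.integers(100, 10_000)))
    draw = rng.random()
    if draw < 0.15:
        code = "O" + code  # letter O, so the zero-for-O error is applicable
    elif draw < 0.35:
        code = chr(ord("A") + int(rng.integers(0, 12))) + code
    return code


def generate_vocabulary(config: GeneratorConfig) -> list[CodeTableRow]:
    """Toy code table: unique alphanumeric codes, a hierarchy of the requested
    depth, a mix of default and finite validity windows, a few replacements."""
    rng = np.random.default_rng(config.seed)
    codes: list[str] = []
    seen: set[str] = set()
    while len(codes) < config.n_codes:
        code = _make_code(rng)
        if code not in seen:
            seen.add(code)
            codes.append(code)
    if config.error_mix.get("zero_for_O", 0) > 0 and not any("O" in c for c in codes):
        replacement = "O" + codes[0]
        if replacement not in seen:
            codes[0] = replacement

    depth = config.hierarchy_depth
    # backbone chain guarantees the deepest leaf sits exactly at `depth`
    levels: dict[str, int] = {codes[i]: i + 1 for i in range(depth)}
    by_level: dict[int, list[str]] = {i + 1: [codes[i]] for i in range(depth)}
    for code in codes[depth:]:
        level = int(rng.integers(2, depth + 1)) if depth > 1 else 1
        levels[code] = level
        by_level.setdefault(level, []).append(code)

    window_lo, window_hi = config.date_window
    rows: list[CodeTableRow] = []
    finite_codes: list[str] = []
    for code in codes:
        level = levels[code]
        parent = ""
        if level > 1:
            parents = by_level[level - 1]
            parent = parents[int(rng.integers(0, len(parents)))]
            if parent == code:  # only possible on the backbone, never in practice
                parent = codes[level - 2]
        if rng.random() < config.p_finite_window:
            start = window_lo + dt.timedelta(days=int(rng.integers(0, 731)))
            end = start + dt.timedelta(days=int(rng.integers(180, 1462)))
            finite_codes.append(code)
        else:
            start, end = None, None
        rows.append(
            CodeTableRow(
                code=code,
                name_de=f"Leistung {code}",
                name_en=f"Service item {code}",
                parent_code=parent,
                domain_id="Procedure",
                concept_class_id="Level " + str(level),
                valid_start_date=start,
                valid_end_date=end,
            )
        )
    # a few superseded codes among finite-window leaves (keeps their explicit
    # windows intact through the build)
    leaves = [
        c for c in finite_codes if levels[c] == depth and c not in codes[:depth]
    ]
    n_repl = min(len(leaves) // 2, int(round(config.p_replaced * config.n_codes)))
    row_by_code = {r.code: r for r in rows}
    for i in range(n_repl):
        old, new = leaves[2 * i], leaves[2 * i + 1]
        row_by_code[old].replaced_by_code = new
    return rows


def corrupt_code(
    code: str,
    operator: str,
    rng: np.random.Generator,
    known_codes: set[str],
    max_retries: int = 10,
) -> str:
    """Apply one documentation-error operator; never returns a known code."""

    def attempt(op: str) -> Optional[str]:
        if op == "transpose_digits":
            pairs = [
                i
                for i in range(len(code) - 1)
                if code[i].isdigit() and code[i + 1].isdigit() and code[i] != code[i + 1]
            ]
            if not pairs:
                return None
            i = pairs[int(rng.integers(0, len(pairs)))]
            return code[:i] + code[i + 1] + code[i] + code[i + 2 :]
        if op == "delete_char":
            if len(code) < 2:
                return None
            i = int(rng.integers(0, len(code)))
            return code[:i] + code[i + 1 :]
        if op == "zero_for_O":
            positions = [i for i, ch in enumerate(code) if ch == "O"]
            if not positions:
                return None
            i = positions[int(rng.integers(0, len(positions)))]
            return code[:i] + "0" + code[i + 1 :]
        raise GeneratorError(f"unknown operator {operator!r}")

    for op in (operator, "delete_char"):
        for _ in range(max_retries):
            out = attempt(op)
            if out is None:
                break
            if out and out != code and out not in known_codes:
                return out
    raise GeneratorError(
        f"could not corrupt code {code!r} without colliding with the vocabulary"
    )


def generate_extract(
    config: GeneratorConfig, vocabulary: Sequence[CodeTableRow]
) -> tuple[ClaimsExtract, GroundTruthManifest]:
    """Claims extract with manifest-tracked defects drawn from ``vocabulary``.

    Validity windows are taken from the built concept records (the same
    windows the evaluators will see), so defect dates are out of range and
    clean dates in range by construction.
    """
    if not vocabulary:
        raise GeneratorError("vocabulary is empty")
    rng = np.random.default_rng((config.seed * 2_654_435_761 + 97) % 2**31)
    build_cfg = BuildConfig("SYN", "Synthetic vocabulary")
    ids = allocate_concept_ids(vocabulary, build_cfg)
    concepts = build_concepts(vocabulary, ids, build_cfg)
    known = {c.concept_code for c in concepts}
    windows = {
        c.concept_code: (c.valid_start_date, c.valid_end_date) for c in concepts
    }
    all_codes = sorted(known)
    before_eligible = [
        c for c in all_codes if windows[c][0] != DEFAULT_VALID_START
    ]
    after_eligible = [c for c in all_codes if windows[c][1] != DEFAULT_VALID_END]

    ops = sorted(k for k, w in config.error_mix.items() if w > 0)
    op_weights = np.array([config.error_mix[k] for k in ops], dtype=float)
    op_weights /= op_weights.sum() if len(ops) else 1.0

    window_lo, window_hi = config.date_window
    classes = list(DEFECT_CLASSES)
    draws = rng.choice(len(classes), size=config.n_records, p=config.defect_probabilities)

    def clean_date(code: str) -> dt.date:
        start, end = windows[code]
        if (start, end) == (DEFAULT_VALID_START, DEFAULT_VALID_END):
            return _sample_date(rng, window_lo, window_hi)
        return _sample_date(rng, start, end)

    ex_rows: list[ClaimsExtractRow] = []
    mf_rows: list[ManifestRow] = []
    for row_id, class_idx in enumerate(draws):
        defect = classes[int(class_idx)]
        if defect in ("date_before_start", "date_after_end"):
            eligible = before_eligible if defect == "date_before_start" else after_eligible
            if not eligible:
                log.warning(
                    "row %d: no code can host a %s defect; emitting a clean row",
                    row_id,
                    defect,
                )
                defect = "none"
        if defect == "missing_code":
            code, date, original = "", _sample_date(rng, window_lo, window_hi), ""
        elif defect == "missing_date":
            original = all_codes[int(rng.integers(0, len(all_codes)))]
            code, date = original, None
        elif defect == "unknown_code":
            original = all_codes[int(rng.integers(0, len(all_codes)))]
            op = ops[int(rng.choice(len(ops), p=op_weights))] if ops else "delete_char"
            code = corrupt_code(original, op, rng, known)
            date = clean_date(original)
        elif defect == "date_before_start":
            original = eligible[int(rng.integers(0, len(eligible)))]
            code = original
            date = windows[code][0] - dt.timedelta(days=int(rng.integers(1, 366)))
        elif defect == "date_after_end":
            original = eligible[int(rng.integers(0, len(eligible)))]
            code = original
            date = windows[code][1] + dt.timedelta(days=int(rng.integers(1, 366)))
        else:
            original = all_codes[int(rng.integers(0, len(all_codes)))]
            code, date = original, clean_date(original)
        ex_rows.append(ClaimsExtractRow(code, date, source_table="synthetic"))
        mf_rows.append(ManifestRow(row_id, defect, original, code, date))
    return (
        ClaimsExtract(rows=ex_rows, name="SYN"),
        GroundTruthManifest(rows=mf_rows),
    )
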