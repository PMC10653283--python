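"""Four-category vocabulary-coverage determination.

Each source vocabulary of a claims data set is assigned to exactly one
availability category with respect to the OMOP CDM:

* ``available_in_athena`` — distributed with the standardized vocabularies;
* ``athena_ready`` — prepared as custom 2-billion concepts, only the upload
  into Athena remains;
* ``interim_mapping`` — representable through a ``source_to_concept_map``
  to existing standard concepts;
* ``not_available`` — not representable (typically licensing restrictions).

Scoring is one-hot: a vocabulary contributes 1 to its category and 0 to the
others; the report is the percentage distribution over the four categories.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import pandas as pd

CATEGORIES = (
    "available_in_athena",
    "athena_ready",
    "interim_mapping",
    "not_available",
)


@dataclass(frozen=True)
class CoverageAssignment:
    vocabulary_name: str
    category: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(
                f"unknown category {self.category!r}; expected one of {CATEGORIES}"
            )


@dataclass
class CoverageReport:
    counts: dict[str, int]
    total: int

    @property
    def percentages(self) -> dict[str, float]:
        return {c: 100.0 * n / self.total for c, n in self.counts.items()}

    def render(self) -> list[tuple[str, int, str]]:
        """(category, count, percent text); integer text when exact."""
        out = []
        for c in CATEGORIES:
            pct = 100.0 * self.counts[c] / self.total
            text = str(int(pct)) if pct == int(pct) else f"{pct:.2f}".rstrip("0").rstrip(".")
            out.append((c, self.counts[c], text))
        return out


def determine_coverage(assignments: Sequence[CoverageAssignment]) -> CoverageReport:
    """Count and percentage distribution of vocabularies over the categories."""
    if not assignments:
        raise ValueError("no coverage assignments supplied")
    names = [a.vocabulary_name for a in assignments]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate vocabulary assignment(s): {dupes}")
    counts = {c: 0 for c in CATEGORIES}
    for a in assignments:
        counts[a.category] += 1
    return CoverageReport(counts=counts, total=len(assignments))


def read_assignments(path) -> list[CoverageAssignment]:
    """Read an assignment CSV with columns (vocabulary_name, category, note)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = {"vocabulary_name", "category"} - set(df.columns)
    if missing:
        raise ValueError(f"assignment file lacks column(s): {sorted(missing)}")
    return [
        CoverageAssignment(
            vocabulary_name=r.vocabulary_name,
            category=r.category,
            note=getattr(r, "note", ""),
        )
        for r in df.itertuples(index=False)
    ]


def german_claims_assignments() -> list[CoverageAssignment]:
    """Packaged 20-vocabulary assignment for German claims data.

    The per-vocabulary category labels are a synthetic reconstruction chosen
    to be consistent with the published category counts (3 available in
    Athena, 6 Athena-ready, 9 via interim mapping, 2 not available); the
    individual rows are illustrative, not authoritative.
    """
    ref = resources.files("vocabprep.data") / "german_claims_coverage_synthetic.csv"
    with resources.as_file(ref) as path:
        return read_assignments(path)
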