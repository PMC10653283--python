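import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

from vocabprep.builder import BuildConfig, CodeTableRow, assemble_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_rows() -> list[CodeTableRow]:
    """5 codes, 2 classes, 4 parent edges, 1 replacement (D superseded by E)."""
    d = dt.date
    return [
        CodeTableRow("A", "Wurzel", "Root", "", "Procedure", "C1"),
        CodeTableRow("B", "Ast B", "Branch B", "A", "Procedure", "C1"),
        CodeTableRow("C", "Ast C", "Branch C", "A", "Procedure", "C2"),
        CodeTableRow(
            "D", "Blatt D", "Leaf D", "B", "Procedure", "C2",
            valid_start_date=d(2005, 1, 1), valid_end_date=d(2008, 12, 31),
            replaced_by_code="E",
        ),
        CodeTableRow(
            "E", "Blatt E", "Leaf E", "B", "Procedure", "C2",
            valid_start_date=d(2009, 1, 1), valid_end_date=d(2015, 12, 31),
        ),
    ]


@pytest.fixture
def toy_config() -> BuildConfig:
    return BuildConfig(
        vocabulary_id="HPNR",
        vocabulary_name="Therapeutic service item numbers",
        vocabulary_version="toy",
    )


@pytest.fixture
def toy_bundle(toy_rows, toy_config):
    return assemble_bundle(toy_rows, toy_config)
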