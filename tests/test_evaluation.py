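"""Completeness and correctness evaluators and their reporting layer."""

import datetime as dt

import numpy as np
import pytest

from vocabprep.builder import BuildConfig, assemble_bundle
from vocabprep.evaluation import (
    ClaimsExtract,
    ClaimsExtractRow,
    assess_completeness,
    assess_correctness,
    build_lookup,
    format_fraction,
    format_percent,
    render_report,
)
from vocabprep.stcm import SourceToConceptMapRecord, SourceToConceptMapTable
from vocabprep.synth import GeneratorConfig, generate_extract, generate_vocabulary

D = dt.date


def naive_evaluate(extract, sources):
    """Independent per-record linear scan, the reference for both evaluators."""
    entries = []  # (code, concept_id, start, end)
    for src in sources:
        if hasattr(src, "concepts"):
            for c in src.concepts:
                entries.append(
                    (c.concept_code, c.concept_id, c.valid_start_date, c.valid_end_date)
                )
        else:
            for r in src.records:
                entries.append(
                    (r.source_code, r.target_concept_id, r.valid_start_date, r.valid_end_date)
                )
    missing_codes, matched_codes = set(), set()
    records_missing = records_total = 0
    combos = {}
    invalid_records = 0
    correctness_records = 0
    for row in extract.rows:
        if not row.source_code:
            continue
        records_total += 1
        hits = [e for e in entries if e[0] == row.source_code]
        if not hits:
            missing_codes.add(row.source_code)
            records_missing += 1
            continue
        matched_codes.add(row.source_code)
        if row.event_date is None:
            continue
        correctness_records += 1
        valid = any(start <= row.event_date <= end for _, _, start, end in hits)
        combos[(row.source_code, row.event_date)] = valid
        if not valid:
            invalid_records += 1
    return {
        "unique_missing": len(missing_codes),
        "unique_total": len(missing_codes | matched_codes),
        "records_missing": records_missing,
        "records_total": records_total,
        "invalid_combos": sum(1 for v in combos.values() if not v),
        "combos_total": len(combos),
        "invalid_records": invalid_records,
        "correctness_records": correctness_records,
    }


@pytest.fixture
def bundle(toy_bundle):
    return toy_bundle


def extract_of(*rows):
    return ClaimsExtract(rows=[ClaimsExtractRow(*r) for r in rows], name="T")


class TestCompleteness:
    def test_all_codes_present_nothing_missing(self, bundle):
        ex = extract_of(("A", D(2015, 1, 1)), ("B", D(2015, 1, 1)), ("A", None))
        res = assess_completeness(ex, [bundle])
        assert (res.unique_missing, res.records_missing) == (0, 0)
        assert (res.unique_total, res.records_total) == (2, 3)

    def test_unknown_codes_resolve_to_concept_zero(self, bundle):
        ex = extract_of(("A", None), ("GHOST", None), ("GHOST", None))
        res = assess_completeness(ex, [bundle])
        assert res.per_code["GHOST"].concept_id == 0
        assert res.per_code["GHOST"].record_count == 2
        assert (res.unique_missing, res.records_missing) == (1, 2)
        matched, missing = res.to_frames()
        assert list(missing.source_code) == ["GHOST"]
        assert list(missing.occurrence_count) == [2]

    def test_empty_source_set_is_a_usage_error(self, bundle):
        with pytest.raises(ValueError):
            assess_completeness(extract_of(("A", None)), [])

    def test_multi_vocabulary_lookup_matches_in_any_source(self, bundle):
        stcm = SourceToConceptMapTable(
            "EXTRA",
            [SourceToConceptMapRecord("Q9", 0, "EXTRA", "", 4000, "S",
                                      D(1970, 1, 1), D(2099, 12, 31), "")],
        )
        ex = extract_of(("A", None), ("Q9", None), ("NOPE", None))
        res = assess_completeness(ex, [bundle, stcm])
        assert res.unique_missing == 1
        assert res.per_code["Q9"].matched

    def test_missing_code_rows_excluded_and_counted(self, bundle):
        ex = extract_of(("", D(2015, 1, 1)), ("A", None))
        res = assess_completeness(ex, [bundle])
        assert res.excluded_missing_code == 1
        assert res.records_total == 1

    def test_normalization_switch(self, bundle):
        ex = extract_of((" a ", None))
        strict = assess_completeness(ex, [bundle])
        relaxed = assess_completeness(ex, [bundle], normalize=True)
        assert strict.unique_missing == 1
        assert relaxed.unique_missing == 0


class TestCorrectness:
    def run(self, bundle, *rows):
        ex = extract_of(*rows)
        comp = assess_completeness(ex, [bundle])
        return assess_correctness(ex, comp, [bundle])

    def test_boundary_dates_are_valid_inclusive(self, bundle):
        # concept D carries the finite window 2005-01-01 .. 2008-12-31
        res = self.run(bundle, ("D", D(2005, 1, 1)), ("D", D(2008, 12, 31)))
        assert res.unique_invalid == 0 and res.unique_total == 2

    def test_sides_classified(self, bundle):
        res = self.run(
            bundle,
            ("D", D(2004, 12, 31)),
            ("D", D(2009, 6, 1)),
            ("D", D(2006, 6, 1)),
        )
        assert res.unique_invalid == 2
        assert res.invalid_by_side() == {"before_start": 1, "after_end": 1}

    def test_union_of_windows_across_sources(self, bundle):
        # second source re-opens code D for 2010 onwards
        stcm = SourceToConceptMapTable(
            "EXTRA",
            [SourceToConceptMapRecord("D", 0, "EXTRA", "", 4000, "S",
                                      D(2010, 1, 1), D(2012, 12, 31), "")],
        )
        ex = extract_of(("D", D(2011, 6, 1)))
        comp = assess_completeness(ex, [bundle, stcm])
        res = assess_correctness(ex, comp, [bundle, stcm])
        assert res.unique_invalid == 0

    def test_missing_fields_excluded_and_counted(self, bundle):
        res = self.run(bundle, ("A", None), ("", D(2015, 1, 1)), ("A", D(2015, 1, 1)))
        assert res.excluded_missing_fields == 2
        assert res.records_total == 1

    def test_unmatched_codes_outside_scope(self, bundle):
        res = self.run(bundle, ("GHOST", D(2015, 1, 1)), ("A", D(2015, 1, 1)))
        assert res.unique_total == 1
        assert ("GHOST", D(2015, 1, 1)) not in res.per_combo

    def test_dateless_source_reported_not_evaluable(self, bundle):
        res = self.run(bundle, ("A", None), ("B", None))
        assert not res.evaluable
        rows = render_report(res)
        assert rows[0][3] == "not evaluable"

    def test_internal_consistency_error_when_sources_change(self, bundle):
        ex = extract_of(("A", D(2015, 1, 1)))
        comp = assess_completeness(ex, [bundle])
        stcm_only = SourceToConceptMapTable("X", [])
        with pytest.raises((RuntimeError, ValueError)):
            assess_correctness(ex, comp, [stcm_only])


class TestManifestRecovery:
    def test_seeded_defects_recovered_exactly(self):
        cfg = GeneratorConfig(seed=7, n_codes=80, n_records=1000, p_unknown_code=0.1)
        vocab = generate_vocabulary(cfg)
        bundle = assemble_bundle(vocab, BuildConfig("SYN", "SYN"))
        extract, manifest = generate_extract(cfg, vocab)
        agg = manifest.aggregates()
        comp = assess_completeness(extract, [bundle])
        corr = assess_correctness(extract, comp, [bundle])
        assert comp.unique_missing == agg["unique_missing"]
        assert comp.records_missing == agg["records_missing"]
        assert corr.unique_invalid == agg["invalid_combos"]
        assert corr.records_invalid == agg["invalid_records"]
        assert corr.invalid_by_side() == {
            "before_start": agg["invalid_combos_before_start"],
            "after_end": agg["invalid_combos_after_end"],
        }
        assert corr.excluded_missing_fields == agg["excluded_missing_fields"]

    def test_partition_of_codes_and_records(self):
        cfg = GeneratorConfig(seed=11, n_codes=50, n_records=800)
        vocab = generate_vocabulary(cfg)
        bundle = assemble_bundle(vocab, BuildConfig("SYN", "SYN"))
        extract, _ = generate_extract(cfg, vocab)
        comp = assess_completeness(extract, [bundle])
        corr = assess_correctness(extract, comp, [bundle])
        distinct = {r.source_code for r in extract.rows if r.source_code}
        assert comp.unique_total == len(distinct)
        n_nonempty = sum(1 for r in extract.rows if r.source_code)
        assert comp.records_total == n_nonempty
        assert comp.records_total + comp.excluded_missing_code == len(extract.rows)
        # matched records split into dated (correctness scope) and excluded
        matched_records = comp.records_total - comp.records_missing
        assert corr.records_total + (
            corr.excluded_missing_fields - comp.excluded_missing_code
        ) == matched_records

    def test_oracle_equivalence_on_random_extracts(self):
        rng = np.random.default_rng(5)
        for seed in rng.integers(0, 2**31, size=5):
            cfg = GeneratorConfig(seed=int(seed), n_codes=40, n_records=500)
            vocab = generate_vocabulary(cfg)
            bundle = assemble_bundle(vocab, BuildConfig("SYN", "SYN"))
            extract, _ = generate_extract(cfg, vocab)
            comp = assess_completeness(extract, [bundle])
            corr = assess_correctness(extract, comp, [bundle])
            ref = naive_evaluate(extract, [bundle])
            assert (comp.unique_missing, comp.records_missing) == (
                ref["unique_missing"], ref["records_missing"]
            )
            assert (comp.unique_total, comp.records_total) == (
                ref["unique_total"], ref["records_total"]
            )
            assert (corr.unique_invalid, corr.unique_total) == (
                ref["invalid_combos"], ref["combos_total"]
            )
            assert (corr.records_invalid, corr.records_total) == (
                ref["invalid_records"], ref["correctness_records"]
            )


class TestReporting:
    @pytest.mark.parametrize(
        "n, total, expected",
        [
            (12, 116, "10.34"),
            (0, 37, "0"),
            (5, 137106, "0.0036"),
            (2, 27197, "0.0074"),
            (4074, 5973, "68.21"),
            (1422808, 6563865, "21.68"),
            (2938, 137101, "2.14"),
            (1, 1172, "0.09"),
            (442, 33439, "1.32"),
        ],
    )
    def test_percent_rendering(self, n, total, expected):
        assert format_percent(n, total) == expected

    def test_undefined_percent_rendered_as_dash(self):
        assert format_percent(0, 0) == "—"

    def test_fraction_uses_thousands_separators(self):
        assert format_fraction(1_422_808, 6_563_865) == "1,422,808/6,563,865 (21.68)"

    def test_render_report_two_levels(self, bundle):
        ex = extract_of(("A", None), ("GHOST", None))
        res = assess_completeness(ex, [bundle])
        rows = render_report(res)
        assert rows == [("T", 1, 2, "50.00"), ("T", 1, 2, "50.00")]
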