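"""Ingestion: joining, deduplication, normalisation, suspect filtering."""

import warnings

import pytest

from pvsignal.faers_io import (
    FaersFormatError,
    clean_cases,
    deduplicate_cases,
    filter_primary_suspect,
    normalize_age,
    read_quarter,
    read_table,
    split_target_background,
)
from pvsignal.simulate import SimConfig, generate_reports, write_faers_tables

from conftest import make_raw_case


class TestReadQuarter:
    def test_joins_all_tables(self, quarter_dir):
        cases = {c.primaryid: c for c in read_quarter(quarter_dir)}
        assert set(cases) == {100101, 100201, 100301}
        assert sorted(len(c.reactions) for c in cases.values()) == [2, 2, 3]
        first = cases[100101]
        assert len(first.drugs) == 2
        assert first.drugs[0].role == "PS"
        assert first.drugs[0].indications == ("Atrial fibrillation", "Thrombosis")
        assert first.outcome_codes == ("HO", "DE")
        assert cases[100301].age is None

    def test_demo_row_without_reactions(self, quarter_dir, tmp_path):
        demo = quarter_dir["demo"].read_text() + "100401$10040$20180101$55$YR$F$MD$US\n"
        quarter_dir["demo"].write_text(demo)
        cases = {c.primaryid: c for c in read_quarter(quarter_dir)}
        assert cases[100401].reactions == ()
        # and the downstream cleaning step excludes it
        assert all(r.primaryid != 100401 for r in clean_cases(cases.values()))

    def test_missing_mandatory_column_names_it(self, quarter_dir):
        text = quarter_dir["demo"].read_text().replace("primaryid", "reportid")
        quarter_dir["demo"].write_text(text)
        with pytest.raises(FaersFormatError, match="primaryid"):
            read_quarter(quarter_dir)

    def test_empty_file_warns(self, tmp_path):
        p = tmp_path / "DEMO.txt"
        p.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            df = read_table(p, "demo")
        assert df.empty

    def test_legacy_isr_alias(self, tmp_path):
        p = tmp_path / "REAC.txt"
        p.write_text("ISR$PT\n1001$Epistaxis\n")
        df = read_table(p, "reac")
        assert list(df.columns) == ["primaryid", "pt"]


class TestDeduplication:
    def test_latest_fda_dt_wins(self):
        a = make_raw_case(90011, caseid=9001, fda_dt=20150101)
        b = make_raw_case(90012, caseid=9001, fda_dt=20160101)
        kept, audit = deduplicate_cases([a, b])
        assert [c.primaryid for c in kept] == [90012]
        assert audit.n_dropped_duplicate == 1

    def test_tie_broken_by_primaryid(self):
        a = make_raw_case(90011, caseid=9001, fda_dt=20150101)
        b = make_raw_case(90012, caseid=9001, fda_dt=20150101)
        kept, _ = deduplicate_cases([b, a])
        assert [c.primaryid for c in kept] == [90012]

    def test_deleted_caseids_removed(self):
        cases = [make_raw_case(i * 10 + 1, caseid=i) for i in range(1, 6)]
        kept, audit = deduplicate_cases(cases, deleted_caseids={3})
        assert len(kept) == 4
        assert audit.n_dropped_deleted == 1
        assert audit.n_input == audit.n_kept + audit.n_dropped_duplicate + audit.n_dropped_deleted

    def test_idempotent(self):
        cases = [
            make_raw_case(90011, caseid=9001, fda_dt=20150101),
            make_raw_case(90012, caseid=9001, fda_dt=20160101),
            make_raw_case(90021, caseid=9002, fda_dt=20150101),
        ]
        once, _ = deduplicate_cases(cases)
        twice, audit = deduplicate_cases(once)
        assert once == twice
        assert audit.n_dropped_duplicate == 0


class TestNormalizeAge:
    @pytest.mark.parametrize(
        "value, unit, expected",
        [
            (72, "YR", 72.0),
            (18, "MON", 1.5),
            (2, "DEC", 20.0),
            (730.5, "DY", 2.0),
            (52.1429, "WK", 1.0),
        ],
    )
    def test_unit_conversion(self, value, unit, expected):
        assert normalize_age(value, unit) == pytest.approx(expected)

    def test_unknown_unit_is_missing_with_warning(self):
        with pytest.warns(UserWarning, match="unknown age unit"):
            assert normalize_age(5, "FORTNIGHT") is None

    @pytest.mark.parametrize("value, unit", [(150, "YR"), (-3, "YR"), (20, "DEC")])
    def test_out_of_range_is_missing(self, value, unit):
        with pytest.warns(UserWarning, match="out of range"):
            assert normalize_age(value, unit) is None

    def test_missing_value_passes_through(self):
        assert normalize_age(None, "YR") is None


class TestPrimarySuspectFilter:
    def test_case_insensitive_name_and_ai_match(self, quarter_dir):
        clean = clean_cases(read_quarter(quarter_dir))
        target = filter_primary_suspect(clean, ["rivaroxaban", "xarelto"])
        # 100101: PS XARELTO matches; 100201: rivaroxaban entry is SS only;
        # 100301: PS name RIVAROXABAN. matches by substring
        assert sorted(r.primaryid for r in target) == [100101, 100301]

    def test_non_ps_role_excluded(self):
        clean = clean_cases([make_raw_case(11, drugname="rivaroxaban", role="C")])
        assert filter_primary_suspect(clean, ["rivaroxaban"]) == []

    def test_fixture_count_and_attachments(self, quarter_dir):
        clean = clean_cases(read_quarter(quarter_dir))
        target = filter_primary_suspect(clean, ["rivaroxaban"])
        by_id = {r.primaryid: r for r in target}
        assert by_id[100101].ps_drug == "XARELTO"
        assert by_id[100101].indications == frozenset({"Atrial fibrillation", "Thrombosis"})
        assert by_id[100101].route == "oral"
        assert by_id[100101].serious  # HO + DE codes
        assert by_id[100101].outcomes == frozenset({"hospitalization", "death"})

    def test_output_subset_with_ps_drug_set(self):
        raws = [
            make_raw_case(i * 10 + 1, drugname="RIVAROXABAN" if i % 3 == 0 else "OTHER")
            for i in range(12)
        ]
        clean = clean_cases(raws)
        target = filter_primary_suspect(clean, ["rivaroxaban"])
        assert len(target) == 4
        ids = {r.primaryid for r in clean}
        assert all(r.primaryid in ids and r.ps_drug for r in target)

    def test_empty_patterns_rejected(self):
        with pytest.raises(ValueError):
            filter_primary_suspect([], [])

    def test_split_partitions_by_primaryid(self, quarter_dir):
        clean = clean_cases(read_quarter(quarter_dir))
        target, background = split_target_background(clean, ["rivaroxaban"])
        assert len(target) + len(background) == len(clean)
        assert not {r.primaryid for r in target} & {r.primaryid for r in background}


def test_write_read_round_trip(tmp_path):
    """The synthetic writer emits the same dialect the reader parses."""
    cases = generate_reports(SimConfig(n_reports=40, seed=3))
    write_faers_tables(cases, tmp_path)
    back = read_quarter({n: tmp_path / f"{n.upper()}.txt" for n in ("demo", "drug", "reac", "indi", "outc")})
    assert len(back) == len(cases)
    orig = {c.primaryid: c for c in cases}
    for c in back:
        o = orig[c.primaryid]
        assert c.caseid == o.caseid
        assert c.fda_dt == o.fda_dt
        assert sorted(c.reactions) == sorted(o.reactions)
        assert c.age == o.age
        assert [d.role for d in c.drugs] == [d.role for d in o.drugs]
        assert c.drugs[0].indications == o.drugs[0].indications
        assert sorted(c.outcome_codes) == sorted(o.outcome_codes)
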