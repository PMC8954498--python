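"""Quarterly-extract parsing, schema harmonization and field normalization."""

import pandas as pd
import pytest

from faers_forge.report_io import (FaersDataset, QuarterExtract,
                                   apply_deleted_cases, merge_quarters,
                                   normalize_age, normalize_country,
                                   parse_quarter)
from faers_forge.synthetic import SynthConfig, generate_dataset

from conftest import norm_frame, write_quarter

DEMO_H = ["primaryid", "caseid", "caseversion", "i_f_code", "event_dt",
          "fda_dt", "age", "age_cod", "sex", "reporter_country"]
DRUG_H = ["primaryid", "drug_seq", "role_cod", "drugname", "prod_ai", "nda_num"]
REAC_H = ["primaryid", "pt"]


def _minimal_quarter(tmp_path, period="2012Q1", demo_rows=None, drug_rows=None,
                     reac_rows=None):
    demo_rows = demo_rows if demo_rows is not None else [
        ["1", "10", "1", "I", "20120101", "20120201", "25", "YR", "F", "US"],
        ["2", "11", "1", "I", "", "20120202", "", "", "M", "FRANCE"],
        ["3", "12", "2", "F", "20120103", "20120203", "24", "MON", "", "XYZLAND"],
    ]
    drug_rows = drug_rows if drug_rows is not None else [
        ["1", "1", "PS", "ABEXOLID", "", ""],
        ["2", "1", "SS", "KELVORIN", "", ""],
        ["3", "1", "PS", "WEXFORMIN", "", ""],
    ]
    reac_rows = reac_rows if reac_rows is not None else [
        ["1", "HEADACHE"], ["2", "RASH"], ["3", "NAUSEA"],
    ]
    return write_quarter(tmp_path, period, {
        "demo": (DEMO_H, demo_rows),
        "drug": (DRUG_H, drug_rows),
        "reac": (REAC_H, reac_rows),
    })


class TestParseQuarter:
    def test_identity_parse_stamps_period(self, tmp_path):
        extract = _minimal_quarter(tmp_path)
        tables, deleted, audit = parse_quarter(extract)
        assert len(tables["demo"]) == 3
        assert (tables["demo"]["period"] == "2012Q1").all()
        assert audit["tables"]["demo"]["rows"] == 3
        assert not deleted

    def test_legacy_isr_becomes_primaryid(self, tmp_path):
        laers_demo_h = ["ISR", "CASE", "i_f_cod", "event_dt", "fda_dt", "age",
                        "age_cod", "gndr_cod", "reporter_country"]
        extract = write_quarter(tmp_path, "2008Q2", {
            "demo": (laers_demo_h,
                     [["7001", "901", "I", "", "20080501", "40", "YR", "F", "US"]]),
            "drug": (["ISR", "drug_seq", "role_cod", "drugname", "nda_num"],
                     [["7001", "1", "PS", "ABEXOLID", ""]]),
            "reac": (["ISR", "pt"], [["7001", "HEADACHE"]]),
        })
        tables, _, _ = parse_quarter(extract)
        demo = tables["demo"]
        assert demo["primaryid"].tolist() == ["7001"]
        assert demo["caseid"].tolist() == ["901"]
        assert demo["caseversion"].tolist() == ["0"]  # absent in legacy layout
        assert (demo["source"] == "LAERS").all()
        assert "prod_ai" in tables["drug"].columns  # null-filled schema gap
        assert tables["drug"]["prod_ai"].isna().all()

    def test_wrong_field_count_quarantined_never_dropped(self, tmp_path):
        extract = _minimal_quarter(tmp_path, drug_rows=[
            ["1", "1", "PS", "ABEXOLID", "", ""],
            ["2", "1", "SS", "KELVORIN", ""],            # one field short
            ["3", "1", "PS", "WEXFORMIN", "", "", "X"],  # one field extra
        ])
        tables, _, audit = parse_quarter(extract, quarantine_dir=tmp_path / "q")
        assert len(tables["drug"]) == 1
        rej = audit["tables"]["drug"]
        assert rej["quarantined"] == 2
        # row conservation: parsed + quarantined = physical data lines
        n_lines = sum(1 for line in open(extract.paths["drug"])) - 1
        assert rej["rows"] + rej["quarantined"] == n_lines
        # quarantine file records the 1-based line numbers
        qfile = (tmp_path / "q" / "2012Q1_drug.rejects.txt").read_text()
        assert qfile.startswith("3\t")

    def test_missing_mandatory_file_is_hard_error(self, tmp_path):
        with pytest.raises(ValueError, match="reac"):
            QuarterExtract(period="2012Q1", paths={})
        extract = _minimal_quarter(tmp_path)
        paths = dict(extract.paths)
        del paths["reac"]
        with pytest.raises(ValueError, match="reac"):
            QuarterExtract(period="2012Q1", paths=paths)

    def test_bad_period_label_rejected(self, tmp_path):
        extract = _minimal_quarter(tmp_path)
        with pytest.raises(ValueError, match="period"):
            QuarterExtract(period="2012Q5", paths=extract.paths)


class TestMergeQuarters:
    def test_union_of_rows_and_serial_drug_ids(self, tmp_path):
        e1 = _minimal_quarter(tmp_path, "2012Q1")
        e2 = _minimal_quarter(tmp_path, "2012Q2", demo_rows=[
            ["4", "13", "1", "I", "", "20120401", "30", "YR", "F", "US"],
            ["5", "14", "1", "I", "", "20120402", "", "", "", ""],
        ], drug_rows=[
            ["4", "1", "PS", "ABEXOLID", "", ""],
            ["5", "1", "PS", "KELVORIN", "", ""],
        ], reac_rows=[["4", "RASH"], ["5", "FALL"]])
        ds = merge_quarters([e1, e2])
        assert len(ds.demo) == 5
        assert ds.drug["drug_id"].tolist() == [1, 2, 3, 4, 5]
        assert ds.demo["period"].notna().all()

    def test_duplicate_period_is_hard_error(self, tmp_path):
        e1 = _minimal_quarter(tmp_path, "2012Q1")
        with pytest.raises(ValueError, match="duplicate"):
            merge_quarters([e1, e1])

    def test_demo_gains_normalized_age_and_country(self, tmp_path):
        ds = merge_quarters([_minimal_quarter(tmp_path)])
        demo = ds.demo.set_index("primaryid")
        assert demo.loc["1", "age_years"] == 25.0
        assert demo.loc["3", "age_years"] == 2.0
        assert demo.loc["1", "country_code"] == "US"
        assert demo.loc["2", "country_code"] == "FR"
        assert pd.isna(demo.loc["3", "country_code"])
        assert "XYZLAND" in ds.audit["unmatched_countries"]


class TestNormalizeAge:
    @pytest.mark.parametrize("value,unit,expected", [
        (25, "YR", 25.0),
        (24, "MON", 2.0),
        (3, "DEC", 30.0),
        (52, "WK", 1.0),
        (365, "DY", 1.0),
        (8760, "HR", 1.0),
        ("25", "yr", 25.0),      # case-insensitive unit, string value
        (None, "YR", None),
        (25, None, None),
        (25, "FORTNIGHT", None),  # unknown unit
        (-5, "YR", None),         # implausible
        (200, "YR", None),
        ("abc", "YR", None),
    ])
    def test_conversion_table(self, value, unit, expected):
        assert normalize_age(value, unit) == expected

    def test_idempotent_on_normalized_values(self):
        for v in (0.5, 2.0, 25.0, 149.9):
            once = normalize_age(v, "YR")
            assert normalize_age(once, "YR") == once


class TestNormalizeCountry:
    @pytest.mark.parametrize("raw,expected", [
        ("US", "US"),
        ("United States of America", "US"),
        ("UNITED  KINGDOM", "GB"),
        ("japan", "JP"),
        ("XYZLAND", None),
        (None, None),
    ])
    def test_alias_lookup(self, raw, expected):
        assert normalize_country(raw) == expected


class TestDeletedCases:
    def _dataset(self, n=10):
        cfg = SynthConfig(n_cases=n, seed=1)
        ds, _, _ = generate_dataset(cfg)
        return ds

    def test_set_difference(self):
        ds = self._dataset(10)
        victims = set(ds.demo["caseid"].iloc[:2])
        out, removed = apply_deleted_cases(ds, victims)
        assert removed == 2
        assert len(out.demo) == 8
        assert not out.demo["caseid"].isin(victims).any()

    def test_absent_caseid_is_noop(self):
        ds = self._dataset(10)
        out, removed = apply_deleted_cases(ds, {"nonexistent"})
        assert removed == 0
        assert len(out.demo) == 10

    def test_idempotent_across_lists(self):
        ds = self._dataset(10)
        victim = {ds.demo["caseid"].iat[0]}
        once, r1 = apply_deleted_cases(ds, victim)
        twice, r2 = apply_deleted_cases(once, victim)
        assert (r1, r2) == (1, 0)
        assert len(twice.demo) == 9


def test_save_load_round_trip(tmp_path, small_run):
    _, ds, _ = small_run
    ds.save(tmp_path / "rt")
    back = FaersDataset.load(tmp_path / "rt")
    for kind, df in ds.tables():
        assert norm_frame(df).equals(norm_frame(getattr(back, kind))), kind
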