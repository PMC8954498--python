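"""Vocabulary handling, name cleaning and the mapping cascade."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from faers_forge.standardize import (cascade_map, clean_name, exact_match,
                                     map_by_nda, normalize_to_ingredients,
                                     read_two_column_table, standardize_all,
                                     write_two_column_table)
from faers_forge.vocab import Vocabulary, VocabularyEntry


class TestVocabulary:
    def test_rrf_round_trip(self, tmp_path, mini):
        mini.vocab.to_rrf(tmp_path)
        back = Vocabulary.from_rrf(tmp_path, exceptions=mini.vocab.exception_map())
        assert len(back) == len(mini.vocab)
        for rxaui, entry in mini.vocab.entries.items():
            assert back.entries[rxaui] == entry
        # relationship walks survive the round trip
        combo = mini.combo_rxaui["ABEXOLID / CALDEPRAN"]
        assert sorted(back.walk_targets(combo)) == \
            sorted(mini.vocab.walk_targets(combo))

    def test_lookup_prefers_primary_source_ingredient(self):
        vocab = Vocabulary([
            VocabularyEntry("300002", "600001", "DUPLONAME", "BN", "RXNORM"),
            VocabularyEntry("300003", "600002", "DUPLONAME", "IN", "MMSL"),
            VocabularyEntry("300001", "600003", "DUPLONAME", "IN", "RXNORM"),
        ])
        # primary-source ingredient atom first despite higher rxaui order
        assert vocab.lookup("DUPLONAME")[0] == "300001"
        assert vocab.lookup("duploname ")[0] == "300001"  # normalized lookup

    def test_lookup_tie_breaks_on_lowest_rxaui(self):
        vocab = Vocabulary([
            VocabularyEntry("300009", "600001", "X", "IN", "RXNORM"),
            VocabularyEntry("300004", "600002", "X", "IN", "RXNORM"),
        ])
        assert vocab.lookup("X")[0] == "300004"

    def test_duplicate_rxaui_rejected(self):
        e = VocabularyEntry("1", "2", "A", "IN", "RXNORM")
        with pytest.raises(ValueError, match="duplicate"):
            Vocabulary([e, e])


class TestCleanName:
    @pytest.mark.parametrize("raw,level,expected", [
        (" aspirin  ", "minimal", "ASPIRIN"),
        ("GALANTAMINE 4MG", "deep", "GALANTAMINE"),
        ("LESCOL ^SANDOZ^", "deep", "LESCOL"),
        ("LOXOPROFEN SODIUM (LOXOPROFEN SODIUM)", "deep", "LOXOPROFEN SODIUM"),
        ("PHENERGAN TABLETS/SUPPOSITORIES", "deep", "PHENERGAN"),
        ("CALCIUM & VITAMIN D /01483701/", "minimal", "CALCIUM & VITAMIN D"),
        ("CLOPIDOGREL/ASPIRIN) -", "minimal", "CLOPIDOGREL/ASPIRIN"),
        ("LOSEC I.V.", "deep", "LOSEC"),
        ("TERCIAN TABLETS", "deep", "TERCIAN"),
        ("EPITOMAX  (TOOPIRAMATE)", "minimal", "EPITOMAX (TOOPIRAMATE)"),
    ])
    def test_known_messy_styles(self, raw, level, expected):
        assert clean_name(raw, level) == expected

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError):
            clean_name("X", "aggressive")

    @given(st.text(alphabet="ABCXYZ 0123456789()^/?-.&,;", max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_idempotent_at_both_levels(self, raw):
        for level in ("minimal", "deep"):
            once = clean_name(raw, level)
            assert clean_name(once, level) == once


class TestCascadeStages:
    def test_nda_lookup(self, mini):
        nda = next(iter(mini.nda_table))
        assert map_by_nda(nda, mini.nda_table, mini.vocab) == mini.nda_table[nda]
        assert map_by_nda(None, mini.nda_table, mini.vocab) is None
        assert map_by_nda("999999", mini.nda_table, mini.vocab) is None

    def test_exact_match_misses_typos(self, mini):
        assert exact_match("ABEXOLID", mini.vocab) == mini.ingredient_rxaui["ABEXOLID"]
        assert exact_match("ABEXOLIT", mini.vocab) is None  # single-char typo

    def test_cascade_stage_order_and_provenance(self, mini):
        foreign = next(iter(mini.idd))
        # IDD entry resolves with method IDD (stage 3)
        res = cascade_map(foreign.title(), None, mini.vocab, mini.idd, {},
                          mini.nda_table)
        assert res.method == "IDD"
        assert res.ingredient_rxauis == [mini.idd[foreign]]
        # a name known only to the overrides table resolves as MANUAL
        overrides = {"MYSTERY SYRUP": mini.ingredient_rxaui["KELVORIN"]}
        res = cascade_map("mystery syrup", None, mini.vocab, mini.idd,
                          overrides, mini.nda_table)
        assert res.method == "MANUAL"
        # strength suffix needs the deep-clean pass
        res = cascade_map("ABEXOLID 4MG", None, mini.vocab, mini.idd, {},
                          mini.nda_table)
        assert res.method == "CLEANED_EXACT"
        # NDA outranks an exact-matchable name
        nda = next(n for n, rx in mini.nda_table.items()
                   if rx == mini.ingredient_rxaui["ABEXOLID"])
        res = cascade_map("ABEXOLID", nda, mini.vocab, mini.idd, {},
                          mini.nda_table)
        assert res.method == "NDA"

    def test_unresolvable_names_stay_unmapped(self, mini):
        res = cascade_map("BLOOD THINNER", None, mini.vocab, mini.idd, {},
                          mini.nda_table)
        assert res.method == "UNMAPPED"
        assert res.matched_rxaui is None
        assert res.ingredient_rxauis == []


class TestNormalizeToIngredients:
    def test_single_ingredient_is_identity(self, mini):
        rx = mini.ingredient_rxaui["ABEXOLID"]
        assert normalize_to_ingredients(rx, mini.vocab) == ([rx], "none")

    def test_combo_splits_into_constituents(self, mini):
        combo = mini.combo_rxaui["ELTRAZONE / IXOLAMIDE / KELVORIN"]
        ings, flag = normalize_to_ingredients(combo, mini.vocab)
        assert flag == "none"
        assert sorted(ings) == sorted(mini.ingredient_rxaui[n] for n in
                                      ("ELTRAZONE", "IXOLAMIDE", "KELVORIN"))

    def test_brand_walks_to_generic(self, mini):
        rx = mini.brand_rxaui["ABEXOR"]
        ings, _ = normalize_to_ingredients(rx, mini.vocab)
        assert ings == [mini.ingredient_rxaui["ABEXOLID"]]

    def test_vaccine_kept_whole(self, mini):
        rx = mini.vaccine_rxauis[0]
        assert normalize_to_ingredients(rx, mini.vocab) == ([rx], "vaccine")

    def test_non_primary_and_granularity_flags(self, mini):
        rx = mini.ingredient_rxaui["PLUVASTONE"]
        assert normalize_to_ingredients(rx, mini.vocab) == \
            ([rx], "non_rxnorm_ingredient")
        rx = mini.ingredient_rxaui["DORNIVUDINE TRIPHOSPHATE"]
        assert normalize_to_ingredients(rx, mini.vocab) == ([rx], "granularity")

    def test_cycle_guard_fails_closed(self):
        vocab = Vocabulary(
            [VocabularyEntry("1", "10", "A", "BN", "RXNORM"),
             VocabularyEntry("2", "20", "B", "BN", "RXNORM")],
            [("1", "tradename_of", "2"), ("2", "tradename_of", "1")])
        assert normalize_to_ingredients("1", vocab) == ([], "walk_failed")
        res = cascade_map("A", None, vocab)
        assert res.method == "UNMAPPED"
        assert res.note and res.note.startswith("walk_failed")


class TestStandardizeAll:
    def test_drug_id_conservation_and_provenance_totality(self, small_run, mini):
        _, ds, _ = small_run
        std, report = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                      mini.nda_table)
        assert set(std["drug_id"]) == set(ds.drug["drug_id"])
        assert std["method"].notna().all()
        assert sum(report["method_counts"].values()) == len(ds.drug)
        # unmapped rows are retained, not deleted
        unmapped = std[std["method"] == "UNMAPPED"]
        assert unmapped["ingredient_rxaui"].isna().all()

    def test_cascade_monotone_in_lookup_resources(self, small_run, mini):
        _, ds, _ = small_run
        _, bare = standardize_all(ds.drug, mini.vocab, {}, {}, {})
        _, full = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                  mini.nda_table)
        assert bare["mapped_fraction"] <= full["mapped_fraction"]

    def test_overrides_never_unmap(self, small_run, mini):
        _, ds, _ = small_run
        std0, r0 = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                   mini.nda_table)
        unmapped = std0.loc[std0["method"] == "UNMAPPED", "verbatim_name"]
        overrides = {clean_name(n, "minimal"): mini.ingredient_rxaui["ABEXOLID"]
                     for n in unmapped.head(5)}
        std1, r1 = standardize_all(ds.drug, mini.vocab, mini.idd, overrides,
                                   mini.nda_table)
        assert r1["method_counts"]["UNMAPPED"] <= r0["method_counts"]["UNMAPPED"]
        previously = set(std0.loc[std0["method"] != "UNMAPPED", "drug_id"])
        now = set(std1.loc[std1["method"] != "UNMAPPED", "drug_id"])
        assert previously <= now

    def test_prod_ai_conflict_logged_but_verbatim_wins(self, mini):
        drug = pd.DataFrame({
            "drug_id": pd.array([1], dtype="Int64"),
            "primaryid": ["1"], "drug_seq": ["1"], "role_code": ["PS"],
            "drugname": ["ABEXOLID"], "prod_ai": ["KELVORIN"],
            "nda_num": [pd.NA], "period": ["2016Q2"],
        })
        std, report = standardize_all(drug, mini.vocab, mini.idd, {},
                                      mini.nda_table)
        assert report["prod_ai_conflicts"] == 1
        assert std["ingredient_rxaui"].tolist() == [mini.ingredient_rxaui["ABEXOLID"]]

    def test_manual_threshold_surfaces_frequent_unmapped(self, mini):
        drug = pd.DataFrame({
            "drug_id": pd.array(range(1, 8), dtype="Int64"),
            "primaryid": [str(i) for i in range(7)],
            "drug_seq": ["1"] * 7,
            "drugname": ["MYSTERY BREW"] * 6 + ["ABEXOLID"],
            "prod_ai": [pd.NA] * 7, "nda_num": [pd.NA] * 7,
            "period": ["2016Q2"] * 7, "role_code": ["PS"] * 7,
        })
        _, report = standardize_all(drug, mini.vocab, manual_threshold=5)
        assert report["unmapped_frequent"] == [("MYSTERY BREW", 6)]

    def test_two_column_table_io(self, tmp_path, mini):
        path = tmp_path / "idd.tsv"
        write_two_column_table(mini.idd, path, "foreign_name")
        assert read_two_column_table(path) == mini.idd
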