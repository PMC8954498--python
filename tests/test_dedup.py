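"""Two-stage deduplication: version retention, pair rule, group closure."""

from itertools import combinations

import pandas as pd
import pytest

from faers_forge.dedup import (CaseSignature, _DSU, build_signatures,
                               deduplicate, find_cross_duplicates,
                               is_duplicate_pair, keep_latest_version)
from faers_forge.standardize import standardize_all
from faers_forge.synthetic import SynthConfig, generate_dataset


def _demo(rows):
    return pd.DataFrame(rows, columns=["primaryid", "caseid", "caseversion",
                                       "fda_dt"])


class TestKeepLatestVersion:
    def test_max_caseversion_retained(self):
        demo = _demo([["1", "123", "1", "20200101"],
                      ["2", "123", "2", "20200102"],
                      ["3", "123", "3", "20200103"],
                      ["4", "999", "1", "20200101"]])
        kept, removed = keep_latest_version(demo)
        assert sorted(kept["primaryid"]) == ["3", "4"]
        assert sorted(removed) == ["1", "2"]

    def test_single_version_untouched(self):
        demo = _demo([["1", "123", "1", "20200101"]])
        kept, removed = keep_latest_version(demo)
        assert len(kept) == 1 and not removed

    def test_fda_dt_breaks_version_ties(self):
        demo = _demo([["1", "123", "2", "20200101"],
                      ["2", "123", "2", "20200301"]])
        kept, _ = keep_latest_version(demo)
        assert kept["primaryid"].tolist() == ["2"]

    def test_primaryid_breaks_remaining_ties_numerically(self):
        demo = _demo([["9", "123", "1", "20200101"],
                      ["10", "123", "1", "20200101"]])
        kept, _ = keep_latest_version(demo)
        assert kept["primaryid"].tolist() == ["10"]

    def test_null_caseid_passes_through(self):
        demo = _demo([["1", None, "1", "20200101"],
                      ["2", None, "1", "20200101"]])
        kept, removed = keep_latest_version(demo)
        assert len(kept) == 2 and not removed


def _sig(pid="1", drugs=("A",), reactions=("R",), gender="F", age=30,
         country="US", event="20200101", starts=("20190101",),
         indis=("hypertension",), fda="20200301"):
    return CaseSignature(pid, frozenset(drugs), frozenset(reactions), gender,
                         age, country, event, frozenset(starts),
                         frozenset(indis), fda)


class TestIsDuplicatePair:
    def test_complete_match_is_duplicate(self):
        dup, report = is_duplicate_pair(_sig("1"), _sig("2"))
        assert dup
        assert all(v == "match" for v in report.values())

    @pytest.mark.parametrize("kw", [
        {"gender": "M"}, {"age": 31}, {"country": "FR"},
        {"event": "20200202"}, {"starts": ("20180101",)},
        {"indis": ("asthma",)},
    ])
    def test_single_soft_mismatch_still_duplicate(self, kw):
        dup, _ = is_duplicate_pair(_sig("1"), _sig("2", **kw))
        assert dup

    def test_two_soft_mismatches_not_duplicate(self):
        dup, report = is_duplicate_pair(_sig("1"), _sig("2", gender="M", age=31))
        assert not dup
        assert sum(1 for f, v in report.items() if v == "mismatch") == 2

    @pytest.mark.parametrize("kw", [{"drugs": ("A", "B")},
                                    {"reactions": ("R", "S")}])
    def test_hard_key_mismatch_never_duplicate(self, kw):
        dup, _ = is_duplicate_pair(_sig("1"), _sig("2", **kw))
        assert not dup

    def test_null_soft_field_does_not_consume_allowance(self):
        # one unknown + one mismatch still qualifies under the default policy
        dup, report = is_duplicate_pair(
            _sig("1", gender=None), _sig("2", age=35))
        assert dup
        assert report["gender"] == "unknown"

    def test_null_policy_mismatch_consumes(self):
        s1 = _sig("1", gender=None)
        s2 = _sig("2", age=35)
        assert is_duplicate_pair(s1, s2, null_policy="unknown")[0]
        assert not is_duplicate_pair(s1, s2, null_policy="mismatch")[0]
        # both-null still matches under the mismatch policy
        assert is_duplicate_pair(_sig("1", gender=None),
                                 _sig("2", gender=None),
                                 null_policy="mismatch")[0]

    def test_empty_start_date_set_is_unknown(self):
        dup, report = is_duplicate_pair(_sig("1", starts=()), _sig("2"))
        assert dup and report["start_dates"] == "unknown"


class TestSignatures:
    @pytest.fixture(scope="class")
    def run(self, mini):
        cfg = SynthConfig(n_cases=300, seed=13, duplicate_rate=0.2)
        ds, ledger, _ = generate_dataset(cfg, mini)
        std, _ = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                 mini.nda_table)
        return ds, std, ledger

    def test_sets_are_order_insensitive_and_deduplicated(self, run, mini):
        ds, std, _ = run
        sigs = build_signatures(ds, std)
        for sig in sigs.values():
            assert isinstance(sig.drugs, frozenset)
            assert isinstance(sig.reactions, frozenset)
        # every case has both hard keys populated (every report has >=1 each)
        assert all(s.complete for s in sigs.values())

    def test_all_null_start_dates_mean_missing(self, run, mini):
        ds, std, _ = run
        sigs = build_signatures(ds, std)
        no_start = set(ds.ther.groupby("primaryid")["start_dt"]
                       .apply(lambda s: s.isna().all())
                       .pipe(lambda s: s[s].index))
        for pid in no_start:
            assert sigs[pid].start_dates == frozenset()

    def test_planted_duplicates_match_in_hard_keys(self, run, mini):
        ds, std, ledger = run
        sigs = build_signatures(ds, std)
        for group in ledger.duplicate_groups:
            if len(group) < 2:
                continue
            members = sorted(group)
            for x, y in combinations(members, 2):
                dup, report = is_duplicate_pair(sigs[x], sigs[y])
                assert dup, (x, y, report)


class TestFindCrossDuplicates:
    def test_transitive_closure_groups(self):
        # 1~2 and 2~3 via different single mismatches: one group of three
        s1 = _sig("1")
        s2 = _sig("2", gender="M")
        s3 = _sig("3", gender="M", age=31)
        groups = find_cross_duplicates([s1, s2, s3])
        assert len(groups) == 1
        assert groups[0].members == ("1", "2", "3")

    def test_retained_member_has_latest_fda_then_highest_id(self):
        s1 = _sig("7", fda="20200401")
        s2 = _sig("8", fda="20200301")
        groups = find_cross_duplicates([s1, s2])
        assert groups[0].retained == "7"
        s3 = _sig("9", fda="20200401")
        groups = find_cross_duplicates([s1, s3])
        assert groups[0].retained == "9"

    def test_all_distinct_cases_yield_no_groups(self, mini):
        cfg = SynthConfig(n_cases=200, seed=17, duplicate_rate=0.0)
        ds, _, _ = generate_dataset(cfg, mini)
        std, _ = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                 mini.nda_table)
        assert find_cross_duplicates(build_signatures(ds, std)) == []

    def test_blocked_search_equals_exhaustive_pairwise(self, mini):
        """Brute-force oracle: blocking must lose no duplicate pair."""
        cfg = SynthConfig(n_cases=500, seed=23, duplicate_rate=0.3)
        ds, _, _ = generate_dataset(cfg, mini)
        std, _ = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                 mini.nda_table)
        sigs = build_signatures(ds, std)
        blocked = find_cross_duplicates(sigs)
        # exhaustive O(n^2) closure, no blocking
        complete = [s for s in sigs.values() if s.complete]
        dsu = _DSU([s.primaryid for s in complete])
        for s1, s2 in combinations(complete, 2):
            if is_duplicate_pair(s1, s2)[0]:
                dsu.union(s1.primaryid, s2.primaryid)
        clusters = {}
        for s in complete:
            clusters.setdefault(dsu.find(s.primaryid), []).append(s.primaryid)
        exhaustive = sorted(tuple(sorted(v)) for v in clusters.values()
                            if len(v) > 1)
        assert sorted(g.members for g in blocked) == exhaustive


class TestDeduplicateEndToEnd:
    @pytest.fixture(scope="class")
    def run(self, mini):
        cfg = SynthConfig(n_cases=2000, seed=7, duplicate_rate=0.2)
        ds, ledger, _ = generate_dataset(cfg, mini)
        std, _ = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                 mini.nda_table)
        deduped, audit = deduplicate(ds, std)
        return ds, std, ledger, deduped, audit

    def test_ground_truth_recovery(self, run):
        ds, std, ledger, deduped, audit = run
        true_groups = sorted(tuple(sorted(g)) for g in ledger.duplicate_groups
                             if len(g) > 1)
        found = sorted(tuple(g["members"]) for g in audit["groups"])
        assert found == [tuple(g) for g in true_groups]
        assert len(deduped.demo) == len(ledger.duplicate_groups)

    def test_monotone_and_counts_reconcile(self, run):
        ds, _, _, deduped, audit = run
        assert len(deduped.demo) <= len(ds.demo)
        assert audit["input_cases"] - audit["stage1_removed"] \
            - audit["deleted_removed"] - audit["cross_removed"] \
            == audit["output_cases"]

    def test_idempotent_fixpoint(self, run, mini):
        _, std, _, deduped, _ = run
        again, audit2 = deduplicate(deduped, std)
        assert audit2["cross_removed"] == 0
        assert audit2["stage1_removed"] == 0
        assert len(again.demo) == len(deduped.demo)

    def test_referential_integrity(self, run):
        _, _, _, deduped, _ = run
        demo_ids = set(deduped.demo["primaryid"])
        for kind, df in deduped.tables():
            assert set(df["primaryid"]) <= demo_ids, kind

    def test_no_duplicates_means_identity_after_stage1(self, mini):
        cfg = SynthConfig(n_cases=300, seed=29, duplicate_rate=0.0)
        ds, _, _ = generate_dataset(cfg, mini)
        std, _ = standardize_all(ds.drug, mini.vocab, mini.idd, {},
                                 mini.nda_table)
        deduped, audit = deduplicate(ds, std)
        assert len(deduped.demo) == len(ds.demo)
        assert audit["cross_removed"] == 0
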