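"""Two-stage case deduplication for spontaneous-report data.

Stage 1 keeps the most recent report per case identifier (max caseversion,
ties broken by max fda_dt, then max primaryid), mirroring the follow-up
mechanism of the reporting system.  Deleted-case lists are applied next.

Stage 2 collapses cross-source duplicates — the same real-world case
reported independently under different case identifiers — using an
eight-criterion signature: the *hard* keys (the set of administered drugs
and the set of adverse-reaction preferred terms) must match exactly, and at
most one of the six *soft* keys (gender, age in whole years, reporting
country, event date, the set of therapy start dates, the set of indication
terms) may mismatch.  A soft key that is null on either side counts as an
unknown — it neither matches nor consumes the single allowed mismatch
(configurable via ``null_policy``).

Candidate pairs are restricted to blocks sharing both hard keys (exact-set
blocking is lossless here, since the rule requires exact hard-key
equality); pairwise edges are closed under union-find into disjoint groups,
and the member with the latest fda_dt (then highest primaryid) survives.

Drug comparison runs at standardized single-ingredient level by default so
differently written mentions of the same substance still match; rows the
mapping cascade left UNMAPPED contribute their deep-cleaned verbatim string
as a tagged stand-in key, so a case is only excluded from stage 2 when it
has no drug or no reaction rows at all.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

import pandas as pd

from .report_io import FaersDataset, apply_deleted_cases
from .standardize import clean_name

SOFT_FIELDS = ("gender", "age", "country", "event_dt", "start_dates", "indications")

#: indication phrases that are null-equivalent (removed at export as well)
UNKNOWN_INDICATION_PHRASES = frozenset({
    "product used for unknown indication",
    "product used for the unknown indication",
    "drug use for unknown indication",
    "drug use for the unknown indication",
})

NULL_POLICIES = ("unknown", "match", "mismatch")


@dataclass(frozen=True)
class CaseSignature:
    """The eight-field matching key for one case report."""

    primaryid: str
    drugs: frozenset
    reactions: frozenset
    gender: str | None
    age: int | None
    country: str | None
    event_dt: str | None
    start_dates: frozenset
    indications: frozenset
    fda_dt: str | None = None

    @property
    def complete(self) -> bool:
        return bool(self.drugs) and bool(self.reactions)


@dataclass
class DuplicateGroup:
    members: tuple[str, ...]
    retained: str
    reason: str = "cross-source duplicate"


def _pid_sort_key(pid) -> tuple[int, str]:
    s = str(pid)
    return (int(s), s) if s.isdigit() else (0, s)


# ------------------------------------------------------------------- stage one

def keep_latest_version(demo: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """One record per caseid: max caseversion, then fda_dt, then primaryid.

    Rows with a null caseid pass through untouched.  Returns the retained
    DEMO rows (original order) and the removed primaryids.
    """
    if demo.empty:
        return demo, []
    has_case = demo["caseid"].notna()
    sub = demo[has_case].copy()
    ver = pd.to_numeric(sub["caseversion"], errors="coerce").fillna(-1)
    fda = sub["fda_dt"].fillna("").astype(str)
    pid = pd.to_numeric(sub["primaryid"], errors="coerce").fillna(-1)
    order = pd.DataFrame({"ver": ver, "fda": fda, "pid": pid}, index=sub.index)
    ranked = order.sort_values(["ver", "fda", "pid"], kind="stable")
    keep_idx = ranked.groupby(sub["caseid"].loc[ranked.index], sort=False).tail(1).index
    removed = sub.index.difference(keep_idx)
    removed_ids = demo.loc[removed, "primaryid"].tolist()
    kept = demo.drop(index=removed)
    return kept, removed_ids


# ------------------------------------------------------------------ signatures

def build_signatures(
    dataset: FaersDataset,
    standardized: pd.DataFrame | None = None,
    drug_level: str = "ingredient",
) -> dict[str, CaseSignature]:
    """Signatures for every case in the dataset's DEMO table.

    ``drug_level='ingredient'`` compares standardized ingredient sets (needs
    the standardized drug table); ``'verbatim'`` compares minimally cleaned
    verbatim names.
    """
    if drug_level not in ("ingredient", "verbatim"):
        raise ValueError(f"unknown drug_level {drug_level!r}")
    demo = dataset.demo

    if drug_level == "ingredient":
        if standardized is None:
            raise ValueError("ingredient-level comparison needs the standardized table")
        std = standardized
        mapped = std[std["ingredient_rxaui"].notna()]
        keys = dict(mapped.groupby("primaryid")["ingredient_rxaui"]
                    .agg(frozenset))
        unmapped = std[std["ingredient_rxaui"].isna()]
        if len(unmapped):
            fallback = unmapped.assign(
                _k=unmapped["verbatim_name"].astype(str)
                .map(lambda s: ("VERBATIM", clean_name(s, "deep"))))
            for pid, ks in fallback.groupby("primaryid")["_k"].agg(frozenset).items():
                keys[pid] = keys.get(pid, frozenset()) | ks
        drug_keys = keys
    else:
        drug = dataset.drug
        named = drug[drug["drugname"].notna()]
        drug_keys = dict(named.assign(
            _k=named["drugname"].astype(str).map(lambda s: clean_name(s, "minimal")))
            .groupby("primaryid")["_k"].agg(frozenset))

    reac = dataset.reac
    reac_keys = dict(reac[reac["pt"].notna()].assign(
        _k=reac["pt"].astype(str).str.strip().str.casefold())
        .groupby("primaryid")["_k"].agg(frozenset))

    ther = dataset.ther
    start_sets = dict(ther[ther["start_dt"].notna()]
                      .groupby("primaryid")["start_dt"].agg(frozenset))

    indi = dataset.indi
    ipt = indi[indi["indi_pt"].notna()].assign(
        _k=indi["indi_pt"].astype(str).str.strip().str.casefold())
    ipt = ipt[~ipt["_k"].isin(UNKNOWN_INDICATION_PHRASES)]
    indi_sets = dict(ipt.groupby("primaryid")["_k"].agg(frozenset))

    ages = demo["age_years"] if "age_years" in demo.columns else pd.Series(
        pd.NA, index=demo.index)

    sigs: dict[str, CaseSignature] = {}
    empty = frozenset()
    for i, pid in enumerate(demo["primaryid"]):
        age = ages.iat[i]
        age_i = int(round(float(age))) if pd.notna(age) else None
        gender = demo["gender"].iat[i] if "gender" in demo.columns else None
        country = demo["country_code"].iat[i] if "country_code" in demo.columns else None
        event = demo["event_dt"].iat[i]
        fda = demo["fda_dt"].iat[i]
        sigs[pid] = CaseSignature(
            primaryid=pid,
            drugs=drug_keys.get(pid, empty),
            reactions=reac_keys.get(pid, empty),
            gender=None if pd.isna(gender) else str(gender),
            age=age_i,
            country=None if pd.isna(country) else str(country),
            event_dt=None if pd.isna(event) else str(event),
            start_dates=start_sets.get(pid, empty),
            indications=indi_sets.get(pid, empty),
            fda_dt=None if pd.isna(fda) else str(fda),
        )
    return sigs


def _soft_status(v1, v2) -> str:
    null1 = v1 is None or (isinstance(v1, frozenset) and not v1)
    null2 = v2 is None or (isinstance(v2, frozenset) and not v2)
    if null1 or null2:
        return "unknown"
    return "match" if v1 == v2 else "mismatch"


def is_duplicate_pair(
    s1: CaseSignature,
    s2: CaseSignature,
    null_policy: str = "unknown",
) -> tuple[bool, dict[str, str]]:
    """Apply the eight-criterion rule to a pair of signatures.

    Returns the decision plus a per-field report (``match`` / ``mismatch`` /
    ``unknown``).  Hard keys must match exactly; at most one soft field may
    mismatch.  ``null_policy`` controls how an unknown (null either side)
    counts: non-consuming (``unknown``, default), as a match (``match``) or
    as a mismatch (``mismatch``, both-null still matches).
    """
    if null_policy not in NULL_POLICIES:
        raise ValueError(f"unknown null_policy {null_policy!r}")
    report: dict[str, str] = {}
    report["drugs"] = "match" if s1.drugs == s2.drugs else "mismatch"
    report["reactions"] = "match" if s1.reactions == s2.reactions else "mismatch"
    for name in SOFT_FIELDS:
        report[name] = _soft_status(getattr(s1, name), getattr(s2, name))
    if report["drugs"] != "match" or report["reactions"] != "match":
        return False, report
    mismatches = sum(1 for f in SOFT_FIELDS if report[f] == "mismatch")
    if null_policy == "mismatch":
        # one-side-null unknowns consume like mismatches under this policy
        for f in SOFT_FIELDS:
            if report[f] == "unknown":
                v1, v2 = getattr(s1, f), getattr(s2, f)
                n1 = v1 is None or (isinstance(v1, frozenset) and not v1)
                n2 = v2 is None or (isinstance(v2, frozenset) and not v2)
                if n1 != n2:
                    mismatches += 1
    return mismatches <= 1, report


# ------------------------------------------------------------------- stage two

class _DSU:
    def __init__(self, items: Iterable[str]):
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        p = self.parent
        while p[x] != x:
            p[x] = p[p[x]]
            x = p[x]
        return x

    def union(self, x: str, y: str) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def find_cross_duplicates(
    signatures: dict[str, CaseSignature] | Iterable[CaseSignature],
    null_policy: str = "unknown",
) -> list[DuplicateGroup]:
    """Disjoint duplicate groups (size >= 2) among complete signatures.

    Candidates are blocked on the exact (drugs, reactions) hard-key pair —
    lossless, because the duplicate rule requires hard-key equality — and
    pairwise edges are closed transitively with union-find.
    """
    if isinstance(signatures, dict):
        sigs = list(signatures.values())
    else:
        sigs = list(signatures)
    sigs = [s for s in sigs if s.complete]
    blocks: dict[tuple[frozenset, frozenset], list[CaseSignature]] = {}
    for s in sigs:
        blocks.setdefault((s.drugs, s.reactions), []).append(s)
    dsu = _DSU([s.primaryid for s in sigs])
    for block in blocks.values():
        if len(block) < 2:
            continue
        for s1, s2 in combinations(block, 2):
            dup, _ = is_duplicate_pair(s1, s2, null_policy)
            if dup:
                dsu.union(s1.primaryid, s2.primaryid)
    clusters: dict[str, list[CaseSignature]] = {}
    for s in sigs:
        clusters.setdefault(dsu.find(s.primaryid), []).append(s)
    groups = []
    for members in clusters.values():
        if len(members) < 2:
            continue
        retained = max(members, key=lambda s: (s.fda_dt or "", _pid_sort_key(s.primaryid)))
        groups.append(DuplicateGroup(
            members=tuple(sorted(m.primaryid for m in members)),
            retained=retained.primaryid))
    groups.sort(key=lambda g: g.members)
    return groups


def deduplicate(
    dataset: FaersDataset,
    standardized: pd.DataFrame | None = None,
    null_policy: str = "unknown",
    drug_level: str = "ingredient",
) -> tuple[FaersDataset, dict]:
    """Run both stages plus deleted-case removal; filter every table.

    Returns the deduplicated dataset and an audit of counts removed per
    stage (including the recovered cross-source groups).
    """
    n_input = len(dataset.demo)
    kept_demo, stage1_removed = keep_latest_version(dataset.demo)
    ds = dataset.filter_cases(kept_demo["primaryid"])
    ds, n_deleted = apply_deleted_cases(ds)
    std = standardized
    if std is not None:
        std = std[std["primaryid"].isin(set(ds.demo["primaryid"]))]
    sigs = build_signatures(ds, std, drug_level)
    groups = find_cross_duplicates(sigs, null_policy)
    drop = {m for g in groups for m in g.members if m != g.retained}
    out = ds.filter_cases(set(ds.demo["primaryid"]) - drop)
    audit = {
        "input_cases": n_input,
        "stage1_removed": len(stage1_removed),
        "deleted_removed": n_deleted,
        "cross_groups": len(groups),
        "cross_removed": len(drop),
        "output_cases": len(out.demo),
        "incomplete_signatures": sum(1 for s in sigs.values() if not s.complete),
        "groups": [{"members": list(g.members), "retained": g.retained}
                   for g in groups],
    }
    out.audit = dict(out.audit)
    out.audit["dedup"] = {k: v for k, v in audit.items() if k != "groups"}
    return out, audit
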