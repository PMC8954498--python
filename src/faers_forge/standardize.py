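"""Drug-name standardization: the lookup cascade and ingredient normalization.

Verbatim drug mentions in spontaneous reports mix trade names, generic
names, strengths, dosage forms, manufacturer tags, foreign trade names and
typos.  Each mention is resolved against the vocabulary by a cascade of
exact lookups — never fuzzy matching, which would silently diverge from a
lookup-based audit trail:

1. NDA number -> approved-product table (pre-mapped to vocabulary atoms);
2. exact name match after *minimal* cleaning (trim/case/symbol stripping);
3. multinational trade-name dictionary (IDD) lookup;
4. manual override table (human-curated verbatim -> atom mappings);
5. exact match after *deep* cleaning (strength/dosage-form/manufacturer
   token removal, echo-parenthesis removal);
6. IDD lookup on the deep-cleaned string.

The first hit wins and is recorded as the mapping method, giving every drug
row exactly one provenance tag.  The matched atom is then normalized to
single-active-ingredient level by walking the vocabulary's relationship
graph; multi-ingredient products split into one row per constituent, all
sharing the parent drug_id so combination products stay traceable.
Exceptions: vaccines are kept whole at their best-matching atom, and atoms
flagged as more granular in (or only maintained by) a non-primary source
vocabulary are returned as-is with the corresponding flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .vocab import Vocabulary, normalize_lookup_name

METHODS = ("NDA", "EXACT", "IDD", "MANUAL", "CLEANED_EXACT", "CLEANED_IDD", "UNMAPPED")

#: dosage-form / packaging tokens removed by deep cleaning
DOSAGE_FORM_STOPWORDS = frozenset({
    "TAB", "TABS", "TABLET", "TABLETS", "CAP", "CAPS", "CAPSULE", "CAPSULES",
    "SUPPOSITORY", "SUPPOSITORIES", "INJECTION", "INJECTABLE", "SYRUP",
    "CREAM", "OINTMENT", "GEL", "SOLUTION", "SUSPENSION", "DROPS", "PATCH",
    "SPRAY", "LOTION", "ORAL", "TOPICAL", "I.V.", "I.V", "IV", "I.M.", "IM",
    "UNIT", "DOSE", "UNIT-DOSE", "NOS", "UNKNOWN", "UNSPECIFIED",
    "LONG-ACTING", "EXTENDED-RELEASE", "ER", "SR", "XR",
})

_CODE_RE = re.compile(r"/\d{5,}/")               # reporter codes like /01483701/
_STRENGTH_RE = re.compile(
    r"\b\d+(?:\.\d+)?\s*(?:MG|MCG|MICROGRAMS?|GM?|KG|ML|L|%|IU|UNITS?|MEQ)\b\.?")
_MFR_TAG_RE = re.compile(r"\^[^^]*\^")           # ^SANDOZ^-style manufacturer tags
_WS_RE = re.compile(r"\s+")

_HOP_BOUND_DEFAULT = 5


def _strip_unmatched_brackets(s: str) -> str:
    """Drop parentheses that never close/open; keep balanced pairs."""
    out = []
    depth = 0
    opens: list[int] = []
    for ch in s:
        if ch == "(":
            opens.append(len(out))
            out.append(ch)
            depth += 1
        elif ch == ")":
            if depth == 0:
                continue  # unmatched close
            depth -= 1
            opens.pop()
            out.append(ch)
        else:
            out.append(ch)
    # drop any opens never closed
    for idx in reversed(opens):
        del out[idx]
    return "".join(out)


def _minimal_once(s: str) -> str:
    s = _WS_RE.sub(" ", str(s)).strip().upper()
    s = _CODE_RE.sub(" ", s)
    s = s.replace("?", " ")
    s = _strip_unmatched_brackets(s)
    s = s.replace("()", " ")
    s = _WS_RE.sub(" ", s).strip()
    s = s.strip(" -;:,/\\")
    return s.strip()


def _deep_once(s: str) -> str:
    s = _MFR_TAG_RE.sub(" ", s)
    # echo form "X (X)" -> "X"
    m = re.fullmatch(r"(.+?)\s*\((.+?)\)", s)
    if m and m.group(1).strip() == m.group(2).strip():
        s = m.group(1).strip()
    s = _STRENGTH_RE.sub(" ", s)
    kept = []
    for token in _WS_RE.sub(" ", s).strip().split(" "):
        parts = [p for p in token.split("/") if p]
        if parts and all(p in DOSAGE_FORM_STOPWORDS for p in parts):
            continue
        kept.append(token)
    return _minimal_once(" ".join(kept))


def clean_name(verbatim: str, level: str = "minimal") -> str:
    """Clean a verbatim drug string at ``minimal`` or ``deep`` level.

    Both levels are idempotent (applied to a fixed point, bounded).
    """
    if level not in ("minimal", "deep"):
        raise ValueError(f"unknown cleaning level {level!r}")
    s = _minimal_once(verbatim)
    if level == "deep":
        for _ in range(6):
            nxt = _deep_once(s)
            if nxt == s:
                break
            s = nxt
    else:
        for _ in range(3):
            nxt = _minimal_once(s)
            if nxt == s:
                break
            s = nxt
    return s


@dataclass
class MappingResult:
    """The resolution of one verbatim drug mention."""

    drug_id: int | None
    verbatim_name: str
    matched_rxaui: str | None
    method: str
    ingredient_rxauis: list[str] = field(default_factory=list)
    exception_flag: str = "none"
    note: str | None = None


# ----------------------------------------------------------- cascade stages

def map_by_nda(nda_num, nda_table: Mapping[str, str], vocab: Vocabulary) -> str | None:
    """Resolve via the New Drug Application number, when present and known."""
    if nda_num is None or nda_num is pd.NA:
        return None
    key = str(nda_num).strip()
    if not key:
        return None
    rxaui = nda_table.get(key)
    if rxaui is not None and rxaui in vocab:
        return rxaui
    return None


def exact_match(name: str, vocab: Vocabulary) -> str | None:
    """Exact lookup of a (cleaned) name; ambiguity resolved by atom rank."""
    cands = vocab.lookup(name)
    return cands[0] if cands else None


def normalize_to_ingredients(
    rxaui: str,
    vocab: Vocabulary,
    max_hops: int = _HOP_BOUND_DEFAULT,
) -> tuple[list[str], str]:
    """Walk a matched atom down to single-active-ingredient atoms.

    Returns ``(ingredient_rxauis, exception_flag)``.  Vaccine- and
    granularity-flagged atoms are returned whole; ingredient atoms kept only
    in a non-primary source return themselves flagged
    ``non_rxnorm_ingredient``.  A walk that finds no ingredient within the
    hop bound (cycle guard) returns ``([], "walk_failed")``.
    """
    entry = vocab.get(rxaui)
    if entry is None:
        return [], "walk_failed"
    if entry.exception in ("vaccine", "granularity"):
        return [rxaui], entry.exception
    if entry.is_ingredient:
        flag = entry.exception or "none"
        if flag == "none" and entry.source != "RXNORM":
            flag = "non_rxnorm_ingredient"
        return [rxaui], flag
    found: set[str] = set()
    frontier = [rxaui]
    seen = {rxaui}
    for _ in range(max_hops):
        nxt: list[str] = []
        for node in frontier:
            for target in vocab.walk_targets(node):
                if target in seen:
                    continue
                seen.add(target)
                t = vocab.get(target)
                if t is None:
                    continue
                if t.is_ingredient or t.exception in ("vaccine", "granularity"):
                    found.add(target)
                else:
                    nxt.append(target)
        if found:
            break
        frontier = nxt
        if not frontier:
            break
    if not found:
        return [], "walk_failed"
    out = sorted(found, key=lambda r: (int(r) if r.isdigit() else 0, r))
    return out, "none"


def cascade_map(
    verbatim: str,
    nda_num,
    vocab: Vocabulary,
    idd: Mapping[str, str] | None = None,
    overrides: Mapping[str, str] | None = None,
    nda_table: Mapping[str, str] | None = None,
    drug_id: int | None = None,
    max_hops: int = _HOP_BOUND_DEFAULT,
) -> MappingResult:
    """Resolve one verbatim mention through the full lookup cascade."""
    idd = idd or {}
    overrides = overrides or {}
    nda_table = nda_table or {}
    minimal = clean_name(verbatim, "minimal")

    matched: str | None = None
    method = "UNMAPPED"

    rxaui = map_by_nda(nda_num, nda_table, vocab)
    if rxaui is not None:
        matched, method = rxaui, "NDA"
    if matched is None:
        rxaui = exact_match(minimal, vocab)
        if rxaui is not None:
            matched, method = rxaui, "EXACT"
    if matched is None:
        rxaui = idd.get(minimal)
        if rxaui is not None and rxaui in vocab:
            matched, method = rxaui, "IDD"
    if matched is None:
        rxaui = overrides.get(minimal)
        if rxaui is not None and rxaui in vocab:
            matched, method = rxaui, "MANUAL"
    if matched is None:
        deep = clean_name(verbatim, "deep")
        rxaui = exact_match(deep, vocab)
        if rxaui is not None:
            matched, method = rxaui, "CLEANED_EXACT"
        if matched is None:
            rxaui = idd.get(deep)
            if rxaui is not None and rxaui in vocab:
                matched, method = rxaui, "CLEANED_IDD"

    if matched is None:
        return MappingResult(drug_id, verbatim, None, "UNMAPPED")

    ingredients, flag = normalize_to_ingredients(matched, vocab, max_hops)
    if not ingredients:
        # relation walk failed within the hop bound: UNMAPPED-equivalent
        return MappingResult(drug_id, verbatim, None, "UNMAPPED",
                             note=f"walk_failed:{matched}")
    return MappingResult(drug_id, verbatim, matched, method,
                         ingredient_rxauis=ingredients, exception_flag=flag)


# -------------------------------------------------------------- batch mapping

def standardize_all(
    drug_table: pd.DataFrame,
    vocab: Vocabulary,
    idd: Mapping[str, str] | None = None,
    overrides: Mapping[str, str] | None = None,
    nda_table: Mapping[str, str] | None = None,
    manual_threshold: int = 200,
) -> tuple[pd.DataFrame, dict]:
    """Map every row of the combined drug table; never delete a row.

    Returns the standardized table — one row per (drug row, ingredient),
    UNMAPPED rows retained with a null ingredient — and a mapping report:
    per-method row counts, the mapped fraction, the UNMAPPED names whose
    frequency exceeds ``manual_threshold`` (candidates for the manual
    override file), and the count of rows where a stated active-ingredient
    field (prod_ai) disagrees with the verbatim-name mapping (the verbatim
    mapping wins; the conflict is only logged).
    """
    idd = idd or {}
    overrides = overrides or {}
    nda_table = nda_table or {}

    df = drug_table.reset_index(drop=True)
    key_name = df["drugname"].astype("string").fillna("")
    key_nda = df["nda_num"].astype("string").fillna("") if "nda_num" in df.columns \
        else pd.Series([""] * len(df), dtype="string")

    unique_keys = pd.DataFrame({"name": key_name, "nda": key_nda}).drop_duplicates()
    cache: dict[tuple[str, str], MappingResult] = {}
    for name, nda in unique_keys.itertuples(index=False):
        cache[(name, nda)] = cascade_map(
            name, nda if nda else None, vocab, idd, overrides, nda_table)

    rows = []
    method_counts: dict[str, int] = {m: 0 for m in METHODS}
    unmapped_names: dict[str, int] = {}
    prod_ai_conflicts = 0
    has_prod_ai = "prod_ai" in df.columns
    prod_ai_cache: dict[str, frozenset[str]] = {}

    for i in range(len(df)):
        rec = df.iloc[i]
        res = cache[(key_name.iat[i], key_nda.iat[i])]
        method_counts[res.method] += 1
        if res.method == "UNMAPPED":
            nm = clean_name(key_name.iat[i], "minimal")
            unmapped_names[nm] = unmapped_names.get(nm, 0) + 1
            rows.append((rec["drug_id"], rec["primaryid"], rec["drug_seq"],
                         rec["drugname"], None, "UNMAPPED", None, None,
                         "none", rec.get("period"), rec.get("role_code")))
            continue
        if has_prod_ai and pd.notna(rec.get("prod_ai")):
            ai = str(rec["prod_ai"])
            if ai not in prod_ai_cache:
                stated = exact_match(clean_name(ai, "minimal"), vocab)
                stated_ings: frozenset[str] = frozenset()
                if stated is not None:
                    ings, _ = normalize_to_ingredients(stated, vocab)
                    stated_ings = frozenset(ings)
                prod_ai_cache[ai] = stated_ings
            stated_ings = prod_ai_cache[ai]
            if stated_ings and stated_ings != frozenset(res.ingredient_rxauis):
                prod_ai_conflicts += 1
        for ing in res.ingredient_rxauis:
            entry = vocab.get(ing)
            rows.append((rec["drug_id"], rec["primaryid"], rec["drug_seq"],
                         rec["drugname"], res.matched_rxaui, res.method, ing,
                         entry.name if entry else None, res.exception_flag,
                         rec.get("period"), rec.get("role_code")))

    std = pd.DataFrame(rows, columns=[
        "drug_id", "primaryid", "drug_seq", "verbatim_name", "matched_rxaui",
        "method", "ingredient_rxaui", "ingredient_name", "exception_flag",
        "period", "role_code"])
    std["drug_id"] = std["drug_id"].astype("Int64")

    n_rows = len(df)
    mapped_rows = n_rows - method_counts["UNMAPPED"]
    report = {
        "n_drug_rows": n_rows,
        "method_counts": method_counts,
        "mapped_fraction": (mapped_rows / n_rows) if n_rows else None,
        "unmapped_frequent": sorted(
            [(n, c) for n, c in unmapped_names.items() if c > manual_threshold],
            key=lambda t: (-t[1], t[0])),
        "prod_ai_conflicts": prod_ai_conflicts,
    }
    return std, report


def read_two_column_table(path) -> dict[str, str]:
    """Read an IDD or manual-override file: tab-delimited name -> rxaui."""
    out: dict[str, str] = {}
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    name_col, aui_col = df.columns[:2]
    for name, rxaui in zip(df[name_col], df[aui_col]):
        if name and rxaui:
            out[normalize_lookup_name(name)] = rxaui
    return out


def write_two_column_table(mapping: Mapping[str, str], path,
                           name_header: str = "verbatim_name") -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"{name_header}\trxaui\n")
        for name in sorted(mapping):
            fh.write(f"{name}\t{mapping[name]}\n")
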