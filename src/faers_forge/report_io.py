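"""Reading and harmonizing FAERS/LAERS quarterly data extracts.

Each quarterly extract is a set of "$"-delimited ASCII files with one header
line: DEMO (one row per report), DRUG, REAC, INDI, OUTC, THER and RPSR,
plus a deleted-case list from 2019Q1 onward.  The legacy (LAERS, pre-2012Q4)
and current (FAERS) layouts differ only slightly — the legacy primary key
``ISR`` vs ``primaryid``, the absence of ``caseversion`` and ``prod_ai`` in
the legacy files, and a few column spellings.  This module parses both,
consolidates them into one canonical schema, stamps every row with its
source PERIOD, and normalizes ages (to years) and reporter countries (to
ISO 3166 alpha-2 codes).

Rows with the wrong field count are never silently dropped: they are
quarantined with their line number and reported in the audit log, so that
parsed rows + quarantined rows always equals the physical data lines.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._countries import COUNTRY_ALIASES

TABLE_KINDS = ("demo", "drug", "reac", "indi", "ther", "outc", "rpsr")
MANDATORY_KINDS = ("demo", "drug", "reac")  # every report has >=1 drug and reaction

PERIOD_RE = re.compile(r"^\d{4}Q[1-4]$")

#: raw header -> canonical column name (covers both eras' spellings)
COLUMN_RENAMES = {
    "isr": "primaryid",
    "case": "caseid",
    "i_f_cod": "i_f_code",
    "gndr_cod": "gender",
    "sex": "gender",
    "role_cod": "role_code",
    "outc_cod": "outc_code",
    "rpsr_cod": "rpsr_code",
}

#: canonical column order per table kind (before the PERIOD/source stamps)
CANONICAL_COLUMNS: dict[str, tuple[str, ...]] = {
    "demo": ("primaryid", "caseid", "caseversion", "i_f_code", "event_dt",
             "fda_dt", "age", "age_cod", "gender", "reporter_country"),
    "drug": ("primaryid", "drug_seq", "role_code", "drugname", "prod_ai",
             "nda_num"),
    "reac": ("primaryid", "pt"),
    "indi": ("primaryid", "indi_drug_seq", "indi_pt"),
    "ther": ("primaryid", "dsg_drug_seq", "start_dt", "end_dt", "dur",
             "dur_cod"),
    "outc": ("primaryid", "outc_code"),
    "rpsr": ("primaryid", "rpsr_code"),
}

#: age-unit -> factor converting the reported value to years.  The extract
#: codes decades, years, months, weeks, days and hours; conventional
#: calendar factors are used.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.0,
    "HR": 1.0 / 8760.0,
}

AGE_PLAUSIBLE_MAX = 150.0  # out-of-range ages are nulled, not clamped


@dataclass(frozen=True)
class QuarterExtract:
    """Locations of one quarter's extract files, keyed by table kind."""

    period: str
    paths: Mapping[str, Path]  # kind -> path; kinds from TABLE_KINDS + "deleted"

    def __post_init__(self) -> None:
        if not PERIOD_RE.match(self.period):
            raise ValueError(f"bad period label {self.period!r} (want YYYYQn)")
        missing = [k for k in MANDATORY_KINDS if k not in self.paths]
        if missing:
            raise ValueError(
                f"{self.period}: missing mandatory table file(s): {', '.join(missing)}"
            )


@dataclass
class FaersDataset:
    """The combined, harmonized tables for a set of quarters."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    indi: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    rpsr: pd.DataFrame
    deleted_caseids: set[str] = field(default_factory=set)
    audit: dict = field(default_factory=dict)

    def tables(self) -> Iterable[tuple[str, pd.DataFrame]]:
        for kind in TABLE_KINDS:
            yield kind, getattr(self, kind)

    @property
    def case_ids(self) -> pd.Series:
        return self.demo["primaryid"]

    def filter_cases(self, keep: Iterable[str]) -> "FaersDataset":
        """A new dataset restricted to the given primaryids (all tables)."""
        keep = set(keep)
        kw = {k: df[df["primaryid"].isin(keep)].reset_index(drop=True)
              for k, df in self.tables()}
        return FaersDataset(**kw, deleted_caseids=set(self.deleted_caseids),
                            audit=dict(self.audit))

    def save(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for kind, df in self.tables():
            df.to_csv(outdir / f"{kind.upper()}_combined.txt", sep="\t",
                      index=False, na_rep="")
        pd.Series(sorted(self.deleted_caseids)).to_csv(
            outdir / "DELETED_caseids.txt", index=False, header=["caseid"])

    @classmethod
    def load(cls, indir: str | Path) -> "FaersDataset":
        indir = Path(indir)
        kw = {}
        for kind in TABLE_KINDS:
            df = pd.read_csv(indir / f"{kind.upper()}_combined.txt", sep="\t",
                             dtype=str, keep_default_na=False)
            df = df.replace("", pd.NA)
            if kind == "demo" and "age_years" in df.columns:
                df["age_years"] = df["age_years"].astype("Float64")
            if kind == "drug" and "drug_id" in df.columns:
                df["drug_id"] = df["drug_id"].astype("Int64")
            kw[kind] = df
        del_path = indir / "DELETED_caseids.txt"
        deleted: set[str] = set()
        if del_path.exists():
            s = pd.read_csv(del_path, dtype=str, keep_default_na=False)
            if "caseid" in s.columns:
                deleted = set(s["caseid"].dropna()) - {""}
        return cls(**kw, deleted_caseids=deleted)


# --------------------------------------------------------------------- parsing

def _read_dollar_file(path: str | Path) -> tuple[pd.DataFrame, list[tuple[int, str]]]:
    """Split a "$"-delimited file into a string table plus quarantined lines.

    The first line is the header.  Any data line whose field count differs
    from the header's (too few or too many) is quarantined with its 1-based
    line number.
    """
    text = Path(path).read_text(encoding="utf-8", errors="replace")
    lines = text.splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file (no header line)")
    header = [h.strip().lower() for h in lines[0].split("$")]
    ncol = len(header)
    rows: list[list[str]] = []
    rejects: list[tuple[int, str]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("$")
        if len(parts) != ncol:
            rejects.append((lineno, line))
            continue
        rows.append([p.strip() for p in parts])
    df = pd.DataFrame(rows, columns=header, dtype=object)
    df = df.replace("", pd.NA)
    return df, rejects


def _harmonize(df: pd.DataFrame, kind: str, period: str) -> pd.DataFrame:
    """Rename legacy columns, fill schema gaps, stamp PERIOD and source."""
    source = "LAERS" if "isr" in df.columns else "FAERS"
    df = df.rename(columns=COLUMN_RENAMES)
    canonical = CANONICAL_COLUMNS[kind]
    for col in canonical:
        if col not in df.columns:
            df[col] = pd.NA
    if kind == "demo":
        # legacy extracts carry no version; 0 sorts before any FAERS version
        df["caseversion"] = df["caseversion"].fillna("0")
    extras = [c for c in df.columns if c not in canonical]
    df = df[list(canonical) + extras]
    df["period"] = period
    df["source"] = source
    return df


def parse_quarter(
    extract: QuarterExtract,
    quarantine_dir: str | Path | None = None,
) -> tuple[dict[str, pd.DataFrame], set[str], dict]:
    """Parse one quarter into harmonized raw tables.

    Returns ``(tables, deleted_caseids, audit)``.  No rows are filtered at
    parse time; the audit carries per-table parsed/quarantined line counts
    for the record-count validation step.
    """
    tables: dict[str, pd.DataFrame] = {}
    audit: dict = {"period": extract.period, "tables": {}}
    for kind in TABLE_KINDS:
        path = extract.paths.get(kind)
        if path is None:
            if kind in MANDATORY_KINDS:
                raise FileNotFoundError(
                    f"{extract.period}: mandatory table {kind.upper()} missing")
            continue
        df, rejects = _read_dollar_file(path)
        df = _harmonize(df, kind, extract.period)
        tables[kind] = df
        audit["tables"][kind] = {"rows": len(df), "quarantined": len(rejects)}
        if rejects and quarantine_dir is not None:
            qdir = Path(quarantine_dir)
            qdir.mkdir(parents=True, exist_ok=True)
            with open(qdir / f"{extract.period}_{kind}.rejects.txt", "w",
                      encoding="utf-8") as fh:
                for lineno, line in rejects:
                    fh.write(f"{lineno}\t{line}\n")
        audit["tables"][kind]["reject_lines"] = rejects
    deleted: set[str] = set()
    if "deleted" in extract.paths:
        ddf, drejects = _read_dollar_file(extract.paths["deleted"])
        col = "caseid" if "caseid" in ddf.columns else ddf.columns[0]
        deleted = set(ddf[col].dropna().astype(str))
        audit["tables"]["deleted"] = {"rows": len(ddf), "quarantined": len(drejects)}
    return tables, deleted, audit


# ----------------------------------------------------------- field normalizers

def normalize_age(value, unit_code) -> float | None:
    """Convert a reported (value, unit) age to years; total, nullable.

    Unknown or missing units and non-numeric values yield null, as do
    results outside the plausible [0, 150]-year range.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)) or value is pd.NA:
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    unit = None if unit_code is None or unit_code is pd.NA else str(unit_code).strip().upper()
    factor = AGE_UNIT_TO_YEARS.get(unit)
    if factor is None:
        return None
    years = v * factor
    if years < 0 or years > AGE_PLAUSIBLE_MAX:
        return None
    return years


def normalize_age_series(values: pd.Series, units: pd.Series) -> pd.Series:
    v = pd.to_numeric(values, errors="coerce").astype(float)
    u = units.astype("string").str.strip().str.upper()
    factor = u.map(AGE_UNIT_TO_YEARS).astype("Float64")
    years = (pd.array(v, dtype="Float64") * factor)
    years = years.to_numpy(dtype=object)
    out = pd.Series(years, index=values.index, dtype="Float64")
    out[(out < 0) | (out > AGE_PLAUSIBLE_MAX)] = pd.NA
    return out


def normalize_country(raw) -> str | None:
    """Map a raw reporter-country value to an ISO 3166 alpha-2 code."""
    if raw is None or raw is pd.NA:
        return None
    key = " ".join(str(raw).split()).upper()
    return COUNTRY_ALIASES.get(key)


def normalize_country_series(values: pd.Series) -> tuple[pd.Series, dict[str, int]]:
    """Vectorized country normalization plus an unmatched-value tally."""
    keys = values.astype("string").str.split().str.join(" ").str.upper()
    mapped = keys.map(COUNTRY_ALIASES)
    unmatched = keys[mapped.isna() & keys.notna()]
    tally = unmatched.value_counts().to_dict()
    return mapped.astype("string"), {str(k): int(v) for k, v in tally.items()}


# --------------------------------------------------------------------- merging

def assemble_dataset(
    per_quarter_tables: Sequence[dict[str, pd.DataFrame]],
    deleted_sets: Sequence[set[str]] = (),
    audits: Sequence[dict] = (),
) -> FaersDataset:
    """Union harmonized per-quarter tables into one combined dataset.

    Missing table kinds become empty tables; DRUG rows get globally unique
    serial ``drug_id`` numbers in ingest order; DEMO gains the normalized
    ``age_years`` and ``country_code`` columns.
    """
    combined: dict[str, pd.DataFrame] = {}
    for kind in TABLE_KINDS:
        parts = [t[kind] for t in per_quarter_tables if kind in t]
        if parts:
            df = pd.concat(parts, ignore_index=True)
        else:
            df = pd.DataFrame(columns=list(CANONICAL_COLUMNS[kind]) + ["period", "source"])
        combined[kind] = df
    drug = combined["drug"]
    drug["drug_id"] = pd.array(np.arange(1, len(drug) + 1), dtype="Int64")
    demo = combined["demo"]
    if len(demo):
        demo["age_years"] = normalize_age_series(demo["age"], demo["age_cod"])
        demo["country_code"], unmatched = normalize_country_series(demo["reporter_country"])
        demo["gender"] = demo["gender"].astype("string").str.strip().str.upper()
        demo.loc[~demo["gender"].isin(["F", "M", "UNK"]), "gender"] = pd.NA
    else:
        demo["age_years"] = pd.array([], dtype="Float64")
        demo["country_code"] = pd.array([], dtype="string")
        unmatched = {}
    audit = {
        "quarters": [a.get("period") for a in audits],
        "per_quarter": list(audits),
        "combined_rows": {k: len(v) for k, v in combined.items()},
        "unmatched_countries": unmatched,
    }
    deleted = set().union(*deleted_sets) if deleted_sets else set()
    return FaersDataset(**combined, deleted_caseids=deleted, audit=audit)


def merge_quarters(
    extracts: Sequence[QuarterExtract],
    quarantine_dir: str | Path | None = None,
) -> FaersDataset:
    """Parse and merge quarterly extracts into one combined dataset."""
    periods = [e.period for e in extracts]
    dupes = {p for p in periods if periods.count(p) > 1}
    if dupes:
        raise ValueError(f"duplicate quarter(s) supplied: {sorted(dupes)}")
    parsed, deleted_sets, audits = [], [], []
    for extract in sorted(extracts, key=lambda e: e.period):
        tables, deleted, audit = parse_quarter(extract, quarantine_dir)
        parsed.append(tables)
        deleted_sets.append(deleted)
        audits.append(audit)
    return assemble_dataset(parsed, deleted_sets, audits)


def apply_deleted_cases(
    dataset: FaersDataset,
    deleted_caseids: Iterable[str] | None = None,
) -> tuple[FaersDataset, int]:
    """Drop every report whose caseid appears in a deleted-case list.

    Idempotent; returns the filtered dataset and the number of reports
    removed.
    """
    deleted = set(deleted_caseids) if deleted_caseids is not None else dataset.deleted_caseids
    if not deleted:
        return dataset, 0
    demo = dataset.demo
    drop_mask = demo["caseid"].isin(deleted)
    n_removed = int(drop_mask.sum())
    keep_ids = demo.loc[~drop_mask, "primaryid"]
    out = dataset.filter_cases(keep_ids)
    out.audit = dict(dataset.audit)
    out.audit["deleted_cases_removed"] = n_removed
    return out, n_removed
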