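"""Materialization of the eleven curated output tables.

The curated dataset is exported as eleven tab-delimited UTF-8 text files
(nulls as empty fields, dates as 8-digit YYYYMMDD strings) plus a
machine-readable data dictionary and an audit manifest with row counts,
column lists and file checksums:

DEMOGRAPHICS, DRUGS_STANDARDIZED, ADVERSE_REACTIONS,
DRUG_ADVERSE_REACTIONS_PAIRS, DRUG_ADVERSE_REACTIONS_COUNT,
DRUG_INDICATIONS, CASE_OUTCOMES, THERAPY_DATES, REPORT_SOURCES,
CONTINGENCY_TABLE, PROPORTIONATE_ANALYSIS.

Indication rows whose description is an unknown-indication placeholder
("Product used for (the) unknown indication" / "Drug use for (the) unknown
indication") are treated as null and deleted before export.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .dedup import UNKNOWN_INDICATION_PHRASES
from .report_io import FaersDataset

EXPORT_TABLES = (
    "DEMOGRAPHICS", "DRUGS_STANDARDIZED", "ADVERSE_REACTIONS",
    "DRUG_ADVERSE_REACTIONS_PAIRS", "DRUG_ADVERSE_REACTIONS_COUNT",
    "DRUG_INDICATIONS", "CASE_OUTCOMES", "THERAPY_DATES", "REPORT_SOURCES",
    "CONTINGENCY_TABLE", "PROPORTIONATE_ANALYSIS",
)

_DICTIONARY = {
    "DEMOGRAPHICS": "One row per deduplicated case report: identifiers, "
                    "receipt/event dates, gender, age normalized to years, "
                    "reporter country as ISO 3166 alpha-2, source quarter.",
    "DRUGS_STANDARDIZED": "One row per (drug mention, active ingredient): "
                          "verbatim name, mapping method, matched atom and "
                          "ingredient-level atom; constituents of a "
                          "multi-ingredient product share the parent drug_id.",
    "ADVERSE_REACTIONS": "Adverse-event preferred terms per case.",
    "DRUG_ADVERSE_REACTIONS_PAIRS": "Distinct (case, ingredient, event) triples.",
    "DRUG_ADVERSE_REACTIONS_COUNT": "Distinct (ingredient, event) pairs with "
                                    "report frequency (the contingency a cell).",
    "DRUG_INDICATIONS": "Indication terms per drug mention; unknown-indication "
                        "placeholder rows deleted.",
    "CASE_OUTCOMES": "Case outcome codes.",
    "THERAPY_DATES": "Therapy start/end dates and duration per drug mention.",
    "REPORT_SOURCES": "Report source codes.",
    "CONTINGENCY_TABLE": "a, b, c, d and N per (ingredient, event) pair, "
                         "counted in distinct reports.",
    "PROPORTIONATE_ANALYSIS": "PRR, ROR (with 95% CI), Yates chi-squared, "
                              "a_exp and IC with IC025/IC975 per pair; "
                              "undefined ratio statistics are null with a "
                              "reason code.",
}


@dataclass
class ExportManifest:
    tables: dict[str, dict] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"tables": self.tables, "stage_counts": self.stage_counts,
                "config": self.config}


def clean_indications(indi: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop unknown-indication placeholder rows (case-insensitive, trimmed)."""
    if indi.empty:
        return indi, 0
    key = indi["indi_pt"].astype("string").str.strip().str.casefold()
    drop = key.isin(UNKNOWN_INDICATION_PHRASES)
    return indi[~drop].reset_index(drop=True), int(drop.sum())


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def export_all(
    dataset: FaersDataset,
    standardized: pd.DataFrame,
    contingency: pd.DataFrame,
    analysis: pd.DataFrame,
    outdir: str | Path,
    stage_counts: dict | None = None,
    config: dict | None = None,
) -> ExportManifest:
    """Write the eleven tables plus data dictionary and manifest.

    The output directory is verified writable before any table is written
    (no partial exports on a bad path).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # pragma: no cover - environment-specific
        raise OSError(f"output directory {outdir} is not writable") from exc

    demo_cols = ["primaryid", "caseid", "caseversion", "i_f_code", "event_dt",
                 "fda_dt", "age_years", "gender", "country_code", "period",
                 "source"]
    demographics = dataset.demo[[c for c in demo_cols if c in dataset.demo.columns]]

    pairs = (standardized[standardized["ingredient_rxaui"].notna()]
             [["primaryid", "ingredient_rxaui", "ingredient_name"]]
             .merge(dataset.reac[["primaryid", "pt"]], on="primaryid")
             .drop_duplicates(["primaryid", "ingredient_rxaui", "pt"])
             .reset_index(drop=True))
    counts = (pairs.groupby(["ingredient_rxaui", "ingredient_name", "pt"])
              .size().rename("frequency").reset_index()
              .sort_values(["ingredient_rxaui", "pt"]).reset_index(drop=True))

    indi_clean, n_unknown = clean_indications(dataset.indi)

    tables: dict[str, pd.DataFrame] = {
        "DEMOGRAPHICS": demographics,
        "DRUGS_STANDARDIZED": standardized,
        "ADVERSE_REACTIONS": dataset.reac[["primaryid", "pt", "period"]],
        "DRUG_ADVERSE_REACTIONS_PAIRS": pairs,
        "DRUG_ADVERSE_REACTIONS_COUNT": counts,
        "DRUG_INDICATIONS": indi_clean[["primaryid", "indi_drug_seq",
                                        "indi_pt", "period"]],
        "CASE_OUTCOMES": dataset.outc[["primaryid", "outc_code", "period"]],
        "THERAPY_DATES": dataset.ther[["primaryid", "dsg_drug_seq", "start_dt",
                                       "end_dt", "dur", "dur_cod", "period"]],
        "REPORT_SOURCES": dataset.rpsr[["primaryid", "rpsr_code", "period"]],
        "CONTINGENCY_TABLE": contingency,
        "PROPORTIONATE_ANALYSIS": analysis,
    }

    manifest = ExportManifest(stage_counts=dict(stage_counts or {}),
                              config=dict(config or {}))
    manifest.stage_counts["unknown_indication_rows_removed"] = n_unknown
    for name in EXPORT_TABLES:
        df = tables[name]
        path = outdir / f"{name}.txt"
        df.to_csv(path, sep="\t", index=False, na_rep="")
        manifest.tables[name] = {
            "rows": int(len(df)),
            "columns": list(df.columns),
            "sha256": _sha256(path),
        }
    with open(outdir / "data_dictionary.json", "w", encoding="utf-8") as fh:
        json.dump({n: {"description": _DICTIONARY[n],
                       "columns": manifest.tables[n]["columns"],
                       "delimiter": "tab", "encoding": "UTF-8",
                       "null_representation": "empty field"}
                   for n in EXPORT_TABLES}, fh, indent=2)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest.to_dict(), fh, indent=2, default=str)
    return manifest
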