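"""End-to-end orchestration: ingest -> mapping -> dedup -> statistics -> export.

The stage order is fixed and recorded in the manifest: parse/merge the
quarterly extracts, standardize drug names (mapping runs *before*
cross-source deduplication so the duplicate rule compares ingredient sets),
stage-1 dedup + deleted-case removal + cross-source dedup, contingency
table and proportionate analysis, export.  Each stage writes a checkpoint
under the output directory; a rerun with the identical config resumes from
the last complete checkpoint and produces identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import dedup as dedup_mod
from . import export as export_mod
from . import stats as stats_mod
from .report_io import FaersDataset, QuarterExtract, TABLE_KINDS, merge_quarters
from .standardize import read_two_column_table, standardize_all
from .vocab import Vocabulary

STAGES = ("ingest", "map_drugs", "dedup", "stats", "export")


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serialized into the manifest."""

    input_dir: str | None = None
    quarters: tuple[str, ...] = ()
    vocab_dir: str | None = None
    idd_path: str | None = None
    overrides_path: str | None = None
    nda_path: str | None = None
    null_policy: str = "unknown"
    drug_level: str = "ingredient"
    manual_threshold: int = 200
    continuity: float = 0.0
    min_a: int = 1
    outdir: str = "faers_forge_out"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["quarters"] = list(self.quarters)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()


@dataclass
class PipelineResult:
    dataset: FaersDataset
    standardized: pd.DataFrame
    contingency: pd.DataFrame
    analysis: pd.DataFrame
    mapping_report: dict = field(default_factory=dict)
    dedup_audit: dict = field(default_factory=dict)
    manifest: export_mod.ExportManifest | None = None


def discover_extracts(input_dir: str | Path,
                      quarters: tuple[str, ...] = ()) -> list[QuarterExtract]:
    """Find per-quarter extract files laid out as ``<input_dir>/<period>/``."""
    input_dir = Path(input_dir)
    extracts = []
    for qdir in sorted(p for p in input_dir.iterdir() if p.is_dir()):
        period = qdir.name
        if quarters and period not in quarters:
            continue
        paths = {}
        for kind in TABLE_KINDS + ("deleted",):
            hits = sorted(qdir.glob(f"{kind.upper()}*"))
            if hits:
                paths[kind] = hits[0]
        if paths:
            extracts.append(QuarterExtract(period=period, paths=paths))
    return extracts


def load_resources(config: RunConfig):
    """Vocabulary + lookup tables per the run config (mini-vocab fallback)."""
    if config.vocab_dir:
        vdir = Path(config.vocab_dir)
        exc_path = vdir / "exceptions.json"
        exceptions = json.loads(exc_path.read_text()) if exc_path.exists() else None
        vocab = Vocabulary.from_rrf(vdir, exceptions=exceptions)
        idd = read_two_column_table(config.idd_path) if config.idd_path else {}
        nda = {}
        if config.nda_path:
            df = pd.read_csv(config.nda_path, sep="\t", dtype=str,
                             keep_default_na=False)
            nda = {r[0]: r[1] for r in df.itertuples(index=False) if r[0] and r[1]}
    else:
        from .synthetic import build_mini_vocabulary
        mini = build_mini_vocabulary()
        vocab, idd, nda = mini.vocab, mini.idd, mini.nda_table
    overrides = (read_two_column_table(config.overrides_path)
                 if config.overrides_path else {})
    return vocab, idd, overrides, nda


def run_pipeline(
    extracts_or_dataset,
    vocab: Vocabulary,
    idd=None,
    overrides=None,
    nda_table=None,
    null_policy: str = "unknown",
    drug_level: str = "ingredient",
    manual_threshold: int = 200,
    continuity: float = 0.0,
    min_a: int = 1,
) -> PipelineResult:
    """The library entry point: run all compute stages in memory."""
    if isinstance(extracts_or_dataset, FaersDataset):
        dataset = extracts_or_dataset
    else:
        dataset = merge_quarters(extracts_or_dataset)
    std, mapping_report = standardize_all(
        dataset.drug, vocab, idd, overrides, nda_table, manual_threshold)
    deduped, dedup_audit = dedup_mod.deduplicate(
        dataset, std, null_policy=null_policy, drug_level=drug_level)
    keep = set(deduped.demo["primaryid"])
    std = std[std["primaryid"].isin(keep)].reset_index(drop=True)
    pairs = (std[std["ingredient_rxaui"].notna()]
             [["primaryid", "ingredient_rxaui"]]
             .merge(deduped.reac[["primaryid", "pt"]], on="primaryid"))
    cells = stats_mod.build_contingency(pairs, n_total=len(deduped.demo))
    if min_a > 1:
        cells = cells[cells["a"] >= min_a].reset_index(drop=True)
    analysis = stats_mod.proportionate_analysis(cells, continuity)
    return PipelineResult(dataset=deduped, standardized=std,
                          contingency=cells, analysis=analysis,
                          mapping_report=mapping_report,
                          dedup_audit={k: v for k, v in dedup_audit.items()
                                       if k != "groups"})


# ------------------------------------------------------------ checkpointed run

def _ckpt_dir(config: RunConfig) -> Path:
    return Path(config.outdir) / "checkpoints"


def _ckpt_done(config: RunConfig, stage: str) -> bool:
    marker = _ckpt_dir(config) / stage / "DONE.json"
    if not marker.exists():
        return False
    try:
        return json.loads(marker.read_text()).get("config_digest") == config.digest()
    except (OSError, json.JSONDecodeError):
        return False


def _ckpt_mark(config: RunConfig, stage: str) -> None:
    d = _ckpt_dir(config) / stage
    d.mkdir(parents=True, exist_ok=True)
    (d / "DONE.json").write_text(json.dumps(
        {"stage": stage, "config_digest": config.digest()}))


def run(config: RunConfig, extracts: list[QuarterExtract] | None = None,
        resume: bool = True) -> export_mod.ExportManifest:
    """Checkpointed end-to-end run producing the exported dataset.

    ``extracts`` defaults to discovery under ``config.input_dir``.  With
    ``resume`` (default) a stage whose checkpoint matches the exact config
    digest is reloaded instead of recomputed.
    """
    outdir = Path(config.outdir)
    ck = _ckpt_dir(config)
    vocab, idd, overrides, nda = load_resources(config)

    # ingest
    ingest_dir = ck / "ingest"
    if resume and _ckpt_done(config, "ingest"):
        dataset = FaersDataset.load(ingest_dir)
    else:
        if extracts is None:
            if not config.input_dir:
                raise ValueError("no extracts given and no input_dir configured")
            extracts = discover_extracts(config.input_dir, tuple(config.quarters))
        dataset = merge_quarters(extracts, quarantine_dir=outdir / "quarantine")
        ingest_dir.mkdir(parents=True, exist_ok=True)
        dataset.save(ingest_dir)
        _ckpt_mark(config, "ingest")

    # map drugs
    map_dir = ck / "map_drugs"
    if resume and _ckpt_done(config, "map_drugs"):
        std = pd.read_csv(map_dir / "DRUGS_STANDARDIZED.txt", sep="\t",
                          dtype=str, keep_default_na=False).replace("", pd.NA)
        std["drug_id"] = std["drug_id"].astype("Int64")
        mapping_report = json.loads((map_dir / "mapping_report.json").read_text())
    else:
        std, mapping_report = standardize_all(
            dataset.drug, vocab, idd, overrides, nda,
            manual_threshold=config.manual_threshold)
        map_dir.mkdir(parents=True, exist_ok=True)
        std.to_csv(map_dir / "DRUGS_STANDARDIZED.txt", sep="\t", index=False,
                   na_rep="")
        (map_dir / "mapping_report.json").write_text(
            json.dumps(mapping_report, indent=2))
        _ckpt_mark(config, "map_drugs")

    # dedup
    dedup_dir = ck / "dedup"
    if resume and _ckpt_done(config, "dedup"):
        deduped = FaersDataset.load(dedup_dir)
        dedup_audit = json.loads((dedup_dir / "dedup_audit.json").read_text())
    else:
        deduped, dedup_audit = dedup_mod.deduplicate(
            dataset, std, null_policy=config.null_policy,
            drug_level=config.drug_level)
        dedup_dir.mkdir(parents=True, exist_ok=True)
        deduped.save(dedup_dir)
        slim = {k: v for k, v in dedup_audit.items() if k != "groups"}
        (dedup_dir / "dedup_audit.json").write_text(json.dumps(slim, indent=2))
        removed = [m for g in dedup_audit.get("groups", [])
                   for m in g["members"] if m != g["retained"]]
        (dedup_dir / "removed_ids.txt").write_text(
            "\n".join(removed) + ("\n" if removed else ""))
        _ckpt_mark(config, "dedup")
    keep = set(deduped.demo["primaryid"])
    std = std[std["primaryid"].isin(keep)].reset_index(drop=True)

    # stats
    stats_dir = ck / "stats"
    if resume and _ckpt_done(config, "stats"):
        cells = pd.read_csv(stats_dir / "CONTINGENCY_TABLE.txt", sep="\t",
                            dtype={"ingredient_rxaui": str, "pt": str})
        # integer cells round-trip exactly; recomputing the float statistics
        # from them is deterministic, unlike re-parsing printed floats
        analysis = stats_mod.proportionate_analysis(cells, config.continuity)
    else:
        pairs = (std[std["ingredient_rxaui"].notna()]
                 [["primaryid", "ingredient_rxaui"]]
                 .merge(deduped.reac[["primaryid", "pt"]], on="primaryid"))
        cells = stats_mod.build_contingency(pairs, n_total=len(deduped.demo))
        if config.min_a > 1:
            cells = cells[cells["a"] >= config.min_a].reset_index(drop=True)
        analysis = stats_mod.proportionate_analysis(cells, config.continuity)
        stats_dir.mkdir(parents=True, exist_ok=True)
        cells.to_csv(stats_dir / "CONTINGENCY_TABLE.txt", sep="\t", index=False)
        analysis.to_csv(stats_dir / "PROPORTIONATE_ANALYSIS.txt", sep="\t",
                        index=False, na_rep="")
        _ckpt_mark(config, "stats")

    # export
    stage_counts = {
        "parsed_cases": int(dataset.audit.get("combined_rows", {}).get("demo", len(dataset.demo))),
        "deduplicated_cases": len(deduped.demo),
        "mapped_drug_rows": mapping_report["n_drug_rows"]
        - mapping_report["method_counts"]["UNMAPPED"],
        "stage_order": list(STAGES),
    }
    manifest = export_mod.export_all(
        deduped, std, cells, analysis, outdir / "dataset",
        stage_counts=stage_counts, config=config.to_dict())
    _ckpt_mark(config, "export")
    return manifest
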