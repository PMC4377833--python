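"""End-to-end sample processing: merge, filter, bin, call, report.

Runs the full analysis for one tumour (with optional matched normal) or a
batch of samples from a sample sheet, writing per-locus length
distributions, call reports (TSV + JSON), and a run log whose read
accounting is exactly conserved at every stage boundary:
``pairs_in = merged + merge_failed``, ``merged = q_kept + q_discarded``,
``q_kept = sum(assigned per locus) + unassigned``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .binning import LengthDistribution, bin_reads, build_lookup
from .classify import (ClassifyConfig, ComparatorSource, LocusCall,
                       SampleResult, call_locus, overall_status)
from .fastq import read_pairs
from .panel import Panel
from .preprocess import MergedRead, MergeFailure, PreprocessConfig, \
    merge_pair, quality_filter

__all__ = ["RunConfig", "ReadAccounting", "process_fastq", "run_sample",
           "run_batch"]

logger = logging.getLogger("msiamp")


@dataclass
class ReadAccounting:
    """Per-stage read counts; conserved across every boundary."""

    pairs_in: int = 0
    merged: int = 0
    merge_failed: int = 0
    q_kept: int = 0
    q_discarded: int = 0
    assigned: dict[str, int] = field(default_factory=dict)
    unassigned: int = 0

    def as_dict(self) -> dict:
        return {
            "pairs_in": self.pairs_in, "merged": self.merged,
            "merge_failed": self.merge_failed, "q_kept": self.q_kept,
            "q_discarded": self.q_discarded,
            "assigned": dict(self.assigned),
            "unassigned": self.unassigned,
        }


@dataclass
class RunConfig:
    """One sample run: inputs, output directory and analysis parameters.

    Absence of normal reads switches classification to tumour-only mode,
    where only loci carrying an explicit ``reference_modal_length`` are
    called (quasimonomorphic markers such as BAT25/BAT26).
    """

    panel: Panel
    tumour_r1: Path
    tumour_r2: Path
    out_dir: Path
    normal_r1: Path | None = None
    normal_r2: Path | None = None
    sample_id: str = "sample"
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    classify: ClassifyConfig = field(default_factory=ClassifyConfig)
    max_flank_mismatches: int = 0

    @property
    def paired(self) -> bool:
        return self.normal_r1 is not None and self.normal_r2 is not None


def process_fastq(r1: Path, r2: Path, panel: Panel,
                  pre_cfg: PreprocessConfig | None = None,
                  max_flank_mismatches: int = 0
                  ) -> tuple[dict[str, LengthDistribution], ReadAccounting]:
    """Merge, quality-filter and bin one sample's paired FASTQ files."""
    pre_cfg = pre_cfg or PreprocessConfig()
    table = build_lookup(panel)
    acct = ReadAccounting()
    kept: list[MergedRead] = []
    for pair in read_pairs(r1, r2):
        acct.pairs_in += 1
        merged = merge_pair(pair, pre_cfg)
        if isinstance(merged, MergeFailure):
            acct.merge_failed += 1
            continue
        acct.merged += 1
        if quality_filter(merged, pre_cfg):
            acct.q_kept += 1
            kept.append(merged)
        else:
            acct.q_discarded += 1
    dists, assigned, unassigned = bin_reads(kept, table,
                                            max_flank_mismatches)
    acct.assigned = assigned
    acct.unassigned = unassigned
    return dists, acct


def _empty_dist(locus_name: str) -> LengthDistribution:
    return LengthDistribution(locus_name=locus_name, counts={})


def _call_sample(cfg: RunConfig,
                 tumour_dists: dict[str, LengthDistribution],
                 normal_dists: dict[str, LengthDistribution] | None
                 ) -> SampleResult:
    calls: list[LocusCall] = []
    for locus in cfg.panel:
        tumour = tumour_dists.get(locus.name, _empty_dist(locus.name))
        if normal_dists is not None:
            comparator = normal_dists.get(locus.name,
                                          _empty_dist(locus.name))
        else:
            if locus.reference_modal_length is None:
                logger.info(
                    "locus %s skipped: tumour-only mode requires an "
                    "explicit reference_modal_length", locus.name)
                continue
            comparator = locus.reference_modal_length
        calls.append(call_locus(tumour, comparator, locus, cfg.classify))
    return overall_status(calls, cfg.classify, sample_id=cfg.sample_id)


def _write_distributions(path: Path, sample_id: str,
                         dists_by_role: dict[str, dict[str,
                                                       LengthDistribution]]
                         ) -> None:
    rows = []
    for role, dists in dists_by_role.items():
        for locus_name in sorted(dists):
            d = dists[locus_name]
            for length in sorted(d.counts):
                rows.append({"sample": sample_id, "role": role,
                             "locus": locus_name, "length_bp": length,
                             "read_count": d.counts[length]})
    pd.DataFrame(rows, columns=["sample", "role", "locus", "length_bp",
                                "read_count"]
                 ).to_csv(path, sep="\t", index=False)


def _report_frame(result: SampleResult) -> pd.DataFrame:
    rows = []
    for c in result.calls:
        rows.append({
            "sample": result.sample_id, "locus": c.locus_name,
            "tumour_mode": c.tumour_modal_length,
            "comparator_mode": c.comparator_modal_length,
            "comparator_source": (c.comparator_source.value
                                  if c.comparator_source else None),
            "delta_bp": c.delta_bp, "cutoff_bp": c.cutoff_bp,
            "status": c.status.value,
        })
    rows.append({"sample": result.sample_id, "locus": "OVERALL",
                 "tumour_mode": None, "comparator_mode": None,
                 "comparator_source": None, "delta_bp": None,
                 "cutoff_bp": None, "status": result.overall.value})
    return pd.DataFrame(rows)


def run_sample(cfg: RunConfig) -> SampleResult:
    """Process one sample end to end and write all reports.

    Writes ``<sample>_distributions.tsv``, ``<sample>_report.tsv``,
    ``<sample>_report.json`` and ``<sample>_run.log`` under ``out_dir``.
    """
    for p in (cfg.tumour_r1, cfg.tumour_r2, cfg.normal_r1, cfg.normal_r2):
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"input file not found: {p}")
    cfg.out_dir = Path(cfg.out_dir)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)

    tumour_dists, t_acct = process_fastq(
        cfg.tumour_r1, cfg.tumour_r2, cfg.panel, cfg.preprocess,
        cfg.max_flank_mismatches)
    accounting = {"tumour": t_acct}
    dists_by_role = {"tumour": tumour_dists}
    normal_dists = None
    if cfg.paired:
        normal_dists, n_acct = process_fastq(
            cfg.normal_r1, cfg.normal_r2, cfg.panel, cfg.preprocess,
            cfg.max_flank_mismatches)
        accounting["normal"] = n_acct
        dists_by_role["normal"] = normal_dists

    result = _call_sample(cfg, tumour_dists, normal_dists)

    base = cfg.out_dir / cfg.sample_id
    _write_distributions(Path(f"{base}_distributions.tsv"), cfg.sample_id,
                         dists_by_role)
    report = _report_frame(result)
    report.to_csv(f"{base}_report.tsv", sep="\t", index=False)
    payload = {
        "sample": cfg.sample_id,
        "mode": "paired" if cfg.paired else "tumour_only",
        "overall": result.overall.value,
        "n_unstable": result.n_unstable,
        "n_informative": result.n_informative,
        "calls": report.to_dict(orient="records"),
        "accounting": {role: a.as_dict()
                       for role, a in accounting.items()},
    }
    Path(f"{base}_report.json").write_text(json.dumps(payload, indent=2))
    log_lines = [f"sample={cfg.sample_id}",
                 f"mode={'paired' if cfg.paired else 'tumour_only'}"]
    for role, a in accounting.items():
        d = a.as_dict()
        assigned_total = sum(d["assigned"].values())
        log_lines.append(
            f"[{role}] pairs_in={d['pairs_in']} merged={d['merged']} "
            f"merge_failed={d['merge_failed']} q_kept={d['q_kept']} "
            f"q_discarded={d['q_discarded']} assigned={assigned_total} "
            f"unassigned={d['unassigned']}")
        for name, n in sorted(d["assigned"].items()):
            log_lines.append(f"[{role}] assigned[{name}]={n}")
    log_lines.append(f"overall={result.overall.value}")
    Path(f"{base}_run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("sample %s -> %s", cfg.sample_id, result.overall.value)
    return result


def run_batch(sheet_path: Path, panel: Panel, out_dir: Path,
              preprocess: PreprocessConfig | None = None,
              classify: ClassifyConfig | None = None,
              max_flank_mismatches: int = 0) -> pd.DataFrame:
    """Run every sample in a sample sheet; per-row failures are recorded
    and the batch continues.

    The sheet is TSV with columns ``sample_id``, ``tumour_r1``,
    ``tumour_r2`` and optional ``normal_r1``/``normal_r2``. Returns (and
    writes as ``cohort.tsv``) one row per sample with each locus's status
    and the overall call, mirroring a per-locus cohort table.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sheet = pd.read_csv(sheet_path, sep="\t", dtype=str)
    if len(sheet) == 0:
        cohort = pd.DataFrame(
            columns=["sample", *panel.locus_names, "overall", "error"])
        cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
        return cohort

    rows = []
    for _, entry in sheet.iterrows():
        sample_id = entry["sample_id"]
        row: dict = {"sample": sample_id}
        try:
            def _get(col: str) -> Path | None:
                v = entry.get(col)
                return Path(v) if isinstance(v, str) and v.strip() else None
            cfg = RunConfig(
                panel=panel,
                tumour_r1=Path(entry["tumour_r1"]),
                tumour_r2=Path(entry["tumour_r2"]),
                normal_r1=_get("normal_r1"), normal_r2=_get("normal_r2"),
                out_dir=out_dir, sample_id=sample_id,
                preprocess=preprocess or PreprocessConfig(),
                classify=classify or ClassifyConfig(),
                max_flank_mismatches=max_flank_mismatches)
            result = run_sample(cfg)
            statuses = {c.locus_name: c.status.value for c in result.calls}
            for name in panel.locus_names:
                row[name] = statuses.get(name, "")
            row["overall"] = result.overall.value
            row["error"] = ""
        except Exception as exc:  # noqa: BLE001 — batch must continue
            logger.error("sample %s failed: %s", sample_id, exc)
            for name in panel.locus_names:
                row[name] = ""
            row["overall"] = ""
            row["error"] = str(exc)
        rows.append(row)
    cohort = pd.DataFrame(rows)
    cohort.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)
    return cohort
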