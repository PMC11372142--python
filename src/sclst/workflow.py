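"""End-to-end orchestration: configuration, the full per-cell pipeline,
output serialization, and the report bundle.

Every run writes TSV/JSON artifacts per stage plus a manifest with a config
hash and a checksum for each output file, so fixed-seed runs are verifiably
byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classifier as clf
from . import genes as genes_mod
from . import genome as genome_mod
from . import lst as lst_mod
from . import pipeline as pipe
from . import simulate as sim

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, sufficient to reproduce a run.

    ``genome_preset`` is "test" (three 100 Mb chromosomes) or
    "hg19_autosomes". ``lst_threshold_mode`` is "fixed" (high at
    ``lst_threshold``) or "cohort_median" (high at or above the cohort
    median LST count).
    """

    genome_preset: str = "test"
    bin_width: int = genome_mod.DEFAULT_BIN_WIDTH
    min_reads: int = pipe.MIN_TOTAL_READS
    min_gii: int = pipe.MIN_GII
    seg_alpha: float = 0.01
    seg_permutations: int = 1000
    seg_merge_delta: float = 0.1
    gain_threshold: float = pipe.GAIN_LOG2
    loss_threshold: float = pipe.LOSS_LOG2
    smooth_min_size_mb: float = lst_mod.SMOOTH_MIN_SIZE_MB
    lst_threshold_mode: str = "fixed"
    lst_threshold: int = lst_mod.LST_HIGH_THRESHOLD
    exclude_chr19_from_lst: bool = False
    n_trees: int = 500
    smote_k: int = 5
    vimp_permutations: int = 5
    n_boot: int = 1000
    n_panel_genes: int = 39
    seed: int = 0
    simulate: sim.SimConfig | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulate is not None:
            d["simulate"]["delta_distribution"] = {
                str(k): v for k, v in
                d["simulate"]["delta_distribution"].items()}
            d["simulate"]["event_length_range"] = list(
                d["simulate"]["event_length_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("simulate"):
            s = dict(d["simulate"])
            if "delta_distribution" in s:
                s["delta_distribution"] = {
                    int(k): v for k, v in s["delta_distribution"].items()}
            if "event_length_range" in s:
                s["event_length_range"] = tuple(s["event_length_range"])
            d["simulate"] = sim.SimConfig(**s)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()

    def build_genome(self) -> genome_mod.GenomeModel:
        if self.genome_preset == "test":
            return genome_mod.toy_genome()
        if self.genome_preset == "hg19_autosomes":
            return genome_mod.hg19_autosomes()
        raise ValueError(f"unknown genome preset {self.genome_preset!r}")


@dataclass
class RunManifest:
    config_hash: str
    checksums: dict[str, str] = field(default_factory=dict)
    counts: dict[str, int] = field(default_factory=dict)
    timestamp: str = ""

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir,
                 counts_list: list[pipe.BinCounts] | None = None,
                 grid: genome_mod.BinGrid | None = None,
                 panel: genome_mod.GenePanel | None = None,
                 gii_table: dict[str, int] | None = None,
                 truth: list[sim.TruthProfile] | None = None) -> RunManifest:
    """Run qc -> normalize -> segment -> call -> aberrancy -> smooth -> lst
    -> gene matrix -> group statistics -> classifier, writing one artifact
    per stage plus a checksummed manifest.

    When ``counts_list`` is None a synthetic cohort is simulated from
    ``config.simulate`` (which must then be set). Stage errors abort with
    the stage name and offending cell id.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config.config_hash())
    genome = config.build_genome()
    if grid is None:
        grid = genome_mod.build_bin_grid(genome, config.bin_width)
        genome_mod.annotate_gc_mappability(grid)
    rng = np.random.default_rng(config.seed)
    if panel is None:
        if config.genome_preset == "hg19_autosomes":
            panel = genome_mod.fixture_panel()
        else:
            panel = genome_mod.synthetic_panel(
                genome, config.n_panel_genes,
                np.random.default_rng(config.seed + 7))

    if counts_list is None:
        if config.simulate is None:
            raise ValueError("no input counts and no simulation config")
        truth, counts_list = sim.simulate_cohort(
            config.simulate, genome, grid, panel)
        sim.counts_to_tsv(counts_list, grid, outdir / "bin_counts.tsv")
        sim.truth_to_seg(truth, outdir / "truth_segments.seg")
        sim.truth_summary(truth).to_csv(outdir / "truth_summary.tsv",
                                        sep="\t", index=False)
    manifest.counts["cells_in"] = len(counts_list)

    # --- QC -----------------------------------------------------------
    qc = pipe.qc_filter(counts_list, gii_table,
                        min_reads=config.min_reads, min_gii=config.min_gii)
    pipe.qc_report(qc).to_csv(outdir / "qc.tsv", sep="\t", index=False)
    passed_ids = {r.cell_id for r in qc if r.passed}
    kept = [bc for bc in counts_list if bc.cell_id in passed_ids]
    manifest.counts["cells_qc_excluded"] = len(counts_list) - len(kept)
    manifest.counts["cells_qc_passed"] = len(kept)
    log.info("QC: %d/%d cells pass (min reads %d)", len(kept),
             len(counts_list), config.min_reads)
    if not kept:
        raise RuntimeError("pipeline: no cells pass QC")

    # --- per-cell profiling -------------------------------------------
    seg_params = pipe.SegmentationParams(
        alpha=config.seg_alpha, n_permutations=config.seg_permutations,
        merge_delta=config.seg_merge_delta)
    all_segments: list[pipe.Segment] = []
    calls_by_cell: dict[str, list[pipe.CNACall]] = {}
    profiles: dict[str, pipe.CNAProfile] = {}
    lst_counts: dict[str, int] = {}
    lst_excluded = ("chr19",) if config.exclude_chr19_from_lst else ()
    for bc in kept:
        try:
            prof = pipe.normalize(bc, grid)
            segments = pipe.segment(
                prof, grid, seg_params,
                seed=int(rng.integers(0, 2**31 - 1)))
            calls = pipe.call_states(
                segments, prof, gain_threshold=config.gain_threshold,
                loss_threshold=config.loss_threshold)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline stage failed for cell {bc.cell_id}: {exc}"
            ) from exc
        all_segments.extend(segments)
        calls_by_cell[bc.cell_id] = calls
        profiles[bc.cell_id] = pipe.cna_profile(bc.cell_id, calls)
        lst_calls = [c for c in calls if c.chrom not in lst_excluded]
        smoothed = lst_mod.smooth_segments(lst_calls, config.smooth_min_size_mb)
        lst_counts[bc.cell_id] = lst_mod.count_lst(smoothed)
    manifest.counts["segments"] = len(all_segments)
    pipe.segments_to_seg(all_segments, outdir / "segments.seg")
    pipe.calls_to_tsv([c for cs in calls_by_cell.values() for c in cs],
                      outdir / "calls.tsv")

    # --- LST classification -------------------------------------------
    if config.lst_threshold_mode == "cohort_median":
        threshold = int(np.ceil(np.median(list(lst_counts.values()))))
    else:
        threshold = config.lst_threshold
    cells = pd.DataFrame({
        "cell_id": list(lst_counts),
        "total_reads": [bc.total_reads for bc in kept],
        "n_gain": [profiles[c].n_gain for c in lst_counts],
        "n_loss": [profiles[c].n_loss for c in lst_counts],
        "n_cna": [profiles[c].n_cna for c in lst_counts],
        "aberrant": [profiles[c].aberrant for c in lst_counts],
        "lst": list(lst_counts.values()),
    })
    cells["lst_class"] = [lst_mod.classify_lst(v, threshold)
                          for v in cells["lst"]]
    cells.to_csv(outdir / "cells.tsv", sep="\t", index=False)

    # --- gene-level matrix and group statistics ------------------------
    matrix = genes_mod.annotate_genes(calls_by_cell, panel)
    matrix.to_csv(outdir / "gene_matrix.tsv", sep="\t",
                  index_label="cell_id")
    classes = cells.set_index("cell_id")["lst_class"]
    stats_out: dict = {"lst_threshold": threshold}
    n_high = int((classes == "high").sum())
    n_low = int((classes == "low").sum())
    if min(n_high, n_low) >= 2:
        try:
            flags = genes_mod.hrd_loss_flags(matrix)
        except ValueError:
            flags = pd.Series(False, index=matrix.index)
        stats_out["comparison"] = genes_mod.compare_groups(
            classes, cells.set_index("cell_id")["n_cna"], flags)
    else:
        stats_out["comparison"] = None
        log.info("group comparison skipped: class sizes %d high / %d low",
                 n_high, n_low)
    with open(outdir / "group_stats.json", "w") as fh:
        json.dump(stats_out, fh, indent=2, sort_keys=True)

    # --- classifier ----------------------------------------------------
    classifier_msg = ""
    if n_high >= 2 and n_low >= 2 and \
            min(n_high, n_low) > config.smote_k:
        table = clf.FeatureTable(X=matrix.astype(int), y=classes)
        report = clf.end_to_end_classifier(
            table,
            smote_params=clf.SMOTEParams(k_neighbors=config.smote_k,
                                         seed=config.seed),
            rf_params=clf.RFParams(n_trees=config.n_trees, seed=config.seed),
            vimp_permutations=config.vimp_permutations,
            n_boot=config.n_boot, seed=config.seed)
        (outdir / "classifier.json").write_text(report.to_json())
        report.roc.to_csv(outdir / "roc.tsv", sep="\t", index=False)
    else:
        classifier_msg = (
            f"classifier skipped: needs both LST classes with more than "
            f"smote_k={config.smote_k} cells each (have {n_high} high, "
            f"{n_low} low)")
        log.warning(classifier_msg)
        (outdir / "classifier.json").write_text(
            json.dumps({"skipped": classifier_msg}))

    # --- report bundle and manifest ------------------------------------
    report_bundle(outdir, panel=panel)
    config.to_yaml(outdir / "config.yaml")
    for f in sorted(outdir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.checksums[f.name] = _sha256(f)
    manifest.counts["cells_out"] = len(cells)
    manifest.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def report_bundle(outdir, panel: genome_mod.GenePanel | None = None) -> dict:
    """Build the report tables from a run directory's artifacts: LST
    histogram and cohort summary, top-altered genes, VIMP ranking, ROC
    points. Missing upstream artifacts are named explicitly; a skipped
    classifier is noted and its tables omitted."""
    outdir = Path(outdir)
    cells_path = outdir / "cells.tsv"
    if not cells_path.exists():
        raise FileNotFoundError(
            f"report needs per-cell results at {cells_path}")
    cells = pd.read_csv(cells_path, sep="\t")
    summary = lst_mod.lst_distribution_summary(cells["lst"].tolist())
    summary["histogram"].to_csv(outdir / "lst_histogram.tsv", sep="\t",
                                index=False)
    with open(outdir / "cohort_summary.json", "w") as fh:
        json.dump({k: v for k, v in summary.items() if k != "histogram"},
                  fh, indent=2, sort_keys=True)
    matrix_path = outdir / "gene_matrix.tsv"
    if matrix_path.exists():
        matrix = pd.read_csv(matrix_path, sep="\t", index_col="cell_id")
        genes_mod.top_altered_genes(matrix, panel).to_csv(
            outdir / "top_genes.tsv", sep="\t", index=False)
    clf_path = outdir / "classifier.json"
    out = {"summary": {k: v for k, v in summary.items() if k != "histogram"}}
    if clf_path.exists():
        data = json.loads(clf_path.read_text())
        if "skipped" in data:
            log.info("report: classifier output absent (%s); VIMP/ROC "
                     "tables omitted", data["skipped"])
        else:
            vimp_df = pd.DataFrame(
                {"gene": list(data["vimp"]), "vimp": list(data["vimp"].values())})
            vimp_df.to_csv(outdir / "vimp.tsv", sep="\t", index=False)
            out["auc"] = data["auc"]
    return out
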