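"""End-to-end pipeline orchestration.

``run_germline`` wires the stages in order: align -> mark duplicates ->
base quality recalibration -> indel realignment -> snapshot -> 16-genotype
calling -> filtration.  Individual stages can be skipped; a stage failure
aborts with the stage name and removes partial outputs.  ``run_from_snapshot``
re-runs calling and filtration from a stored snapshot and, with identical
parameters, reproduces the original VCF byte for byte.
"""

from __future__ import annotations

import json
import os
from collections import defaultdict
from dataclasses import dataclass, field, fields

import numpy as np

from . import germline, preprocess, realign as realign_mod, somatic as somatic_mod
from .align import AlignedRead, AlignerParams, align_pairs, build_index
from .formats import (Reference, Region, read_bed, read_fasta, read_sam,
                      stream_fastq_pairs, write_sam, write_somatic_vcf,
                      write_vcf)
from .germline import PriorModel, RFModel, call_snapshot, rf_filter
from .realign import RealignParams
from .snapshot import Snapshot, build_snapshot, load_snapshot, write_snapshot

__all__ = ["PipelineConfig", "StageError", "run_germline", "run_from_snapshot",
           "run_somatic"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    reference: str = ""
    fastq1: str | None = None
    fastq2: str | None = None
    sam: str | None = None
    out_prefix: str = "out"
    bed: str | None = None
    k: int = 16
    max_occ: int = 64
    insert_mean: float = 500.0
    insert_sd: float = 25.0
    dedup: bool = True
    bqsr: bool = True
    realign: bool = True
    min_support: int = 2
    clip_support: int = 4
    theta_snp: float = 1e-3
    theta_indel: float = 1e-4
    rf_model: str | None = None
    prob_threshold: float = 0.95
    qual_threshold: float = 30.0
    threads: int = 1
    seed: int = 0
    log_level: str = "INFO"
    sam_out: bool = False

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def aligner_params(self) -> AlignerParams:
        return AlignerParams(k=self.k, max_occ=self.max_occ,
                             insert_mean=self.insert_mean,
                             insert_sd=self.insert_sd)

    def priors(self) -> PriorModel:
        return PriorModel(theta_snp=self.theta_snp,
                          theta_indel=self.theta_indel)


def _group_by_contig(alignments: list[AlignedRead]) -> dict[str, list[AlignedRead]]:
    out: dict[str, list[AlignedRead]] = defaultdict(list)
    for a in alignments:
        out[a.contig].append(a)
    return dict(out)


def run_germline(config: PipelineConfig) -> dict:
    """Full germline pipeline; returns the run report (also written to JSON)."""
    report: dict = {"stages": {}}
    outputs = [config.out_prefix + ".vcf", config.out_prefix + ".snapshot",
               config.out_prefix + ".report.json"]
    try:
        return _run_germline(config, report)
    except Exception:
        for path in outputs:
            if os.path.exists(path):
                os.remove(path)
        raise


def _run_germline(config: PipelineConfig, report: dict) -> dict:
    stage = "load-reference"
    try:
        reference = read_fasta(config.reference)
        regions = read_bed(config.bed, reference) if config.bed else None
        stage = "align"
        if config.sam:
            alignments = list(read_sam(config.sam, reference))
            for i, a in enumerate(alignments):
                a.pair_id = i // 2 if a.mate is not None else i
            report["stages"]["align"] = {"source": "sam",
                                         "reads": len(alignments)}
        else:
            index = build_index(reference, config.k, config.max_occ)
            pairs = stream_fastq_pairs(config.fastq1, config.fastq2)
            alignments = align_pairs(pairs, index, config.aligner_params())
            n_pairs = max((a.pair_id for a in alignments), default=-1) + 1
            report["stages"]["align"] = {
                "source": "fastq", "pairs": n_pairs,
                "reads_aligned": len(alignments),
                "properly_paired": sum(1 for a in alignments
                                       if a.properly_paired and a.mate == 0)}
        by_contig = _group_by_contig(alignments)
        stage = "mark-duplicates"
        if config.dedup:
            _, stats = preprocess.mark_duplicates(alignments)
            report["stages"]["dedup"] = {"input_pairs": stats.input_pairs,
                                         "kept": stats.kept_pairs,
                                         "flagged": stats.flagged_pairs}
        else:
            report["stages"]["dedup"] = {"skipped": True}
        stage = "bqsr"
        if config.bqsr:
            mask = preprocess.candidate_mask(by_contig, reference)
            table = preprocess.build_recal_table(by_contig, reference, mask)
            preprocess.apply_recalibration(by_contig, table)
            report["stages"]["bqsr"] = {
                "observations": int(table.observations.sum()),
                "mismatches": int(table.mismatches.sum())}
        else:
            report["stages"]["bqsr"] = {"skipped": True}
        stage = "realign"
        if config.realign:
            reports = realign_mod.realign(
                by_contig, reference,
                RealignParams(min_support=config.min_support,
                              clip_support=config.clip_support))
            report["stages"]["realign"] = {
                "windows": len(reports),
                "rewritten": sum(r["rewritten"] for r in reports)}
        else:
            report["stages"]["realign"] = {"skipped": True}
        stage = "snapshot"
        snap = build_snapshot(by_contig, reference, regions)
        write_snapshot(snap, config.out_prefix + ".snapshot")
        report["stages"]["snapshot"] = {
            "regions": len(snap.regions),
            "positions": sum(r.end - r.start for r in snap.regions)}
        if config.sam_out:
            write_sam(alignments, reference, config.out_prefix + ".sam")
        stage = "call"
        calls = call_snapshot(snap, reference, config.priors())
        stage = "filter"
        model = RFModel.load(config.rf_model) if config.rf_model else None
        calls = rf_filter(calls, model, config.prob_threshold,
                          config.qual_threshold)
        write_vcf(calls, reference, config.out_prefix + ".vcf")
        report["stages"]["call"] = {
            "calls": len(calls),
            "snps": sum(1 for c in calls if all(k == "SNP" for k in c.classes)),
            "indels": sum(1 for c in calls if any(k != "SNP" for k in c.classes)),
            "pass": sum(1 for c in calls if c.filter_status == "PASS")}
        report["outputs"] = {"vcf": config.out_prefix + ".vcf",
                             "snapshot": config.out_prefix + ".snapshot"}
        with open(config.out_prefix + ".report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report
    except StageError:
        raise
    except Exception as e:
        raise StageError(stage, e) from e


def run_from_snapshot(snapshot_path, config: PipelineConfig) -> str:
    """Calling + filtration only, from a stored snapshot.

    With parameters identical to the original run the VCF is byte-identical
    to the one the full pipeline wrote.
    """
    reference = read_fasta(config.reference)
    snap = load_snapshot(snapshot_path)
    snap.verify_reference(reference)
    calls = call_snapshot(snap, reference, config.priors())
    model = RFModel.load(config.rf_model) if config.rf_model else None
    calls = rf_filter(calls, model, config.prob_threshold, config.qual_threshold)
    out = config.out_prefix + ".vcf"
    write_vcf(calls, reference, out)
    return out


def run_somatic(normal_path, tumor_path, config: PipelineConfig,
                params: somatic_mod.SomaticParams | None = None,
                do_cnv: bool = True, cnv_window: int = 1000) -> dict:
    """Somatic SNV/indel + CNV calling from two snapshots."""
    reference = read_fasta(config.reference)
    normal = load_snapshot(normal_path)
    tumor = load_snapshot(tumor_path)
    calls = somatic_mod.call_somatic(normal, tumor, reference, params,
                                     config.priors())
    vcf = config.out_prefix + ".somatic.vcf"
    write_somatic_vcf(calls, reference, vcf)
    report = {
        "somatic_calls": len(calls),
        "by_class": {k: sum(1 for c in calls if c.vclass == k)
                     for k in ("SNV", "INS", "DEL")},
        "outputs": {"vcf": vcf},
    }
    if do_cnv:
        segments = somatic_mod.call_cnv(normal, tumor, reference,
                                        window=cnv_window)
        bed = config.out_prefix + ".cnv.bed"
        tsv = config.out_prefix + ".cnv.tsv"
        somatic_mod.cnv_bed(segments, bed)
        somatic_mod.cnv_tsv(segments, tsv)
        report["cnv_segments"] = len(segments)
        report["cnv_by_state"] = {s: sum(1 for x in segments if x.state == s)
                                  for s in ("GAIN", "LOSS", "NEUTRAL")}
        report["outputs"]["cnv_bed"] = bed
        report["outputs"]["cnv_tsv"] = tsv
    with open(config.out_prefix + ".somatic.report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
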