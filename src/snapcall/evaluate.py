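"""Truth-versus-called comparison.

Both sides are decomposed into (contig, pos, ref, alt) alleles and
left-normalized against the same reference before matching.  A SNP matches
on site + alt allele; an indel matches on the full normalized
(anchor, ref, alt) — exact after normalization.  Truth is restricted to
variants covered by at least one simulated read (the origin table supplies
per-position coverage), since an uncovered variant is unknowable to any
caller.  Genotype concordance is reported separately from site sensitivity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .formats import Reference
from .simulate import OriginTable, TruthSet
from .variants import VariantCall, left_normalize, variant_class

__all__ = ["ClassCounts", "ComparisonReport", "match_calls", "load_vcf_calls"]

DP_BINS = (0, 10, 20, 30, 10 ** 9)
AAF_BINS = (0.0, 0.1, 0.3, 0.5, 1.01)


@dataclass
class ClassCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    genotype_concordant: int = 0
    genotype_discordant: int = 0

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else float("nan")

    @property
    def fdr(self) -> float:
        d = self.tp + self.fp
        return self.fp / d if d else float("nan")

    @property
    def genotype_concordance(self) -> float:
        d = self.genotype_concordant + self.genotype_discordant
        return self.genotype_concordant / d if d else float("nan")


@dataclass
class ComparisonReport:
    snp: ClassCounts
    indel: ClassCounts
    by_depth: dict[str, dict[str, ClassCounts]] = field(default_factory=dict)
    by_aaf: dict[str, dict[str, ClassCounts]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        def f(x: float):
            return None if np.isnan(x) else x

        def cc(c: ClassCounts) -> dict:
            return {"tp": c.tp, "fp": c.fp, "fn": c.fn,
                    "sensitivity": f(c.sensitivity), "fdr": f(c.fdr),
                    "genotype_concordance": f(c.genotype_concordance)}
        return {
            "snp": cc(self.snp),
            "indel": cc(self.indel),
            "by_depth": {k: {c: cc(v) for c, v in d.items()}
                         for k, d in self.by_depth.items()},
            "by_aaf": {k: {c: cc(v) for c, v in d.items()}
                       for k, d in self.by_aaf.items()},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def table(self) -> str:
        lines = ["class\tTP\tFP\tFN\tsensitivity\tFDR\tGT_concordance"]
        for name, c in (("SNP", self.snp), ("indel", self.indel)):
            lines.append(f"{name}\t{c.tp}\t{c.fp}\t{c.fn}\t"
                         f"{c.sensitivity:.4f}\t{c.fdr:.4f}\t"
                         f"{c.genotype_concordance:.4f}")
        return "\n".join(lines)


def _bin_label(value: float, bins) -> str:
    for lo, hi in zip(bins, bins[1:]):
        if lo <= value < hi:
            return f"[{lo},{hi})"
    return f"[{bins[-2]},inf)"


def match_calls(truth: TruthSet, calls: list[VariantCall],
                reference: Reference, origin: OriginTable | None = None,
                statuses: tuple[str, ...] | None = None) -> ComparisonReport:
    """Compare calls to planted truth; returns per-class counts.

    ``statuses`` restricts which filter states count as called (default: all).
    Calls are decomposed into alleles and normalized; permuting the call list
    never changes the report.
    """
    seqs = {c: reference.seq(c) for c in reference.contigs}
    coverage = {}
    if origin is not None:
        for c in reference.contigs:
            if c in origin.contigs:
                coverage[c] = origin.coverage(c, reference.length(c))
    truth_keys: dict[tuple, object] = {}
    for v in truth.variants:
        if origin is not None:
            cov = coverage.get(v.contig)
            if cov is None or cov[min(v.pos, len(cov) - 1)] < 1:
                continue
        pos, ref_a, alt_a = left_normalize(seqs[v.contig], v.pos, v.ref, v.alt)
        truth_keys[(v.contig, pos, ref_a, alt_a)] = v
    report = ComparisonReport(ClassCounts(), ClassCounts())
    seen: set[tuple] = set()
    for call in sorted(calls, key=lambda c: (c.contig, c.pos)):
        if statuses is not None and call.filter_status not in statuses:
            continue
        for pos, ref_a, alt_a in call.alleles():
            npos, nref, nalt = left_normalize(seqs[call.contig], pos, ref_a, alt_a)
            key = (call.contig, npos, nref, nalt)
            cls = variant_class(nref, nalt)
            cc = report.snp if cls == "SNP" else report.indel
            dp_label = _bin_label(call.depth, DP_BINS)
            aaf_label = _bin_label(max(call.alt_fractions), AAF_BINS)
            strat_dp = report.by_depth.setdefault(dp_label, {}).setdefault(
                "SNP" if cls == "SNP" else "indel", ClassCounts())
            strat_af = report.by_aaf.setdefault(aaf_label, {}).setdefault(
                "SNP" if cls == "SNP" else "indel", ClassCounts())
            if key in truth_keys and key not in seen:
                seen.add(key)
                cc.tp += 1
                strat_dp.tp += 1
                strat_af.tp += 1
                v = truth_keys[key]
                call_hom = call.is_hom and len(set(call.genotype_indices)) == 1
                if (v.zygosity == "hom") == call_hom:
                    cc.genotype_concordant += 1
                else:
                    cc.genotype_discordant += 1
            else:
                cc.fp += 1
                strat_dp.fp += 1
                strat_af.fp += 1
    for key, v in truth_keys.items():
        if key not in seen:
            cls = "SNP" if v.vclass == "SNP" else "indel"
            cc = report.snp if cls == "SNP" else report.indel
            cc.fn += 1
            if coverage:
                dp = int(coverage[v.contig][min(v.pos,
                                                len(coverage[v.contig]) - 1)])
                report.by_depth.setdefault(_bin_label(dp, DP_BINS), {}) \
                    .setdefault(cls, ClassCounts()).fn += 1
    return report


def load_vcf_calls(path) -> list[VariantCall]:
    """Read a snapcall VCF back into VariantCall records (for `evaluate`)."""
    import pysam

    def info(rec, key, default):
        # pysam raises instead of defaulting when the key is not declared
        # in the header (e.g. a plain truth VCF with no INFO fields)
        try:
            return rec.info[key]
        except (KeyError, ValueError):
            return default

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            sample = rec.samples[0] if rec.samples else None
            gt = sample["GT"] if sample and "GT" in sample else (0, 1)
            filt = list(rec.filter) or ["UNFILTERED"]
            calls.append(VariantCall(
                contig=rec.contig, pos=rec.pos - 1, ref=rec.ref,
                alts=list(rec.alts or []),
                genotype_indices=tuple(g if g is not None else 0 for g in gt),
                qual=rec.qual or 0.0,
                depth=int(info(rec, "DP", 0)),
                alt_fractions=list(info(rec, "AF", [0.0])),
                strand_bias=float(info(rec, "SBP", 0.0)),
                mean_mq=float(info(rec, "MQ", 60.0)),
                filter_status=filt[0]))
    return calls
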