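"""Duplicate marking and base quality score recalibration (BQSR).

Duplicate marking is a single hash pass over read pairs keyed by the
unclipped 5' coordinates and strands of both mates — no coordinate sort is
needed.  Among pairs sharing a key the pair with the highest summed base
quality survives; ties keep the first seen.

BQSR stratifies aligned bases by (reported quality, machine cycle,
preceding+current dinucleotide in sequencing orientation), counts mismatches
against the reference outside masked candidate-variant sites, and replaces
each reported quality with the cell's empirical quality
phred((mismatches+1)/(observations+2)), capped at Q60.  Sites whose pileup
shows a non-reference allele fraction >= 0.2 are masked in a first pass, so
true variants do not deflate the empirical qualities — this replaces a
known-sites file and keeps the tool self-contained.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .align import AlignedRead
from .formats import Reference
from .readops import ReadBatch

__all__ = ["DedupStats", "RecalTable", "mark_duplicates",
           "candidate_mask", "build_recal_table", "apply_recalibration"]

MIN_QUAL = 2         # bases below this reported quality carry no signal
MAX_QUAL = 60
N_DINUC = 17         # 16 dinucleotides + sentinel for cycle 0 / N context
MASK_ALT_FRACTION = 0.2


@dataclass
class DedupStats:
    input_pairs: int = 0
    kept_pairs: int = 0
    flagged_pairs: int = 0


def _pair_key(mates: list[AlignedRead]):
    ends = []
    for a in mates:
        ends.append((a.contig, a.five_prime(), a.strand))
    if len(ends) == 1:
        return ("single",) + ends[0]
    ends.sort()
    return ("pair",) + ends[0] + ends[1]


def mark_duplicates(alignments: list[AlignedRead]) -> tuple[list[AlignedRead], DedupStats]:
    """Flag duplicate pairs in place; returns (alignments, stats).

    Pairs are keyed by canonical (contig, unclipped 5', strand) of both
    mates; the kept-set size is invariant under permutation of the input
    (only which member of an exact-quality tie survives follows input order).
    """
    by_pair: dict[int, list[AlignedRead]] = defaultdict(list)
    for a in alignments:
        by_pair[a.pair_id].append(a)
    best: dict[tuple, tuple[int, int]] = {}  # key -> (qual_sum, pair_id)
    members: dict[tuple, list[int]] = defaultdict(list)
    for pid, mates in by_pair.items():
        key = _pair_key(mates)
        qsum = sum(m.qual_sum() for m in mates)
        members[key].append(pid)
        cur = best.get(key)
        if cur is None or qsum > cur[0]:
            best[key] = (qsum, pid)
    stats = DedupStats(input_pairs=len(by_pair))
    keep = {pid for _, pid in best.values()}
    for pid, mates in by_pair.items():
        dup = pid not in keep
        for m in mates:
            m.is_duplicate = dup
    stats.kept_pairs = len(keep)
    stats.flagged_pairs = stats.input_pairs - stats.kept_pairs
    return alignments, stats


def candidate_mask(alignments_by_contig: dict[str, list[AlignedRead]],
                   reference: Reference,
                   min_fraction: float = MASK_ALT_FRACTION) -> dict[str, np.ndarray]:
    """First-pass scan: boolean mask of positions whose non-reference allele
    fraction is >= ``min_fraction`` (candidate variants, excluded from BQSR)."""
    masks = {}
    for contig, reads in alignments_by_contig.items():
        L = reference.length(contig)
        batch = ReadBatch(reads)
        depth = np.bincount(batch.pos, minlength=L)
        refb = reference.sequences[contig][batch.pos] if len(batch.pos) else batch.pos
        nonref = (batch.base != refb) & (batch.base != 4)
        alt = np.bincount(batch.pos[nonref], minlength=L)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac = np.where(depth > 0, alt / np.maximum(depth, 1), 0.0)
        masks[contig] = frac >= min_fraction
    return masks


class RecalTable:
    """Empirical quality per (reported quality, cycle, dinucleotide) cell."""

    def __init__(self, max_cycle: int):
        self.max_cycle = max_cycle
        shape = (MAX_QUAL + 1, max_cycle, N_DINUC)
        self.observations = np.zeros(shape, dtype=np.int64)
        self.mismatches = np.zeros(shape, dtype=np.int64)

    def empirical(self) -> np.ndarray:
        q = -10 * np.log10((self.mismatches + 1) / (self.observations + 2))
        return np.minimum(np.round(q), MAX_QUAL).astype(np.uint8)

    def marginal(self) -> np.ndarray:
        """Reported-quality-only fallback for unseen (cycle, dinuc) cells."""
        obs = self.observations.sum(axis=(1, 2))
        mis = self.mismatches.sum(axis=(1, 2))
        q = -10 * np.log10((mis + 1) / (obs + 2))
        emp = np.minimum(np.round(q), MAX_QUAL).astype(np.uint8)
        # where a reported quality was never observed, keep it unchanged
        return np.where(obs > 0, emp, np.arange(MAX_QUAL + 1, dtype=np.uint8))

    def check(self) -> None:
        assert (self.mismatches <= self.observations).all()

    def dump_tsv(self, path) -> None:
        emp = self.empirical()
        with open(path, "w") as fh:
            fh.write("reported_qual\tcycle\tdinuc\tobservations\tmismatches\tempirical_qual\n")
            q, c, d = np.nonzero(self.observations)
            for qi, ci, di in zip(q, c, d):
                fh.write(f"{qi}\t{ci}\t{di}\t{self.observations[qi, ci, di]}\t"
                         f"{self.mismatches[qi, ci, di]}\t{emp[qi, ci, di]}\n")

    @classmethod
    def load_tsv(cls, path, max_cycle: int) -> "RecalTable":
        t = cls(max_cycle)
        with open(path) as fh:
            next(fh)
            for line in fh:
                qi, ci, di, obs, mis, _ = line.split("\t")
                t.observations[int(qi), int(ci), int(di)] = int(obs)
                t.mismatches[int(qi), int(ci), int(di)] = int(mis)
        return t


def _covariates(batch: ReadBatch):
    """(qual, cycle, dinuc) per aligned base, sequencing orientation."""
    cyc = batch.cycle()
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    minus = batch.strand == 1
    cur = np.where(minus, comp[batch.base], batch.base)
    # previous base in sequencing orientation is the next stored base on -
    prev_idx = np.where(minus, batch.flat_idx + 1, batch.flat_idx - 1)
    # cycle 0 has no previous base; guard the gather then overwrite
    prev_idx = np.clip(prev_idx, 0, len(batch.bases_flat) - 1)
    prev_raw = batch.bases_flat[prev_idx]
    prev = np.where(minus, comp[prev_raw], prev_raw)
    dinuc = prev.astype(np.int64) * 4 + cur
    dinuc[(cyc == 0) | (prev > 3) | (cur > 3)] = 16
    return batch.qual.astype(np.int64), cyc, dinuc


def build_recal_table(alignments_by_contig: dict[str, list[AlignedRead]],
                      reference: Reference,
                      mask: dict[str, np.ndarray] | None = None) -> RecalTable:
    """Count (observation, mismatch) per covariate cell over all contigs."""
    max_cycle = 0
    any_base = False
    for reads in alignments_by_contig.values():
        for a in reads:
            max_cycle = max(max_cycle, len(a.bases))
            any_base = True
    if not any_base:
        raise ValueError("no aligned bases: cannot build a recalibration table")
    table = RecalTable(max_cycle)
    for contig, reads in alignments_by_contig.items():
        batch = ReadBatch(reads)
        if len(batch.pos) == 0:
            continue
        refb = reference.sequences[contig][batch.pos]
        use = (batch.base != 4) & (refb != 4) & (batch.qual >= MIN_QUAL)
        if mask is not None:
            use &= ~mask[contig][batch.pos]
        q, cyc, dinuc = _covariates(batch)
        cell = (q * table.max_cycle + cyc) * N_DINUC + dinuc
        cell = cell[use]
        mism = (batch.base != refb)[use]
        size = table.observations.size
        table.observations += np.bincount(cell, minlength=size).reshape(
            table.observations.shape)
        table.mismatches += np.bincount(cell[mism], minlength=size).reshape(
            table.observations.shape)
    table.check()
    return table


def apply_recalibration(alignments_by_contig: dict[str, list[AlignedRead]],
                        table: RecalTable) -> None:
    """Replace every aligned base's quality with its cell's empirical quality.

    Unseen (cycle, dinuc) cells fall back to the reported-quality marginal.
    Soft-clipped and inserted bases keep their reported quality.  The map is
    deterministic: re-applying the same table to already-recalibrated reads
    maps through the (new) reported qualities, so outputs are stable only
    for a freshly built table — by design the table is built once per run.
    """
    emp = table.empirical()
    marg = table.marginal()
    seen = table.observations > 0
    for reads in alignments_by_contig.values():
        batch = ReadBatch(reads, include_duplicates=True)
        if len(batch.pos) == 0:
            continue
        q, cyc, dinuc = _covariates(batch)
        q = np.minimum(q, MAX_QUAL)
        cyc = np.minimum(cyc, table.max_cycle - 1)
        newq = np.where(seen[q, cyc, dinuc], emp[q, cyc, dinuc], marg[q])
        newq = np.where(batch.qual >= MIN_QUAL, newq, batch.qual).astype(np.uint8)
        flat = batch.quals_flat.copy()
        flat[batch.flat_idx] = newq
        offs = batch.read_offsets
        for ri, a in enumerate(reads):
            a.quals = flat[offs[ri] : offs[ri + 1]]
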