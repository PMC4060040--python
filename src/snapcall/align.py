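"""Seed-and-extend paired-end alignment.

A hash table of reference k-mers supplies candidate loci; candidates are
scored with the affine-gap kernels in :mod:`snapcall.dp` (match +1,
mismatch -4, gap open -6, gap extend -1).  Reads whose non-overlapping
seeds agree on a single diagonal and differ from the reference by at most
two interior substitutions skip the DP entirely — the gapless alignment is
provably optimal there, and on typical short-read data that is the vast
majority of reads.

Mates are paired by maximising score1 + score2 + pair_bonus, where the
bonus applies when the mates land on opposite strands with an insert within
mean +/- 4 sd.  A mate with no seed hits is rescued by DP inside the window
its partner and the insert model imply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dp
from .formats import Reference, revcomp_codes

__all__ = ["AlignedRead", "SeedIndex", "AlignerParams", "build_index",
           "align_read", "pair_and_rescue", "align_pairs"]

READ_OPS = {"M", "X", "I", "S"}
REF_OPS = {"M", "X", "D"}


@dataclass
class AlignedRead:
    """One read's placement on the reference.

    ``bases``/``quals`` are stored in *reference orientation* (a minus-strand
    read is stored reverse-complemented), so ``ops`` always read left to
    right along the reference.
    """

    name: str
    contig: str
    start: int
    strand: str
    ops: list[tuple[str, int]]
    bases: np.ndarray
    quals: np.ndarray
    mapq: int = 0
    mate: int | None = None
    properly_paired: bool = False
    is_duplicate: bool = False
    score: int = 0
    pair_id: int = -1

    @property
    def end(self) -> int:
        return self.start + sum(l for op, l in self.ops if op in REF_OPS)

    @property
    def read_length(self) -> int:
        return len(self.bases)

    def consumed_read(self) -> int:
        return sum(l for op, l in self.ops if op in READ_OPS)

    def unclipped_start(self) -> int:
        lead = self.ops[0][1] if self.ops and self.ops[0][0] == "S" else 0
        return self.start - lead

    def unclipped_end(self) -> int:
        tail = self.ops[-1][1] if self.ops and self.ops[-1][0] == "S" else 0
        return self.end + tail

    def five_prime(self) -> int:
        """Unclipped 5' coordinate in sequencing orientation."""
        return self.unclipped_start() if self.strand == "+" else self.unclipped_end()

    def cigar(self) -> str:
        out = []
        run = 0
        for op, l in self.ops:
            if op in ("M", "X"):
                run += l
                continue
            if run:
                out.append(f"{run}M")
                run = 0
            out.append(f"{l}{'I' if op == 'I' else op}")
        if run:
            out.append(f"{run}M")
        return "".join(out)

    def has_indel(self) -> bool:
        return any(op in ("I", "D") for op, _ in self.ops)

    def qual_sum(self) -> int:
        return int(self.quals.sum())


@dataclass
class AlignerParams:
    k: int = 16
    max_occ: int = 64
    band: int = 16
    pair_bonus: int = 15
    insert_mean: float = 500.0
    insert_sd: float = 25.0
    max_candidates: int = 8
    min_rescue_score: int = 40

    def band_for(self, read_len: int) -> int:
        return max(self.band, int(0.1 * read_len))


class SeedIndex:
    """k-mer hash over the forward strand of every contig.

    Both read orientations are queried against it, which is equivalent to a
    canonical-k-mer index.  k-mers occurring more than ``max_occ`` times are
    recorded as repetitive and yield no hits at query time.
    """

    def __init__(self, reference: Reference, k: int, max_occ: int = 64):
        if not (4 <= k <= 32):
            raise ValueError(f"k={k} out of supported range [4, 32]")
        self.k = k
        self.max_occ = max_occ
        self.reference = reference
        names = reference.contigs
        self.contig_names = names
        # concatenate contigs with k N's between so no k-mer spans a boundary
        offs = []
        pieces = []
        cur = 0
        pad = np.full(k, 4, dtype=np.uint8)
        for name in names:
            offs.append(cur)
            s = reference.sequences[name]
            pieces.append(s)
            pieces.append(pad)
            cur += len(s) + k
        self.offsets = np.array(offs, dtype=np.int64)
        self.cat = np.concatenate(pieces) if pieces else np.zeros(0, dtype=np.uint8)
        self.positions: dict[int, np.ndarray] = {}
        self.repetitive: dict[int, int] = {}
        self._build()

    def _build(self) -> None:
        k = self.k
        if len(self.cat) < k:
            return
        win = np.lib.stride_tricks.sliding_window_view(self.cat, k)
        valid = (win != 4).all(axis=1)
        pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        codes = win.astype(np.int64) @ pows
        idx = np.flatnonzero(valid)
        codes = codes[idx]
        self._pows = pows
        if len(codes) == 0:
            return
        order = np.argsort(codes, kind="stable")
        codes_sorted = codes[order]
        pos_sorted = idx[order].astype(np.int64)
        bounds = np.flatnonzero(np.diff(codes_sorted)) + 1
        starts = np.concatenate(([0], bounds))
        ends = np.concatenate((bounds, [len(codes_sorted)]))
        for s, e in zip(starts, ends):
            code = int(codes_sorted[s])
            if e - s > self.max_occ:
                self.repetitive[code] = int(e - s)
            else:
                self.positions[code] = pos_sorted[s:e]
        self._pows = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)

    def to_global(self, contig: str, pos: int) -> int:
        return int(self.offsets[self.contig_names.index(contig)]) + pos

    def to_contig(self, gpos: int) -> tuple[str, int]:
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return self.contig_names[i], int(gpos - self.offsets[i])

    def lookup(self, code: int) -> np.ndarray | None:
        return self.positions.get(code)

    def read_codes(self, bases: np.ndarray, offsets) -> list[tuple[int, int]]:
        """(offset, code) pairs for the read k-mers at the given offsets."""
        k = self.k
        out = []
        for o in offsets:
            seg = bases[o : o + k]
            if (seg == 4).any():
                continue
            out.append((o, int(seg.astype(np.int64) @ self._pows)))
        return out


def build_index(reference: Reference, k: int = 16, max_occ: int = 64) -> SeedIndex:
    return SeedIndex(reference, k, max_occ)


def _seed_offsets(read_len: int, k: int) -> list[int]:
    offs = list(range(0, read_len - k + 1, k))
    if offs and offs[-1] != read_len - k:
        offs.append(read_len - k)
    return offs


def _candidate_starts(index: SeedIndex, bases: np.ndarray, band: int) -> list[tuple[int, int]]:
    """Cluster seed hits into (implied_global_start, n_supporting_seeds)."""
    offs = _seed_offsets(len(bases), index.k)
    implied = []
    for o, code in index.read_codes(bases, offs):
        hits = index.lookup(code)
        if hits is None:
            continue
        implied.append(hits - o)
    if not implied:
        return []
    starts = np.sort(np.concatenate(implied))
    clusters = []
    cs = starts[0]
    members = [int(cs)]
    for s in starts[1:]:
        if s - members[-1] <= band:
            members.append(int(s))
        else:
            clusters.append(members)
            members = [int(s)]
    clusters.append(members)
    out = []
    for mem in clusters:
        vals, counts = np.unique(mem, return_counts=True)
        mode = int(vals[np.argmax(counts)])  # leftmost mode on ties
        out.append((mode, len(mem)))
    return out


def _align_at(index: SeedIndex, bases, quals, strand, gstart, n_seeds,
              params: AlignerParams, name, mate) -> AlignedRead | None:
    """Score one candidate locus: gapless fast path, else DP in a window."""
    contig, start = index.to_contig(gstart)
    ref = index.reference.sequences[contig]
    L = len(bases)
    band = params.band_for(L)
    fast = None
    if 0 <= start and start + L <= len(ref):
        score, ops, nmis = dp.hamming_ops(bases, ref[start : start + L])
        if nmis <= 2:
            idx = [i for i, (op, _) in enumerate(ops) if op == "X"]
            # interior mismatches only: clipping could not beat this alignment
            pos = []
            acc = 0
            for op, l in ops:
                if op == "X":
                    pos.append(acc)
                acc += l
            if all(4 <= p < L - 4 for p in pos):
                fast = (score, start, ops)
    if fast is None:
        ws = max(0, start - band)
        we = min(len(ref), start + L + band)
        if we - ws < index.k:
            return None
        score, w0, w1, opc, opl = dp.sw_align(bases, ref[ws:we])
        if score <= 0:
            return None
        ops = dp.ops_from_arrays(opc, opl)
        start = ws + int(w0)
    else:
        score, start, ops = fast
    return AlignedRead(name=name, contig=contig, start=start, strand=strand,
                       ops=ops, bases=bases, quals=quals, mate=mate, score=score)


def align_read(bases: np.ndarray, quals: np.ndarray, index: SeedIndex,
               params: AlignerParams, name: str = "", mate: int | None = None
               ) -> list[AlignedRead]:
    """All candidate placements of one read, best score first.

    Ties break on (contig order, position, strand with + before -).
    """
    if len(bases) < index.k:
        return []
    band = params.band_for(len(bases))
    cands: list[AlignedRead] = []
    for strand, b, q in (("+", bases, quals),
                         ("-", revcomp_codes(bases), quals[::-1])):
        for gstart, nseeds in _candidate_starts(index, b, band):
            a = _align_at(index, b, q, strand, gstart, nseeds, params, name, mate)
            if a is not None:
                cands.append(a)
    order = {c: i for i, c in enumerate(index.contig_names)}
    cands.sort(key=lambda a: (-a.score, order[a.contig], a.start, a.strand != "+"))
    # drop duplicate placements (same locus reached from different clusters)
    seen = set()
    uniq = []
    for a in cands:
        key = (a.contig, a.start, a.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    return uniq[: params.max_candidates]


def _mapq(chosen_score: int, scores: list[int]) -> int:
    others = [s for s in scores]
    others.remove(chosen_score)
    if not others:
        return 60
    diff = chosen_score - max(others)
    if diff < 0:
        diff = 0
    if diff == 0:
        return 0
    return min(60, 60 if diff >= 10 else 6 * diff)


def _insert(a1: AlignedRead, a2: AlignedRead) -> int:
    return max(a1.end, a2.end) - min(a1.start, a2.start)


def _proper(a1: AlignedRead, a2: AlignedRead, params: AlignerParams) -> bool:
    if a1.contig != a2.contig or a1.strand == a2.strand:
        return False
    return abs(_insert(a1, a2) - params.insert_mean) <= 4 * params.insert_sd


def _rescue(placed: AlignedRead, bases: np.ndarray, quals: np.ndarray,
            reference: Reference, params: AlignerParams, name: str, mate: int
            ) -> AlignedRead | None:
    """DP the unplaced mate inside the window implied by its partner."""
    ref = reference.sequences[placed.contig]
    L = len(bases)
    slack = int(4 * params.insert_sd) + params.band_for(L)
    if placed.strand == "+":
        center = placed.start + int(params.insert_mean) - L
        strand = "-"
        b, q = revcomp_codes(bases), quals[::-1]
    else:
        center = placed.end - int(params.insert_mean)
        strand = "+"
        b, q = bases, quals
    ws = max(0, center - slack)
    we = min(len(ref), center + L + slack)
    if we - ws < L // 2:
        return None
    score, w0, w1, opc, opl = dp.sw_align(b, ref[ws:we])
    if score < params.min_rescue_score:
        return None
    return AlignedRead(name=name, contig=placed.contig, start=ws + int(w0),
                       strand=strand, ops=dp.ops_from_arrays(opc, opl),
                       bases=b, quals=q, mate=mate, score=score, mapq=0)


def pair_and_rescue(cands1: list[AlignedRead], cands2: list[AlignedRead],
                    reference: Reference, params: AlignerParams,
                    read1=None, read2=None, name: str = ""
                    ) -> tuple[AlignedRead | None, AlignedRead | None, bool]:
    """Select the best mate combination; rescue a seedless mate by DP.

    ``read1``/``read2`` are (bases, quals) in original sequencing orientation,
    needed only when a mate has no candidates and rescue is attempted.
    """
    if not cands1 and not cands2:
        return None, None, False
    if not cands1 and read1 is not None:
        r = _rescue(cands2[0], read1[0], read1[1], reference, params, name, 0)
        if r is not None:
            cands1 = [r]
    if not cands2 and read2 is not None:
        r = _rescue(cands1[0], read2[0], read2[1], reference, params, name, 1)
        if r is not None:
            cands2 = [r]
    if not cands1 or not cands2:
        placed = (cands1 or cands2)[0]
        placed.mapq = _mapq(placed.score, [c.score for c in (cands1 or cands2)])
        placed.properly_paired = False
        return (placed, None, False) if cands1 else (None, placed, False)
    best = None
    best_total = None
    for a1 in cands1:
        for a2 in cands2:
            total = a1.score + a2.score
            if _proper(a1, a2, params):
                total += params.pair_bonus
            if best_total is None or total > best_total:
                best_total = total
                best = (a1, a2)
    a1, a2 = best
    a1.mapq = _mapq(a1.score, [c.score for c in cands1])
    a2.mapq = _mapq(a2.score, [c.score for c in cands2])
    proper = _proper(a1, a2, params)
    a1.properly_paired = a2.properly_paired = proper
    return a1, a2, proper


def align_pairs(pairs, index: SeedIndex, params: AlignerParams | None = None
                ) -> list[AlignedRead]:
    """Align an iterable of ReadPair; returns all placed reads.

    Pair ids number the input pairs so duplicate marking can re-associate
    mates later without name lookups.
    """
    from .formats import encode_bases

    params = params or AlignerParams()
    dp.warm_up()
    out: list[AlignedRead] = []
    for pid, pair in enumerate(pairs):
        b1, q1 = encode_bases(pair.seq1), pair.qual1
        b2, q2 = encode_bases(pair.seq2), pair.qual2
        c1 = align_read(b1, q1, index, params, name=pair.name, mate=0)
        c2 = align_read(b2, q2, index, params, name=pair.name, mate=1)
        a1, a2, proper = pair_and_rescue(c1, c2, index.reference, params,
                                         read1=(b1, q1), read2=(b2, q2),
                                         name=pair.name)
        for a in (a1, a2):
            if a is not None:
                a.pair_id = pid
                out.append(a)
    return out
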