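"""Exhaustive indel realignment.

Gapped alignments (and clusters of soft-clip boundaries) nominate indel
hypotheses; each hypothesis defines a candidate haplotype — the reference
edited by that single event.  Every read overlapping a window is scored
against every haplotype with the same affine-gap kernel the aligner uses.
Because haplotypes carry one event each, selection is greedy and iterative:
the haplotype maximizing the achievable summed read score is applied, its
improvers are rewritten as reference-space alignments through the event,
and the remaining hypotheses are reconsidered until none helps — a window
holding several nearby true indels resolves all of them.  A read only
counts toward (and is only rewritten onto) a haplotype when it gains at
least the gap-open cost: smaller gains come from restoring soft-clipped
read ends, which cannot distinguish a real event from a clipped mismatch.
Total alignment score over a window never decreases, and a second pass
over an already-realigned window is a no-op.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np

from . import dp
from .align import AlignedRead
from .formats import Reference, decode_bases, encode_bases
from .variants import left_normalize

__all__ = ["IndelHypothesis", "RealignmentWindow", "RealignParams",
           "collect_hypotheses", "build_windows", "realign_window", "realign"]


@dataclass
class RealignParams:
    min_support: int = 2
    clip_support: int = 4
    flank: int = 100
    max_window: int = 400
    max_hypotheses: int = 8
    # a read counts for (and is rewritten onto) a haplotype only when it
    # gains at least the gap-open cost; smaller gains come from soft-clip
    # restoration at read ends, which cannot distinguish a real event from
    # a clipped mismatch
    min_gain: int = 5


@dataclass(frozen=True)
class IndelHypothesis:
    """A left-normalized candidate indel, (pos, ref, alt) anchored VCF-style."""

    contig: str
    pos: int
    ref: str
    alt: str
    support: int

    @property
    def kind(self) -> str:
        return "INS" if len(self.alt) > len(self.ref) else "DEL"

    @property
    def ref_end(self) -> int:
        return self.pos + len(self.ref)


@dataclass
class RealignmentWindow:
    contig: str
    start: int
    end: int
    hypotheses: list[IndelHypothesis]


def _read_events(a: AlignedRead) -> list[tuple[int, str, str]]:
    """Raw (pos, ref_allele_len, ins_seq) indel events of one alignment,
    returned as un-normalized (pos, ref, alt) coordinates strings deferred."""
    events = []
    rpos = a.start
    qpos = 0
    for op, l in a.ops:
        if op in ("M", "X"):
            rpos += l
            qpos += l
        elif op == "I":
            events.append((rpos - 1, 0, qpos, l))  # anchor, del_len, read_off, ins_len
            qpos += l
        elif op == "D":
            events.append((rpos - 1, l, qpos, 0))
            rpos += l
        else:
            qpos += l
    return events


def collect_hypotheses(alignments: list[AlignedRead], reference: Reference,
                       min_support: int = 2, clip_support: int = 4
                       ) -> list[IndelHypothesis]:
    """Left-normalize and merge every indel edit op into supported hypotheses.

    Soft-clip clusters of >= ``clip_support`` reads sharing a boundary seed an
    insertion hypothesis whose payload is the per-offset majority consensus of
    the clipped bases.
    """
    support: dict[tuple, int] = defaultdict(int)
    clips: dict[tuple, list[np.ndarray]] = defaultdict(list)
    seqs = {c: decode_bases(s) for c, s in reference.sequences.items()}
    for a in alignments:
        if a.is_duplicate:
            continue
        for anchor, dlen, roff, ilen in _read_events(a):
            if anchor < 0:
                continue
            seq = seqs[a.contig]
            if dlen:
                if anchor + dlen + 1 > len(seq):
                    continue
                ref_a = seq[anchor : anchor + dlen + 1]
                alt_a = seq[anchor]
            else:
                ref_a = seq[anchor]
                alt_a = ref_a + decode_bases(a.bases[roff : roff + ilen])
            if "N" in ref_a or "N" in alt_a:
                continue
            pos, ref_a, alt_a = left_normalize(seq, anchor, ref_a, alt_a)
            support[(a.contig, pos, ref_a, alt_a)] += 1
        if a.ops and a.ops[0][0] == "S":
            l = a.ops[0][1]
            clips[(a.contig, a.start, "L")].append(a.bases[:l][::-1])
        if a.ops and a.ops[-1][0] == "S":
            l = a.ops[-1][1]
            clips[(a.contig, a.end, "R")].append(a.bases[-l:])
    for (contig, boundary, side), pieces in clips.items():
        if len(pieces) < clip_support:
            continue
        cons = _clip_consensus(pieces, clip_support)
        if len(cons) == 0:
            continue
        seq = seqs[contig]
        anchor = boundary - 1
        if anchor < 0:
            continue
        ins = decode_bases(cons[::-1] if side == "L" else cons)
        if "N" in ins:
            continue
        pos, ref_a, alt_a = left_normalize(seq, anchor, seq[anchor],
                                           seq[anchor] + ins)
        key = (contig, pos, ref_a, alt_a)
        support[key] = max(support[key], len(pieces))
    out = [IndelHypothesis(c, p, r, a, n)
           for (c, p, r, a), n in support.items() if n >= min_support]
    out.sort(key=lambda h: (h.contig, h.pos, h.ref, h.alt))
    return out


def _clip_consensus(pieces: list[np.ndarray], min_cov: int) -> np.ndarray:
    """Majority base per offset (offsets counted from the boundary outward),
    truncated where coverage drops below half the cluster threshold."""
    max_len = min(max(len(p) for p in pieces), 20)
    cons = []
    for i in range(max_len):
        col = [int(p[i]) for p in pieces if len(p) > i]
        if len(col) < max(2, min_cov // 2):
            break
        vals, counts = np.unique(col, return_counts=True)
        cons.append(int(vals[np.argmax(counts)]))
    return np.array(cons, dtype=np.uint8)


def build_windows(hypotheses: list[IndelHypothesis], reference: Reference,
                  params: RealignParams) -> list[RealignmentWindow]:
    """Group hypotheses into flanked windows; overlapping windows merge and
    oversize windows split (keeping the best-supported hypotheses)."""
    windows: list[RealignmentWindow] = []
    by_contig: dict[str, list[IndelHypothesis]] = defaultdict(list)
    for h in hypotheses:
        by_contig[h.contig].append(h)
    for contig, hyps in by_contig.items():
        L = reference.length(contig)
        hyps.sort(key=lambda h: h.pos)
        group: list[IndelHypothesis] = []
        for h in hyps:
            if group and h.pos - group[-1].ref_end > 2 * params.flank:
                windows.extend(_finalize(contig, group, L, params))
                group = []
            group.append(h)
        if group:
            windows.extend(_finalize(contig, group, L, params))
    return windows


def _finalize(contig, group, L, params) -> list[RealignmentWindow]:
    start = max(0, group[0].pos - params.flank)
    end = min(L, max(h.ref_end for h in group) + params.flank)
    if end - start > params.max_window and len(group) > 1:
        mid = len(group) // 2
        return (_finalize(contig, group[:mid], L, params)
                + _finalize(contig, group[mid:], L, params))
    if len(group) > params.max_hypotheses:
        group = sorted(group, key=lambda h: -h.support)[: params.max_hypotheses]
        group.sort(key=lambda h: h.pos)
    return [RealignmentWindow(contig, start, end, group)]


def _haplotype(refwin: np.ndarray, ws: int, hyp: IndelHypothesis
               ) -> tuple[np.ndarray, np.ndarray]:
    """Window haplotype for one hypothesis plus hap->ref coordinate map
    (-1 marks inserted bases)."""
    A = hyp.pos - ws
    alt = encode_bases(hyp.alt)
    hap = np.concatenate([refwin[:A], alt, refwin[A + len(hyp.ref):]])
    coords = np.concatenate([
        np.arange(ws, ws + A, dtype=np.int64),
        np.array([hyp.pos], dtype=np.int64),
        np.full(len(alt) - 1, -1, dtype=np.int64) if len(alt) > len(hyp.ref)
        else np.arange(hyp.pos + 1, hyp.pos + len(alt), dtype=np.int64),
        np.arange(hyp.pos + len(hyp.ref), ws + len(refwin), dtype=np.int64),
    ])
    return hap, coords


def _remap_ops(opc, opl, read: AlignedRead, hap_start: int,
               coords: np.ndarray) -> tuple[int, list[tuple[str, int]]] | None:
    """Convert an alignment against a window haplotype into reference-space
    ops, inserting D across deleted reference bases and turning bases aligned
    to inserted haplotype positions into I ops."""
    ops: list[tuple[str, int]] = []
    hp = hap_start
    start_ref = None
    last_ref = None

    def push(op, l=1):
        if ops and ops[-1][0] == op and op != "X":
            ops[-1] = (op, ops[-1][1] + l)
        else:
            ops.append((op, l))

    for code, l in zip(opc, opl):
        ch = dp.OP_CHARS[code]
        if ch == "S":
            push("S", int(l))
        elif ch == "I":
            push("I", int(l))
        elif ch in ("M", "X"):
            for _ in range(int(l)):
                r = int(coords[hp])
                if r < 0:
                    push("I")
                else:
                    if start_ref is None:
                        start_ref = r
                    elif last_ref is not None and r > last_ref + 1:
                        push("D", r - last_ref - 1)
                    push("M" if ch == "M" else "X")
                    last_ref = r
                hp += 1
        elif ch == "D":
            for _ in range(int(l)):
                r = int(coords[hp])
                if r >= 0 and last_ref is not None:
                    if r > last_ref + 1:
                        push("D", r - last_ref - 1)
                    push("D")
                    last_ref = r
                elif r >= 0:
                    # deletion before any ref-aligned base: shift start
                    pass
                hp += 1
    if start_ref is None:
        return None
    # a leading/trailing I sees only part of the inserted sequence; folding
    # it into a soft clip avoids minting partial-payload insertion events
    cleaned: list[tuple[str, int]] = []
    for i, (op, l) in enumerate(ops):
        if op == "I":
            before = all(o in ("S", "I") for o, _ in ops[:i])
            after = all(o in ("S", "I") for o, _ in ops[i + 1:])
            if before or after:
                op = "S"
        if cleaned and cleaned[-1][0] == op and op != "X":
            cleaned[-1] = (op, cleaned[-1][1] + l)
        else:
            cleaned.append((op, l))
    while cleaned and cleaned[-1][0] == "D":
        cleaned.pop()
    while cleaned and cleaned[0][0] == "D":
        start_ref += cleaned[0][1]
        cleaned.pop(0)
    consumed = sum(l for op, l in cleaned if op in ("M", "X", "I", "S"))
    if consumed != len(read.bases):
        return None
    return start_ref, cleaned


def realign_window(window: RealignmentWindow, reads: list[AlignedRead],
                   reference: Reference, params: RealignParams | None = None
                   ) -> dict:
    """Score reads x haplotypes, pick the best haplotype, rewrite improvers.

    Returns a report dict with the selected hypothesis (or None for the
    reference), summed scores before/after, and the rewritten read count.
    """
    params = params or RealignParams()
    ws, we = window.start, window.end
    ref = reference.sequences[window.contig]
    refwin = ref[ws:we]
    overlapping = [a for a in reads
                   if not a.is_duplicate
                   and a.unclipped_start() < we and a.unclipped_end() > ws]
    # only reads that can see an event distinguish haplotypes
    ev_lo = min(h.pos for h in window.hypotheses)
    ev_hi = max(h.ref_end for h in window.hypotheses)
    cares = [a for a in overlapping
             if a.unclipped_start() < ev_hi + 1 and a.unclipped_end() > ev_lo]
    report = {"window": window, "selected": None, "selected_all": [],
              "rewritten": 0,
              "score_before": float(sum(a.score for a in cares)),
              "score_after": float(sum(a.score for a in cares))}
    if not cares:
        return report
    haplotypes = [_haplotype(refwin, ws, h) for h in window.hypotheses]
    # read x haplotype score matrix, computed once
    hap_scores = np.array([[dp.sw_score(a.bases, hap) for a in cares]
                           for hap, _ in haplotypes])
    ref_scores = np.array([dp.sw_score(a.bases, refwin) for a in cares])
    # Greedy selection: window haplotypes carry a single event each, so a
    # window holding several real indels is resolved one haplotype at a
    # time — pick the haplotype maximizing the achievable summed read score,
    # rewrite its strict improvers, and repeat until no haplotype helps.
    remaining = list(range(len(window.hypotheses)))
    rewritten = 0
    min_gain = params.min_gain
    while remaining:
        cur = np.array([a.score for a in cares])
        # the reference "haplotype" competes on the same footing
        baseline = int(np.maximum(ref_scores, cur).sum())
        totals = [int(np.where(hap_scores[h] >= cur + min_gain,
                               hap_scores[h], cur).sum()) for h in remaining]
        best_i = int(np.argmax(totals))
        if totals[best_i] <= baseline:
            break
        h = remaining.pop(best_i)
        hyp = window.hypotheses[h]
        hap, coords = haplotypes[h]
        report["selected_all"].append(hyp)
        if report["selected"] is None:
            report["selected"] = hyp
        for i, a in enumerate(cares):
            if hap_scores[h][i] < a.score + min_gain:
                continue
            score, h0, h1, opc, opl = dp.sw_align(a.bases, hap)
            if score < a.score + min_gain:
                continue
            remapped = _remap_ops(opc, opl, a, int(h0), coords)
            if remapped is None:
                continue
            a.start, a.ops = remapped
            a.score = score
            rewritten += 1
    report["rewritten"] = rewritten
    report["score_after"] = float(sum(a.score for a in cares))
    assert report["score_after"] >= report["score_before"] - 1e-9
    return report


def realign(alignments_by_contig: dict[str, list[AlignedRead]],
            reference: Reference, params: RealignParams | None = None
            ) -> list[dict]:
    """Full realignment pass: collect hypotheses, build windows, realign each.

    Reads are modified in place; returns the per-window reports.
    """
    params = params or RealignParams()
    dp.warm_up()
    all_reads = [a for reads in alignments_by_contig.values() for a in reads]
    hyps = collect_hypotheses(all_reads, reference,
                              params.min_support, params.clip_support)
    windows = build_windows(hyps, reference, params)
    # index reads by start so each window touches only nearby reads
    sorted_reads: dict[str, tuple[list[AlignedRead], np.ndarray, int]] = {}
    for contig, reads in alignments_by_contig.items():
        rs = sorted(reads, key=lambda a: a.unclipped_start())
        starts = np.array([a.unclipped_start() for a in rs], dtype=np.int64)
        span = max((a.unclipped_end() - a.unclipped_start() for a in rs),
                   default=0)
        sorted_reads[contig] = (rs, starts, span)
    reports = []
    for w in windows:
        rs, starts, span = sorted_reads.get(w.contig, ([], np.zeros(0), 0))
        lo = int(np.searchsorted(starts, w.start - span))
        hi = int(np.searchsorted(starts, w.end))
        reports.append(realign_window(w, rs[lo:hi], reference, params))
    return reports


def report_tsv(reports: list[dict], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tn_hypotheses\tselected\trewritten\t"
                 "score_before\tscore_after\n")
        for r in reports:
            w = r["window"]
            sel = r["selected"]
            sel_s = f"{sel.pos}:{sel.ref}>{sel.alt}" if sel else "."
            fh.write(f"{w.contig}\t{w.start}\t{w.end}\t{len(w.hypotheses)}\t"
                     f"{sel_s}\t{r['rewritten']}\t{r['score_before']}\t"
                     f"{r['score_after']}\n")
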