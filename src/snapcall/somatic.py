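"""Tumor-normal somatic SNV/indel calling and depth-ratio CNV segmentation,
both operating directly on snapshot files.

Somatic calling evaluates the joint posterior over all 16 x 16 genotype
pairs (G_normal, G_tumor):

    P(G_n, G_t | D) ∝ prior(G_n) · P(D_n | G_n) · T(G_t | G_n) · P(D_t | G_t)

where the transition prior T keeps the tumor genotype equal to the normal
one with probability 1 - mu and spreads the somatic rate mu (default 1e-6)
uniformly over the other 15 genotypes.  The somatic score is the phred of
one minus the posterior mass of pairs in which the normal is homozygous
reference and the tumor carries a novel allele.  Indel alleles are bound
from the pooled tumor+normal event ranking so I/I' mean the same event in
both samples.

CNV calling compares per-window (default 1000 bp) median-normalized depths,
GC-corrects the log2 ratio by GC-bin medians, and segments by recursive
binary splitting on the Welch t statistic (split accepted when
|delta mean| >= 0.2 and Bonferroni-adjusted p < 1e-4); segment states are
GAIN (mean >= +0.3), LOSS (mean <= -0.3), else NEUTRAL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .formats import Reference
from .germline import GENOTYPES, PriorModel, genotype_likelihoods
from .snapshot import Snapshot

__all__ = ["SomaticCall", "CnvSegment", "SomaticParams", "call_somatic",
           "call_cnv"]


@dataclass
class SomaticParams:
    mu: float = 1e-6              # somatic transition rate per genotype
    min_score: float = 30.0
    min_normal_depth: int = 8
    min_tumor_depth: int = 8
    max_normal_alt_fraction: float = 0.03
    min_alt_per_strand: int = 1   # SNVs: alt reads required on each strand
    min_candidate_alt: int = 2


@dataclass
class SomaticCall:
    contig: str
    pos: int
    ref: str
    alt: str
    vclass: str                   # SNV | INS | DEL
    score: float
    normal_gt: str
    tumor_gt: str
    normal_depth: int
    tumor_depth: int
    normal_alt_fraction: float
    tumor_alt_fraction: float
    normal_ad: tuple[int, int]
    tumor_ad: tuple[int, int]


@dataclass
class CnvSegment:
    contig: str
    start: int
    end: int
    mean_log2: float
    state: str                    # GAIN | LOSS | NEUTRAL
    n_windows: int


def _gt_string(gi: int, ref_code: int) -> str:
    a1, a2 = GENOTYPES[gi]
    names = {0: "A", 1: "C", 2: "G", 3: "T", 4: "I", 5: "I'"}
    return names[a1] + "/" + names[a2]


def _pooled_events(col_n, col_t) -> list[tuple[str, object]]:
    """Indel events ranked by combined support across both samples."""
    support: dict[tuple[str, object], int] = {}
    for col in (col_n, col_t):
        for seq, (f, r, _) in col.insertions.items():
            support[("INS", seq)] = support.get(("INS", seq), 0) + f + r
        for ln, (f, r) in col.deletions.items():
            support[("DEL", int(ln))] = support.get(("DEL", int(ln)), 0) + f + r
    ranked = sorted(support.items(), key=lambda kv: (-kv[1], kv[0][0], str(kv[0][1])))
    return [k for k, _ in ranked]


def call_somatic(normal: Snapshot, tumor: Snapshot, reference: Reference,
                 params: SomaticParams | None = None,
                 priors: PriorModel | None = None) -> list[SomaticCall]:
    """Joint 16x16 genotype-pair somatic calling over paired snapshots."""
    params = params or SomaticParams()
    priors = priors or PriorModel()
    if normal.reference_checksum != tumor.reference_checksum:
        raise ValueError("normal and tumor snapshots built on different references")
    normal.verify_reference(reference)
    prior_m = priors.log_prior_matrix()
    log_stay = np.log1p(-params.mu)
    log_move = np.log(params.mu / 15.0)
    T = np.full((16, 16), log_move)
    np.fill_diagonal(T, log_stay)
    calls: list[SomaticCall] = []
    t_by_key = {(p.contig, p.start, p.end): p for p in tumor.pileups}
    for pn in normal.pileups:
        pt = t_by_key.get((pn.contig, pn.start, pn.end))
        if pt is None:
            raise ValueError("normal and tumor snapshots cover different regions")
        refc = reference.sequences[pn.contig][pn.start : pn.end]
        counts_t = (pt.base_fwd + pt.base_rev).astype(np.int64)
        total_t = counts_t.sum(axis=0)
        ref_cnt = np.where(refc < 4,
                           counts_t[np.minimum(refc, 3), np.arange(len(refc))], 0)
        alt_t = total_t - ref_cnt
        cand = set(np.flatnonzero((alt_t >= params.min_candidate_alt)
                                  & (refc < 4)).tolist())
        cand |= {pos - pn.start for pos in
                 (set(pt.insertions) | set(pt.deletions))
                 if pn.start <= pos < pn.end and refc[pos - pn.start] < 4}
        for rel in sorted(cand):
            pos = rel + pn.start
            col_n = pn.column(pos)
            col_t = pt.column(pos)
            if (col_n.depth < params.min_normal_depth
                    or col_t.depth < params.min_tumor_depth):
                continue
            r = int(refc[rel])
            events = _pooled_events(col_n, col_t)
            st_n = genotype_likelihoods(col_n, r, prior_m, pn.contig, pos,
                                        bound_events=events)
            st_t = genotype_likelihoods(col_t, r, prior_m, pn.contig, pos,
                                        bound_events=events)
            if st_n is None or st_t is None:
                continue
            joint = (prior_m[r][:, None] + st_n.log_likelihoods[:, None]
                     + T + st_t.log_likelihoods[None, :])
            finite = np.isfinite(joint)
            if not finite.any():
                continue
            m = joint[finite].max()
            w = np.zeros((16, 16))
            w[finite] = np.exp(joint[finite] - m)
            w /= w.sum()
            hom_ref = GENOTYPES.index((r, r))
            p_som = w[hom_ref, :].sum() - w[hom_ref, hom_ref]
            score = float(min(-10 * np.log10(max(1 - p_som, 1e-300)), 10000.0))
            if score < params.min_score:
                continue
            gi_n, gi_t = np.unravel_index(np.argmax(np.where(finite, joint,
                                                             -np.inf)), (16, 16))
            call = _build_somatic_call(pn.contig, pos, r, int(gi_t), col_n,
                                       col_t, events, score,
                                       int(gi_n), reference, params)
            if call is not None:
                calls.append(call)
    return calls


def _allele_counts(col, allele: int, events) -> tuple[int, int]:
    """(fwd, rev) observation counts for one allele code at a column."""
    if allele < 4:
        return int(col.base_fwd[allele]), int(col.base_rev[allele])
    if allele - 4 >= len(events):
        return 0, 0
    kind, payload = events[allele - 4]
    if kind == "INS":
        f, r, _ = col.insertions.get(payload, (0, 0, 0))
    else:
        f, r = col.deletions.get(payload, (0, 0))
    return int(f), int(r)


def _build_somatic_call(contig, pos, r, gi_t, col_n, col_t, events, score,
                        gi_n, reference: Reference, params: SomaticParams
                        ) -> SomaticCall | None:
    normal_alleles = set(GENOTYPES[gi_n])
    novel = [a for a in GENOTYPES[gi_t] if a not in normal_alleles and a != r]
    if not novel:
        # score came from the somatic posterior mass; report the strongest
        # non-reference tumor allele instead of the (hom-ref) argmax
        novel = [a for a in GENOTYPES[gi_t] if a != r]
        if not novel:
            return None
    a = novel[0]
    seq = reference.seq(contig)
    if a < 4:
        ref_a, alt_a, vclass = seq[pos], "ACGT"[a], "SNV"
    else:
        if a - 4 >= len(events):
            return None
        kind, payload = events[a - 4]
        if kind == "DEL":
            ref_a, alt_a, vclass = seq[pos : pos + payload + 1], seq[pos], "DEL"
        else:
            ref_a, alt_a, vclass = seq[pos], seq[pos] + payload, "INS"
    nf, nr = _allele_counts(col_n, a, events)
    tf, tr = _allele_counts(col_t, a, events)
    n_af = (nf + nr) / col_n.depth if col_n.depth else 0.0
    t_af = (tf + tr) / col_t.depth if col_t.depth else 0.0
    if n_af >= params.max_normal_alt_fraction:
        return None
    if vclass == "SNV" and (tf < params.min_alt_per_strand
                            or tr < params.min_alt_per_strand):
        return None
    rn = int(col_n.base_counts[r])
    rt = int(col_t.base_counts[r])
    return SomaticCall(contig, pos, ref_a, alt_a, vclass, score,
                       _gt_string(gi_n, r), _gt_string(gi_t, r),
                       col_n.depth, col_t.depth, n_af, t_af,
                       (rn, nf + nr), (rt, tf + tr))


# --- CNV ------------------------------------------------------------------

def call_cnv(normal: Snapshot, tumor: Snapshot, reference: Reference,
             window: int = 1000, min_normal_depth: float = 10.0,
             min_delta: float = 0.2, alpha: float = 1e-4,
             gain_cut: float = 0.3, loss_cut: float = -0.3,
             min_windows: int = 50) -> list[CnvSegment]:
    """Segment the log2 tumor/normal depth ratio into GAIN/LOSS/NEUTRAL."""
    if normal.reference_checksum != tumor.reference_checksum:
        raise ValueError("snapshots built on different references")
    t_by_key = {(p.contig, p.start, p.end): p for p in tumor.pileups}
    segments: list[CnvSegment] = []
    for pn in normal.pileups:
        pt = t_by_key.get((pn.contig, pn.start, pn.end))
        if pt is None:
            raise ValueError("snapshots cover different regions")
        dn = pn.depth_array().astype(np.float64)
        dt = pt.depth_array().astype(np.float64)
        n_win = len(dn) // window
        if n_win == 0:
            continue
        wn = dn[: n_win * window].reshape(n_win, window).mean(axis=1)
        wt = dt[: n_win * window].reshape(n_win, window).mean(axis=1)
        gc = _window_gc(reference.sequences[pn.contig]
                        [pn.start : pn.start + n_win * window], window)
        usable = wn >= min_normal_depth
        if usable.sum() < min_windows:
            raise ValueError(
                f"only {int(usable.sum())} usable windows (<{min_windows}): "
                "too little data for CNV segmentation")
        n_med = np.median(wn[usable])
        t_med = np.median(wt[usable])
        if n_med <= 0 or t_med <= 0:
            raise ValueError("zero median depth")
        with np.errstate(divide="ignore"):
            r = np.log2(np.maximum(wt / t_med, 1e-6)
                        / np.maximum(wn / n_med, 1e-6))
        r = _gc_correct(r, gc, usable)
        idx = np.flatnonzero(usable)
        rv = r[idx]
        for lo, hi in _binary_segment(rv, min_delta, alpha):
            w0, w1 = idx[lo], idx[hi - 1] + 1
            mean = float(rv[lo:hi].mean())
            state = ("GAIN" if mean >= gain_cut
                     else "LOSS" if mean <= loss_cut else "NEUTRAL")
            segments.append(CnvSegment(pn.contig, pn.start + int(w0) * window,
                                       pn.start + int(w1) * window, mean,
                                       state, hi - lo))
    return segments


def _window_gc(codes: np.ndarray, window: int) -> np.ndarray:
    n_win = len(codes) // window
    isgc = ((codes == 1) | (codes == 2)).astype(np.float64)
    return isgc[: n_win * window].reshape(n_win, window).mean(axis=1)


def _gc_correct(r: np.ndarray, gc: np.ndarray, usable: np.ndarray,
                bin_width: float = 0.02, neutral_band: float = 0.2
                ) -> np.ndarray:
    """Subtract the per-GC-bin median ratio (coarse LOESS-style correction).

    Bin medians are estimated from apparently copy-neutral windows only
    (within ``neutral_band`` of the global median); otherwise a GC bin
    dominated by a real gain or loss would have the event subtracted out of
    its own windows.
    """
    out = r.copy()
    bins = np.floor(gc / bin_width).astype(int)
    neutral = usable & (np.abs(r - np.median(r[usable])) < neutral_band)
    for b in np.unique(bins[usable]):
        sel = (bins == b) & usable
        fit = sel & neutral
        if fit.sum() >= 5:
            out[sel] -= np.median(r[fit])
    return out


def _binary_segment(r: np.ndarray, min_delta: float, alpha: float,
                    min_size: int = 2, refine_span: int = 5
                    ) -> list[tuple[int, int]]:
    """Binary segmentation with merge and boundary refinement.

    Recursion splits a segment at the position maximizing the Welch t
    statistic when the (Bonferroni-adjusted within the recursion) p-value is
    below ``alpha``; adjacent segments whose means differ by less than
    ``min_delta`` are merged back, and each surviving boundary is nudged
    within ``refine_span`` windows to minimize the within-segment sum of
    squares — this recovers sharp breakpoints the t test alone places a
    window or two off.
    """
    out: list[tuple[int, int]] = []
    tests_done = 0
    # noise level from first differences (robust to the jumps themselves);
    # a within-segment variance estimate would absorb any embedded event and
    # blind the split test to short gains/losses
    if len(r) > 1:
        sigma = max(1.4826 * np.median(np.abs(np.diff(r))) / np.sqrt(2), 1e-4)
    else:
        sigma = 1e-4

    def recurse(lo: int, hi: int):
        nonlocal tests_done
        n = hi - lo
        if n < 2 * min_size:
            out.append((lo, hi))
            return
        seg = r[lo:hi]
        csum = np.concatenate(([0.0], np.cumsum(seg)))
        ks = np.arange(min_size, n - min_size + 1)
        mean_a = csum[ks] / ks
        mean_b = (csum[n] - csum[ks]) / (n - ks)
        t = np.abs(mean_a - mean_b) / (sigma * np.sqrt(1 / ks + 1 / (n - ks)))
        best_i = int(np.argmax(t))
        best_k = int(ks[best_i])
        best_p = 2 * stats.t.sf(t[best_i], df=max(n - 2, 1))
        tests_done += 1
        if best_p * tests_done < alpha:
            recurse(lo, lo + best_k)
            recurse(lo + best_k, hi)
        else:
            out.append((lo, hi))

    recurse(0, len(r))
    out.sort()
    # merge adjacent segments closer than min_delta in mean
    merged: list[tuple[int, int]] = []
    for lo, hi in out:
        if merged and abs(r[merged[-1][0]:merged[-1][1]].mean()
                          - r[lo:hi].mean()) < min_delta:
            merged[-1] = (merged[-1][0], hi)
        else:
            merged.append((lo, hi))
    # refine each internal boundary by minimizing the two-segment SSE
    for i in range(len(merged) - 1):
        (a_lo, b0), (_, b_hi) = merged[i], merged[i + 1]
        best_b, best_sse = b0, np.inf
        for b in range(max(a_lo + 1, b0 - refine_span),
                       min(b_hi - 1, b0 + refine_span) + 1):
            left, right = r[a_lo:b], r[b:b_hi]
            sse = (((left - left.mean()) ** 2).sum()
                   + ((right - right.mean()) ** 2).sum())
            if sse < best_sse:
                best_sse, best_b = sse, b
        merged[i] = (a_lo, best_b)
        merged[i + 1] = (best_b, b_hi)
    return merged


def cnv_bed(segments: list[CnvSegment], path) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.state}\t"
                     f"{s.mean_log2:.4f}\n")


def cnv_tsv(segments: list[CnvSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("contig\tstart\tend\tlog2_ratio\tstate\tn_windows\n")
        for s in segments:
            fh.write(f"{s.contig}\t{s.start}\t{s.end}\t{s.mean_log2:.4f}\t"
                     f"{s.state}\t{s.n_windows}\n")
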