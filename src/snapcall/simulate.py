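"""Illumina-style synthetic data: references, planted diploid variants,
paired-end reads, tumor-normal pairs and trios.

The generator is the oracle for the rest of the package: every read records
its true origin, and planted variants form a left-normalized truth set the
evaluation layer compares calls against.  Reads are 100 bp by default with a
500 +/- 25 bp insert; substitution errors follow a linear cycle profile
(0.1% at the first cycle rising to 0.5% at the last) and reported qualities
are the cycle's true Phred value jittered by +/-3.  All generators are pure
functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .formats import (CODE_TO_BASE, Reference, Region, decode_bases,
                      encode_bases, revcomp_codes)
from .variants import left_normalize, variant_class

__all__ = ["SimProfile", "TruthVariant", "TruthSet", "Diploid", "OriginTable",
           "make_reference", "plant_variants", "simulate_reads",
           "make_tumor_pair", "make_trio"]


@dataclass(frozen=True)
class TruthVariant:
    contig: str
    pos: int          # 0-based, left-normalized, anchored for indels
    ref: str
    alt: str
    zygosity: str     # "het" | "hom"
    vclass: str       # "SNP" | "INS" | "DEL"
    hap: int          # 0 or 1 for het (which haplotype carries it), -1 for hom

    @property
    def key(self):
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class TruthSet:
    variants: list[TruthVariant]

    def by_class(self, vclass: str | None = None) -> list[TruthVariant]:
        if vclass is None:
            return list(self.variants)
        if vclass == "indel":
            return [v for v in self.variants if v.vclass != "SNP"]
        return [v for v in self.variants if v.vclass == vclass]


@dataclass
class Diploid:
    """Two edited haplotypes per contig plus the coordinate maps back to
    reference space (piecewise-linear, one breakpoint per planted indel)."""

    reference: Reference
    haplotypes: dict[str, tuple[np.ndarray, np.ndarray]]
    maps: dict[str, tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]]
    truth: TruthSet

    def hap_to_ref(self, contig: str, hap: int, hpos: int) -> int:
        hb, rb = self.maps[contig][hap]
        i = int(np.searchsorted(hb, hpos, side="right")) - 1
        return int(rb[i] + (hpos - hb[i]))


def make_reference(length: int, gc: float = 0.41, seed: int = 0,
                   name: str = "sim1", n_contigs: int = 1,
                   repeat_tracts: int = 0, repeat_len: int = 300) -> Reference:
    """Random reference with target GC content.

    ``repeat_tracts`` copies a ``repeat_len`` segment to a second random
    location per tract, for aligner stress tests.
    """
    if length < 10_000:
        raise ValueError("reference length must be >= 10,000")
    if not (0.0 < gc < 1.0):
        raise ValueError(f"gc={gc} outside (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs: dict[str, np.ndarray] = {}
    per = length // n_contigs
    for i in range(n_contigs):
        codes = rng.choice(4, size=per, p=p).astype(np.uint8)
        for _ in range(repeat_tracts):
            src = rng.integers(0, per - repeat_len)
            dst = rng.integers(0, per - repeat_len)
            codes[dst : dst + repeat_len] = codes[src : src + repeat_len]
        cname = name if n_contigs == 1 else f"{name}_{i + 1}"
        seqs[cname] = codes
    return Reference(seqs)


_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}  # A<->G, C<->T


def _draw_alt(rng, ref_code: int) -> int:
    """Alt base with transition:transversion prior 2:1."""
    if rng.random() < 0.5:
        return _TRANSITION[ref_code]
    tv = [b for b in range(4) if b != ref_code and b != _TRANSITION[ref_code]]
    return tv[rng.integers(0, 2)]


def plant_variants(reference: Reference, snp_rate: float = 1e-3,
                   indel_rate: float = 1e-4, het_fraction: float = 2 / 3,
                   indel_len_geom_p: float = 0.4, max_indel: int = 20,
                   seed: int = 0) -> Diploid:
    """Poisson-place SNPs and indels on a diploid genome.

    Indel lengths are geometric(p) capped at ``max_indel``; insertions and
    deletions are equally likely; overlapping draws resolve by dropping the
    later one.  Variants are stored left-normalized.
    """
    rng = np.random.default_rng(seed)
    all_variants: list[TruthVariant] = []
    haplotypes = {}
    maps = {}
    for contig, codes in reference.sequences.items():
        L = len(codes)
        seq = decode_bases(codes)
        snp_pos = np.flatnonzero(rng.random(L) < snp_rate)
        ind_pos = np.flatnonzero(rng.random(L) < indel_rate)
        draws = sorted(
            [(int(p), "SNP") for p in snp_pos] + [(int(p), "IND") for p in ind_pos]
        )
        raw: list[tuple[int, str, str]] = []  # (pos, ref, alt) pre-normalization
        last_end = 0  # first ref position free for the next variant
        for pos, kind in draws:
            if pos < 1 or pos <= last_end:
                continue
            if kind == "SNP":
                ref_a = seq[pos]
                if ref_a == "N":
                    continue
                alt_a = "ACGT"[_draw_alt(rng, int(codes[pos]))]
                raw.append((pos, ref_a, alt_a))
                last_end = pos + 1
            else:
                ln = min(int(rng.geometric(indel_len_geom_p)), max_indel)
                if rng.random() < 0.5:  # insertion after pos
                    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, ln))
                    raw.append((pos, seq[pos], seq[pos] + ins))
                    last_end = pos + 1
                else:                   # deletion of pos+1 .. pos+ln
                    if pos + ln + 1 >= L:
                        continue
                    raw.append((pos, seq[pos : pos + ln + 1], seq[pos]))
                    last_end = pos + ln + 1
        # left-normalize, then drop anything that now collides
        normed = []
        for pos, ref_a, alt_a in raw:
            npos, nref, nalt = left_normalize(seq, pos, ref_a, alt_a)
            normed.append((npos, nref, nalt))
        normed.sort()
        kept: list[TruthVariant] = []
        last_end = -1
        for pos, ref_a, alt_a in normed:
            # keep a one-base buffer so adjacent events stay representable
            span = pos + len(ref_a)
            if pos <= last_end:
                continue
            last_end = span
            if rng.random() < het_fraction:
                zyg, hap = "het", int(rng.integers(0, 2))
            else:
                zyg, hap = "hom", -1
            kept.append(TruthVariant(contig, pos, ref_a, alt_a, zyg,
                                     variant_class(ref_a, alt_a), hap))
        all_variants.extend(kept)
        hap_pair = []
        map_pair = []
        for h in (0, 1):
            hvars = [(v.pos, v.ref, v.alt) for v in kept if v.hap in (h, -1)]
            hcodes, hmap = _apply_variants(codes, hvars)
            hap_pair.append(hcodes)
            map_pair.append(hmap)
        haplotypes[contig] = tuple(hap_pair)
        maps[contig] = tuple(map_pair)
    return Diploid(reference, haplotypes, maps, TruthSet(all_variants))


def _apply_variants(codes: np.ndarray, hvars: list[tuple[int, str, str]]):
    """Apply sorted non-overlapping (pos, ref, alt) edits; return the edited
    sequence and a (hap_breaks, ref_breaks) coordinate map."""
    pieces = []
    hap_breaks = [0]
    ref_breaks = [0]
    cur = 0
    hlen = 0
    for pos, ref_a, alt_a in hvars:
        pieces.append(codes[cur:pos])
        hlen += pos - cur
        alt_codes = encode_bases(alt_a)
        pieces.append(alt_codes)
        hlen += len(alt_codes)
        cur = pos + len(ref_a)
        if len(alt_a) != len(ref_a):
            hap_breaks.append(hlen)
            ref_breaks.append(cur)
    pieces.append(codes[cur:])
    hap = np.concatenate(pieces) if pieces else codes.copy()
    return hap, (np.array(hap_breaks, dtype=np.int64),
                 np.array(ref_breaks, dtype=np.int64))


@dataclass
class SimProfile:
    read_len: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 25.0
    depth: float = 40.0
    err_start: float = 0.001   # substitution rate at cycle 1
    err_end: float = 0.005     # ... rising linearly to this at the last cycle
    qual_jitter: int = 3
    read_indel_rate: float = 1e-5  # per base
    seed: int = 0

    def __post_init__(self):
        for r in (self.err_start, self.err_end, self.read_indel_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("error rates must lie in [0, 1]")

    def cycle_error(self) -> np.ndarray:
        return np.linspace(self.err_start, self.err_end, self.read_len)

    def cycle_qual(self) -> np.ndarray:
        e = np.maximum(self.cycle_error(), 1e-6)
        return np.round(-10 * np.log10(e)).astype(np.int64)


class OriginTable:
    """True origin of every simulated read, keyed by pair name ``{contig}:{i}``.

    Per mate: reference start (mapped back through the haplotype's coordinate
    map), strand and source haplotype.  Substitution-error cycles are kept as
    parallel (pair, mate, cycle) arrays.
    """

    def __init__(self, read_len: int):
        self.read_len = read_len
        self.contigs: dict[str, dict] = {}

    def add_contig(self, contig, hap, ref_start1, strand1, ref_start2, strand2,
                   err_pair, err_mate, err_cycle):
        self.contigs[contig] = dict(hap=hap, ref_start1=ref_start1,
                                    strand1=strand1, ref_start2=ref_start2,
                                    strand2=strand2, err_pair=err_pair,
                                    err_mate=err_mate, err_cycle=err_cycle)

    def n_pairs(self, contig: str) -> int:
        return len(self.contigs[contig]["hap"])

    def true_starts(self, contig: str, pair_index: int) -> tuple[int, int]:
        c = self.contigs[contig]
        return int(c["ref_start1"][pair_index]), int(c["ref_start2"][pair_index])

    def coverage(self, contig: str, contig_len: int) -> np.ndarray:
        """Per-position count of simulated reads overlapping each position."""
        c = self.contigs[contig]
        diff = np.zeros(contig_len + 1, dtype=np.int64)
        for key in ("ref_start1", "ref_start2"):
            starts = np.clip(c[key], 0, contig_len)
            ends = np.clip(c[key] + self.read_len, 0, contig_len)
            np.add.at(diff, starts, 1)
            np.add.at(diff, ends, -1)
        return np.cumsum(diff)[:contig_len]

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("pair\tmate\thap\tref_start\tstrand\n")
            for contig, c in self.contigs.items():
                for i in range(len(c["hap"])):
                    for m, (rs, st) in enumerate(
                        ((c["ref_start1"][i], c["strand1"][i]),
                         (c["ref_start2"][i], c["strand2"][i])), 1):
                        fh.write(f"{contig}:{i}\t{m}\t{c['hap'][i]}\t{rs}\t"
                                 f"{'+-'[int(st)]}\n")


def simulate_reads(diploid: Diploid, profile: SimProfile, path1, path2,
                   cnv_spec: list[tuple[Region, int]] | None = None,
                   chunk: int = 20_000) -> OriginTable:
    """Simulate paired-end reads into two FASTQ files; returns the origin table.

    Fragments are drawn uniformly per haplotype (weighted by copy number when
    ``cnv_spec`` is given), FR-oriented, with Gaussian insert sizes.  Which
    physical mate is the forward read is randomized per pair.
    """
    rng = np.random.default_rng(profile.seed)
    R = profile.read_len
    origin = OriginTable(R)
    e_cycle = profile.cycle_error()
    q_cycle = profile.cycle_qual()
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for contig, (hapA, hapB) in diploid.haplotypes.items():
            L = diploid.reference.length(contig)
            weight = np.ones(L)
            wmax = 1.0
            if cnv_spec:
                for region, cn in cnv_spec:
                    if region.contig == contig:
                        weight[region.start:region.end] = cn / 2.0
                wmax = float(weight.max())
            n_pairs = int(round(wmax * profile.depth * L / (2 * R)))
            haps = (hapA, hapB)
            hap_choice = rng.integers(0, 2, n_pairs)
            hap_len = np.array([len(hapA), len(hapB)])
            frag = np.clip(np.round(rng.normal(profile.insert_mean,
                                               profile.insert_sd, n_pairs)),
                           R, None).astype(np.int64)
            maxstart = hap_len[hap_choice] - frag
            bad = maxstart < 0
            frag[bad] = hap_len[hap_choice[bad]]
            maxstart[bad] = 0
            start = np.floor(rng.random(n_pairs) * (maxstart + 1)).astype(np.int64)
            if cnv_spec and wmax > 1.0 + 1e-9:
                mid = np.minimum(start + frag // 2, L - 1)
                # map hap coord to ref coord approximately via identity;
                # planted indels shift by <<1 window so this is adequate
                keep = rng.random(n_pairs) < weight[np.clip(mid, 0, L - 1)] / wmax
                hap_choice, frag, start = hap_choice[keep], frag[keep], start[keep]
                n_pairs = len(start)
            swap = rng.random(n_pairs) < 0.5  # mate1 is the reverse read
            # per-pair true origins in reference coordinates
            ref_left = np.empty(n_pairs, dtype=np.int64)
            ref_right = np.empty(n_pairs, dtype=np.int64)
            for h in (0, 1):
                hb, rb = diploid.maps[contig][h]
                sel = hap_choice == h
                for arr, s in ((ref_left, start[sel]),
                               (ref_right, start[sel] + frag[sel] - R)):
                    i = np.searchsorted(hb, s, side="right") - 1
                    arr[sel] = rb[i] + (s - hb[i])
            strand1 = np.where(swap, 1, 0).astype(np.int8)  # 0=+, 1=-
            strand2 = 1 - strand1
            rs1 = np.where(swap, ref_right, ref_left)
            rs2 = np.where(swap, ref_left, ref_right)
            err_pair, err_mate, err_cycle_l = [], [], []
            for lo in range(0, n_pairs, chunk):
                hi = min(lo + chunk, n_pairs)
                n = hi - lo
                left = np.empty((n, R), dtype=np.uint8)
                right = np.empty((n, R), dtype=np.uint8)
                for h in (0, 1):
                    sel = hap_choice[lo:hi] == h
                    if not sel.any():
                        continue
                    s = start[lo:hi][sel]
                    f = frag[lo:hi][sel]
                    idx = s[:, None] + np.arange(R)[None, :]
                    left[sel] = haps[h][idx]
                    idx2 = (s + f - R)[:, None] + np.arange(R)[None, :]
                    right[sel] = haps[h][idx2]
                right_rc = 3 - right[:, ::-1]  # revcomp (no N in simulated refs)
                # both mates written in sequencing orientation
                m1 = np.where(swap[lo:hi, None], right_rc, left)
                m2 = np.where(swap[lo:hi, None], left, right_rc)
                for mate, mat in ((0, m1), (1, m2)):
                    emask = rng.random((n, R)) < e_cycle[None, :]
                    if emask.any():
                        k = int(emask.sum())
                        mat[emask] = (mat[emask] + rng.integers(1, 4, k)) % 4
                        pi, cy = np.nonzero(emask)
                        err_pair.append(pi + lo)
                        err_mate.append(np.full(k, mate, dtype=np.int8))
                        err_cycle_l.append(cy)
                    # occasional 1 bp read indel errors
                    hit = np.flatnonzero(rng.random(n) <
                                         profile.read_indel_rate * R)
                    for ri in hit:
                        p = int(rng.integers(5, R - 5))
                        if rng.random() < 0.5:  # deletion: shift left, pad end
                            mat[ri, p:-1] = mat[ri, p + 1:]
                            mat[ri, -1] = rng.integers(0, 4)
                        else:                   # insertion of a random base
                            mat[ri, p + 1:] = mat[ri, p:-1]
                            mat[ri, p] = rng.integers(0, 4)
                    jit = rng.integers(-profile.qual_jitter,
                                       profile.qual_jitter + 1, (n, R))
                    qual = np.clip(q_cycle[None, :] + jit, 2, 60).astype(np.uint8)
                    fh = f1 if mate == 0 else f2
                    seq_bytes = CODE_TO_BASE[mat]
                    qual_bytes = qual + 33
                    for i in range(n):
                        fh.write(f"@{contig}:{lo + i}/{mate + 1}\n"
                                 f"{seq_bytes[i].tobytes().decode()}\n+\n"
                                 f"{qual_bytes[i].tobytes().decode()}\n")
            origin.add_contig(
                contig, hap_choice, rs1, strand1, rs2, strand2,
                np.concatenate(err_pair) if err_pair else np.zeros(0, np.int64),
                np.concatenate(err_mate) if err_mate else np.zeros(0, np.int8),
                np.concatenate(err_cycle_l) if err_cycle_l else np.zeros(0, np.int64),
            )
    return origin


def make_tumor_pair(reference: Reference, germline: Diploid,
                    somatic_snv_rate: float = 1e-5,
                    somatic_indel_rate: float = 2e-6,
                    cnv_spec: list[tuple[Region, int]] | None = None,
                    seed: int = 0) -> tuple[Diploid, TruthSet]:
    """Tumor haplotypes = germline haplotypes + somatic edits (purity 1.0).

    Somatic events are het (one haplotype) and disjoint from germline events;
    expected alt fraction 0.5 outside CNV regions.  Returns the tumor Diploid
    and the somatic truth set.  Overlapping CNV regions raise.
    """
    if cnv_spec:
        regs = sorted((r for r, _ in cnv_spec))
        for a, b in zip(regs, regs[1:]):
            if a.contig == b.contig and b.start < a.end:
                raise ValueError("overlapping CNV regions")
    rng = np.random.default_rng(seed)
    occupied = {}
    for v in germline.truth.variants:
        occupied.setdefault(v.contig, set()).update(
            range(v.pos - 1, v.pos + len(v.ref) + 1))
    som_vars: list[TruthVariant] = []
    tumor_haps = {}
    tumor_maps = {}
    for contig, codes in reference.sequences.items():
        L = len(codes)
        seq = decode_bases(codes)
        occ = occupied.get(contig, set())
        draws = sorted(
            [(int(p), "SNP") for p in np.flatnonzero(rng.random(L) < somatic_snv_rate)]
            + [(int(p), "IND") for p in np.flatnonzero(rng.random(L) < somatic_indel_rate)]
        )
        kept = []
        last_end = 0
        for pos, kind in draws:
            if pos < 1 or pos <= last_end or pos in occ:
                continue
            if kind == "SNP":
                alt_a = "ACGT"[_draw_alt(rng, int(codes[pos]))]
                pr, rr, aa = pos, seq[pos], alt_a
                last_end = pos + 1
            else:
                ln = min(int(rng.geometric(0.4)), 20)
                if rng.random() < 0.5:
                    ins = "".join("ACGT"[b] for b in rng.integers(0, 4, ln))
                    pr, rr, aa = pos, seq[pos], seq[pos] + ins
                    last_end = pos + 1
                else:
                    if pos + ln + 1 >= L:
                        continue
                    pr, rr, aa = pos, seq[pos : pos + ln + 1], seq[pos]
                    last_end = pos + ln + 1
            npos, nref, nalt = left_normalize(seq, pr, rr, aa)
            if npos in occ:
                continue
            kept.append(TruthVariant(contig, npos, nref, nalt, "het",
                                     variant_class(nref, nalt),
                                     int(rng.integers(0, 2))))
        som_vars.extend(kept)
        # re-apply germline + somatic edits per haplotype, in ref order
        germ = [v for v in germline.truth.variants if v.contig == contig]
        hap_pair, map_pair = [], []
        for h in (0, 1):
            hv = sorted([(v.pos, v.ref, v.alt) for v in germ + kept
                         if v.hap in (h, -1)])
            hcodes, hmap = _apply_variants(codes, hv)
            hap_pair.append(hcodes)
            map_pair.append(hmap)
        tumor_haps[contig] = tuple(hap_pair)
        tumor_maps[contig] = tuple(map_pair)
    tumor = Diploid(reference, tumor_haps, tumor_maps,
                    TruthSet(germline.truth.variants + som_vars))
    return tumor, TruthSet(som_vars)


def make_trio(reference: Reference, snp_rate: float = 1e-3,
              indel_rate: float = 1e-4, seed: int = 0, de_novo: int = 0
              ) -> tuple[Diploid, Diploid, Diploid]:
    """Father and mother planted independently; the child inherits one whole
    haplotype from each (no recombination at desk scale).  ``de_novo`` forces
    that many extra child-only SNVs."""
    father = plant_variants(reference, snp_rate, indel_rate, seed=seed)
    mother = plant_variants(reference, snp_rate, indel_rate, seed=seed + 1)
    rng = np.random.default_rng(seed + 2)
    child_vars: list[TruthVariant] = []
    child_haps = {}
    child_maps = {}
    for contig, codes in reference.sequences.items():
        fh = int(rng.integers(0, 2))
        mh = int(rng.integers(0, 2))
        f_alleles = {(v.pos, v.ref, v.alt) for v in father.truth.variants
                     if v.contig == contig and v.hap in (fh, -1)}
        m_alleles = {(v.pos, v.ref, v.alt) for v in mother.truth.variants
                     if v.contig == contig and v.hap in (mh, -1)}
        seq = decode_bases(codes)
        if de_novo:
            free = []
            occupied = {v.pos for v in father.truth.variants + mother.truth.variants
                        if v.contig == contig}
            while len(free) < de_novo:
                p = int(rng.integers(1, len(codes) - 1))
                if p not in occupied:
                    occupied.add(p)
                    free.append(p)
            for p in free:
                alt = "ACGT"[_draw_alt(rng, int(codes[p]))]
                dv = (p, seq[p], alt)
                if rng.random() < 0.5:
                    f_alleles.add(dv)
                else:
                    m_alleles.add(dv)
        both = f_alleles & m_alleles
        for pos, ref_a, alt_a in sorted(f_alleles | m_alleles):
            if (pos, ref_a, alt_a) in both:
                zyg, hap = "hom", -1
            else:
                zyg = "het"
                hap = 0 if (pos, ref_a, alt_a) in f_alleles else 1
            child_vars.append(TruthVariant(contig, pos, ref_a, alt_a, zyg,
                                           variant_class(ref_a, alt_a), hap))
        hap_pair, map_pair = [], []
        cvars = [v for v in child_vars if v.contig == contig]
        for h in (0, 1):
            hv = sorted([(v.pos, v.ref, v.alt) for v in cvars if v.hap in (h, -1)])
            # drop overlaps that arise from combining two parents
            clean = []
            last_end = -1
            for pos, r, a in hv:
                if pos <= last_end:
                    continue
                clean.append((pos, r, a))
                last_end = pos + len(r)
            hcodes, hmap = _apply_variants(codes, clean)
            hap_pair.append(hcodes)
            map_pair.append(hmap)
        child_haps[contig] = tuple(hap_pair)
        child_maps[contig] = tuple(map_pair)
    child = Diploid(reference, child_haps, child_maps, TruthSet(child_vars))
    return father, mother, child


def truth_to_vcf(truth: TruthSet, reference: Reference, path) -> None:
    """Write a truth set as a minimal VCF (GT only)."""
    order = {c: i for i, c in enumerate(reference.contigs)}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n##source=snapcall-sim\n")
        for c in reference.contigs:
            fh.write(f"##contig=<ID={c},length={reference.length(c)}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTRUTH\n")
        for v in sorted(truth.variants, key=lambda v: (order[v.contig], v.pos)):
            gt = "1/1" if v.zygosity == "hom" else "0/1"
            fh.write(f"{v.contig}\t{v.pos + 1}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\t"
                     f"GT\t{gt}\n")
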