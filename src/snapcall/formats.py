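"""Readers and writers for the standard text formats the pipeline touches.

All internal coordinates are 0-based half-open. Conversion to the 1-based
conventions of SAM and VCF happens only inside :func:`read_sam`,
:func:`write_sam` and :func:`write_vcf`, so there is a single conversion
point for each format.

Bases are held either as Python strings (A/C/G/T/N) or as numpy ``uint8``
codes (A=0, C=1, G=2, T=3, N=4); :data:`BASE_TO_CODE` / :data:`CODE_TO_BASE`
translate between the two.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pysam
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "Reference",
    "ReadPair",
    "Region",
    "read_fasta",
    "write_fasta",
    "stream_fastq_pairs",
    "write_fastq_pair",
    "read_bed",
    "read_sam",
    "write_sam",
    "write_vcf",
    "encode_bases",
    "decode_bases",
]


class FormatError(ValueError):
    """Raised for malformed input files or contract violations."""


# A=0 C=1 G=2 T=3, anything else (incl. N) = 4
BASE_TO_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    BASE_TO_CODE[ord(_b)] = _i
    BASE_TO_CODE[ord(_b.lower())] = _i
CODE_TO_BASE = np.frombuffer(b"ACGTN", dtype=np.uint8)
# complement of a code; N stays N
COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def encode_bases(seq: str) -> np.ndarray:
    """Encode a base string into uint8 codes (non-ACGT folds to 4/N)."""
    return BASE_TO_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_bases(codes: np.ndarray) -> str:
    """Decode uint8 codes back into an A/C/G/T/N string."""
    return CODE_TO_BASE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return COMP_CODE[codes[::-1]]


@dataclass
class Reference:
    """A reference genome held fully in memory as uint8 code arrays."""

    sequences: dict[str, np.ndarray]

    @property
    def contigs(self) -> list[str]:
        return list(self.sequences.keys())

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    def seq(self, contig: str, start: int = 0, end: int | None = None) -> str:
        return decode_bases(self.sequences[contig][start:end])

    def checksum(self) -> str:
        """MD5 over contig names and sequences, identifying the reference."""
        h = hashlib.md5()
        for name, codes in self.sequences.items():
            h.update(name.encode())
            h.update(b"\x00")
            h.update(codes.tobytes())
        return h.hexdigest()

    @classmethod
    def from_strings(cls, seqs: dict[str, str]) -> "Reference":
        return cls({name: encode_bases(s) for name, s in seqs.items()})


@dataclass
class ReadPair:
    name: str
    seq1: str
    qual1: np.ndarray
    seq2: str
    qual2: np.ndarray

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(
                f"read {self.name}: sequence and quality lengths differ"
            )


@dataclass(frozen=True, order=True)
class Region:
    """0-based half-open interval on a contig."""

    contig: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid region {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start


def read_fasta(path) -> Reference:
    """Load a FASTA file; lowercase folds to uppercase, non-ACGTN to N.

    Raises :class:`FormatError` (naming the offending line) for an empty
    file, sequence data before the first header, a header with an empty
    name, or a duplicate contig name.
    """
    sequences: dict[str, np.ndarray] = {}
    name = None
    chunks: list[str] = []

    def flush(lineno):
        if name is not None:
            if not chunks:
                raise FormatError(f"{path}: contig {name!r} is empty (line {lineno})")
            sequences[name] = encode_bases("".join(chunks))

    with open(path) as fh:
        lineno = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(lineno)
                name = line[1:].split()[0] if len(line) > 1 else ""
                if not name:
                    raise FormatError(f"{path}: empty FASTA header at line {lineno}")
                if name in sequences:
                    raise FormatError(
                        f"{path}: duplicate contig {name!r} at line {lineno}"
                    )
                chunks = []
            else:
                if name is None:
                    raise FormatError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                chunks.append(line)
        flush(lineno)
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return Reference(sequences)


def write_fasta(reference: Reference, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, codes in reference.sequences.items():
            fh.write(f">{name}\n")
            s = decode_bases(codes)
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def _decode_qual(qual: str, name: str) -> np.ndarray:
    q = np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int64) - 33
    if q.min(initial=0) < 0:
        raise FormatError(f"read {name}: quality character below '!' (Phred+33)")
    if q.max(initial=0) > 60:
        raise FormatError(
            f"read {name}: quality above Q60 — input looks Phred+64 encoded; "
            "only Phred+33 (Illumina >=1.8) is supported"
        )
    return q.astype(np.uint8)


def _strip_mate(name: str) -> str:
    return name.split()[0].removesuffix("/1").removesuffix("/2")


def stream_fastq_pairs(path1, path2):
    """Yield :class:`ReadPair` from two mate FASTQ files (Phred+33).

    Raises on record-count mismatch and on read-name mismatch between the
    files (after stripping ``/1``/``/2`` suffixes).
    """
    with open(path1) as fh1, open(path2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        n = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                return
            if (r1 is None) != (r2 is None):
                raise FormatError(
                    f"{path1} and {path2} have different record counts "
                    f"(mismatch after {n} pairs)"
                )
            name1, seq1, qual1 = r1
            name2, seq2, qual2 = r2
            n1, n2 = _strip_mate(name1), _strip_mate(name2)
            if n1 != n2:
                raise FormatError(f"read name mismatch at record {n + 1}: {n1} vs {n2}")
            yield ReadPair(n1, seq1.upper(), _decode_qual(qual1, n1),
                           seq2.upper(), _decode_qual(qual2, n2))
            n += 1


def write_fastq_pair(pairs, path1, path2) -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            q1 = (p.qual1 + 33).tobytes().decode("ascii")
            q2 = (p.qual2 + 33).tobytes().decode("ascii")
            f1.write(f"@{p.name}/1\n{p.seq1}\n+\n{q1}\n")
            f2.write(f"@{p.name}/2\n{p.seq2}\n+\n{q2}\n")


def read_bed(path, reference: Reference | None = None) -> list[Region]:
    """Parse a 3-column BED (0-based half-open) into sorted, merged regions."""
    regions = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: need >=3 BED columns")
            contig, start, end = parts[0], int(parts[1]), int(parts[2])
            if reference is not None:
                if contig not in reference.sequences:
                    raise FormatError(f"{path}: line {lineno}: unknown contig {contig}")
                if end > reference.length(contig):
                    raise FormatError(
                        f"{path}: line {lineno}: region beyond contig end"
                    )
            regions.append(Region(contig, start, end))
    return merge_regions(regions)


def merge_regions(regions: list[Region]) -> list[Region]:
    out: list[Region] = []
    for r in sorted(regions):
        if out and out[-1].contig == r.contig and r.start <= out[-1].end:
            out[-1] = Region(r.contig, out[-1].start, max(out[-1].end, r.end))
        else:
            out.append(r)
    return out


# --- SAM ---------------------------------------------------------------

def read_sam(path, reference: Reference):
    """Stream mapped SAM records as AlignedRead objects.

    Soft clips are preserved; hard-clipped records are rejected (the read
    bases are not recoverable). Unmapped records are skipped and counted on
    the returned generator via ``.skipped`` after exhaustion.
    """
    from .align import AlignedRead  # local import to avoid cycle

    def gen():
        with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
            skipped = 0
            for rec in _wrap_parse_errors(sam, path):
                if rec.is_unmapped:
                    skipped += 1
                    continue
                if rec.reference_name not in reference.sequences:
                    raise FormatError(f"SAM contig {rec.reference_name} not in reference")
                if any(op in (5,) for op, _ in rec.cigartuples or ()):
                    raise FormatError(f"read {rec.query_name}: hard clips unsupported")
                seq = rec.query_sequence
                if seq is None:
                    raise FormatError(f"read {rec.query_name}: missing SEQ")
                consumed = sum(l for op, l in rec.cigartuples if op in (0, 1, 4, 7, 8))
                if consumed != len(seq):
                    raise FormatError(
                        f"read {rec.query_name}: CIGAR consumes {consumed} bases, "
                        f"SEQ has {len(seq)}"
                    )
                bases = encode_bases(seq)
                quals = (np.array(rec.query_qualities, dtype=np.uint8)
                         if rec.query_qualities is not None
                         else np.full(len(seq), 30, dtype=np.uint8))
                ops = []
                ref = reference.sequences[rec.reference_name]
                rpos = rec.reference_start
                qpos = 0
                for op, length in rec.cigartuples:
                    if op in (0, 7, 8):  # M/=/X: split into match/mismatch runs
                        seg = bases[qpos : qpos + length]
                        refseg = ref[rpos : rpos + length]
                        mism = seg != refseg
                        i = 0
                        while i < length:
                            j = i
                            if mism[i]:
                                ops.append(("X", 1))
                                i += 1
                            else:
                                while j < length and not mism[j]:
                                    j += 1
                                ops.append(("M", j - i))
                                i = j
                        rpos += length
                        qpos += length
                    elif op == 1:
                        ops.append(("I", length))
                        qpos += length
                    elif op == 2:
                        ops.append(("D", length))
                        rpos += length
                    elif op == 4:
                        ops.append(("S", length))
                        qpos += length
                    elif op == 3:
                        ops.append(("D", length))  # treat N as deletion span
                        rpos += length
                    else:
                        raise FormatError(f"unsupported CIGAR op {op}")
                if rpos > len(ref):
                    raise FormatError(f"read {rec.query_name}: alignment beyond contig end")
                yield AlignedRead(
                    name=rec.query_name,
                    contig=rec.reference_name,
                    start=rec.reference_start,
                    strand="-" if rec.is_reverse else "+",
                    ops=ops,
                    bases=bases,
                    quals=quals,
                    mapq=rec.mapping_quality,
                    mate=1 if rec.is_read2 else 0,
                    properly_paired=rec.is_proper_pair,
                    is_duplicate=rec.is_duplicate,
                )
            gen.skipped = skipped

    gen.skipped = 0
    return gen()


def _wrap_parse_errors(sam, path):
    """Convert htslib parse failures (e.g. CIGAR/SEQ length clashes) into
    FormatError so callers see one error type for malformed SAM."""
    it = iter(sam)
    while True:
        try:
            rec = next(it)
        except StopIteration:
            return
        except (OSError, ValueError) as e:
            raise FormatError(f"{path}: malformed SAM record: {e}") from e
        yield rec


def write_sam(alignments, reference: Reference, path) -> None:
    """Debug SAM output of internal alignments (CIGAR from the edit script)."""
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": reference.length(c)} for c in reference.contigs],
    }
    order = {c: i for i, c in enumerate(reference.contigs)}
    alns = sorted(alignments, key=lambda a: (order[a.contig], a.start))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for a in alns:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = a.name
            rec.query_sequence = decode_bases(a.bases)
            rec.query_qualities = pysam.qualitystring_to_array(
                (a.quals + 33).tobytes().decode("ascii")
            )
            rec.reference_name = a.contig
            rec.reference_start = a.start
            rec.mapping_quality = a.mapq
            rec.cigarstring = a.cigar()
            flag = 0
            if a.strand == "-":
                flag |= 0x10
            if a.mate is not None:
                flag |= 0x1 | (0x40 if a.mate == 0 else 0x80)
            if a.properly_paired:
                flag |= 0x2
            if a.is_duplicate:
                flag |= 0x400
            rec.flag = flag
            out.write(rec)


# --- VCF ---------------------------------------------------------------

VCF_FILTERS = {
    "PASS": "All filters passed",
    "LowQual": "Classifier probability >=0.95 but QUAL<30",
    "RF_FAIL": "Classifier probability <0.95",
    "UNFILTERED": "No classifier applied",
}


def write_vcf(calls, reference: Reference, path, sample: str = "SAMPLE",
              extra_info: dict | None = None) -> None:
    """Write VariantCalls as a VCFv4.2 file.

    Calls must be sorted by (contig order, position); indel alleles must be
    left-normalized with a shared anchor base (the caller guarantees both).
    POS is converted 0-based -> 1-based here and nowhere else.
    """
    order = {c: i for i, c in enumerate(reference.contigs)}
    lines = [
        "##fileformat=VCFv4.2",
        "##source=snapcall",
    ]
    for c in reference.contigs:
        lines.append(f"##contig=<ID={c},length={reference.length(c)}>")
    for fid, desc in VCF_FILTERS.items():
        if fid == "PASS":
            continue
        lines.append(f'##FILTER=<ID={fid},Description="{desc}">')
    lines += [
        '##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction">',
        '##INFO=<ID=SBP,Number=1,Type=Float,Description="Phred-scaled strand bias">',
        '##INFO=<ID=MQ,Number=1,Type=Float,Description="Mean mapping quality">',
        '##INFO=<ID=RFP,Number=1,Type=Float,Description="Classifier probability">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample,
    ]
    prev = None
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for call in calls:
            key = (order[call.contig], call.pos)
            if prev is not None and key < prev:
                raise FormatError("VCF calls not sorted by (contig, position)")
            prev = key
            if "N" in call.ref or any("N" in a for a in call.alts):
                raise FormatError(f"allele containing N at {call.contig}:{call.pos}")
            info = [f"DP={call.depth}",
                    "AF=" + ",".join(f"{f:.4g}" for f in call.alt_fractions),
                    f"SBP={call.strand_bias:.2f}",
                    f"MQ={call.mean_mq:.1f}"]
            if call.rf_prob is not None:
                info.append(f"RFP={call.rf_prob:.4f}")
            gt = "/".join(str(i) for i in sorted(call.genotype_indices))
            fh.write(
                f"{call.contig}\t{call.pos + 1}\t.\t{call.ref}\t"
                f"{','.join(call.alts)}\t{min(call.qual, 10000):.2f}\t"
                f"{call.filter_status}\t{';'.join(info)}\tGT:DP\t"
                f"{gt}:{call.depth}\n"
            )


def write_somatic_vcf(calls, reference: Reference, path) -> None:
    """Somatic calls as a two-sample (NORMAL, TUMOR) VCF."""
    order = {c: i for i, c in enumerate(reference.contigs)}
    lines = ["##fileformat=VCFv4.2", "##source=snapcall-somatic"]
    for c in reference.contigs:
        lines.append(f"##contig=<ID={c},length={reference.length(c)}>")
    lines += [
        '##INFO=<ID=SOMATIC,Number=0,Type=Flag,Description="Somatic event">',
        '##INFO=<ID=SSC,Number=1,Type=Float,Description="Somatic score (phred)">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">',
        '##FORMAT=<ID=AF,Number=1,Type=Float,Description="Alt fraction">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNORMAL\tTUMOR",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
        for c in sorted(calls, key=lambda c: (order[c.contig], c.pos)):
            fh.write(
                f"{c.contig}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t{c.score:.2f}\t"
                f"PASS\tSOMATIC;SSC={c.score:.2f}\tGT:DP:AD:AF\t"
                f"{c.normal_gt}:{c.normal_depth}:{c.normal_ad[0]},{c.normal_ad[1]}:"
                f"{c.normal_alt_fraction:.4g}\t"
                f"{c.tumor_gt}:{c.tumor_depth}:{c.tumor_ad[0]},{c.tumor_ad[1]}:"
                f"{c.tumor_alt_fraction:.4g}\n"
            )
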