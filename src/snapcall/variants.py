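"""Shared variant representation and left-normalization.

Every producer (simulator truth, indel hypotheses, caller output) and the
evaluation layer normalize indels through the same routine, so equality of
(pos, ref, alt) is meaningful across the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def left_normalize(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim one variant against its contig sequence.

    ``seq`` is the full contig as an A/C/G/T/N string; ``pos`` is the 0-based
    position of the first REF base.  Follows the standard normalization: trim
    shared trailing bases, shift indels left through repeat context, then trim
    shared leading bases keeping the indel anchor.
    """
    if ref == alt:
        return pos, ref, alt
    while True:
        if len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
            continue
        if (len(ref) == 1) != (len(alt) == 1) and ref[-1] == alt[-1] and pos > 0:
            prev = seq[pos - 1]
            ref = prev + ref[:-1]
            alt = prev + alt[:-1]
            pos -= 1
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def variant_class(ref: str, alt: str) -> str:
    if len(ref) == len(alt) == 1:
        return "SNP"
    return "INS" if len(alt) > len(ref) else "DEL"


def homopolymer_length(seq: str, pos: int) -> int:
    """Length of the homopolymer run starting at pos+1 (indel context)."""
    i = pos + 1
    if i >= len(seq):
        return 0
    b = seq[i]
    j = i
    while j < len(seq) and seq[j] == b:
        j += 1
    return j - i


@dataclass
class VariantCall:
    """One emitted non-reference site, destined for a VCF row."""

    contig: str
    pos: int                       # 0-based position of the first REF base
    ref: str
    alts: list[str]
    genotype_indices: tuple[int, int]   # indices into [ref] + alts
    qual: float
    depth: int
    alt_fractions: list[float]
    strand_bias: float = 0.0
    mean_mq: float = 60.0
    mean_alt_qual: float = 30.0
    filter_status: str = "UNFILTERED"
    rf_prob: float | None = None
    homopolymer_len: int = 0
    dist_nearest: int = 10 ** 9

    @property
    def classes(self) -> list[str]:
        return [variant_class(self.ref, a) for a in self.alts]

    @property
    def is_hom(self) -> bool:
        return self.genotype_indices[0] == self.genotype_indices[1]

    def alleles(self) -> list[tuple[int, str, str]]:
        """Called (pos, ref, alt) triples, one per non-reference allele."""
        out = []
        for i in set(self.genotype_indices):
            if i == 0:
                continue
            out.append((self.pos, self.ref, self.alts[i - 1]))
        return out
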