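"""Flattened, vectorizable views over collections of aligned reads.

Per-base work (recalibration, pileup construction) would be prohibitively
slow read-by-read in Python; instead every read's M/X runs are collapsed
into contiguous "blocks" and all blocks of a contig are expanded into flat
numpy arrays in one shot.  Indel events are rare and handled per read.
"""

from __future__ import annotations

import numpy as np

from .align import AlignedRead

__all__ = ["expand_ranges", "ReadBatch"]


def expand_ranges(starts: np.ndarray, lengths: np.ndarray) -> np.ndarray:
    """Concatenate [s, s+l) ranges into one index array without a Python loop."""
    if len(starts) == 0:
        return np.zeros(0, dtype=np.int64)
    total = int(lengths.sum())
    # offsets where each range begins in the output
    out = np.ones(total, dtype=np.int64)
    ends = np.cumsum(lengths)
    out[0] = starts[0]
    out[ends[:-1]] = starts[1:] - (starts[:-1] + lengths[:-1]) + 1
    return np.cumsum(out)


class ReadBatch:
    """Flat arrays over one contig's alignments (duplicates excluded).

    Attributes (all aligned-base–parallel, one entry per M/X base):
      pos       reference position
      base      read base code at that position
      qual      reported quality
      read_idx  index into the ``reads`` list
      read_off  index of the base within the stored read
      strand    0 for +, 1 for -
      mapq      read mapping quality
    """

    def __init__(self, reads: list[AlignedRead], include_duplicates: bool = False):
        self.reads = reads
        block_start: list[int] = []
        block_off: list[int] = []
        block_len: list[int] = []
        block_read: list[int] = []
        base_chunks = []
        qual_chunks = []
        off = 0
        offsets = np.empty(len(reads) + 1, dtype=np.int64)
        offsets[0] = 0
        for ri, a in enumerate(reads):
            base_chunks.append(a.bases)
            qual_chunks.append(np.ascontiguousarray(a.quals))
            off += len(a.bases)
            offsets[ri + 1] = off
            if a.is_duplicate and not include_duplicates:
                continue
            rpos = a.start
            qpos = 0
            run_start_r = a.start
            run_start_q = 0
            run_len = 0
            for op, l in a.ops:
                if op in ("M", "X"):
                    if run_len == 0:
                        run_start_r, run_start_q = rpos, qpos
                    run_len += l
                    rpos += l
                    qpos += l
                else:
                    if run_len:
                        block_start.append(run_start_r)
                        block_off.append(run_start_q)
                        block_len.append(run_len)
                        block_read.append(ri)
                        run_len = 0
                    if op == "D":
                        rpos += l
                    else:  # I or S consume read only
                        qpos += l
            if run_len:
                block_start.append(run_start_r)
                block_off.append(run_start_q)
                block_len.append(run_len)
                block_read.append(ri)
        self.bases_flat = (np.concatenate(base_chunks)
                           if base_chunks else np.zeros(0, np.uint8))
        self.quals_flat = (np.concatenate(qual_chunks)
                           if qual_chunks else np.zeros(0, np.uint8))
        self.read_offsets = offsets
        bs = np.asarray(block_start, dtype=np.int64)
        bo = np.asarray(block_off, dtype=np.int64)
        bl = np.asarray(block_len, dtype=np.int64)
        br = np.asarray(block_read, dtype=np.int64)
        self.pos = expand_ranges(bs, bl)
        flat_idx = expand_ranges(offsets[br] + bo, bl)
        self.read_off = flat_idx - np.repeat(offsets[br], bl)
        self.base = self.bases_flat[flat_idx] if len(flat_idx) else np.zeros(0, np.uint8)
        self.qual = self.quals_flat[flat_idx] if len(flat_idx) else np.zeros(0, np.uint8)
        self.read_idx = np.repeat(br, bl)
        self.flat_idx = flat_idx
        strands = np.fromiter((1 if a.strand == "-" else 0 for a in reads),
                              dtype=np.int8, count=len(reads))
        mapqs = np.fromiter((a.mapq for a in reads), dtype=np.int32,
                            count=len(reads))
        lens = np.fromiter((len(a.bases) for a in reads), dtype=np.int64,
                           count=len(reads))
        self.strand = strands[self.read_idx] if len(reads) else np.zeros(0, np.int8)
        self.mapq = mapqs[self.read_idx] if len(reads) else np.zeros(0, np.int32)
        self.read_len = lens[self.read_idx] if len(reads) else np.zeros(0, np.int64)

    def cycle(self) -> np.ndarray:
        """Machine cycle of each aligned base (sequencing orientation)."""
        return np.where(self.strand == 1,
                        self.read_len - 1 - self.read_off, self.read_off)
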