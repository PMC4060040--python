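"""The SNAPSHOT per-base store.

A snapshot is the pipeline's working state dumped per reference position:
stranded base counts, recalibrated-quality and mapping-quality sums, N and
deletion-span counts, and indel event tables.  Calling (germline or somatic)
needs nothing else, so a stored snapshot supports repeatable variant calling
without touching the reads again.  On disk the columns are chunked into
blocks of ``block_size`` positions, each block deflate-compressed and CRC'd,
with an index mapping (region, block start) to byte offsets so that a query
decompresses only the blocks it overlaps.

A read carrying an indel event anchored at position p contributes the event
observation at p instead of its aligned base there, so each overlapping read
is counted exactly once per column:
depth = base counts + N + deletion spans + indel events.

File layout (little-endian): magic ``SNP1``, u32 version, u64 header length,
header JSON (reference checksum, contigs, regions, block size, codec, block
index), then the compressed blocks.  Insertions anchor on the reference base
to their left, matching VCF anchoring.
"""

from __future__ import annotations

import json
import struct
import zlib
from dataclasses import dataclass, field

import numpy as np

from .align import AlignedRead
from .formats import Reference, Region, decode_bases
from .readops import ReadBatch

__all__ = ["SnapshotColumn", "ContigPileup", "Snapshot", "OutOfCoverageError",
           "build_snapshot", "write_snapshot", "load_snapshot", "read_region",
           "query_position", "SnapshotReader"]

MAGIC = b"SNP1"
VERSION = 1
DEFAULT_BLOCK_SIZE = 65_536
COUNT_MAX = 2 ** 32 - 1


class OutOfCoverageError(KeyError):
    """Query outside the snapshot's declared regions."""


@dataclass
class SnapshotColumn:
    """Aggregate evidence at one reference position."""

    base_fwd: np.ndarray          # (4,) forward-strand counts per base
    base_rev: np.ndarray          # (4,)
    qual_sum: np.ndarray          # (4,) summed recalibrated quality
    mq_sum: np.ndarray            # (4,) summed mapping quality
    n_count: int
    del_span: int                 # reads whose deletion covers this position
    insertions: dict[str, tuple[int, int, int]]   # seq -> (fwd, rev, qual_sum)
    deletions: dict[int, tuple[int, int]]         # length -> (fwd, rev)

    @property
    def base_counts(self) -> np.ndarray:
        return self.base_fwd + self.base_rev

    @property
    def event_count(self) -> int:
        return (sum(f + r for f, r, _ in self.insertions.values())
                + sum(f + r for f, r in self.deletions.values()))

    @property
    def depth(self) -> int:
        return int(self.base_counts.sum()) + self.n_count + self.del_span \
            + self.event_count

    def __eq__(self, other) -> bool:
        return (np.array_equal(self.base_fwd, other.base_fwd)
                and np.array_equal(self.base_rev, other.base_rev)
                and np.array_equal(self.qual_sum, other.qual_sum)
                and np.array_equal(self.mq_sum, other.mq_sum)
                and self.n_count == other.n_count
                and self.del_span == other.del_span
                and self.insertions == other.insertions
                and self.deletions == other.deletions)


class ContigPileup:
    """Column arrays over one declared region [start, end) of a contig."""

    def __init__(self, contig: str, start: int, end: int):
        n = end - start
        self.contig = contig
        self.start = start
        self.end = end
        self.base_fwd = np.zeros((4, n), dtype=np.uint32)
        self.base_rev = np.zeros((4, n), dtype=np.uint32)
        self.qual_sum = np.zeros((4, n), dtype=np.uint32)
        self.mq_sum = np.zeros((4, n), dtype=np.uint32)
        self.n_count = np.zeros(n, dtype=np.uint32)
        self.del_span = np.zeros(n, dtype=np.uint32)
        self.insertions: dict[int, dict[str, list[int]]] = {}
        self.deletions: dict[int, dict[int, list[int]]] = {}

    def column(self, pos: int) -> SnapshotColumn:
        if not (self.start <= pos < self.end):
            raise OutOfCoverageError(f"{self.contig}:{pos} outside region")
        i = pos - self.start
        ins = {s: tuple(v) for s, v in self.insertions.get(pos, {}).items()}
        dels = {l: tuple(v) for l, v in self.deletions.get(pos, {}).items()}
        return SnapshotColumn(
            self.base_fwd[:, i].copy(), self.base_rev[:, i].copy(),
            self.qual_sum[:, i].copy(), self.mq_sum[:, i].copy(),
            int(self.n_count[i]), int(self.del_span[i]), ins, dels)

    def depth_array(self) -> np.ndarray:
        depth = (self.base_fwd.sum(axis=0, dtype=np.int64)
                 + self.base_rev.sum(axis=0, dtype=np.int64)
                 + self.n_count + self.del_span)
        for pos, evs in self.insertions.items():
            depth[pos - self.start] += sum(f + r for f, r, _ in evs.values())
        for pos, evs in self.deletions.items():
            depth[pos - self.start] += sum(f + r for f, r in evs.values())
        return depth


@dataclass
class Snapshot:
    reference_checksum: str
    contig_lengths: dict[str, int]
    regions: list[Region]             # declared coverage, sorted, non-overlapping
    pileups: list[ContigPileup]       # parallel to regions
    wes: bool = False
    block_size: int = DEFAULT_BLOCK_SIZE

    def _find(self, contig: str, pos: int) -> ContigPileup:
        if contig not in self.contig_lengths:
            raise OutOfCoverageError(f"unknown contig {contig}")
        if pos >= self.contig_lengths[contig] or pos < 0:
            raise OutOfCoverageError(
                f"{contig}:{pos} beyond contig length {self.contig_lengths[contig]}")
        for p in self.pileups:
            if p.contig == contig and p.start <= pos < p.end:
                return p
        raise OutOfCoverageError(f"{contig}:{pos} outside declared regions")

    def column(self, contig: str, pos: int) -> SnapshotColumn:
        return self._find(contig, pos).column(pos)

    def pileup_for(self, contig: str) -> list[ContigPileup]:
        return [p for p in self.pileups if p.contig == contig]

    def verify_reference(self, reference: Reference) -> None:
        if reference.checksum() != self.reference_checksum:
            raise ValueError("snapshot reference checksum mismatch")


END_TRIM = 3


def build_snapshot(alignments_by_contig: dict[str, list[AlignedRead]],
                   reference: Reference,
                   regions: list[Region] | None = None,
                   end_trim: int = END_TRIM) -> Snapshot:
    """Aggregate deduplicated, recalibrated, realigned reads into a snapshot.

    With ``regions`` given (WES mode) only those intervals are stored and
    anything outside raises :class:`OutOfCoverageError` on query.

    The outermost ``end_trim`` aligned bases of each read are counted in the
    N/other bucket rather than as base evidence: a read end that stops at or
    just past an indel anchor cannot distinguish the indel from the
    reference, so letting it vote for the reference base systematically
    biases homozygous indels toward heterozygous calls.
    """
    wes = regions is not None
    if regions is None:
        regions = [Region(c, 0, reference.length(c)) for c in reference.contigs]
    regions = sorted(regions)
    pileups = []
    # full-contig accumulation, then sliced into declared regions
    for contig in reference.contigs:
        creg = [r for r in regions if r.contig == contig]
        if not creg:
            continue
        L = reference.length(contig)
        reads = alignments_by_contig.get(contig, [])
        for a in reads:
            if a.end > L:
                raise ValueError(f"read {a.name} extends past end of {contig}")
        bf = np.zeros((4, L), dtype=np.int64)
        br = np.zeros((4, L), dtype=np.int64)
        qs = np.zeros((4, L), dtype=np.int64)
        ms = np.zeros((4, L), dtype=np.int64)
        nc = np.zeros(L, dtype=np.int64)
        ds = np.zeros(L, dtype=np.int64)
        ins: dict[int, dict[str, list[int]]] = {}
        dels: dict[int, dict[int, list[int]]] = {}
        batch = ReadBatch(reads)
        if len(batch.pos):
            # distance of each aligned base from its read's aligned extent
            n_reads = len(reads)
            min_off = np.full(n_reads, np.iinfo(np.int64).max, dtype=np.int64)
            max_off = np.full(n_reads, -1, dtype=np.int64)
            np.minimum.at(min_off, batch.read_idx, batch.read_off)
            np.maximum.at(max_off, batch.read_idx, batch.read_off)
            interior = ((batch.read_off >= min_off[batch.read_idx] + end_trim)
                        & (batch.read_off <= max_off[batch.read_idx] - end_trim))
            isn = (batch.base == 4) | ~interior
            nc += np.bincount(batch.pos[isn], minlength=L)
            ok = ~isn
            idx = batch.pos[ok] * 4 + batch.base[ok]
            fwd = batch.strand[ok] == 0
            bf += np.bincount(idx[fwd], minlength=4 * L).reshape(L, 4).T
            br += np.bincount(idx[~fwd], minlength=4 * L).reshape(L, 4).T
            qs += np.bincount(idx, weights=batch.qual[ok].astype(np.float64),
                              minlength=4 * L).reshape(L, 4).T.astype(np.int64)
            ms += np.bincount(idx, weights=batch.mapq[ok].astype(np.float64),
                              minlength=4 * L).reshape(L, 4).T.astype(np.int64)
        # indel events + anchor-base exclusivity
        live = [a for a in reads if not a.is_duplicate and a.has_indel()]
        for a in live:
            fwd = a.strand == "+"
            aligned = [q for q, op in _aligned_offsets(a)]
            lo = min(aligned) + end_trim if aligned else 0
            hi = max(aligned) - end_trim if aligned else -1
            rpos = a.start
            qpos = 0
            for op, l in a.ops:
                if op in ("M", "X"):
                    rpos += l
                    qpos += l
                elif op == "S":
                    qpos += l
                elif op == "I":
                    anchor = rpos - 1
                    if anchor >= 0:
                        seq = decode_bases(a.bases[qpos : qpos + l])
                        rec = ins.setdefault(anchor, {}).setdefault(seq, [0, 0, 0])
                        rec[0 if fwd else 1] += 1
                        rec[2] += int(a.quals[qpos : qpos + l].sum())
                        _remove_anchor_base(a, qpos, anchor, bf, br, qs, ms,
                                            nc, fwd, lo, hi)
                    qpos += l
                else:  # D
                    anchor = rpos - 1
                    if anchor >= 0:
                        rec = dels.setdefault(anchor, {}).setdefault(l, [0, 0])
                        rec[0 if fwd else 1] += 1
                        _remove_anchor_base(a, qpos, anchor, bf, br, qs, ms,
                                            nc, fwd, lo, hi)
                    ds[rpos : rpos + l] += 1
                    rpos += l
        for r in creg:
            p = ContigPileup(contig, r.start, r.end)
            sl = slice(r.start, r.end)
            p.base_fwd = np.minimum(bf[:, sl], COUNT_MAX).astype(np.uint32)
            p.base_rev = np.minimum(br[:, sl], COUNT_MAX).astype(np.uint32)
            p.qual_sum = np.minimum(qs[:, sl], COUNT_MAX).astype(np.uint32)
            p.mq_sum = np.minimum(ms[:, sl], COUNT_MAX).astype(np.uint32)
            p.n_count = np.minimum(nc[sl], COUNT_MAX).astype(np.uint32)
            p.del_span = np.minimum(ds[sl], COUNT_MAX).astype(np.uint32)
            p.insertions = {k: v for k, v in ins.items() if r.start <= k < r.end}
            p.deletions = {k: v for k, v in dels.items() if r.start <= k < r.end}
            pileups.append(p)
    return Snapshot(reference.checksum(),
                    {c: reference.length(c) for c in reference.contigs},
                    regions, pileups, wes=wes)


def _aligned_offsets(a: AlignedRead):
    """(read offset, op) of the first and last aligned base of each M/X run."""
    qpos = 0
    out = []
    for op, l in a.ops:
        if op in ("M", "X"):
            out.append((qpos, op))
            out.append((qpos + l - 1, op))
            qpos += l
        elif op in ("I", "S"):
            qpos += l
    return out


def _remove_anchor_base(a: AlignedRead, qpos: int, anchor: int,
                        bf, br, qs, ms, nc, fwd: bool,
                        lo: int, hi: int) -> None:
    """Undo the base-count contribution of the read base aligned at an indel
    anchor: that read is the event observation there, not a base observation.
    A trimmed (read-end) anchor base was counted in the other bucket instead."""
    if qpos == 0:
        return  # event at read start: the anchor base is not in this read
    off = qpos - 1
    b = int(a.bases[off])
    if b == 4 or not (lo <= off <= hi):
        if nc[anchor] > 0:
            nc[anchor] -= 1
        return
    arr = bf if fwd else br
    if arr[b, anchor] > 0:
        arr[b, anchor] -= 1
        qs[b, anchor] -= int(a.quals[off])
        ms[b, anchor] -= int(a.mapq)


# --- serialization -------------------------------------------------------

def _pack_block(p: ContigPileup, bs: int, be: int) -> bytes:
    sl = slice(bs - p.start, be - p.start)
    arrays = [p.base_fwd[:, sl], p.base_rev[:, sl], p.qual_sum[:, sl],
              p.mq_sum[:, sl], p.n_count[sl], p.del_span[sl]]
    raw = b"".join(np.ascontiguousarray(a, dtype=np.uint32).tobytes()
                   for a in arrays)
    events = {
        "ins": [[pos - bs, seq, v[0], v[1], v[2]]
                for pos, d in sorted(p.insertions.items()) if bs <= pos < be
                for seq, v in sorted(d.items())],
        "del": [[pos - bs, ln, v[0], v[1]]
                for pos, d in sorted(p.deletions.items()) if bs <= pos < be
                for ln, v in sorted(d.items())],
    }
    ev = json.dumps(events).encode()
    return struct.pack("<Q", len(raw)) + raw + ev


def _unpack_block(data: bytes, contig: str, bs: int, be: int) -> ContigPileup:
    n = be - bs
    (raw_len,) = struct.unpack_from("<Q", data, 0)
    raw = data[8 : 8 + raw_len]
    p = ContigPileup(contig, bs, be)
    sizes = [4 * n, 4 * n, 4 * n, 4 * n, n, n]
    off = 0
    out = []
    for s in sizes:
        out.append(np.frombuffer(raw, dtype=np.uint32, count=s,
                                 offset=off * 4).copy())
        off += s
    p.base_fwd = out[0].reshape(4, n)
    p.base_rev = out[1].reshape(4, n)
    p.qual_sum = out[2].reshape(4, n)
    p.mq_sum = out[3].reshape(4, n)
    p.n_count = out[4]
    p.del_span = out[5]
    events = json.loads(data[8 + raw_len :].decode())
    for rel, seq, f, r, q in events["ins"]:
        p.insertions.setdefault(rel + bs, {})[seq] = [f, r, q]
    for rel, ln, f, r in events["del"]:
        p.deletions.setdefault(rel + bs, {})[int(ln)] = [f, r]
    return p


def write_snapshot(snapshot: Snapshot, path) -> None:
    blocks = []
    index = []  # [region_idx, block_start, offset, comp_len, crc32]
    offset = 0
    for ri, (region, p) in enumerate(zip(snapshot.regions, snapshot.pileups)):
        bs = region.start
        while bs < region.end:
            be = min(bs + snapshot.block_size, region.end)
            payload = _pack_block(p, bs, be)
            comp = zlib.compress(payload, 6)
            index.append([ri, bs, offset, len(comp), zlib.crc32(payload)])
            blocks.append(comp)
            offset += len(comp)
            bs = be
    header = {
        "version": VERSION,
        "codec": "zlib",
        "block_size": snapshot.block_size,
        "reference_checksum": snapshot.reference_checksum,
        "contigs": [[c, l] for c, l in snapshot.contig_lengths.items()],
        "regions": [[r.contig, r.start, r.end] for r in snapshot.regions],
        "wes": snapshot.wes,
        "index": index,
    }
    hjson = json.dumps(header).encode()
    with open(path, "wb") as fh:
        fh.write(MAGIC)
        fh.write(struct.pack("<IQ", VERSION, len(hjson)))
        fh.write(hjson)
        for b in blocks:
            fh.write(b)


class SnapshotReader:
    """Random access into a snapshot file; decompresses only touched blocks."""

    def __init__(self, path):
        self.path = path
        self.blocks_read = 0
        with open(path, "rb") as fh:
            magic = fh.read(4)
            if magic != MAGIC:
                raise ValueError(f"{path}: not a snapshot file")
            version, hlen = struct.unpack("<IQ", fh.read(12))
            if version != VERSION:
                raise ValueError(f"{path}: unsupported snapshot version {version}")
            self.header = json.loads(fh.read(hlen).decode())
            self.data_start = 4 + 12 + hlen
        self.regions = [Region(c, s, e) for c, s, e in self.header["regions"]]
        self.contig_lengths = dict((c, l) for c, l in self.header["contigs"])
        self.block_size = self.header["block_size"]
        self.wes = self.header["wes"]
        self.checksum = self.header["reference_checksum"]

    def _read_block(self, entry) -> ContigPileup:
        ri, bs, offset, comp_len, crc = entry
        region = self.regions[ri]
        with open(self.path, "rb") as fh:
            fh.seek(self.data_start + offset)
            comp = fh.read(comp_len)
        try:
            payload = zlib.decompress(comp)
        except zlib.error as e:
            raise ValueError(
                f"{self.path}: corrupt block {region.contig}:{bs} "
                f"(region {ri}): {e}") from e
        if zlib.crc32(payload) != crc:
            raise ValueError(
                f"{self.path}: checksum mismatch in block "
                f"{region.contig}:{bs} (region {ri})")
        self.blocks_read += 1
        be = min(bs + self.block_size, region.end)
        return _unpack_block(payload, region.contig, bs, be)

    def read_region(self, region: Region) -> list[SnapshotColumn]:
        """Columns over a region; errors if any part is outside coverage."""
        cover = [r for r in self.regions if r.contig == region.contig
                 and r.start <= region.start and region.end <= r.end]
        if not cover:
            raise OutOfCoverageError(
                f"{region.contig}:{region.start}-{region.end} outside "
                "declared snapshot coverage")
        out = []
        for entry in self.header["index"]:
            ri, bs = entry[0], entry[1]
            r = self.regions[ri]
            be = min(bs + self.block_size, r.end)
            if r.contig != region.contig or be <= region.start or bs >= region.end:
                continue
            p = self._read_block(entry)
            for pos in range(max(bs, region.start), min(be, region.end)):
                out.append(p.column(pos))
        return out

    def query_position(self, contig: str, pos: int) -> SnapshotColumn:
        if contig not in self.contig_lengths:
            raise OutOfCoverageError(f"unknown contig {contig}")
        if not (0 <= pos < self.contig_lengths[contig]):
            raise OutOfCoverageError(f"{contig}:{pos} beyond contig length")
        for entry in self.header["index"]:
            ri, bs = entry[0], entry[1]
            r = self.regions[ri]
            be = min(bs + self.block_size, r.end)
            if r.contig == contig and bs <= pos < be:
                return self._read_block(entry).column(pos)
        raise OutOfCoverageError(f"{contig}:{pos} outside declared regions")

    def load(self) -> Snapshot:
        """Materialize the whole file back into an in-memory snapshot."""
        by_region: dict[int, list[ContigPileup]] = {}
        for entry in self.header["index"]:
            by_region.setdefault(entry[0], []).append(self._read_block(entry))
        pileups = []
        for ri, region in enumerate(self.regions):
            parts = by_region.get(ri, [])
            p = ContigPileup(region.contig, region.start, region.end)
            for part in parts:
                sl = slice(part.start - region.start, part.end - region.start)
                p.base_fwd[:, sl] = part.base_fwd
                p.base_rev[:, sl] = part.base_rev
                p.qual_sum[:, sl] = part.qual_sum
                p.mq_sum[:, sl] = part.mq_sum
                p.n_count[sl] = part.n_count
                p.del_span[sl] = part.del_span
                p.insertions.update(part.insertions)
                p.deletions.update(part.deletions)
            pileups.append(p)
        return Snapshot(self.checksum, self.contig_lengths, self.regions,
                        pileups, wes=self.wes, block_size=self.block_size)


def load_snapshot(path) -> Snapshot:
    return SnapshotReader(path).load()


def read_region(path, region: Region) -> list[SnapshotColumn]:
    return SnapshotReader(path).read_region(region)


def query_position(path, contig: str, pos: int) -> SnapshotColumn:
    return SnapshotReader(path).query_position(contig, pos)


def view_tsv(snapshot: Snapshot, region: Region, out) -> None:
    """Pileup-style TSV of a region for eyeballing."""
    out.write("contig\tpos\tdepth\tA\tC\tG\tT\tN\tdel_span\tins\tdel\n")
    for pos in range(region.start, region.end):
        col = snapshot.column(region.contig, pos)
        bc = col.base_counts
        ins = ";".join(f"{s}:{f}+{r}" for s, (f, r, _) in
                       sorted(col.insertions.items())) or "."
        dl = ";".join(f"{l}:{f}+{r}" for l, (f, r) in
                      sorted(col.deletions.items())) or "."
        out.write(f"{region.contig}\t{pos}\t{col.depth}\t{bc[0]}\t{bc[1]}\t"
                  f"{bc[2]}\t{bc[3]}\t{col.n_count}\t{col.del_span}\t{ins}\t{dl}\n")
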