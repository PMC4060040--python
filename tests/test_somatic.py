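import copy

import numpy as np
import pytest

from conftest import make_column
from snapcall.formats import Reference, Region
from snapcall.germline import PriorModel
from snapcall.snapshot import ContigPileup, Snapshot
from snapcall.somatic import (SomaticParams, call_cnv, call_somatic,
                              _binary_segment)


def _snapshot_from_columns(ref, columns):
    """Snapshot over one contig with hand-placed columns {pos: column}."""
    L = ref.length("c1")
    p = ContigPileup("c1", 0, L)
    for pos, col in columns.items():
        p.base_fwd[:, pos] = col.base_fwd
        p.base_rev[:, pos] = col.base_rev
        p.qual_sum[:, pos] = col.qual_sum
        p.mq_sum[:, pos] = col.mq_sum
        p.n_count[pos] = col.n_count
        p.del_span[pos] = col.del_span
        if col.insertions:
            p.insertions[pos] = {k: list(v) for k, v in col.insertions.items()}
        if col.deletions:
            p.deletions[pos] = {k: list(v) for k, v in col.deletions.items()}
    return Snapshot(ref.checksum(), {"c1": L}, [Region("c1", 0, L)], [p])


@pytest.fixture()
def ref():
    rng = np.random.default_rng(77)
    codes = rng.integers(0, 4, 60_000).astype(np.uint8)
    codes[500] = 0  # ref base A at the site under test
    return Reference({"c1": codes})


def _base_depth(ref, depth=30):
    """Columns giving every position `depth` reference-base reads."""
    L = ref.length("c1")
    p = ContigPileup("c1", 0, L)
    codes = ref.sequences["c1"]
    idx = np.arange(L)
    half = depth // 2
    p.base_fwd[codes, idx] = depth - half
    p.base_rev[codes, idx] = half
    p.qual_sum[codes, idx] = depth * 30
    p.mq_sum[codes, idx] = depth * 60
    return Snapshot(ref.checksum(), {"c1": L}, [Region("c1", 0, L)], [p])


class TestSomaticSnv:
    def test_clear_somatic_snv_called(self, ref):
        normal = _snapshot_from_columns(ref, {500: make_column((30, 0, 0, 0))})
        tumor = _snapshot_from_columns(ref, {500: make_column((15, 0, 15, 0))})
        calls = call_somatic(normal, tumor, ref)
        assert len(calls) == 1
        c = calls[0]
        assert (c.pos, c.ref, c.alt, c.vclass) == (500, "A", "G", "SNV")
        assert c.tumor_gt == "A/G" and c.normal_gt == "A/A"
        assert c.score >= 30
        assert c.tumor_alt_fraction == pytest.approx(0.5)

    def test_shared_germline_het_not_somatic(self, ref):
        het = {500: make_column((15, 0, 15, 0))}
        normal = _snapshot_from_columns(ref, het)
        tumor = _snapshot_from_columns(ref, het)
        assert call_somatic(normal, tumor, ref) == []

    def test_single_low_quality_alt_read_scores_below_threshold(self, ref):
        normal = _snapshot_from_columns(ref, {500: make_column((30, 0, 0, 0))})
        t = make_column((29, 0, 0, 0))
        t.base_fwd[2] = 1
        t.qual_sum[2] = 10  # one G read at Q10
        tumor = _snapshot_from_columns(ref, {500: t})
        assert call_somatic(normal, tumor, ref) == []

    def test_somatic_indel_called_with_shared_binding(self, ref):
        normal = _snapshot_from_columns(ref, {500: make_column((30, 0, 0, 0))})
        tumor = _snapshot_from_columns(
            ref, {500: make_column((15, 0, 0, 0), deletions={3: (8, 7)})})
        calls = call_somatic(normal, tumor, ref)
        assert len(calls) == 1
        assert calls[0].vclass == "DEL"
        assert calls[0].ref == ref.seq("c1", 500, 504)

    def test_normal_alt_contamination_filtered(self, ref):
        n = make_column((28, 0, 2, 0))   # 6.7% alt in normal
        t = make_column((15, 0, 15, 0))
        normal = _snapshot_from_columns(ref, {500: n})
        tumor = _snapshot_from_columns(ref, {500: t})
        assert call_somatic(normal, tumor, ref) == []

    def test_checksum_mismatch_rejected(self, ref):
        other = Reference({"c1": np.zeros(60_000, np.uint8)})
        normal = _snapshot_from_columns(ref, {})
        tumor = _snapshot_from_columns(other, {})
        with pytest.raises(ValueError, match="different references"):
            call_somatic(normal, tumor, ref)

    def test_identical_snapshots_yield_zero_calls(self, ref):
        rng = np.random.default_rng(3)
        cols = {}
        for pos in rng.integers(100, 59_000, 40):
            kind = rng.random()
            if kind < 0.5:
                cols[int(pos)] = make_column((15, 0, 15, 0))
            else:
                cols[int(pos)] = make_column((20, 0, 0, 0),
                                             deletions={2: (5, 5)})
        normal = _snapshot_from_columns(ref, cols)
        tumor = copy.deepcopy(normal)
        assert call_somatic(normal, tumor, ref) == []


class TestCnv:
    def _pair(self, ref, tumor_factor, seed=0, depth=35):
        rng = np.random.default_rng(seed)
        L = ref.length("c1")
        normal = _base_depth(ref, depth)
        tumor = _base_depth(ref, depth)
        nd = rng.poisson(depth, L)
        td = rng.poisson(depth * tumor_factor)
        codes = ref.sequences["c1"]
        idx = np.arange(L)
        pn, pt = normal.pileups[0], tumor.pileups[0]
        pn.base_fwd[:, :] = 0
        pn.base_rev[:, :] = 0
        pn.base_fwd[codes, idx] = nd
        pt.base_fwd[:, :] = 0
        pt.base_rev[:, :] = 0
        pt.base_fwd[codes, idx] = td
        return normal, tumor

    def test_equal_depths_give_single_neutral_segment(self, ref):
        rng = np.random.default_rng(1)
        L = ref.length("c1")
        factor = np.ones(L)
        normal, tumor = self._pair(ref, factor, seed=1)
        segs = call_cnv(normal, tumor, ref, window=1000)
        assert len(segs) == 1
        assert segs[0].state == "NEUTRAL"
        assert abs(segs[0].mean_log2) < 0.1
        assert (segs[0].start, segs[0].end) == (0, 60_000)

    def test_planted_gain_recovered_within_two_windows(self, ref):
        L = ref.length("c1")
        factor = np.ones(L)
        factor[20_000:35_000] = 1.5   # 3 copies: log2(1.5) ~ 0.585
        normal, tumor = self._pair(ref, factor, seed=2)
        segs = call_cnv(normal, tumor, ref, window=1000)
        gains = [s for s in segs if s.state == "GAIN"]
        assert len(gains) == 1
        g = gains[0]
        assert abs(g.start - 20_000) <= 2000 and abs(g.end - 35_000) <= 2000
        assert g.mean_log2 == pytest.approx(np.log2(1.5), abs=0.1)

    def test_hemizygous_loss_recovered(self, ref):
        L = ref.length("c1")
        factor = np.ones(L)
        factor[40_000:52_000] = 0.5   # one copy: log2 ratio -1
        normal, tumor = self._pair(ref, factor, seed=3)
        segs = call_cnv(normal, tumor, ref, window=1000)
        losses = [s for s in segs if s.state == "LOSS"]
        assert len(losses) == 1
        assert abs(losses[0].start - 40_000) <= 2000
        assert abs(losses[0].end - 52_000) <= 2000
        assert losses[0].mean_log2 == pytest.approx(-1.0, abs=0.15)

    def test_segments_tile_without_overlap(self, ref):
        L = ref.length("c1")
        factor = np.ones(L)
        factor[10_000:20_000] = 1.5
        factor[40_000:45_000] = 0.5
        normal, tumor = self._pair(ref, factor, seed=4)
        segs = sorted(call_cnv(normal, tumor, ref, window=1000),
                      key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            assert a.end == b.start
        assert segs[0].start == 0 and segs[-1].end == 60_000

    def test_too_few_windows_rejected(self):
        rng = np.random.default_rng(9)
        small = Reference({"c1": rng.integers(0, 4, 20_000).astype(np.uint8)})
        normal = _base_depth(small)
        tumor = _base_depth(small)
        with pytest.raises(ValueError, match="usable windows"):
            call_cnv(normal, tumor, small, window=1000)

    def test_low_normal_depth_windows_masked(self, ref):
        normal, tumor = self._pair(ref, np.ones(ref.length("c1")), seed=5)
        normal.pileups[0].base_fwd[:, :5000] = 0   # uncovered in normal
        segs = call_cnv(normal, tumor, ref, window=1000)
        assert min(s.start for s in segs) == 5000

    def test_binary_segmentation_finds_sharp_step(self):
        rng = np.random.default_rng(6)
        r = np.concatenate([rng.normal(0, 0.05, 60),
                            rng.normal(0.6, 0.05, 30),
                            rng.normal(0, 0.05, 60)])
        segs = _binary_segment(r, min_delta=0.2, alpha=1e-4)
        assert (0, 60) in segs and (60, 90) in segs and (90, 150) in segs
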