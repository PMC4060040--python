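import numpy as np
import pytest

from snapcall import dp
from snapcall.align import AlignedRead, AlignerParams, align_read, build_index
from snapcall.formats import Reference, decode_bases
from snapcall.realign import (RealignParams, RealignmentWindow, build_windows,
                              collect_hypotheses, realign, realign_window)


@pytest.fixture(scope="module", autouse=True)
def _warm():
    dp.warm_up()


def _read(name, start, bases, ops, strand="+", score=None):
    b = np.asarray(bases, dtype=np.uint8)
    nmis = sum(1 for op, _ in ops if op == "X")
    if score is None:
        score = sum(l for op, l in ops if op == "M") - 4 * nmis
    return AlignedRead(name=name, contig="c1", start=start, strand=strand,
                       ops=ops, bases=b, quals=np.full(len(b), 30, np.uint8),
                       score=score)


@pytest.fixture()
def ref():
    rng = np.random.default_rng(31)
    return Reference({"c1": rng.integers(0, 4, 2000).astype(np.uint8)})


class TestCollectHypotheses:
    def test_identical_events_merge_with_summed_support(self, ref):
        reads = [_read(f"r{i}", 100, ref.sequences["c1"][100:130],
                       [("M", 15), ("D", 2), ("M", 15)]) for i in range(3)]
        hyps = collect_hypotheses(reads, ref, min_support=2)
        assert len(hyps) == 1 and hyps[0].support == 3
        assert hyps[0].kind == "DEL"

    def test_single_read_below_min_support_dropped(self, ref):
        bases = np.concatenate([ref.sequences["c1"][100:115],
                                np.array([0, 1], np.uint8),
                                ref.sequences["c1"][115:130]])
        reads = [_read("r", 100, bases, [("M", 15), ("I", 2), ("M", 15)])]
        assert collect_hypotheses(reads, ref, min_support=2) == []
        assert len(collect_hypotheses(reads, ref, min_support=1)) == 1

    def test_homopolymer_deletions_normalize_to_one_anchor(self):
        # c1: ...C AAAA G...: deleting any single A is the same event
        seq = "ACGTC" + "AAAA" + "GTCAGCTTACG" * 4
        ref = Reference.from_strings({"c1": seq})
        reads = []
        for shift in (0, 1, 2):
            start = 0
            ops = [("M", 5 + shift + 1), ("D", 1), ("M", 20 - shift)]
            bases = np.concatenate([ref.sequences["c1"][:5 + shift + 1],
                                    ref.sequences["c1"][5 + shift + 2:][:20 - shift]])
            reads.append(_read(f"r{shift}", start, bases, ops))
        hyps = collect_hypotheses(reads, ref, min_support=2)
        assert len(hyps) == 1
        assert hyps[0].pos == 4 and hyps[0].ref == "CA" and hyps[0].alt == "C"
        assert hyps[0].support == 3

    def test_duplicate_reads_ignored(self, ref):
        reads = [_read(f"r{i}", 100, ref.sequences["c1"][100:130],
                       [("M", 15), ("D", 2), ("M", 15)]) for i in range(3)]
        for r in reads:
            r.is_duplicate = True
        assert collect_hypotheses(reads, ref) == []

    def test_clip_cluster_seeds_insertion_consensus(self, ref):
        ins = np.array([2, 2, 0, 3], np.uint8)  # GGAT inserted after pos 149
        reads = []
        for i in range(5):
            bases = np.concatenate([ref.sequences["c1"][120:150], ins])
            reads.append(_read(f"r{i}", 120, bases, [("M", 30), ("S", 4)]))
        hyps = collect_hypotheses(reads, ref, min_support=2, clip_support=4)
        assert any(h.kind == "INS" and "GGAT" in h.alt for h in hyps)


class TestRealignWindow:
    def _deletion_dataset(self, ref, del_pos=1000, del_len=2, n_reads=10):
        """Reads from a haplotype with a deletion, aligned against the ref."""
        idx = build_index(ref, k=16)
        hap = np.concatenate([ref.sequences["c1"][:del_pos + 1],
                              ref.sequences["c1"][del_pos + 1 + del_len:]])
        reads = []
        rng = np.random.default_rng(9)
        for i in range(n_reads):
            s = del_pos - 80 + int(rng.integers(0, 60))
            bases = hap[s:s + 100]
            cands = align_read(bases, np.full(100, 30, np.uint8), idx,
                               AlignerParams(), name=f"r{i}")
            reads.append(cands[0])
        return reads

    def test_true_deletion_recovered_with_score_increase(self, ref):
        reads = self._deletion_dataset(ref)
        hyps = collect_hypotheses(reads, ref, min_support=2)
        assert hyps, "aligner should nominate the deletion"
        windows = build_windows(hyps, ref, RealignParams())
        before = sum(r.score for r in reads)
        rep = realign_window(windows[0], reads, ref)
        after = sum(r.score for r in reads)
        assert rep["selected"] is not None
        assert after >= before
        # every read crossing the anchor now carries the deletion, cleanly
        for r in reads:
            if r.start < 1000 < r.end:
                assert ("D", 2) in r.ops
                assert not any(op == "X" for op, _ in r.ops)

    def test_realignment_is_idempotent(self, ref):
        reads = self._deletion_dataset(ref)
        hyps = collect_hypotheses(reads, ref, min_support=2)
        windows = build_windows(hyps, ref, RealignParams())
        realign_window(windows[0], reads, ref)
        state = [(r.start, list(r.ops), r.score) for r in reads]
        rep2 = realign_window(windows[0], reads, ref)
        assert rep2["rewritten"] == 0
        assert state == [(r.start, list(r.ops), r.score) for r in reads]

    def test_spurious_hypothesis_keeps_reference(self, ref):
        # clean reads plus a borderline 2-read artifact hypothesis
        reads = [_read(f"r{i}", 950 + 7 * i, ref.sequences["c1"]
                       [950 + 7 * i:1050 + 7 * i], [("M", 100)])
                 for i in range(10)]
        art = [_read(f"a{i}", 960, ref.sequences["c1"][960:1060],
                     [("M", 50), ("D", 1), ("M", 49)], score=30)
               for i in range(2)]
        # artificial D op not present in sequence: scoring must prefer ref
        for a in art:
            a.bases = ref.sequences["c1"][960:1060].copy()
        hyps = collect_hypotheses(reads + art, ref, min_support=2)
        assert hyps
        windows = build_windows(hyps, ref, RealignParams())
        rep = realign_window(windows[0], reads + art, ref)
        assert rep["selected"] is None and rep["rewritten"] == 0

    def test_read_not_overlapping_anchor_unchanged(self, ref):
        reads = self._deletion_dataset(ref)
        far = _read("far", 200, ref.sequences["c1"][200:300], [("M", 100)])
        hyps = collect_hypotheses(reads, ref, min_support=2)
        windows = build_windows(hyps, ref, RealignParams())
        before = (far.start, list(far.ops), far.score)
        realign_window(windows[0], reads + [far], ref)
        assert (far.start, list(far.ops), far.score) == before

    def test_full_pass_monotone_over_all_windows(self, ref):
        reads = self._deletion_dataset(ref)
        by_contig = {"c1": reads}
        before = sum(r.score for r in reads)
        reports = realign(by_contig, ref)
        after = sum(r.score for r in reads)
        assert after >= before
        for rep in reports:
            assert rep["score_after"] >= rep["score_before"]


class TestWindows:
    def test_windows_merge_and_split(self, ref):
        from snapcall.realign import IndelHypothesis

        hyps = [IndelHypothesis("c1", p, "AC", "A", 5)
                for p in (500, 520, 540, 1500)]
        windows = build_windows(hyps, ref, RealignParams())
        assert len(windows) == 2
        assert all(w.end - w.start <= RealignParams().max_window
                   for w in windows)

    def test_hypothesis_cap_keeps_best_supported(self, ref):
        from snapcall.realign import IndelHypothesis

        hyps = [IndelHypothesis("c1", 500 + i, "A" if i % 2 else "AC",
                                "AT" if i % 2 else "A", i + 1)
                for i in range(12)]
        windows = build_windows(hyps, ref, RealignParams(max_hypotheses=8))
        assert all(len(w.hypotheses) <= 8 for w in windows)
        supports = [h.support for w in windows for h in w.hypotheses]
        assert min(supports) >= 5  # the weakest were dropped
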