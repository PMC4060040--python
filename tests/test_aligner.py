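import numpy as np
import pytest

from snapcall import dp
from snapcall.align import (AlignedRead, AlignerParams, align_pairs,
                            align_read, build_index, pair_and_rescue)
from snapcall.formats import (ReadPair, Reference, decode_bases, encode_bases,
                              revcomp_codes)
from snapcall.simulate import SimProfile, make_reference, plant_variants, \
    simulate_reads


def brute_sw(read, window, match=1, mismatch=-4, open_ext=7, ext=1):
    """Independent affine-gap local alignment score, plain loops."""
    n, m = len(read), len(window)
    NEG = -10 ** 9
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if (read[i - 1] == window[j - 1] and read[i - 1] != 4) \
                else mismatch
            E[i][j] = max(H[i - 1][j] - open_ext, E[i - 1][j] - ext)
            F[i][j] = max(H[i][j - 1] - open_ext, F[i][j - 1] - ext)
            H[i][j] = max(0, H[i - 1][j - 1] + s, E[i][j], F[i][j])
            best = max(best, H[i][j])
    return best


class TestSeedIndex:
    def test_toy_kmer_positions(self):
        ref = Reference.from_strings({"c1": "ACGTACGT"})
        idx = build_index(ref, k=4)
        code = int(encode_bases("ACGT").astype(np.int64)
                   @ (4 ** np.arange(3, -1, -1)))
        assert sorted(idx.positions[code].tolist()) == [0, 4]

    def test_all_n_contig_has_no_entries(self):
        ref = Reference.from_strings({"c1": "N" * 50})
        idx = build_index(ref, k=8)
        assert len(idx.positions) == 0

    def test_homopolymer_kmer_flagged_repetitive(self):
        ref = Reference.from_strings({"c1": "A" * 100})
        idx = build_index(ref, k=8, max_occ=64)
        code = 0  # AAAAAAAA encodes to 0
        assert idx.repetitive[code] == 93  # 100 - 8 + 1 occurrences
        assert code not in idx.positions

    @pytest.mark.parametrize("k", [3, 33])
    def test_k_out_of_range(self, k):
        ref = Reference.from_strings({"c1": "ACGT" * 10})
        with pytest.raises(ValueError):
            build_index(ref, k=k)


@pytest.fixture(scope="module")
def random_ref():
    rng = np.random.default_rng(7)
    return Reference({"c1": rng.integers(0, 4, 5000).astype(np.uint8)})


@pytest.fixture(scope="module")
def ref_index(random_ref):
    dp.warm_up()
    return build_index(random_ref, k=16)


class TestAlignRead:
    def test_exact_read_aligns_uniquely(self, random_ref, ref_index):
        read = random_ref.sequences["c1"][100:200]
        quals = np.full(100, 30, dtype=np.uint8)
        cands = align_read(read, quals, ref_index, AlignerParams())
        assert cands[0].start == 100 and cands[0].strand == "+"
        assert cands[0].score == 100
        assert cands[0].ops == [("M", 100)]

    def test_reverse_complement_aligns_minus(self, random_ref, ref_index):
        read = revcomp_codes(random_ref.sequences["c1"][100:200])
        quals = np.full(100, 30, dtype=np.uint8)
        cands = align_read(read, quals, ref_index, AlignerParams())
        assert cands[0].start == 100 and cands[0].strand == "-"

    def test_single_substitution_scored_and_unique(self, random_ref, ref_index):
        read = random_ref.sequences["c1"][100:200].copy()
        read[50] = (read[50] + 1) % 4
        quals = np.full(100, 30, dtype=np.uint8)
        cands = align_read(read, quals, ref_index, AlignerParams())
        best = cands[0]
        assert (best.start, best.score) == (100, 95)
        assert best.ops == [("M", 50), ("X", 1), ("M", 49)]
        # exhaustive gapless scan confirms 100 is the unique optimum
        ref = random_ref.sequences["c1"]
        scores = [int((read == ref[s:s + 100]).sum()) * 5 - 400
                  for s in range(len(ref) - 100)]
        assert int(np.argmax(scores)) == 100

    def test_edit_script_reconstructs_read(self, random_ref, ref_index):
        rng = np.random.default_rng(3)
        ref = random_ref.sequences["c1"]
        for start in (250, 1000, 3000):
            hap = np.concatenate([ref[start:start + 40],
                                  ref[start + 42:start + 104]])  # 2bp deletion
            read = hap[:100].copy()
            read[rng.integers(0, 100)] = rng.integers(0, 4)
            cands = align_read(read, np.full(100, 30, np.uint8), ref_index,
                               AlignerParams())
            a = cands[0]
            rebuilt = []
            rpos, qpos = a.start, 0
            for op, l in a.ops:
                if op == "M":
                    rebuilt.append(ref[rpos:rpos + l])
                    rpos += l
                    qpos += l
                elif op == "X":
                    rebuilt.append(a.bases[qpos:qpos + l])
                    rpos += l
                    qpos += l
                elif op == "I":
                    rebuilt.append(a.bases[qpos:qpos + l])
                    qpos += l
                elif op == "D":
                    rpos += l
                else:  # S: excluded from reconstruction
                    rebuilt.append(a.bases[qpos:qpos + l])
                    qpos += l
            assert np.array_equal(np.concatenate(rebuilt), a.bases)
            assert sum(l for op, l in a.ops
                       if op in ("M", "X", "I", "S")) == 100

    def test_repeat_placement_gets_mapq_zero(self):
        rng = np.random.default_rng(11)
        codes = rng.integers(0, 4, 3000).astype(np.uint8)
        codes[1200:1400] = codes[200:400]  # exact 200 bp repeat
        ref = Reference({"c1": codes})
        idx = build_index(ref, k=16)
        read = codes[250:350]
        cands = align_read(read, np.full(100, 30, np.uint8), idx, AlignerParams())
        assert len(cands) >= 2 and cands[0].score == cands[1].score
        mate2 = align_read(revcomp_codes(codes[650:750]),
                           np.full(100, 30, np.uint8), idx, AlignerParams())
        a1, a2, _ = pair_and_rescue(cands, mate2, ref, AlignerParams())
        assert a1.mapq == 0  # two equal-scoring placements: ambiguous


class TestDpOracle:
    def test_kernel_matches_brute_force_smith_waterman(self):
        rng = np.random.default_rng(42)
        dp.warm_up()
        for _ in range(25):
            n = int(rng.integers(20, 120))
            m = int(rng.integers(n, 200))
            window = rng.integers(0, 4, m).astype(np.uint8)
            # read derived from the window with noise, or fully random
            if rng.random() < 0.7:
                s = int(rng.integers(0, m - n + 1))
                read = window[s:s + n].copy()
                for _ in range(int(rng.integers(0, 5))):
                    read[rng.integers(0, n)] = rng.integers(0, 4)
                if rng.random() < 0.5 and n > 30:
                    cut = int(rng.integers(5, n - 5))
                    read = np.concatenate([read[:cut], read[cut + 2:]])
            else:
                read = rng.integers(0, 4, n).astype(np.uint8)
            assert dp.sw_score(read, window) == brute_sw(read, window)
            score, w0, w1, opc, opl = dp.sw_align(read, window)
            assert score == brute_sw(read, window)

    def test_traceback_score_consistent_with_ops(self):
        rng = np.random.default_rng(1)
        window = rng.integers(0, 4, 150).astype(np.uint8)
        read = window[20:120].copy()
        read = np.concatenate([read[:50], rng.integers(0, 4, 2).astype(np.uint8),
                               read[50:]])  # 2bp insertion
        score, w0, w1, opc, opl = dp.sw_align(read, window)
        recomputed = 0
        for c, l in zip(opc, opl):
            ch = dp.OP_CHARS[c]
            if ch == "M":
                recomputed += l
            elif ch == "X":
                recomputed -= 4 * l
            elif ch in ("I", "D"):
                recomputed -= 6 + l
        assert recomputed == score


class TestPairing:
    def _mk(self, contig, start, strand, score, length=100):
        return AlignedRead(name="p", contig=contig, start=start, strand=strand,
                           ops=[("M", length)],
                           bases=np.zeros(length, np.uint8),
                           quals=np.full(length, 30, np.uint8), score=score)

    def test_proper_orientation_and_insert(self, random_ref):
        a1 = self._mk("c1", 1000, "+", 100)
        a2 = self._mk("c1", 1400, "-", 100)
        r1, r2, proper = pair_and_rescue([a1], [a2], random_ref, AlignerParams())
        assert proper and r1.properly_paired and r2.properly_paired

    def test_same_strand_not_proper(self, random_ref):
        a1 = self._mk("c1", 1000, "+", 100)
        a2 = self._mk("c1", 1400, "+", 100)
        _, _, proper = pair_and_rescue([a1], [a2], random_ref, AlignerParams())
        assert not proper

    def test_insert_outside_band_not_proper(self, random_ref):
        a1 = self._mk("c1", 1000, "+", 100)
        a2 = self._mk("c1", 2000, "-", 100)  # insert 1100 >> 500 + 4*25
        _, _, proper = pair_and_rescue([a1], [a2], random_ref, AlignerParams())
        assert not proper

    def test_seedless_mate_rescued_by_dp(self, random_ref, ref_index):
        ref = random_ref.sequences["c1"]
        b1 = ref[1000:1100].copy()
        # mate2 at insert 500, minus strand, with a mismatch every 12 bp so
        # that every 16-mer seed is broken but DP still aligns it
        true2 = ref[1400:1500].copy()
        for p in range(6, 100, 12):
            true2[p] = (true2[p] + 1) % 4
        b2 = revcomp_codes(true2)
        q = np.full(100, 30, np.uint8)
        c1 = align_read(b1, q, ref_index, AlignerParams())
        c2 = align_read(b2, q, ref_index, AlignerParams())
        assert c2 == []
        a1, a2, proper = pair_and_rescue(c1, c2, random_ref, AlignerParams(),
                                         read1=(b1, q), read2=(b2, q), name="p")
        assert proper and a2.start == 1400 and a2.strand == "-"

    def test_both_mates_empty_reported_unmapped(self, random_ref):
        assert pair_and_rescue([], [], random_ref, AlignerParams()) \
            == (None, None, False)


def test_error_free_pairs_align_to_true_origin(tmp_path):
    """>=99.9% of error-free pairs from unique sequence align to their origin."""
    ref = make_reference(20_000, seed=21)
    diploid = plant_variants(ref, snp_rate=0.0, indel_rate=0.0, seed=22)
    profile = SimProfile(depth=20.0, seed=23, err_start=0.0, err_end=0.0,
                         read_indel_rate=0.0, qual_jitter=0)
    fq1, fq2 = tmp_path / "e1.fq", tmp_path / "e2.fq"
    origin = simulate_reads(diploid, profile, fq1, fq2)
    from snapcall.formats import stream_fastq_pairs

    idx = build_index(ref, k=16)
    alignments = align_pairs(stream_fastq_pairs(fq1, fq2), idx)
    contig = ref.contigs[0]
    by_pair: dict[int, dict[int, AlignedRead]] = {}
    for a in alignments:
        by_pair.setdefault(a.pair_id, {})[a.mate] = a
    ok = 0
    n = origin.n_pairs(contig)
    for i in range(n):
        t1, t2 = origin.true_starts(contig, i)
        mates = by_pair.get(i, {})
        if (0 in mates and 1 in mates and mates[0].start == t1
                and mates[1].start == t2):
            ok += 1
    assert ok / n >= 0.999
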