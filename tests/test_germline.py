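import math

import numpy as np
import pytest

from conftest import make_column, random_column
from snapcall.formats import Reference
from snapcall.germline import (GENOTYPES, PriorModel, RFModel, call_site,
                               genotype_likelihoods, rf_filter, train_rf,
                               trio_conflicts)
from snapcall.variants import VariantCall

PRIORS = PriorModel()
PRIOR_M = PRIORS.log_prior_matrix()


def brute_force_posteriors(column, ref_code, prior_matrix):
    """Independent 16-genotype model: explicit loops over observations.

    Reconstructs the per-read observation list from the column (each base
    count expands to identical observations at the cell's mean quality) and
    evaluates every genotype with plain Python arithmetic.
    """
    observations = []  # (matching alleles, eps)
    base_q = None
    n_bases = int(column.base_counts.sum())
    if n_bases:
        base_q = min(max(float(column.qual_sum.sum()) / n_bases, 2), 60)
    events = []
    for seq, (f, r, qs) in column.insertions.items():
        n = f + r
        q = qs / (n * len(seq)) if n and len(seq) else 30.0
        events.append(("INS", seq, n, min(max(q, 2), 60)))
    for ln, (f, r) in column.deletions.items():
        events.append(("DEL", ln, f + r, base_q if base_q is not None else 30.0))
    events.sort(key=lambda e: (-e[2], e[0], str(e[1])))
    for b in range(4):
        c = int(column.base_counts[b])
        if c:
            q = float(column.qual_sum[b]) / c
            eps = min(max(10 ** (-q / 10), 1e-6), 0.75)
            observations.extend([({b}, eps)] * c)
    for rank, (kind, payload, n, q) in enumerate(events):
        eps = min(max(10 ** (-q / 10), 1e-6), 0.75)
        alleles = {4 + rank} if rank < 2 else set()
        observations.extend([(alleles, eps)] * n)
    # deletion spans are depth-only: no likelihood contribution
    n_ind = min(len(events), 2)
    logliks = []
    for a1, a2 in GENOTYPES:
        if (max(a1, a2) >= 4 and n_ind == 0) or (a2 == 5 and n_ind < 2):
            logliks.append(-math.inf)
            continue
        total = 0.0
        for alleles, eps in observations:
            p1 = (1 - eps) if a1 in alleles else eps / 3
            p2 = (1 - eps) if a2 in alleles else eps / 3
            total += math.log(0.5 * p1 + 0.5 * p2)
        logliks.append(total)
    logpost = [lp + lk for lp, lk in zip(prior_matrix[ref_code], logliks)]
    finite = [x for x in logpost if x > -math.inf]
    m = max(finite)
    z = sum(math.exp(x - m) for x in finite)
    post = [math.exp(x - m) / z if x > -math.inf else 0.0 for x in logpost]
    return np.array(logliks), np.array(post)


class TestGenotypeModel:
    def test_genotype_space_has_sixteen_entries(self):
        assert len(GENOTYPES) == 16
        assert len(set(GENOTYPES)) == 16
        col = make_column((5, 0, 3, 0), deletions={2: (2, 1)})
        state = genotype_likelihoods(col, 0, PRIORS)
        assert state.posteriors.shape == (16,)
        assert state.log_likelihoods.shape == (16,)

    def test_posteriors_normalize(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            col = random_column(rng)
            if col.depth == 0:
                continue
            state = genotype_likelihoods(col, int(rng.integers(0, 4)), PRIOR_M)
            assert abs(state.posteriors.sum() - 1.0) < 1e-9

    def test_matches_brute_force_oracle_on_random_columns(self):
        rng = np.random.default_rng(123)
        checked = 0
        for _ in range(1000):
            col = random_column(rng)
            if col.depth == 0:
                continue
            ref_code = int(rng.integers(0, 4))
            state = genotype_likelihoods(col, ref_code, PRIOR_M)
            bl, bp = brute_force_posteriors(col, ref_code, PRIOR_M)
            finite = np.isfinite(bl)
            assert np.allclose(state.log_likelihoods[finite], bl[finite],
                               atol=1e-9, rtol=1e-12)
            assert np.array_equal(np.isfinite(state.log_likelihoods), finite)
            assert np.allclose(state.posteriors, bp, atol=1e-9)
            checked += 1
        assert checked > 900

    def test_clean_homref_column_is_confident(self):
        col = make_column((10, 0, 0, 0), quals=30)  # ref A, 10x A @ Q30
        state = genotype_likelihoods(col, 0, PRIORS)
        assert GENOTYPES[state.argmax] == (0, 0)
        assert state.posteriors[state.argmax] > 0.999

    def test_balanced_het_snp_wins(self):
        col = make_column((6, 0, 6, 0), quals=30)  # A and G, 6 each
        state = genotype_likelihoods(col, 0, PRIORS)
        assert GENOTYPES[state.argmax] == (0, 2)

    def test_het_indel_beats_base_genotypes(self):
        col = make_column((5, 0, 0, 0), deletions={2: (3, 2)})
        state = genotype_likelihoods(col, 0, PRIORS)
        assert GENOTYPES[state.argmax] == (0, 4)
        assert state.events[0][:2] == ("DEL", 2)

    def test_without_indel_events_indel_genotypes_are_impossible(self):
        col = make_column((4, 4, 0, 0))
        state = genotype_likelihoods(col, 0, PRIORS)
        assert (state.posteriors[10:] == 0).all()
        assert not np.isfinite(state.log_likelihoods[10:]).any()

    def test_depth_zero_returns_none(self):
        assert genotype_likelihoods(make_column(), 0, PRIORS) is None

    def test_priors_sum_to_one_per_ref_base(self):
        M = PRIORS.log_prior_matrix()
        assert np.allclose(np.exp(M).sum(axis=1), 1.0)


REF = Reference.from_strings({"c1": "ACGTACGTAC" * 30})


class TestCallSite:
    def test_hom_ref_argmax_yields_no_call(self):
        col = make_column((20, 0, 0, 0))
        state = genotype_likelihoods(col, 0, PRIORS, "c1", 0)
        assert call_site(state, REF, col) is None

    def test_qual_is_phred_of_homref_posterior(self):
        col = make_column((6, 0, 6, 0), quals=30)
        state = genotype_likelihoods(col, 0, PRIORS, "c1", 0)
        state.posteriors[:] = 0
        state.posteriors[state.hom_ref_index()] = 1e-5
        state.posteriors[GENOTYPES.index((0, 2))] = 1 - 1e-5
        call = call_site(state, REF, col)
        assert call.qual == pytest.approx(50.0)

    def test_hom_insertion_expands_to_anchored_vcf_alleles(self):
        col = make_column(insertions={"GG": (5, 5, 600)})
        state = genotype_likelihoods(col, 0, PRIORS, "c1", 4)  # ref A at pos 4
        assert GENOTYPES[state.argmax] == (4, 4)
        call = call_site(state, REF, col)
        assert (call.pos, call.ref, call.alts) == (4, "A", ["AGG"])
        assert call.genotype_indices == (1, 1)

    def test_het_deletion_call(self):
        col = make_column((8, 0, 0, 0), deletions={2: (4, 4)})
        state = genotype_likelihoods(col, 0, PRIORS, "c1", 4)
        call = call_site(state, REF, col)
        assert call.ref == REF.seq("c1", 4, 7) and call.alts == ["A"]
        assert call.genotype_indices == (0, 1)

    def test_mixed_snp_indel_genotype_single_record(self):
        col = make_column((0, 0, 10, 0), insertions={"TT": (5, 5, 600)})
        state = genotype_likelihoods(col, 0, PRIORS, "c1", 4)
        assert GENOTYPES[state.argmax] == (2, 4)
        call = call_site(state, REF, col)
        assert call.ref == "A" and sorted(call.alts) == ["ATT", "G"]
        assert call.genotype_indices == (1, 2)


class _StubClassifier:
    classes_ = np.array([0, 1])

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return np.column_stack([1 - self.probs, self.probs])


def _call(qual, prob_slot=0):
    return VariantCall(contig="c1", pos=10 + prob_slot, ref="A", alts=["G"],
                       genotype_indices=(0, 1), qual=qual, depth=30,
                       alt_fractions=[0.5])


class TestRfFilter:
    def test_boundary_rules(self):
        calls = [_call(50.0, 0), _call(29.0, 1), _call(200.0, 2)]
        model = RFModel(_StubClassifier([0.96, 0.96, 0.94]),
                        features=RFModel.load.__defaults__ or [])
        model.features = list(model.features)
        filtered = rf_filter(calls, model)
        assert [c.filter_status for c in filtered] == \
            ["PASS", "LowQual", "RF_FAIL"]

    def test_exact_thresholds_inclusive(self):
        calls = [_call(30.0, 0), _call(29.999, 1)]
        model = RFModel(_StubClassifier([0.95, 0.95]), features=[])
        filtered = rf_filter(calls, model)
        assert filtered[0].filter_status == "PASS"
        assert filtered[1].filter_status == "LowQual"

    def test_missing_model_passes_through_unfiltered(self):
        calls = [_call(50.0)]
        out = rf_filter(calls, None)
        assert out[0].filter_status == "UNFILTERED" and out[0].rf_prob is None


def _labeled(n_per_class, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for label in (0, 1):
        for _ in range(n_per_class):
            qual = rng.uniform(200, 900) if (label and separable) \
                else rng.uniform(1, 60)
            c = VariantCall(contig="c1", pos=int(rng.integers(0, 10 ** 6)),
                            ref="A", alts=["G"], genotype_indices=(0, 1),
                            qual=float(qual), depth=int(rng.integers(10, 60)),
                            alt_fractions=[float(rng.uniform(0.2, 0.8))],
                            strand_bias=float(rng.uniform(0, 10)),
                            mean_mq=60.0, mean_alt_qual=30.0)
            out.append((c, label))
    return out


class TestTrainRf:
    def test_separable_data_reaches_perfect_oob(self):
        model = train_rf(_labeled(600), seed=1)
        assert model.oob_score == pytest.approx(1.0, abs=0.01)

    def test_shuffled_labels_give_chance_oob(self):
        rng = np.random.default_rng(5)
        scores = []
        for rep in range(10):
            data = _labeled(500, separable=False, seed=rep)
            labels = np.array([l for _, l in data])
            rng.shuffle(labels)
            model = train_rf([(c, int(l)) for (c, _), l in zip(data, labels)],
                             seed=rep, n_trees=50)
            scores.append(model.oob_score)
        assert abs(np.mean(scores) - 0.5) <= 0.05

    def test_same_seed_identical_model(self, tmp_path):
        import pickle

        m1 = train_rf(_labeled(500), seed=7, n_trees=50)
        m2 = train_rf(_labeled(500), seed=7, n_trees=50)
        assert pickle.dumps(m1.classifier) == pickle.dumps(m2.classifier)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            train_rf([(c, 1) for c, _ in _labeled(50)])

    def test_model_round_trip_with_schema_check(self, tmp_path):
        model = train_rf(_labeled(500), seed=2, n_trees=20)
        path = tmp_path / "rf.model"
        model.save(path)
        back = RFModel.load(path)
        assert back.oob_score == model.oob_score
        back.version = 99
        back.save(path)
        with pytest.raises(ValueError, match="incompatible"):
            RFModel.load(path)


def _gt_call(pos, ref, alts, gt, status="PASS"):
    return VariantCall(contig="c1", pos=pos, ref=ref, alts=list(alts),
                       genotype_indices=gt, qual=100, depth=30,
                       alt_fractions=[0.5] * len(alts), filter_status=status)


class TestTrioConflicts:
    def test_het_child_from_two_hom_parents_consistent(self):
        child = [_gt_call(10, "A", ["G"], (0, 1))]
        father = [_gt_call(10, "A", ["G"], (1, 1))]  # GG
        mother = []                                   # hom-ref AA
        conflicts, checked, rate = trio_conflicts(child, father, mother)
        assert (conflicts, checked) == (0, 1)

    def test_hom_alt_child_from_homref_parents_conflicts(self):
        child = [_gt_call(10, "A", ["G"], (1, 1))]
        conflicts, checked, rate = trio_conflicts(child, [], [])
        assert (conflicts, checked, rate) == (1, 1, 1.0)

    def test_het_child_with_unexplained_allele_conflicts(self):
        child = [_gt_call(10, "A", ["G"], (0, 1))]
        father = [_gt_call(10, "A", ["C"], (1, 1))]
        mother = [_gt_call(10, "A", ["C"], (1, 1))]
        conflicts, _, _ = trio_conflicts(child, father, mother)
        assert conflicts == 1

    def test_filter_status_respected_and_indels_ignored(self):
        child = [_gt_call(10, "A", ["G"], (0, 1), status="RF_FAIL"),
                 _gt_call(20, "A", ["AG"], (0, 1))]
        conflicts, checked, _ = trio_conflicts(child, [], [])
        assert checked == 0
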