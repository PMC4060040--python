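"""Germline calling with a 16-genotype diploid model over SNPs and indels.

At every site the caller enumerates exactly 16 genotypes: the 10 unordered
base pairs {AA, AC, AG, AT, CC, CG, CT, GG, GT, TT}, four base/indel
heterozygotes {A/I, C/I, G/I, T/I}, the homozygous indel I/I and the
compound heterozygote I1/I2, where I and I1/I2 bind to the best- and
second-best-supported indel events observed at the site.  SNPs and indels
therefore compete inside one likelihood rather than being called by separate
models.

Each read contributes one observation at a column: an aligned base, a
deletion span, or an indel event.  An observation o with error probability
eps (from the column's per-cell mean quality) has
P(o | allele a) = 1 - eps when o matches a and eps/3 otherwise, and a
genotype {a1, a2} sees the mixture (P(o|a1) + P(o|a2)) / 2.  Genotype
posteriors combine these likelihoods with a prior built from SNP
heterozygosity theta_snp = 1e-3, indel heterozygosity theta_indel = 1e-4 and
a 2:1 transition:transversion ratio.  QUAL is the phred-scaled posterior
mass of the homozygous-reference genotype.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp
from scipy.stats import fisher_exact

from .formats import Reference
from .snapshot import Snapshot, SnapshotColumn
from .variants import VariantCall, homopolymer_length, left_normalize

__all__ = ["GENOTYPES", "PriorModel", "GenotypeState", "genotype_likelihoods",
           "call_site", "call_snapshot", "rf_filter", "train_rf",
           "trio_conflicts", "RFModel"]

# allele codes: 0..3 = A,C,G,T; 4 = I (top indel event); 5 = I' (second)
BASE_GENOTYPES = [(0, 0), (0, 1), (0, 2), (0, 3), (1, 1), (1, 2), (1, 3),
                  (2, 2), (2, 3), (3, 3)]
GENOTYPES: list[tuple[int, int]] = BASE_GENOTYPES + [
    (0, 4), (1, 4), (2, 4), (3, 4), (4, 4), (4, 5)]
assert len(GENOTYPES) == 16

NEG_INF = -np.inf
_TRANSITION = {0: 2, 2: 0, 1: 3, 3: 1}
MIN_EPS = 1e-6
MAX_EPS = 0.75
DEFAULT_DEL_QUAL = 30.0


@dataclass
class PriorModel:
    """Genotype priors from per-site heterozygosities.

    het SNP prior theta_snp is split across the three alt bases with the
    transition twice as likely as either transversion; hom-alt takes
    theta/2 as usual; the hom-ref genotype absorbs the remainder.
    """

    theta_snp: float = 1e-3
    theta_indel: float = 1e-4
    ts_tv: float = 2.0

    def _weights(self, ref: int) -> dict[int, float]:
        ts = _TRANSITION[ref]
        wts = self.ts_tv / (self.ts_tv + 2.0)
        wtv = 1.0 / (self.ts_tv + 2.0)
        return {b: (wts if b == ts else wtv) for b in range(4) if b != ref}

    def log_prior_matrix(self) -> np.ndarray:
        """(4 ref bases, 16 genotypes) log prior table."""
        M = np.zeros((4, 16))
        for r in range(4):
            w = self._weights(r)
            pri = np.zeros(16)
            for gi, (a1, a2) in enumerate(GENOTYPES):
                if (a1, a2) == (r, r):
                    continue
                if a2 == 5:                       # I1/I2
                    pri[gi] = self.theta_indel ** 2
                elif a2 == 4 and a1 == 4:         # I/I
                    pri[gi] = self.theta_indel / 2
                elif a2 == 4:                     # base/I
                    pri[gi] = (self.theta_indel if a1 == r
                               else self.theta_snp * self.theta_indel * w[a1])
                elif a1 == a2:                    # hom alt
                    pri[gi] = self.theta_snp / 2 * w[a1]
                elif a1 == r or a2 == r:          # het ref/alt
                    b = a2 if a1 == r else a1
                    pri[gi] = self.theta_snp * w[b]
                else:                             # het alt/alt
                    pri[gi] = self.theta_snp ** 2 * w[a1] * w[a2]
            hom_ref = GENOTYPES.index((r, r))
            pri[hom_ref] = 1.0 - pri.sum()
            M[r] = np.log(pri)
        return M


@dataclass
class GenotypeState:
    contig: str
    pos: int
    ref_code: int
    log_likelihoods: np.ndarray       # (16,)
    posteriors: np.ndarray            # (16,) sum to 1
    events: list[tuple[str, object, int, float]]  # (kind, payload, count, qual)

    @property
    def argmax(self) -> int:
        return int(np.argmax(self.posteriors))

    def hom_ref_index(self) -> int:
        return GENOTYPES.index((self.ref_code, self.ref_code))


def _ranked_events(column: SnapshotColumn) -> list[tuple[str, object, int, float]]:
    """Indel events at the column, best-supported first.

    Each entry is (kind, payload, count, mean per-base quality); ties break
    deterministically on (kind, payload).
    """
    events = []
    base_q = _mean_base_qual(column)
    for seq, (f, r, qs) in column.insertions.items():
        n = f + r
        q = qs / (n * len(seq)) if n and len(seq) else DEFAULT_DEL_QUAL
        events.append(("INS", seq, n, float(np.clip(q, 2, 60))))
    for ln, (f, r) in column.deletions.items():
        events.append(("DEL", int(ln), f + r, base_q))
    events.sort(key=lambda e: (-e[2], e[0], str(e[1])))
    return events


def _mean_base_qual(column: SnapshotColumn) -> float:
    n = column.base_counts.sum()
    if n == 0:
        return DEFAULT_DEL_QUAL
    return float(np.clip(column.qual_sum.sum() / n, 2, 60))


def genotype_likelihoods(column: SnapshotColumn, ref_code: int,
                         priors: PriorModel | np.ndarray,
                         contig: str = "", pos: int = 0,
                         bound_events: list[tuple[str, object]] | None = None
                         ) -> GenotypeState | None:
    """Posterior over the 16 genotypes for one column; None when depth is 0.

    ``bound_events`` overrides which indel events the I and I' alleles bind
    to (used by the somatic caller so both samples share one binding); by
    default the column's own two best-supported events are bound.
    """
    if column.depth == 0:
        return None
    prior_m = priors if isinstance(priors, np.ndarray) else priors.log_prior_matrix()
    events = _ranked_events(column)
    if bound_events is None:
        rank_of = {(k, p): i for i, (k, p, _, _) in enumerate(events[:2])}
        n_ind = min(len(events), 2)
    else:
        rank_of = {key: i for i, key in enumerate(bound_events[:2])}
        n_ind = min(len(bound_events), 2)
    # observation batches: (count, eps, match_alleles)
    obs: list[tuple[int, float, frozenset[int]]] = []
    counts = column.base_counts
    for b in range(4):
        n = int(counts[b])
        if n == 0:
            continue
        q = column.qual_sum[b] / n
        eps = float(np.clip(10 ** (-q / 10), MIN_EPS, MAX_EPS))
        obs.append((n, eps, frozenset([b])))
    for kind, payload, n, q in events:
        eps = float(np.clip(10 ** (-q / 10), MIN_EPS, MAX_EPS))
        rank = rank_of.get((kind, payload))
        match = frozenset([4 + rank]) if rank is not None else frozenset()
        obs.append((n, eps, match))
    # deletion-span reads are shadows of deletions anchored at an upstream
    # column; they contribute to depth only.  Letting them vote for this
    # column's deletion alleles would let one stray mis-anchored event
    # inherit the full support of a neighbouring deletion.
    loglik = np.zeros(16)
    for gi, (a1, a2) in enumerate(GENOTYPES):
        # an indel allele only exists when a bound event backs it
        if (max(a1, a2) >= 4 and n_ind == 0) or (a2 == 5 and n_ind < 2):
            loglik[gi] = NEG_INF
            continue
        total = 0.0
        for n, eps, match in obs:
            p1 = (1 - eps) if a1 in match else eps / 3
            p2 = (1 - eps) if a2 in match else eps / 3
            total += n * np.log(0.5 * p1 + 0.5 * p2)
        loglik[gi] = total
    logpost = prior_m[ref_code] + loglik
    finite = np.isfinite(logpost)
    post = np.zeros(16)
    post[finite] = np.exp(logpost[finite] - logsumexp(logpost[finite]))
    return GenotypeState(contig, pos, ref_code, loglik, post, events)


def _phred(p: float) -> float:
    if p <= 0:
        return 10000.0
    return min(-10 * np.log10(p), 10000.0)


def _expand_allele(kind: str, payload, pos: int, seq: str) -> tuple[str, str]:
    """(ref, alt) strings at ``pos`` for an indel event (anchored)."""
    if kind == "DEL":
        return seq[pos : pos + payload + 1], seq[pos]
    return seq[pos], seq[pos] + payload


def call_site(state: GenotypeState, reference: Reference,
              column: SnapshotColumn) -> VariantCall | None:
    """Emit a VariantCall for a non-hom-ref argmax genotype, else None."""
    gi = state.argmax
    a1, a2 = GENOTYPES[gi]
    r = state.ref_code
    if (a1, a2) == (r, r):
        return None
    qual = _phred(float(state.posteriors[state.hom_ref_index()]))
    seq_str = reference.seq(state.contig)
    pos = state.pos
    depth = column.depth
    # assemble the allele set: a common REF window shared by all alts
    alt_specs = []  # (is_indel, ref, alt, support, mean_qual)
    for a in sorted(set((a1, a2))):
        if a == r:
            continue
        if a < 4:
            alt_specs.append((False, seq_str[pos], "ACGT"[a],
                              int(column.base_counts[a]),
                              column.qual_sum[a] / max(int(column.base_counts[a]), 1)))
        else:
            kind, payload, n, q = state.events[a - 4]
            ref_a, alt_a = _expand_allele(kind, payload, pos, seq_str)
            alt_specs.append((True, ref_a, alt_a, n, q))
    if not alt_specs:
        return None
    common_ref = max((s[1] for s in alt_specs), key=len)
    alts = []
    fractions = []
    mean_alt_q = []
    for is_indel, ref_a, alt_a, n, q in alt_specs:
        alts.append(alt_a + common_ref[len(ref_a):])
        fractions.append(n / depth if depth else 0.0)
        mean_alt_q.append(q)
    call_pos, call_ref = pos, common_ref
    if len(alts) == 1:
        call_pos, call_ref, alt0 = left_normalize(seq_str, pos, common_ref, alts[0])
        alts = [alt0]
    allele_index = {}
    idx = 1
    for a in sorted(set((a1, a2))):
        if a != r:
            allele_index[a] = idx
            idx += 1
    gt = tuple(sorted(allele_index.get(a, 0) for a in (a1, a2)))
    sb = _strand_bias(column, [a for a in (a1, a2) if a != r][0], state)
    mq = _mean_mq(column)
    return VariantCall(
        contig=state.contig, pos=call_pos, ref=call_ref, alts=alts,
        genotype_indices=gt, qual=qual, depth=depth,
        alt_fractions=fractions, strand_bias=sb, mean_mq=mq,
        mean_alt_qual=float(np.mean(mean_alt_q)),
        homopolymer_len=homopolymer_length(seq_str, call_pos))


def _strand_bias(column: SnapshotColumn, alt_allele: int,
                 state: GenotypeState) -> float:
    r = state.ref_code
    rf, rr = int(column.base_fwd[r]), int(column.base_rev[r])
    if alt_allele < 4:
        af, ar = int(column.base_fwd[alt_allele]), int(column.base_rev[alt_allele])
    else:
        kind, payload, _, _ = state.events[alt_allele - 4]
        if kind == "INS":
            f, rv, _ = column.insertions[payload]
        else:
            f, rv = column.deletions[payload]
        af, ar = int(f), int(rv)
    _, p = fisher_exact([[rf, rr], [af, ar]])
    return float(-10 * np.log10(max(p, 1e-300)))


def _mean_mq(column: SnapshotColumn) -> float:
    n = column.base_counts.sum()
    if n == 0:
        return 60.0
    return float(column.mq_sum.sum() / n)


# --- whole-snapshot calling (vectorized over non-indel candidate sites) ---

def call_snapshot(snapshot: Snapshot, reference: Reference,
                  priors: PriorModel | None = None) -> list[VariantCall]:
    """Call every covered position; returns calls sorted by (contig, pos).

    Sites without any non-reference base or indel evidence cannot leave the
    hom-ref argmax and are skipped.  Sites free of indel events are evaluated
    with a vectorized 10-genotype computation that is exactly the 16-genotype
    model restricted to its finite entries; indel-event sites run the full
    per-column model.
    """
    priors = priors or PriorModel()
    prior_m = priors.log_prior_matrix()
    calls: list[VariantCall] = []
    order = {c: i for i, c in enumerate(reference.contigs)}
    for p in snapshot.pileups:
        refc = reference.sequences[p.contig][p.start : p.end]
        counts = (p.base_fwd + p.base_rev).astype(np.int64)   # (4, n)
        total = counts.sum(axis=0)
        event_pos = set(p.insertions) | set(p.deletions)
        nonref = total - np.where(refc < 4, counts[np.minimum(refc, 3),
                                                   np.arange(len(refc))], 0)
        cand = np.flatnonzero((nonref > 0) & (refc < 4) & (total > 0))
        ev_rel = sorted(pos - p.start for pos in event_pos
                        if p.start <= pos < p.end and refc[pos - p.start] < 4)
        ev_set = set(ev_rel)
        plain = cand[~np.isin(cand, list(ev_set) or [-1])]
        calls.extend(_call_plain_sites(p, plain, refc, prior_m, reference))
        for rel in ev_rel:
            col = p.column(rel + p.start)
            if col.depth == 0:
                continue
            state = genotype_likelihoods(col, int(refc[rel]), prior_m,
                                         p.contig, rel + p.start)
            if state is None:
                continue
            c = call_site(state, reference, col)
            if c is not None:
                calls.append(c)
    calls.sort(key=lambda c: (order[c.contig], c.pos))
    _fill_nearest(calls)
    return calls


def _call_plain_sites(p, sites: np.ndarray, refc: np.ndarray,
                      prior_m: np.ndarray, reference: Reference
                      ) -> list[VariantCall]:
    """Vectorized 10-base-genotype posterior at indel-free candidate sites."""
    if len(sites) == 0:
        return []
    n = (p.base_fwd + p.base_rev)[:, sites].astype(np.float64)     # (4, s)
    qsum = p.qual_sum[:, sites].astype(np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        meanq = np.where(n > 0, qsum / np.maximum(n, 1), 30.0)
    eps = np.clip(10 ** (-meanq / 10), MIN_EPS, MAX_EPS)            # (4, s)
    log_match = np.log(1 - eps)
    log_mis = np.log(eps / 3)
    nb = len(BASE_GENOTYPES)
    loglik = np.zeros((nb, len(sites)))
    for gi, (a1, a2) in enumerate(BASE_GENOTYPES):
        for b in range(4):
            p1 = np.where(b == a1, 1 - eps[b], eps[b] / 3)
            p2 = np.where(b == a2, 1 - eps[b], eps[b] / 3)
            loglik[gi] += n[b] * np.log(0.5 * p1 + 0.5 * p2)
    logpost = prior_m[refc[sites], :nb].T + loglik                  # (10, s)
    Z = logsumexp(logpost, axis=0)
    post = np.exp(logpost - Z)
    gmax = np.argmax(post, axis=0)
    hom_ref_idx = np.array([BASE_GENOTYPES.index((r, r)) for r in range(4)])
    hri = hom_ref_idx[refc[sites]]
    emit = np.flatnonzero(gmax != hri)
    out = []
    for i in emit:
        rel = int(sites[i])
        col = p.column(rel + p.start)
        state = GenotypeState(p.contig, rel + p.start, int(refc[rel]),
                              np.concatenate([loglik[:, i],
                                              np.full(6, NEG_INF)]),
                              np.concatenate([post[:, i], np.zeros(6)]), [])
        c = call_site(state, reference, col)
        if c is not None:
            out.append(c)
    return out


def _fill_nearest(calls: list[VariantCall]) -> None:
    for i, c in enumerate(calls):
        best = 10 ** 9
        if i > 0 and calls[i - 1].contig == c.contig:
            best = min(best, c.pos - calls[i - 1].pos)
        if i + 1 < len(calls) and calls[i + 1].contig == c.contig:
            best = min(best, calls[i + 1].pos - c.pos)
        c.dist_nearest = best


# --- random-forest filtration -------------------------------------------

RF_FEATURES = ["qual", "depth", "alt_fraction", "strand_bias", "mean_mq",
               "mean_alt_qual", "homopolymer_len", "dist_nearest",
               "is_indel", "indel_len"]
RF_VERSION = 1


@dataclass
class RFModel:
    classifier: object
    features: list[str]
    version: int = RF_VERSION
    oob_score: float = float("nan")

    def save(self, path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"classifier": self.classifier, "features": self.features,
                         "version": self.version, "oob_score": self.oob_score}, fh)

    @classmethod
    def load(cls, path) -> "RFModel":
        with open(path, "rb") as fh:
            d = pickle.load(fh)
        if d["version"] != RF_VERSION or d["features"] != RF_FEATURES:
            raise ValueError("incompatible classifier model file")
        return cls(d["classifier"], d["features"], d["version"], d["oob_score"])


def call_features(call: VariantCall) -> list[float]:
    is_indel = any(c != "SNP" for c in call.classes)
    indel_len = max((abs(len(a) - len(call.ref)) for a in call.alts), default=0)
    return [min(call.qual, 10000.0), call.depth, max(call.alt_fractions),
            call.strand_bias, call.mean_mq, call.mean_alt_qual,
            call.homopolymer_len, min(call.dist_nearest, 10 ** 6),
            float(is_indel), float(indel_len)]


def train_rf(labeled_calls: list[tuple[VariantCall, int]], seed: int = 0,
             n_trees: int = 200) -> RFModel:
    """Train the filtration forest on (call, label) pairs; label 1 = true.

    Requires both classes present and at least 500 examples per class.
    """
    from sklearn.ensemble import RandomForestClassifier

    y = np.array([l for _, l in labeled_calls])
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    X = np.array([call_features(c) for c, _ in labeled_calls])
    clf = RandomForestClassifier(n_estimators=n_trees, oob_score=True,
                                 random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return RFModel(clf, RF_FEATURES, oob_score=float(clf.oob_score_))


def rf_filter(calls: list[VariantCall], model: RFModel | None,
              prob_threshold: float = 0.95, qual_threshold: float = 30.0
              ) -> list[VariantCall]:
    """Assign PASS / LowQual / RF_FAIL (probability and QUAL rule).

    PASS needs classifier probability >= 0.95 and QUAL >= 30; probability
    >= 0.95 with QUAL < 30 is LowQual; anything below the probability
    threshold is RF_FAIL.  Without a model calls pass through UNFILTERED.
    """
    if model is None:
        for c in calls:
            c.filter_status = "UNFILTERED"
            c.rf_prob = None
        return calls
    if not calls:
        return calls
    X = np.array([call_features(c) for c in calls])
    classes = list(model.classifier.classes_)
    probs = model.classifier.predict_proba(X)[:, classes.index(1)]
    for c, p in zip(calls, probs):
        c.rf_prob = float(p)
        if p >= prob_threshold:
            c.filter_status = "PASS" if c.qual >= qual_threshold else "LowQual"
        else:
            c.filter_status = "RF_FAIL"
    return calls


# --- trio ---------------------------------------------------------------

def _genotype_alleles(call: VariantCall) -> tuple[str, str]:
    alleles = [call.ref] + call.alts
    i, j = call.genotype_indices
    return alleles[i], alleles[j]


def trio_conflicts(child_calls: list[VariantCall],
                   father_calls: list[VariantCall],
                   mother_calls: list[VariantCall],
                   statuses: tuple[str, ...] = ("PASS", "UNFILTERED")
                   ) -> tuple[int, int, float]:
    """Mendelian conflicts among the child's passing SNPs.

    A site absent from a parent's call set is taken as homozygous reference.
    Returns (conflicts, child SNPs checked, conflict rate).
    """
    def snp_index(calls):
        idx = {}
        for c in calls:
            if all(cl == "SNP" for cl in c.classes):
                idx[(c.contig, c.pos)] = _genotype_alleles(c)
        return idx

    f_idx = snp_index(father_calls)
    m_idx = snp_index(mother_calls)
    conflicts = 0
    checked = 0
    for c in child_calls:
        if c.filter_status not in statuses:
            continue
        if any(cl != "SNP" for cl in c.classes):
            continue
        checked += 1
        key = (c.contig, c.pos)
        fa = f_idx.get(key, (c.ref, c.ref))
        mo = m_idx.get(key, (c.ref, c.ref))
        # consistent iff one allele from each parent composes the child genotype
        c1, c2 = _genotype_alleles(c)
        ok = any((f == c1 and m == c2) or (f == c2 and m == c1)
                 for f in fa for m in mo)
        if not ok:
            conflicts += 1
    rate = conflicts / checked if checked else 0.0
    return conflicts, checked, rate
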