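"""Label generation and training for the filtration forest.

Positives are unfiltered calls matching the planted truth of a fresh
simulation; negatives are calls absent from it.  Because unfiltered false
calls are rare on clean simulated reads, artifact examples are topped up by
a degraded companion simulation (higher error rate, no realignment), which
produces the misalignment-driven artifacts the filter is meant to catch.
"""

from __future__ import annotations

import os

import numpy as np

from .evaluate import match_calls
from .formats import write_fasta
from .germline import RFModel, train_rf
from .pipeline import PipelineConfig, run_germline
from .simulate import SimProfile, make_reference, plant_variants, simulate_reads
from .variants import VariantCall, left_normalize


def labeled_calls_from_simulation(length: int = 300_000, depth: float = 40.0,
                                  seed: int = 0, workdir: str = ".",
                                  err_scale: float = 1.0,
                                  realign: bool = True
                                  ) -> list[tuple[VariantCall, int]]:
    """One simulate->call round trip returning (call, is_true) pairs."""
    from .evaluate import load_vcf_calls

    ref = make_reference(length, seed=seed)
    fa = os.path.join(workdir, f"train_{seed}.fa")
    write_fasta(ref, fa)
    diploid = plant_variants(ref, seed=seed + 1)
    profile = SimProfile(depth=depth, seed=seed + 2,
                         err_start=0.001 * err_scale,
                         err_end=0.005 * err_scale)
    fq1 = os.path.join(workdir, f"train_{seed}_1.fq")
    fq2 = os.path.join(workdir, f"train_{seed}_2.fq")
    simulate_reads(diploid, profile, fq1, fq2)
    prefix = os.path.join(workdir, f"train_{seed}")
    config = PipelineConfig(reference=fa, fastq1=fq1, fastq2=fq2,
                            out_prefix=prefix, realign=realign, seed=seed)
    run_germline(config)
    calls = load_vcf_calls(prefix + ".vcf")
    seqs = {c: ref.seq(c) for c in ref.contigs}
    truth_keys = set()
    for v in diploid.truth.variants:
        truth_keys.add((v.contig,) + left_normalize(seqs[v.contig], v.pos,
                                                    v.ref, v.alt))
    labeled = []
    for c in calls:
        keys = [(c.contig,) + left_normalize(seqs[c.contig], p, r, a)
                for p, r, a in c.alleles()]
        labeled.append((c, int(any(k in truth_keys for k in keys))))
    for p in (fa, fq1, fq2, prefix + ".vcf", prefix + ".snapshot",
              prefix + ".report.json"):
        if os.path.exists(p):
            os.remove(p)
    return labeled


def train_from_simulation(length: int = 300_000, depth: float = 40.0,
                          seed: int = 0, workdir: str = ".") -> RFModel:
    """Train on a clean simulation plus a degraded one for artifact examples."""
    labeled = labeled_calls_from_simulation(length, depth, seed, workdir)
    labeled += labeled_calls_from_simulation(length // 2, depth, seed + 100,
                                             workdir, err_scale=4.0,
                                             realign=False)
    n_pos = sum(l for _, l in labeled)
    n_neg = len(labeled) - n_pos
    if min(n_pos, n_neg) < 500:
        raise ValueError(
            f"need >=500 examples per class, got {n_pos} true / {n_neg} artifact")
    return train_rf(labeled, seed=seed)
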