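import numpy as np
import pytest

from snapcall.evaluate import load_vcf_calls
from snapcall.formats import write_fasta
from snapcall.pipeline import PipelineConfig, run_germline
from snapcall.simulate import (SimProfile, make_reference, plant_variants,
                               simulate_reads)
from snapcall.snapshot import SnapshotColumn, load_snapshot


@pytest.fixture(scope="session")
def work(tmp_path_factory):
    return tmp_path_factory.mktemp("work")


@pytest.fixture(scope="session")
def sim_bundle(work):
    """An 80 kb diploid genome with planted SNPs+indels and 35x reads."""
    ref = make_reference(80_000, seed=11)
    fa = work / "ref.fa"
    write_fasta(ref, fa)
    diploid = plant_variants(ref, snp_rate=1e-3, indel_rate=1e-3, seed=12)
    fq1, fq2 = work / "sim_1.fq", work / "sim_2.fq"
    origin = simulate_reads(diploid, SimProfile(depth=35.0, seed=13), fq1, fq2)
    return {"reference": ref, "fasta": fa, "diploid": diploid,
            "origin": origin, "fq1": fq1, "fq2": fq2}


@pytest.fixture(scope="session")
def pipeline_run(sim_bundle, work):
    """Full germline pipeline over the shared simulation."""
    prefix = work / "run"
    config = PipelineConfig(reference=str(sim_bundle["fasta"]),
                            fastq1=str(sim_bundle["fq1"]),
                            fastq2=str(sim_bundle["fq2"]),
                            out_prefix=str(prefix))
    report = run_germline(config)
    return {"config": config, "report": report,
            "vcf": str(prefix) + ".vcf",
            "snapshot_path": str(prefix) + ".snapshot",
            "calls": load_vcf_calls(str(prefix) + ".vcf"),
            "snapshot": load_snapshot(str(prefix) + ".snapshot"),
            **sim_bundle}


def make_column(base_counts=(0, 0, 0, 0), quals=30.0, rev=None, mapq=60,
                n_count=0, del_span=0, insertions=None, deletions=None):
    """Hand-build a SnapshotColumn; counts split fwd/rev evenly unless given."""
    fwd = np.array(base_counts, dtype=np.uint32)
    if rev is None:
        rev = fwd // 2
        fwd = fwd - rev
    else:
        rev = np.array(rev, dtype=np.uint32)
    total = fwd + rev
    q = np.broadcast_to(np.asarray(quals, dtype=float), (4,))
    return SnapshotColumn(
        base_fwd=fwd, base_rev=rev,
        qual_sum=(total * q).astype(np.uint32),
        mq_sum=(total * mapq).astype(np.uint32),
        n_count=n_count, del_span=del_span,
        insertions=insertions or {}, deletions=deletions or {})


def random_column(rng: np.random.Generator, with_indels: bool = True
                  ) -> SnapshotColumn:
    counts = rng.integers(0, 25, 4)
    quals = rng.integers(5, 45, 4).astype(float)
    ins, dels, span = {}, {}, 0
    if with_indels and rng.random() < 0.6:
        for _ in range(rng.integers(1, 3)):
            if rng.random() < 0.5:
                seq = "".join(rng.choice(list("ACGT"), rng.integers(1, 5)))
                f, r = int(rng.integers(0, 9)), int(rng.integers(0, 9))
                if f + r:
                    ins[seq] = (f, r, int((f + r) * len(seq) * rng.integers(10, 40)))
            else:
                ln = int(rng.integers(1, 6))
                f, r = int(rng.integers(0, 9)), int(rng.integers(0, 9))
                if f + r:
                    dels[ln] = (f, r)
        span = int(rng.integers(0, 10))
    fwd = rng.binomial(counts, 0.5)
    return SnapshotColumn(
        base_fwd=fwd.astype(np.uint32),
        base_rev=(counts - fwd).astype(np.uint32),
        qual_sum=(counts * quals).astype(np.uint32),
        mq_sum=(counts * 60).astype(np.uint32),
        n_count=int(rng.integers(0, 3)), del_span=span,
        insertions=ins, deletions=dels)
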