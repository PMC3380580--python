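import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

sys.path.insert(0, str(Path(__file__).parent))

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_transcript_set(rng, max_tx=50, genome=100_000):
    """Random transcript models on one small chromosome (both strands)."""
    from genebody.annotation import TranscriptModel
    from genebody.intervals import GenomicInterval

    n = int(rng.integers(1, max_tx + 1))
    out = []
    for i in range(n):
        start = int(rng.integers(0, genome - 200))
        length = int(rng.integers(50, min(5000, genome - start)))
        strand = "+" if rng.random() < 0.5 else "-"
        span = GenomicInterval("chrT", start, start + length, strand)
        if length >= 300 and rng.random() < 0.5:
            cut1 = start + int(rng.integers(50, length // 2))
            cut2 = start + int(rng.integers(length // 2 + 50, length))
            exons = (
                GenomicInterval("chrT", start, cut1, strand),
                GenomicInterval("chrT", cut2, start + length, strand),
            )
        else:
            exons = (span,)
        out.append(TranscriptModel(f"tx{i}", span, exons))
    return out


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """One small simulated dataset plus a full pipeline run, shared read-only."""
    from genebody import RunConfig, SimConfig, run_all, simulate_all

    out = tmp_path_factory.mktemp("sim_small")
    config = SimConfig(n_genes=250, seed=11)
    sim = simulate_all(config, out / "data")
    run_config = RunConfig(
        transcripts=str(sim.files["transcripts"]),
        meth=str(sim.files["meth"]),
        expr=str(sim.files["expr"]),
        chrom_sizes=str(sim.files["sizes"]),
        cage=str(sim.files["cage"]),
        pol2=str(sim.files["pol2"]),
        dhss=str(sim.files["dhss"]),
        out_dir=str(out / "run"),
    )
    result = run_all(run_config)
    return {"config": config, "sim": sim, "run_config": run_config, "result": result}


TINY_BED12 = "\n".join(
    [
        # two-exon transcript: exons [100,300) and [700,900), intron [300,700)
        "chr1\t100\t900\ttxA\t0\t+\t100\t100\t0\t2\t200,200\t0,600",
        # overlaps txA -> same locus
        "chr1\t800\t1500\ttxB\t0\t+\t800\t800\t0\t1\t700\t0",
        # separate locus on the minus strand
        "chr1\t5000\t9000\ttxC\t0\t-\t5000\t5000\t0\t2\t1000,1000\t0,3000",
        # second chromosome, single exon
        "chr2\t0\t2500\ttxD\t0\t+\t0\t0\t0\t1\t2500\t0",
    ]
) + "\n"


@pytest.fixture
def tiny_transcripts():
    from genebody.annotation import read_transcripts

    return read_transcripts(TINY_BED12)


@pytest.fixture
def cpg_index():
    """Hand-laid CpG sites on two chromosomes."""
    from genebody.methylation import CpGIndex

    df = pd.DataFrame(
        {
            "chrom": ["chr1"] * 6 + ["chr2"] * 2,
            "start": [10, 50, 150, 250, 800, 950, 5, 40],
            "end": [11, 51, 151, 251, 801, 951, 6, 41],
            "percent": [50.0, 100.0, 20.0, 20.0, 20.0, 60.0, 80.0, 80.0],
            "coverage": [10, 5, 8, 7, 9, 3, 4, 4],
        }
    )
    return CpGIndex(df)
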