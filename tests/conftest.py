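import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from rloopkit.core import FragmentSet, GeneModel
from rloopkit.pipeline import run_pipeline
from rloopkit.simulate import SimConfig, simulate_dataset


def make_fragments(rows, sample_id="s"):
    """rows: (chrom, start, end, strand[, score]) tuples."""
    recs = []
    for r in rows:
        chrom, start, end, strand = r[:4]
        score = r[4] if len(r) > 4 else 30
        recs.append((chrom, start, end, strand, score))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end", "strand", "score"])
    return FragmentSet(sample_id, df)


@pytest.fixture(scope="session")
def default_dataset():
    """The standard desk-scale synthetic experiment (seed 7)."""
    return simulate_dataset(SimConfig(seed=7))


@pytest.fixture(scope="session")
def default_result(default_dataset):
    ds = default_dataset
    return run_pipeline(ds.treatments, ds.controls, ds.truth.chrom_sizes)


@pytest.fixture
def toy_genes():
    """Two genes on chr1 (one per strand, minus one a pseudogene) for
    hand-checkable annotation windows."""
    return [
        GeneModel("gA", "chr1", "+", 10000, 20000, exons=[(10000, 12000), (15000, 20000)]),
        GeneModel("gB", "chr1", "-", 40000, 50000, exons=[(40000, 50000)], biotype="pseudogene"),
    ]


@pytest.fixture
def toy_sizes():
    return {"chr1": 100000, "chr2": 50000}


def rng(seed=0):
    return np.random.default_rng(seed)
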