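import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from spikecut.core import FeatureCatalog, FragmentSet, GenomeLayout, PeakSet
from spikecut.simulate import SimulationConfig, generate_layout_and_catalog

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def layout():
    return GenomeLayout({"chr1": 100_000, "chr2": 50_000, "spike": 10_000}, {"spike"})


@pytest.fixture
def small_sim_config():
    """A scaled-down simulation for fast end-to-end tests."""
    return SimulationConfig(
        seed=11,
        contigs={"chr1": 500_000},
        n_sites=50,
        n_genes=30,
        n_enhancers=40,
        n_blacklist=4,
    )


@pytest.fixture
def small_dataset(small_sim_config):
    return generate_layout_and_catalog(small_sim_config)


def make_peakset(intervals, sample_id="test"):
    """PeakSet from bare (contig, start, end) tuples with dummy statistics."""
    df = pd.DataFrame(intervals, columns=["contig", "start", "end"])
    df["count"] = 10
    df["lam"] = 1.0
    df["fold"] = 10.0
    df["p"] = 1e-9
    return PeakSet(sample_id=sample_id, df=df)


def make_fragments(layout, triples, sample_id="frags"):
    triples = list(triples)
    return FragmentSet(
        sample_id=sample_id,
        contigs=np.array([t[0] for t in triples], dtype="U64"),
        starts=np.array([t[1] for t in triples], dtype=np.int64),
        ends=np.array([t[2] for t in triples], dtype=np.int64),
        layout=layout,
    )
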