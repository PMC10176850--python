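import pytest
from hypothesis import settings

from m5ckit import pipeline, simulate

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def transcriptome():
    """4 transcripts + 2 spike-ins, 600 bp, balanced GC."""
    return simulate.make_transcriptome(4, length=600, gc_fraction=0.5,
                                       n_spikeins=2, seed=7)


@pytest.fixture(scope="session")
def cluster_truth(transcriptome):
    """Truth map with a planted 3-C cluster: unmethylated in EV, 0.8 restored."""
    txs = list(transcriptome)
    truth = simulate.assign_truth(txs, seed=7)
    tx, start = pipeline._ensure_cluster(txs, 7)
    positions = simulate.plant_cluster(truth, tx, start, {"EV": 0.0, "NSUN7": 0.8})
    return txs, truth, tx, positions
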