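import numpy as np
import pytest

from tfrank.intervals import GenomicInterval
from tfrank.io import MotifModel
from tfrank.simulate import ScenarioConfig, generate_scenario
from tfrank.config_io import write_scenario_config


def make_interval(chrom="chr1", start=0, end=100, **kw):
    return GenomicInterval(chrom, start, end, **kw)


@pytest.fixture
def uniform_motif():
    return MotifModel("UNI", np.full((8, 4), 0.25))


@pytest.fixture
def sharp_motif():
    """8-bp motif strongly preferring the consensus ACGTACGT."""
    consensus = [0, 1, 2, 3, 0, 1, 2, 3]
    m = np.full((8, 4), 0.05)
    m[np.arange(8), consensus] = 0.85
    return MotifModel("SHARP", m)


@pytest.fixture(scope="session")
def signal_scenario(tmp_path_factory):
    """One signal scenario (planted driver TF01), shared across tests."""
    root = tmp_path_factory.mktemp("scenario")
    scenario = generate_scenario(ScenarioConfig(seed=11), root)
    write_scenario_config(scenario)
    return scenario


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory):
    path = tmp_path_factory.mktemp("fa") / "toy.fa"
    path.write_text(">chr1\nACGTAACC\n>chr2\nacgttttt\n")
    return path
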