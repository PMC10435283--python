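import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from orthobridge import build_graph, generate_fta1_fixture, generate_toy_dataset


@pytest.fixture(scope="session")
def fta1_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("fta1") / "data"
    return generate_fta1_fixture(out, seed=1)


@pytest.fixture(scope="session")
def fta1_graph(fta1_dataset):
    return build_graph(fta1_dataset.directory)


@pytest.fixture(scope="session")
def toy_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("toy") / "data"
    return generate_toy_dataset(
        out, n_species=2, genes_per_chromosome=60, n_blocks=2, noise_rate=0.15, seed=7
    )


@pytest.fixture(scope="session")
def toy_graph(toy_dataset):
    return build_graph(toy_dataset.directory)
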