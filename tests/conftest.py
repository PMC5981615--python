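import sys
from pathlib import Path

import networkx as nx
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for _oracles

from slnet.graphcore import SignalingNetwork
from slnet.pipeline import PipelineConfig, run_all
from slnet.synthfix import make_bundle


@pytest.fixture
def path3():
    """A-B-C path, no cancer labels."""
    return SignalingNetwork(graph=nx.path_graph(["A", "B", "C"]))


@pytest.fixture
def c5_net():
    """5-cycle with node 'N0' labeled cancer."""
    G = nx.relabel_nodes(nx.cycle_graph(5), {i: f"N{i}" for i in range(5)})
    return SignalingNetwork(graph=G, cancer_genes=frozenset(["N0"]))


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic fixture: 200 nodes, 20 cancer genes, 5 planted
    bridge pairs, seed 1."""
    return make_bundle(seed=1)


@pytest.fixture(scope="session")
def pipeline_run(default_bundle, tmp_path_factory):
    """One full pipeline run (n_random=100, seed 1) over the default
    bundle, shared across tests; returns (bundle, outdir, stage counts)."""
    base = tmp_path_factory.mktemp("e2e")
    bdir = base / "bundle"
    outdir = base / "run"
    paths = default_bundle.write(bdir)
    config = PipelineConfig.from_yaml(paths["config"])
    assert config.n_random == 100
    counts = run_all(config, outdir)
    return default_bundle, outdir, counts
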