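import numpy as np
import pandas as pd
import pytest

from boolpath import GAConfig, SignedDiGraph, SimulationConfig

KGML_SIMPLE = """<?xml version="1.0"?>
<pathway name="path:toy01" org="hsa" number="01" title="Toy pathway">
  <entry id="1" name="hsa:101" type="gene"><graphics name="A, A1"/></entry>
  <entry id="2" name="hsa:102" type="gene"><graphics name="B"/></entry>
  <entry id="3" name="hsa:103" type="gene"><graphics name="C"/></entry>
  <relation entry1="1" entry2="2" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="2" entry2="3" type="PPrel">
    <subtype name="inhibition" value="--|"/>
  </relation>
</pathway>
"""

KGML_GROUP = """<?xml version="1.0"?>
<pathway name="path:toy02" org="hsa" number="02" title="Group pathway">
  <entry id="1" name="hsa:201" type="gene"><graphics name="X"/></entry>
  <entry id="2" name="hsa:202" type="gene"><graphics name="Y"/></entry>
  <entry id="3" name="hsa:203" type="gene"><graphics name="Z"/></entry>
  <entry id="4" name="undefined" type="group">
    <component id="1"/><component id="2"/>
  </entry>
  <relation entry1="3" entry2="4" type="PPrel">
    <subtype name="activation" value="--&gt;"/>
  </relation>
  <relation entry1="1" entry2="3" type="PPrel">
    <subtype name="binding/association" value="---"/>
  </relation>
</pathway>
"""


@pytest.fixture
def kgml_simple() -> str:
    return KGML_SIMPLE


@pytest.fixture
def kgml_group() -> str:
    return KGML_GROUP


@pytest.fixture
def chain_graph() -> SignedDiGraph:
    """A -> B -> C (both activating)."""
    g = SignedDiGraph()
    g.add_nodes_from("ABC")
    g.add_signed_edge("A", "B", 1)
    g.add_signed_edge("B", "C", 1)
    return g


@pytest.fixture
def feed_forward_graph() -> SignedDiGraph:
    """A -> B, A -> C, B -> C (all activating)."""
    g = SignedDiGraph()
    g.add_nodes_from("ABC")
    g.add_signed_edge("A", "B", 1)
    g.add_signed_edge("A", "C", 1)
    g.add_signed_edge("B", "C", 1)
    return g


@pytest.fixture
def fast_sim() -> SimulationConfig:
    """Reduced ensemble for cheap in-test simulations."""
    return SimulationConfig(runs=200, steps=20, tail=5)


@pytest.fixture
def fast_ga() -> GAConfig:
    return GAConfig(population=24, generations=5, ga_runs=40, seed=0)


def uniform_probs(graph, n_samples, seed=0) -> pd.DataFrame:
    nodes = sorted(graph.nodes)
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        rng.random((len(nodes), n_samples)),
        index=nodes,
        columns=[f"s{i}" for i in range(n_samples)],
    )
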