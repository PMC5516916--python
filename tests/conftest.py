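import networkx as nx
import pytest

from stressnet.map_model import (
    MolecularMap,
    Reaction,
    Species,
    assign_gene_symbols,
)
from stressnet.synthetic import MapGenParams, gen_stress_map


def build_map(species, reactions, stimuli=(), mrnas=(), name="fixture"):
    m = MolecularMap(
        name=name, species=list(species), reactions=list(reactions),
        stimuli=set(stimuli), mrnas=set(mrnas),
    )
    assign_gene_symbols(m)
    m.validate()
    return m


@pytest.fixture
def fig_reaction_map():
    """One state transition: m1 → m2 catalyzed by m3."""
    return build_map(
        [
            Species(id="m1", name="M1", entity_class="protein"),
            Species(id="m2", name="M2", entity_class="protein"),
            Species(id="m3", name="M3", entity_class="protein"),
        ],
        [
            Reaction(id="re1", reaction_class="state_transition",
                     reactants=["m1"], products=["m2"],
                     modifiers=[("m3", "positive")]),
        ],
    )


@pytest.fixture
def chain_graph():
    return nx.DiGraph([("S", "a"), ("a", "T")])


@pytest.fixture
def diamond_graph():
    return nx.DiGraph([("S", "a"), ("a", "T"), ("S", "b"), ("b", "T")])


@pytest.fixture(scope="session")
def default_map():
    """One generated map under the default study conditions."""
    return gen_stress_map(MapGenParams(seed=0))


@pytest.fixture(scope="session")
def module_map():
    """Small map with a reversible-inhibitor module on every core node."""
    return gen_stress_map(MapGenParams(
        n_stimuli=4, n_targets=8, core_size=8, n_intermediates=10,
        edge_density=0.4, p_complex=0.0,
        p_reversible_inhibitor=1.0, seed=3,
    ))
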