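"""Shared fixtures: toy networks, ortholog tables and screen data.

Everything is built programmatically — the only packaged data file is the
transcribed published hit table inside the package itself.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from yana.network_analysis import PPINetwork
from yana.ortholog_map import OrthologTable
from yana.screen_io import ColonyGrid
from yana.synthetic_data import ScreenSimConfig, simulate_screen


def build_network(
    edges, species: str = "pombe", nodes=(), confidence: float = 0.95
) -> PPINetwork:
    """PPINetwork from bare (u, v) pairs, every edge at one confidence."""
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, confidence=confidence)
    return PPINetwork(species, g)


@pytest.fixture
def toy_full_network() -> PPINetwork:
    """Whole-genome stand-in: hits A..D, neighbor N bridging A and D."""
    return build_network(
        [("A", "B"), ("B", "C"), ("A", "N"), ("N", "D"), ("D", "E")]
    )


@pytest.fixture
def ortholog_tables() -> list[OrthologTable]:
    """Two curated sources that disagree on one gene's co-orthologs."""
    return [
        OrthologTable("dbA", {"g1": {"A"}, "g2": {"A", "B"}, "g3": {"C"}}),
        OrthologTable("dbB", {"g1": {"A"}, "g2": {"A"}}),
    ]


@pytest.fixture(scope="session")
def small_screen():
    """400-gene simulated screen with 10 planted SL and 10 planted SS."""
    genes = ScreenSimConfig(n_genes=400).gene_ids()
    config = ScreenSimConfig(
        n_genes=400,
        planted_sl=frozenset(genes[:10]),
        planted_ss=frozenset(genes[10:20]),
        seed=42,
    )
    grids, strain_map, truth = simulate_screen(config)
    return config, grids, strain_map, truth


def make_grid(sizes, plate="p1", condition="inducing", day=1) -> ColonyGrid:
    """384-format grid whose leading entries are ``sizes`` (rest zero)."""
    mat = np.zeros((16, 24))
    flat = mat.reshape(-1)
    flat[: len(sizes)] = sizes
    return ColonyGrid(plate, condition, day, mat)
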