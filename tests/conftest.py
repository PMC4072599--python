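"""Shared fixtures: small simulated datasets and their reduced graphs."""

import itertools

import numpy as np
import pytest

from bayesasm import graph as graph_mod
from bayesasm import read_io, simulate
from bayesasm.state import AssemblyState, validate


@pytest.fixture(scope="session")
def small_truth():
    """600 bp circular genome, 2 variant sites, error-free reads."""
    return simulate.simulate_truth(
        1,
        length=600,
        n_variants=2,
        min_spacing=200,
        n_pairs=300,
        read_length=60,
        insert_mean=90,
        insert_sd=10,
        error_rate=0.0,
    )


@pytest.fixture(scope="session")
def double_bubble(small_truth):
    """Reduced two-bubble assembly graph (6 nodes, 8 edges)."""
    reads = read_io.oriented_sequences(small_truth.reads)
    g = graph_mod.reduce_graph(graph_mod.build_debruijn(reads, 15))
    assert graph_mod.count_bubbles(g) == 2
    return g


@pytest.fixture(scope="session")
def single_bubble():
    """Reduced one-bubble assembly graph (3 nodes, 4 edges)."""
    truth = simulate.simulate_truth(
        3,
        length=400,
        n_variants=1,
        min_spacing=100,
        n_pairs=200,
        read_length=50,
        insert_mean=80,
        insert_sd=8,
        error_rate=0.0,
    )
    reads = read_io.oriented_sequences(truth.reads)
    g = graph_mod.reduce_graph(graph_mod.build_debruijn(reads, 15))
    assert g.n_edges == 4
    return g


def enumerate_valid_states(g):
    """Brute-force enumeration of all valid boolean edge vectors."""
    states = []
    for bits in itertools.product([0, 1], repeat=g.n_edges):
        s = AssemblyState(np.array(bits, dtype=bool))
        if validate(s, g):
            states.append(s)
    return states


@pytest.fixture(scope="session")
def double_bubble_states(double_bubble):
    return enumerate_valid_states(double_bubble)
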