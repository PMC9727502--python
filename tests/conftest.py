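"""Shared fixtures: gridworlds, solved models and oracle helpers.

Expensive free-energy solves are session-scoped so every test file reuses
the same converged solutions.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pytest

from infomdp import (
    GridSpec,
    Neighborhood,
    build_gridworld,
    free_energy_solve,
    pairwise_free_energy,
)


def grid_graph(spec: GridSpec) -> nx.Graph:
    """Independent adjacency oracle: nodes are state indices, edges are the
    legal one-step moves (wall bumps excluded — self loops don't shorten
    paths)."""
    g = nx.Graph()
    g.add_nodes_from(range(spec.n_states))
    for s in range(spec.n_states):
        row, col = divmod(s, spec.width)
        for _, (dr, dc) in spec.moves:
            r2, c2 = row + dr, col + dc
            if 0 <= r2 < spec.height and 0 <= c2 < spec.width:
                g.add_edge(s, r2 * spec.width + c2)
    return g


def bfs_distances(spec: GridSpec) -> np.ndarray:
    """All-pairs shortest-path matrix by breadth-first search."""
    g = grid_graph(spec)
    n = spec.n_states
    dist = np.zeros((n, n))
    for src, lengths in nx.all_pairs_shortest_path_length(g):
        for dst, d in lengths.items():
            dist[src, dst] = d
    return dist


@pytest.fixture(scope="session")
def spec5() -> GridSpec:
    return GridSpec(5, 5, Neighborhood.MANHATTAN)


@pytest.fixture(scope="session")
def spec7() -> GridSpec:
    return GridSpec(7, 7, Neighborhood.MOORE)


@pytest.fixture(scope="session")
def bfs5(spec5):
    return bfs_distances(spec5)


@pytest.fixture(scope="session")
def bfs7(spec7):
    return bfs_distances(spec7)


# --- converged free-energy solutions reused across files -----------------

@pytest.fixture(scope="session")
def sol5_goal12_beta100(spec5):
    return free_energy_solve(build_gridworld(spec5, {12}), 100.0)


@pytest.fixture(scope="session")
def sol5_goal24_beta100(spec5):
    return free_energy_solve(build_gridworld(spec5, {24}), 100.0)


@pytest.fixture(scope="session")
def sol5_goal18_beta100(spec5):
    return free_energy_solve(build_gridworld(spec5, {18}), 100.0)


@pytest.fixture(scope="session")
def sol7_goal6_beta100(spec7):
    return free_energy_solve(build_gridworld(spec7, {6}), 100.0)


@pytest.fixture(scope="session")
def sol7_goal12_beta100(spec7):
    return free_energy_solve(build_gridworld(spec7, {12}), 100.0)


@pytest.fixture(scope="session")
def sol7_goal1_beta001(spec7):
    return free_energy_solve(build_gridworld(spec7, {1}), 0.01)


@pytest.fixture(scope="session")
def sol7_goal8_beta001(spec7):
    return free_energy_solve(build_gridworld(spec7, {8}), 0.01)


@pytest.fixture(scope="session")
def dm3_manhattan_beta1e7():
    return pairwise_free_energy(GridSpec(3, 3, "manhattan"), 1e7)


@pytest.fixture(scope="session")
def dm7_beta007(spec7):
    # ~1 minute: 49 solves in the strongly information-limited regime
    return pairwise_free_energy(spec7, 0.07)
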