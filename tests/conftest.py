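"""Shared fixtures: oracle networks with known labels, and small datasets."""

import itertools

import networkx as nx
import numpy as np
import pytest

from ncpc import BinaryDataset
from ncpc.algorithms import OracleCITest
from ncpc.synthetic import SyntheticNetwork, noisy_and_target


@pytest.fixture(scope="session")
def chain_net():
    """X3 -> X1 -> T <- X2: X1, X2 direct; X3 indirect."""
    return SyntheticNetwork(
        node_names=("T", "X1", "X2", "X3"),
        parents={"T": ("X1", "X2"), "X1": ("X3",), "X2": (), "X3": ()},
        cpt={
            "T": np.array([[0.1, 0.6], [0.7, 0.95]]),
            "X1": np.array([0.2, 0.8]),
            "X2": np.array(0.4),
            "X3": np.array(0.5),
        },
    )


@pytest.fixture(scope="session")
def mb_net():
    """X1 -> T -> X2 <- X4, X3 -> X1, X2 -> X5.

    Markov blanket of T is {X1, X2, X4} (X4 a spouse via the common child
    X2); X3 and X5 are indirect.
    """
    return SyntheticNetwork(
        node_names=("T", "X1", "X2", "X3", "X4", "X5"),
        parents={
            "T": ("X1",),
            "X2": ("T", "X4"),
            "X4": (),
            "X1": ("X3",),
            "X3": (),
            "X5": ("X2",),
        },
        cpt={
            "T": np.array([0.2, 0.8]),
            "X2": np.array([[0.1, 0.5], [0.4, 0.9]]),
            "X4": np.array(0.5),
            "X1": np.array([0.3, 0.7]),
            "X3": np.array(0.5),
            "X5": np.array([0.2, 0.8]),
        },
    )


@pytest.fixture(scope="session")
def collider_net():
    """T -> C <- S with S marginally independent of T (spouse capture case)."""
    return SyntheticNetwork(
        node_names=("T", "C", "S"),
        parents={"T": (), "C": ("T", "S"), "S": ()},
        cpt={
            "T": np.array(0.3),
            "C": np.array([[0.1, 0.6], [0.5, 0.95]]),
            "S": np.array(0.5),
        },
    )


@pytest.fixture(scope="session")
def disconnected_net():
    """No edges at all: every feature should be labelled none."""
    return SyntheticNetwork(
        node_names=("T", "X1", "X2"),
        parents={"T": (), "X1": (), "X2": ()},
        cpt={"T": np.array(0.5), "X1": np.array(0.5), "X2": np.array(0.5)},
    )


@pytest.fixture
def mb_oracle(mb_net):
    return OracleCITest(mb_net, "T")


@pytest.fixture(scope="session")
def twins_data():
    """Two perfectly correlated parents of a noisy-AND target, n = 300."""
    rng = np.random.default_rng(42)
    n = 300
    x1 = (rng.random(n) < 0.5).astype(np.int8)
    x2 = x1.copy()
    x3 = (rng.random(n) < 0.4).astype(np.int8)
    t = noisy_and_target(x1, x2, rng=rng)
    return BinaryDataset(np.column_stack([x1, x2, x3]), ("X1", "X2", "X3"), t)


def all_dags(k):
    """Every labeled DAG on k nodes (no 2-cycles by construction)."""
    pairs = list(itertools.combinations(range(k), 2))
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (i, j), c in zip(pairs, choice):
            if c == 1:
                edges.append((i, j))
            elif c == 2:
                edges.append((j, i))
        g = nx.DiGraph()
        g.add_nodes_from(range(k))
        g.add_edges_from(edges)
        if nx.is_directed_acyclic_graph(g):
            yield g


def dag_to_network(g: nx.DiGraph, rng=None) -> SyntheticNetwork:
    """Wrap a digraph as a network; CPTs random non-degenerate if rng given."""
    names = tuple(f"N{i}" for i in g.nodes)
    parents = {
        names[i]: tuple(names[p] for p in sorted(g.predecessors(i))) for i in g.nodes
    }
    cpt = {}
    for n in names:
        shape = (2,) * len(parents[n])
        if rng is None:
            cpt[n] = np.full(shape, 0.5)
        else:
            cpt[n] = 0.15 + 0.7 * rng.random(shape)
    return SyntheticNetwork(node_names=names, parents=parents, cpt=cpt)


def graph_role_labels(g: nx.DiGraph, t: int) -> dict[str, str]:
    """Expected asymptotic labels from the graph structure itself: direct =
    causal neighbours, conditional = spouses outside the neighbourhood,
    indirect = marginally d-connected non-members, none = the rest.
    Uses networkx d-separation (independent of the package's routine)."""
    names = {i: f"N{i}" for i in g.nodes}
    nbrs = set(g.predecessors(t)) | set(g.successors(t))
    spouses = set()
    for c in g.successors(t):
        spouses |= set(g.predecessors(c))
    spouses -= nbrs | {t}
    exp = {}
    for v in g.nodes:
        if v == t:
            continue
        if v in nbrs:
            exp[names[v]] = "direct"
        elif v in spouses:
            exp[names[v]] = "conditional"
        elif not nx.is_d_separator(g, {v}, {t}, set()):
            exp[names[v]] = "indirect"
        else:
            exp[names[v]] = "none"
    return exp
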