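"""The Direct Dependence Graph: a typed display of local dependence structure.

Vocabulary: the target sits in a circle; Markov-blanket members (direct,
joint, conditional, conditional-joint) are ovals reachable from the target
by undirected edges; indirectly dependent features are rectangles attached
by dot-terminated directed edges from the features that explain them away.
Grey edges mark the mathematically inconsistent rescue patterns (joint and
conditional-joint pairs). Solid feature-feature edges mean the pair is
dependent both marginally and given the target; dashed ones mean the pair
is conditionally independent given the target.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import networkx as nx
import numpy as np

from .citest import MonteCarloCITest
from .core import (
    BinaryDataset,
    DependenceLabel,
    NCPCConfig,
    NCPCResult,
    BLANKET_LABELS,
)

__all__ = ["DDGraph", "DDNode", "DDEdge", "build_ddgraph", "to_dot", "to_graphml"]

_SHAPE = {
    "target": "circle",
    "direct": "oval",
    "joint": "oval",
    "conditional": "oval",
    "conditional_joint": "oval",
    "indirect": "rectangle",
}


@dataclass(frozen=True)
class DDNode:
    name: str
    kind: str  # target | direct | joint | conditional | conditional_joint | indirect
    shape: str  # circle | oval | rectangle | dotted


@dataclass(frozen=True)
class DDEdge:
    source: str
    sink: str
    edge_type: str  # directed_dot | solid_undirected | dashed_undirected
    consistency: str  # consistent | inconsistent
    p_label: float | None = None


@dataclass
class DDGraph:
    target: str
    nodes: list[DDNode] = field(default_factory=list)
    edges: list[DDEdge] = field(default_factory=list)

    def node(self, name: str) -> DDNode:
        for n in self.nodes:
            if n.name == name:
                return n
        raise KeyError(name)

    def undirected_reachable_from_target(self) -> set[str]:
        g = nx.Graph()
        g.add_nodes_from(n.name for n in self.nodes)
        for e in self.edges:
            if e.edge_type in ("solid_undirected", "dashed_undirected"):
                g.add_edge(e.source, e.sink)
        return set(nx.node_connected_component(g, self.target)) - {self.target}


class _MCPairTest:
    """Feature-feature auxiliary test: is X_a dependent with X_b (optionally
    given T)? Reuses the Monte-Carlo machinery by viewing X_b as the target."""

    def __init__(self, data: BinaryDataset, config: NCPCConfig):
        self.data = data
        self.config = config
        self.rng = np.random.default_rng(config.seed + 1)

    def pair_dependent(self, a: str, b: str, given_target: bool) -> bool:
        ia = self.data.index_of(a)
        ib = self.data.index_of(b)
        keep = [i for i in range(self.data.m) if i != ib]
        X = np.column_stack([self.data.X[:, keep], self.data.T])
        names = tuple(self.data.variable_names[i] for i in keep) + (
            self.data.target_name,
        )
        tmp = BinaryDataset(X, names, self.data.X[:, ib], target_name=b)
        test = MonteCarloCITest(tmp, self.config, rng=self.rng)
        cond = (len(keep),) if given_target else ()
        out = test(tmp.index_of(a), cond)
        return out.verdict == "dependent"


def _activators(result: NCPCResult) -> dict[str, list[str]]:
    """Capture evidence from the trace: size-1 conditioning sets that made a
    marginally independent variable dependent."""
    names = result.variable_names
    marg_indep = {
        t.var_index
        for t in result.trace
        if not t.condset and t.performed and t.verdict == "independent"
    }
    out: dict[str, list[str]] = {}
    for t in result.trace:
        if (
            len(t.condset) == 1
            and t.var_index in marg_indep
            and t.performed
            and t.verdict == "dependent"
        ):
            out.setdefault(names[t.var_index], []).append(names[t.condset[0]])
    return out


def build_ddgraph(
    result: NCPCResult,
    data: BinaryDataset | None = None,
    config: NCPCConfig | None = None,
    pair_test=None,
) -> DDGraph:
    """Construct the display graph from a search result.

    ``pair_test`` classifies feature-feature edges (solid vs dashed) via two
    auxiliary queries per pair — marginal, and conditional on the target. It
    is built automatically from ``data``/``config`` (Monte-Carlo) when given;
    an :class:`~ncpc.algorithms.OracleCITest` also qualifies. Without either,
    feature-feature edges default to solid. These edges are display only and
    never feed back into labels.
    """
    if pair_test is None and data is not None:
        pair_test = _MCPairTest(data, config or result.config or NCPCConfig())

    target = "T"
    for (a, _b) in result.edge_pvalues:
        if a not in result.labels:
            target = a
            break
    else:
        if data is not None:
            target = data.target_name

    g = DDGraph(target=target)
    g.nodes.append(DDNode(target, "target", "circle"))

    labels = result.labels
    pair_of: dict[str, str] = {}
    for a, b in result.joint_pairs + result.conditional_joint_pairs:
        pair_of[a] = b
        pair_of[b] = a

    activators = _activators(result)
    mb = {n for n, l in labels.items() if l in BLANKET_LABELS}

    def classify(a: str, b: str) -> str:
        # solid: dependent given T and marginally; dashed: independent given T
        if pair_test is None:
            return "solid_undirected"
        if not pair_test.pair_dependent(a, b, True):
            return "dashed_undirected"
        return "solid_undirected"

    edges: list[DDEdge] = []
    for name in labels:
        lbl = labels[name]
        if lbl is DependenceLabel.NONE:
            continue
        kind = lbl.value
        grey = lbl in (DependenceLabel.JOINT, DependenceLabel.CONDITIONAL_JOINT)
        consistency = "inconsistent" if grey else "consistent"
        if lbl in (DependenceLabel.DIRECT, DependenceLabel.JOINT):
            g.nodes.append(DDNode(name, kind, _SHAPE[kind]))
            edges.append(
                DDEdge(target, name, "solid_undirected", consistency,
                       result.edge_pvalues.get((target, name)))
            )
        elif lbl in (DependenceLabel.CONDITIONAL, DependenceLabel.CONDITIONAL_JOINT):
            acts = [a for a in activators.get(name, []) if a in mb]
            disconnected = (
                lbl is DependenceLabel.CONDITIONAL_JOINT and not acts
                and pair_of.get(name) is not None
            )
            shape = "dotted" if disconnected else _SHAPE[kind]
            g.nodes.append(DDNode(name, kind, shape))
            if acts:
                for a in sorted(set(acts)):
                    edges.append(
                        DDEdge(a, name, classify(a, name), consistency,
                               result.edge_pvalues.get((target, name)))
                    )
            elif not disconnected:
                # keep the blanket reachable when capture evidence is absent
                # (e.g. a variable rescued by the consistency pass)
                edges.append(
                    DDEdge(target, name, "solid_undirected", consistency,
                           result.edge_pvalues.get((target, name)))
                )
        elif lbl is DependenceLabel.INDIRECT:
            g.nodes.append(DDNode(name, kind, _SHAPE[kind]))
            sep = result.separating_set(name)
            if sep is None:
                raise ValueError(
                    f"trace holds no removing test for indirect variable {name!r}"
                )
            p = result.removal_pvalue(name)
            for s in sep:
                edges.append(DDEdge(s, name, "directed_dot", "consistent", p))

    # pairwise edges of the rescue patterns (always grey)
    seen_pairs = set()
    for a, b in result.joint_pairs + result.conditional_joint_pairs:
        key = tuple(sorted((a, b)))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        edges.append(DDEdge(key[0], key[1], classify(*key), "inconsistent", None))

    g.edges = edges
    return g


def _fmt_p(p: float | None) -> str | None:
    if p is None:
        return None
    return f"{p:.3g}"


def to_dot(g: DDGraph) -> str:
    """Deterministic DOT serialization (nodes sorted by name, target first)."""
    shape_attr = {
        "circle": "shape=circle",
        "oval": "shape=ellipse",
        "rectangle": "shape=box",
        "dotted": "shape=ellipse, style=dotted",
    }
    lines = ["digraph ddgraph {"]
    ordered = sorted(g.nodes, key=lambda n: (n.kind != "target", n.name))
    for n in ordered:
        attrs = [shape_attr[n.shape], f'kind="{n.kind}"']
        if n.kind == "target":
            attrs.append("color=green")
        lines.append(f'  "{n.name}" [{", ".join(attrs)}];')
    for e in sorted(g.edges, key=lambda e: (e.source, e.sink, e.edge_type)):
        attrs = []
        if e.edge_type == "directed_dot":
            attrs.append("arrowhead=dot")
        else:
            attrs.append("dir=none")
        if e.edge_type == "dashed_undirected":
            attrs.append("style=dashed")
        if e.consistency == "inconsistent":
            attrs.append("color=grey")
        p = _fmt_p(e.p_label)
        if p is not None:
            attrs.append(f'label="{p}"')
        lines.append(f'  "{e.source}" -> "{e.sink}" [{", ".join(attrs)}];')
    lines.append("}")
    return "\n".join(lines) + "\n"


def to_graphml(g: DDGraph) -> str:
    """GraphML export mirroring the DOT attributes (typed)."""
    G = nx.DiGraph()
    for n in g.nodes:
        G.add_node(n.name, kind=n.kind, shape=n.shape)
    for e in g.edges:
        attrs = {"edge_type": e.edge_type, "consistency": e.consistency}
        if e.p_label is not None:
            attrs["p"] = float(e.p_label)
        G.add_edge(e.source, e.sink, **attrs)
    return "\n".join(nx.generate_graphml(G)) + "\n"
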