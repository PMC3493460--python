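"""Synthetic benchmark generator with known ground truth.

The generator emulates a panel of correlated binary TF-binding-style
features: a random 15-node DAG whose parent counts are binomial (mean 1.5,
max 2) and whose conditional probability tables are Beta draws, a sparse
binary target produced by a noisy AND gate over two designated causal
neighbours (stochastic input readout plus output flip noise, giving ~10%
active observations weakly correlated with each input), and two confounding
scenarios:

* ``time``  — the three chosen variables form a chain X1 -> X2 -> X3
  (binding of one factor at three consecutive stages), with the X1-X3
  correlation weaker than the adjacent ones;
* ``hidden`` — the three variables share a common unobserved cause H
  (e.g. chromatin accessibility), with all pairwise correlations equal.

Only X1 and X2 feed the target, so the ground-truth causal neighbourhood of
every emitted dataset is exactly {X1, X2}.

An exact d-separation oracle and a brute-force joint-distribution evaluator
make the generator usable as a correctness substrate for the search
algorithms; :func:`run_benchmark` scores algorithms against the ground
truth by correct-prediction rate, precision and recall.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .algorithms import ncpc, ncpc_star, pc_local_baseline
from .core import BinaryDataset, NCPCConfig, NCPCResult
from .dsep import d_separated

__all__ = [
    "SyntheticNetwork",
    "NoisyANDParams",
    "DEFAULT_CPT_BETA",
    "generate_network",
    "sample_dataset",
    "noisy_and_target",
    "rewire_time",
    "rewire_hidden",
    "d_separation",
    "joint_distribution",
    "exact_marginal",
    "exact_ci",
    "benchmark_metrics",
    "BenchmarkScore",
    "simulate_study",
    "run_benchmark",
    "ALGORITHMS",
    "register_algorithm",
]

#: Beta(a, b) for conditional-probability-table entries. Calibrated once so
#: that, with the noisy-AND defaults and the real-data-like correlation
#: setting (0.5), the active-target fraction is ~10% and the target-input
#: correlation falls in 0.17-0.25; frozen thereafter.
DEFAULT_CPT_BETA = (2.0, 2.0)


@dataclass(frozen=True)
class NoisyANDParams:
    """Noise model of the two-input AND gate target.

    ``p_read_given_present``/``p_read_given_absent`` are the stochastic
    readout probabilities P(R=1|input=1) and P(R=1|input=0) modelling the
    activity of unmodelled factors; ``fp_rate``/``fn_rate`` flip the gate
    output, modelling reporter-assay noise.
    """

    p_read_given_present: float = 0.5
    p_read_given_absent: float = 0.1
    fp_rate: float = 0.01
    fn_rate: float = 0.2

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{f.name} must be a probability, got {v}")


def _toposort(parents: Mapping[str, tuple]) -> list[str]:
    """Deterministic topological order (name-sorted Kahn)."""
    remaining = {n: set(ps) for n, ps in parents.items()}
    order: list[str] = []
    while remaining:
        ready = sorted(n for n, ps in remaining.items() if not ps)
        if not ready:
            raise ValueError("network contains a directed cycle")
        for n in ready:
            order.append(n)
            del remaining[n]
        for ps in remaining.values():
            ps.difference_update(ready)
    return order


@dataclass(frozen=True)
class SyntheticNetwork:
    """A DAG with per-node CPTs, optional hidden nodes, and ground truth.

    ``cpt[node]`` has shape ``(2,) * n_parents`` (a scalar array for roots)
    and stores P(node = 1 | parent assignment), parents indexed in the order
    given by ``parents[node]``.
    """

    node_names: tuple[str, ...]
    parents: dict[str, tuple[str, ...]]
    cpt: dict[str, np.ndarray]
    hidden_nodes: frozenset[str] = frozenset()
    ground_truth_neighbours: frozenset[str] = frozenset()
    order: tuple[str, ...] | None = None  # topological order used for sampling

    def __post_init__(self) -> None:
        object.__setattr__(self, "node_names", tuple(self.node_names))
        object.__setattr__(self, "hidden_nodes", frozenset(self.hidden_nodes))
        object.__setattr__(
            self, "ground_truth_neighbours", frozenset(self.ground_truth_neighbours)
        )
        for n in self.node_names:
            tab = np.asarray(self.cpt[n], dtype=float)
            if tab.shape != (2,) * len(self.parents[n]):
                raise ValueError(f"CPT shape mismatch for node {n!r}")
            if ((tab < 0) | (tab > 1)).any():
                raise ValueError(f"CPT of node {n!r} is not a probability table")
        if self.order is None:
            object.__setattr__(self, "order", tuple(_toposort(self.parents)))
        else:
            object.__setattr__(self, "order", tuple(self.order))
            pos = {n: i for i, n in enumerate(self.order)}
            if set(pos) != set(self.node_names):
                raise ValueError("order must enumerate exactly the nodes")
            for n, ps in self.parents.items():
                if any(pos[p] > pos[n] for p in ps):
                    raise ValueError("order is not topological")

    @property
    def topological_order(self) -> tuple[str, ...]:
        return self.order  # type: ignore[return-value]

    @property
    def observed_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.node_names if n not in self.hidden_nodes)

    def children_map(self) -> dict[str, tuple[str, ...]]:
        kids: dict[str, list[str]] = {n: [] for n in self.node_names}
        for n, ps in self.parents.items():
            for p in ps:
                kids[p].append(n)
        return {k: tuple(v) for k, v in kids.items()}

    def to_digraph(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.node_names)
        for n, ps in self.parents.items():
            g.add_edges_from((p, n) for p in ps)
        return g


def _rng(seed, rng) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(seed)


def generate_network(
    m: int = 15,
    parent_count_max: int = 2,
    parent_count_mean: float = 1.5,
    cpt_beta: tuple[float, float] = DEFAULT_CPT_BETA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> SyntheticNetwork:
    """Random DAG in a random topological order.

    Parent counts are Binomial(parent_count_max, parent_count_mean /
    parent_count_max) truncated to the number of predecessors; parents are
    drawn uniformly from the predecessors; CPT entries are i.i.d.
    Beta(*cpt_beta*) draws.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if parent_count_mean > parent_count_max:
        raise ValueError("parent_count_mean cannot exceed parent_count_max")
    gen = _rng(seed, rng)
    names = tuple(f"X{i + 1}" for i in range(m))
    order = [names[i] for i in gen.permutation(m)]
    a, b = cpt_beta
    parents: dict[str, tuple[str, ...]] = {}
    cpt: dict[str, np.ndarray] = {}
    for idx, node in enumerate(order):
        preds = order[:idx]
        k = min(int(gen.binomial(parent_count_max, parent_count_mean / parent_count_max)),
                len(preds))
        ps = tuple(sorted(gen.choice(len(preds), size=k, replace=False))) if k else ()
        parents[node] = tuple(preds[i] for i in ps)
        cpt[node] = gen.beta(a, b, size=(2,) * k)
    return SyntheticNetwork(
        node_names=names, parents=parents, cpt=cpt, order=tuple(order)
    )


def sample_dataset(
    net: SyntheticNetwork,
    n_obs: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Ancestral sampling; hidden nodes drive the sampling but are dropped
    from the returned columns."""
    gen = _rng(seed, rng)
    cols: dict[str, np.ndarray] = {}
    for node in net.topological_order:
        ps = net.parents[node]
        tab = np.asarray(net.cpt[node], dtype=float)
        if ps:
            p = tab[tuple(cols[p] for p in ps)]
        else:
            p = np.full(n_obs, float(tab))
        cols[node] = (gen.random(n_obs) < p).astype(np.int8)
    return pd.DataFrame({n: cols[n] for n in net.observed_names})


def noisy_and_target(
    a: Sequence[int],
    b: Sequence[int],
    params: NoisyANDParams | None = None,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noisy AND of two binary inputs: stochastic readout per input, boolean
    AND, then output flips (1->0 with fn_rate, 0->1 with fp_rate)."""
    params = params if params is not None else NoisyANDParams()
    a = np.asarray(a, dtype=np.int8)
    b = np.asarray(b, dtype=np.int8)
    if a.shape != b.shape:
        raise ValueError("input vectors must have equal length")
    gen = _rng(seed, rng)
    p1, p0 = params.p_read_given_present, params.p_read_given_absent
    ra = gen.random(a.size) < np.where(a == 1, p1, p0)
    rb = gen.random(b.size) < np.where(b == 1, p1, p0)
    f = ra & rb
    u = gen.random(a.size)
    t = np.where(f, u >= params.fn_rate, u < params.fp_rate)
    return t.astype(np.int8)


# ---------------------------------------------------------------------------
# exact inference helpers


def _ancestral_closure(net: SyntheticNetwork, nodes: Iterable[str]) -> list[str]:
    want = set(nodes)
    changed = True
    while changed:
        changed = False
        for n in list(want):
            for p in net.parents[n]:
                if p not in want:
                    want.add(p)
                    changed = True
    return [n for n in net.topological_order if n in want]


def joint_distribution(
    net: SyntheticNetwork, nodes: Iterable[str] | None = None
) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Exact joint over the ancestral closure of ``nodes`` (default: all).

    Returns (columns, assignments of shape (2^K, K), probabilities). Only
    feasible for closures of at most 20 nodes.
    """
    scope = _ancestral_closure(net, nodes if nodes is not None else net.node_names)
    k = len(scope)
    if k > 20:
        raise ValueError("joint enumeration limited to 20 nodes")
    assign = ((np.arange(1 << k)[:, None] >> np.arange(k)) & 1).astype(np.int8)
    col = {n: i for i, n in enumerate(scope)}
    probs = np.ones(1 << k)
    for n in scope:
        tab = np.asarray(net.cpt[n], dtype=float)
        ps = net.parents[n]
        p1 = tab[tuple(assign[:, col[p]] for p in ps)] if ps else float(tab)
        v = assign[:, col[n]]
        probs *= np.where(v == 1, p1, 1.0 - p1)
    return scope, assign, probs


def exact_marginal(net: SyntheticNetwork, node: str) -> float:
    """P(node = 1) by enumeration over the node's ancestral closure."""
    scope, assign, probs = joint_distribution(net, [node])
    return float(probs[assign[:, scope.index(node)] == 1].sum())


def exact_ci(
    net: SyntheticNetwork,
    x: str,
    y: str,
    condset: Iterable[str] = (),
    tol: float = 1e-9,
) -> bool:
    """Brute-force conditional independence in the exact joint distribution."""
    condset = tuple(condset)
    scope, assign, probs = joint_distribution(net, (x, y, *condset))
    ix, iy = scope.index(x), scope.index(y)
    ic = [scope.index(c) for c in condset]
    codes = assign[:, ic] @ (1 << np.arange(len(ic))) if ic else np.zeros(len(probs), dtype=int)
    for code in np.unique(codes):
        mask = codes == code
        pz = probs[mask].sum()
        if pz <= tol:
            continue
        pxy = probs[mask & (assign[:, ix] == 1) & (assign[:, iy] == 1)].sum() / pz
        px = probs[mask & (assign[:, ix] == 1)].sum() / pz
        py = probs[mask & (assign[:, iy] == 1)].sum() / pz
        if abs(pxy - px * py) > tol:
            return False
    return True


def d_separation(
    net: SyntheticNetwork, x: str, y: str, condset: Iterable[str] = ()
) -> bool:
    """True iff every trail between x and y is blocked given the set."""
    condset = set(condset)
    for n in (x, y, *condset):
        if n not in net.node_names:
            raise ValueError(f"unknown node {n!r}")
    return d_separated(net.parents, net.children_map(), x, y, condset)


# ---------------------------------------------------------------------------
# scenario rewiring


def _chain_cpt(p: float, r: float) -> np.ndarray:
    """Symmetric binary-chain CPT [P(1|0), P(1|1)] achieving Pearson
    correlation r with a Bernoulli(p) parent while preserving the marginal."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"degenerate parent marginal {p}")
    q1 = p + r * (1.0 - p)
    q0 = p * (1.0 - r)
    if not (0.0 <= q0 <= 1.0 and 0.0 <= q1 <= 1.0):
        raise ValueError(f"correlation {r} unachievable at marginal {p}")
    return np.array([q0, q1])


def rewire_time(
    net: SyntheticNetwork,
    triple: tuple[str, str, str],
    target_correlations: tuple[float, float, float | None],
    seed: int | None = None,
) -> SyntheticNetwork:
    """Rewire three variables into the chain X1 -> X2 -> X3.

    X1 keeps its original parents; X2 and X3 take their sole parent from the
    chain, with symmetric CPTs achieving the requested adjacent correlations
    (the X1-X3 correlation is then implied: r13 = r12 * r23). X2 and X3
    retain their original causal children. The triple must admit an acyclic
    rewiring (choose it in topological order).
    """
    x1, x2, x3 = triple
    if len({x1, x2, x3}) != 3:
        raise ValueError("triple must be three distinct nodes")
    r12, r23, r13 = target_correlations
    if r13 is not None and not r13 < min(r12, r23):
        raise ValueError("r13 must be smaller than the adjacent correlations")
    parents = dict(net.parents)
    cpt = dict(net.cpt)
    parents[x2] = (x1,)
    parents[x3] = (x2,)
    trial = SyntheticNetwork(
        node_names=net.node_names,
        parents=parents,
        cpt={**cpt, x2: np.array([0.5, 0.5]), x3: np.array([0.5, 0.5])},
        hidden_nodes=net.hidden_nodes,
        ground_truth_neighbours=frozenset((x1, x2)),
        order=net.order,
    )  # validates acyclicity (order stays topological) before calibration
    p1 = exact_marginal(trial, x1)
    cpt[x2] = _chain_cpt(p1, r12)
    cpt[x3] = _chain_cpt(p1, r23)  # chain preserves the marginal: p2 = p1
    return SyntheticNetwork(
        node_names=net.node_names,
        parents=parents,
        cpt=cpt,
        hidden_nodes=net.hidden_nodes,
        ground_truth_neighbours=frozenset((x1, x2)),
        order=net.order,
    )


def _unique_name(base: str, taken: Iterable[str]) -> str:
    taken = set(taken)
    if base not in taken:
        return base
    i = 1
    while f"{base}{i}" in taken:
        i += 1
    return f"{base}{i}"


def hidden_correlation_bounds(r: float) -> tuple[float, float]:
    """Marginal range within which a symmetric hidden cause can induce
    pairwise correlation r: p in [r/(1+r), 1/(1+r)]."""
    return r / (1.0 + r), 1.0 / (1.0 + r)


def rewire_hidden(
    net: SyntheticNetwork,
    triple: tuple[str, str, str],
    target_correlation: float,
    seed: int | None = None,
    marginals: tuple[float, float, float] | None = None,
) -> SyntheticNetwork:
    """Give three variables a common hidden cause H with equal pairwise
    correlations.

    H is Bernoulli(1/2) and each variable's CPT is p_i -/+ sqrt(r)*s_i
    (s_i the Bernoulli standard deviation), which preserves each marginal
    p_i and yields correlation r for every pair. Marginals default to the
    variables' original exact marginals; the rewiring errors out when the
    requested correlation is unachievable at those marginals (pass explicit
    achievable ``marginals`` instead).
    """
    x = tuple(triple)
    if len(set(x)) != 3:
        raise ValueError("triple must be three distinct nodes")
    r = target_correlation
    if not 0.0 <= r <= 1.0:
        raise ValueError("hidden-cause correlation must be in [0, 1]")
    if marginals is None:
        marginals = tuple(exact_marginal(net, v) for v in x)
    h = _unique_name("H", net.node_names)
    parents = dict(net.parents)
    cpt = dict(net.cpt)
    for v, p in zip(x, marginals):
        s = math.sqrt(p * (1.0 - p)) if 0.0 < p < 1.0 else 0.0
        a = math.sqrt(r) * s
        lo, hi = p - a, p + a
        if not (0.0 <= lo and hi <= 1.0) or s == 0.0:
            raise ValueError(
                f"correlation {r} unachievable at marginal {p:.3f} for {v!r}"
            )
        parents[v] = (h,)
        cpt[v] = np.array([lo, hi])
    parents[h] = ()
    cpt[h] = np.array(0.5)
    return SyntheticNetwork(
        node_names=net.node_names + (h,),
        parents=parents,
        cpt=cpt,
        hidden_nodes=net.hidden_nodes | {h},
        ground_truth_neighbours=frozenset(x[:2]),
        order=(h,) + tuple(net.order),
    )


# ---------------------------------------------------------------------------
# benchmark


@dataclass(frozen=True)
class BenchmarkScore:
    correct: bool
    precision: float  # nan when undefined (no positives predicted)
    recall: float

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def benchmark_metrics(predicted: Iterable[str], truth: Iterable[str]) -> BenchmarkScore:
    """Set-wise correctness, precision and recall of a predicted
    neighbourhood against the ground truth."""
    predicted, truth = set(predicted), set(truth)
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    correct = fp == 0 and fn == 0
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 1.0 if not truth else float("nan")
    recall = tp / (tp + fn) if tp + fn > 0 else float("nan")
    return BenchmarkScore(correct=correct, precision=precision, recall=recall)


def simulate_study(
    scenario: str,
    correlation: float,
    n_obs: int,
    m: int = 15,
    params: NoisyANDParams | None = None,
    cpt_beta: tuple[float, float] = DEFAULT_CPT_BETA,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[BinaryDataset, SyntheticNetwork, set[str]]:
    """One benchmark replicate: generate, rewire, sample, attach the target.

    Returns the dataset (features + noisy-AND target), the rewired network
    and the ground-truth neighbourhood {X1, X2}.
    """
    if scenario not in ("time", "hidden"):
        raise ValueError(f"unknown scenario {scenario!r}")
    gen = _rng(seed, rng)
    net = generate_network(m=m, cpt_beta=cpt_beta, rng=gen)
    idx = sorted(gen.choice(m, size=3, replace=False))
    topo = net.topological_order
    triple = tuple(sorted((net.node_names[i] for i in idx), key=topo.index))
    if scenario == "time":
        rw = rewire_time(net, triple, (correlation, correlation, None))
    else:
        eps = 1e-6
        lo, hi = hidden_correlation_bounds(correlation)
        marg = tuple(
            float(np.clip(exact_marginal(net, v), lo + eps, hi - eps))
            for v in triple
        )
        rw = rewire_hidden(net, triple, correlation, marginals=marg)
    df = sample_dataset(rw, n_obs, rng=gen)
    t = noisy_and_target(df[triple[0]], df[triple[1]], params=params, rng=gen)
    data = BinaryDataset(
        df.to_numpy(), tuple(df.columns), t, target_name="target"
    )
    return data, rw, {triple[0], triple[1]}


#: Built-in algorithm registry: name -> callable(data, config) -> NCPCResult.
ALGORITHMS: dict[str, Callable[[BinaryDataset, NCPCConfig], NCPCResult]] = {
    "ncpc-dir": lambda d, c: ncpc(d, c, detect_joint=False),
    "ncpc-dir-jnt": lambda d, c: ncpc(d, c, detect_joint=True),
    "ncpc-star": lambda d, c: ncpc_star(d, c, detect_conditional_joint=False),
    "ncpc-star-cjnt": lambda d, c: ncpc_star(d, c, detect_conditional_joint=True),
    "pc-local": lambda d, c: pc_local_baseline(d, c),
}


def register_algorithm(
    name: str, fn: Callable[[BinaryDataset, NCPCConfig], NCPCResult]
) -> None:
    """Plug in an external neighbourhood-discovery algorithm."""
    ALGORITHMS[name] = fn


def run_benchmark(
    scenario: str,
    correlation: float,
    n_obs: int,
    reps: int,
    algorithms: Sequence[str] = ("ncpc-dir", "ncpc-dir-jnt", "pc-local"),
    config: NCPCConfig | None = None,
    seed: int = 0,
    m: int = 15,
) -> pd.DataFrame:
    """Score algorithms over replicate synthetic studies.

    The predicted causal neighbourhood (direct plus joint labels) of each
    algorithm is scored against the ground truth {X1, X2}; the table reports
    mean correct-prediction rate with a 95% normal-approximation confidence
    interval, plus mean precision (undefined replicates excluded) and recall.
    """
    unknown = [a for a in algorithms if a not in ALGORITHMS]
    if unknown:
        raise ValueError(f"unknown algorithm(s): {unknown}")
    base = config if config is not None else NCPCConfig()
    ss = np.random.SeedSequence(seed)
    scores: dict[str, list[BenchmarkScore]] = {a: [] for a in algorithms}
    for child in ss.spawn(reps):
        gen = np.random.default_rng(child)
        data, _net, truth = simulate_study(
            scenario, correlation, n_obs, m=m, rng=gen
        )
        rep_seed = int(gen.integers(0, 2**31 - 1))
        cfg = dataclasses.replace(base, seed=rep_seed)
        for name in algorithms:
            result = ALGORITHMS[name](data, cfg)
            predicted = result.causal_neighbourhood
            scores[name].append(benchmark_metrics(predicted, truth))
    rows = []
    z = 1.959963984540054
    for name in algorithms:
        sc = scores[name]
        correct = np.array([s.correct for s in sc], dtype=float)
        rate = correct.mean()
        half = z * math.sqrt(rate * (1 - rate) / len(sc)) if len(sc) > 1 else 0.0
        prec = np.array([s.precision for s in sc])
        rec = np.array([s.recall for s in sc])
        rows.append(
            {
                "algorithm": name,
                "n_reps": len(sc),
                "correct_rate": rate,
                "correct_ci_low": max(0.0, rate - half),
                "correct_ci_high": min(1.0, rate + half),
                "precision": float(np.nanmean(prec)) if np.isfinite(prec).any() else float("nan"),
                "recall": float(np.nanmean(rec)) if np.isfinite(rec).any() else float("nan"),
            }
        )
    return pd.DataFrame(rows)
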