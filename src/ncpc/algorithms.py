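"""Neighbourhood-consistent local structure search around a binary target.

The searches here label every feature with its type of dependence on the
target: ``direct`` (dependent under every tested conditioning set),
``indirect`` (marginally dependent but explained away), ``conditional``
(marginally independent but dependent given other features, e.g. causal
spouses), ``none``, and the two rescue patterns for highly correlated
features: ``joint`` and ``conditional_joint``.

Three entry points share one engine:

* :func:`ncpc` — candidate set = marginally dependent features; iterative
  elimination over growing conditioning-set sizes; optional joint-pattern
  rescue of correlated candidate pairs that explain each other away.
* :func:`ncpc_star` — additionally captures features that become dependent
  given a single current candidate (spouse capture), labels retained
  captures ``conditional``, detects conditional-joint pairs, and runs a
  Markov-blanket consistency pass that re-tests eliminated features against
  the retained set (only when the power gate allows the test).
* :func:`pc_local_baseline` — the elimination only, no pattern rescue: the
  behaviour of a plain PC-style adjacency search restricted to the target.

Any callable ``(var_index, condset) -> CITestOutcome`` can serve as the CI
test; :class:`~ncpc.citest.MonteCarloCITest` binds the Monte-Carlo tests to
a dataset, while :class:`OracleCITest` answers from d-separation on a known
network (the asymptotic, infinite-sample regime).
"""

from __future__ import annotations

import dataclasses
from collections import defaultdict
from itertools import combinations
from typing import Callable, Iterable, Sequence

import numpy as np

from .citest import MonteCarloCITest, adjust_pvalues, max_condset_size
from .core import (
    BLANKET_LABELS,
    BinaryDataset,
    CITestOutcome,
    DependenceLabel,
    NCPCConfig,
    NCPCResult,
)
from .dsep import d_separated

__all__ = [
    "OracleCITest",
    "marginal_screen",
    "ncpc",
    "ncpc_star",
    "pc_local_baseline",
]


class OracleCITest:
    """Perfect CI test answering from d-separation on a known network.

    Queries are evaluated on the full DAG including hidden nodes (which are
    never conditioned on), so answers match the marginal distribution over
    the observed nodes of a faithful network.
    """

    def __init__(self, network, target: str):
        names = [n for n in network.node_names if n not in network.hidden_nodes]
        if target not in names:
            raise ValueError(f"unknown target {target!r}")
        self.target_name = target
        self.variable_names = tuple(n for n in names if n != target)
        self.parents = {n: tuple(ps) for n, ps in network.parents.items()}
        self.children: dict[str, tuple] = {n: () for n in network.node_names}
        kids = defaultdict(list)
        for n, ps in self.parents.items():
            for p in ps:
                kids[p].append(n)
        self.children.update({k: tuple(v) for k, v in kids.items()})

    @property
    def m(self) -> int:
        return len(self.variable_names)

    def __call__(self, i: int, condset: Iterable[int]) -> CITestOutcome:
        condset = tuple(sorted(set(condset)))
        z = {self.variable_names[j] for j in condset}
        sep = d_separated(
            self.parents, self.children, self.variable_names[i], self.target_name, z
        )
        if sep:
            return CITestOutcome(i, condset, 0.0, 1.0, True, "independent")
        return CITestOutcome(i, condset, float("inf"), 0.0, True, "dependent")

    def pair_dependent(self, a: str, b: str, given_target: bool) -> bool:
        """Auxiliary feature-feature query used for display edges."""
        z = {self.target_name} if given_target else set()
        return not d_separated(self.parents, self.children, a, b, z)


def _resolve(data, config, ci_test):
    if ci_test is None:
        if data is None:
            raise ValueError("either a dataset or a ci_test is required")
        config = config if config is not None else NCPCConfig()
        ci_test = MonteCarloCITest(data, config)
        max_k = max_condset_size(data.T, config)
    else:
        config = config if config is not None else NCPCConfig()
        max_k = (
            config.max_condset_size
            if config.max_condset_size is not None
            else ci_test.m
        )
    return config, ci_test, max_k


def marginal_screen(
    data: BinaryDataset | None,
    config: NCPCConfig | None = None,
    ci_test: Callable | None = None,
) -> tuple[set[int], list[CITestOutcome]]:
    """All-variable marginal screen: the initial direct-dependence candidates.

    Returns the candidate index set C (marginal test rejects independence at
    alpha) and the trace of all m marginal tests.
    """
    config, ci_test, _ = _resolve(data, config, ci_test)
    outcomes = [ci_test(i, ()) for i in range(ci_test.m)]
    outcomes = _apply_correction(outcomes, config)
    C = {t.var_index for t in outcomes if t.verdict == "dependent"}
    return C, outcomes


def _apply_correction(outcomes: list[CITestOutcome], config: NCPCConfig):
    """Re-derive verdicts from batch-adjusted p-values; raw p stays in trace."""
    if config.correction == "none":
        return outcomes
    performed = [t for t in outcomes if t.performed]
    if not performed:
        return outcomes
    adj = adjust_pvalues([t.p_value for t in performed], config.correction)
    adj_iter = iter(adj)
    out = []
    for t in outcomes:
        if not t.performed:
            out.append(t)
            continue
        p_adj = next(adj_iter)
        verdict = "independent" if p_adj > config.alpha else "dependent"
        out.append(dataclasses.replace(t, verdict=verdict))
    return out


def _greedy_pairs(
    eligible: set[int],
    sep_sets: dict[int, list[tuple[int, ...]]],
    strength_p: dict[int, float],
    names: Sequence[str],
) -> list[tuple[int, int]]:
    """Mutually-explaining pairs: every separating set of one contains the
    other. Ties resolved by the pair with the smallest worse marginal p
    (largest minimum dependence strength); a variable joins at most one pair."""
    scored = []
    for i, j in combinations(sorted(eligible), 2):
        if not sep_sets.get(i) or not sep_sets.get(j):
            continue
        if all(j in S for S in sep_sets[i]) and all(i in S for S in sep_sets[j]):
            score = max(strength_p.get(i, 0.0), strength_p.get(j, 0.0))
            scored.append((score, names[i], names[j], i, j))
    scored.sort()
    taken: set[int] = set()
    pairs = []
    for _, _, _, i, j in scored:
        if i in taken or j in taken:
            continue
        pairs.append((i, j))
        taken.update((i, j))
    return pairs


def _search(
    data: BinaryDataset | None,
    config: NCPCConfig | None,
    ci_test: Callable | None,
    *,
    star: bool,
    detect_joint: bool,
    detect_conditional_joint: bool,
    algorithm: str,
) -> NCPCResult:
    config, ci_test, max_k = _resolve(data, config, ci_test)
    names = list(ci_test.variable_names)
    target = getattr(ci_test, "target_name", "target")
    m = len(names)
    trace: list[CITestOutcome] = []
    cache: dict[tuple[int, tuple[int, ...]], CITestOutcome] = {}

    def test(i: int, S: Iterable[int]) -> CITestOutcome:
        key = (i, tuple(sorted(set(S))))
        if key not in cache:
            out = ci_test(i, key[1])
            out = _apply_correction([out], config)[0]
            cache[key] = out
            trace.append(out)
        return cache[key]

    # Step 1: marginal screen (batch-corrected as one family)
    marg = [ci_test(i, ()) for i in range(m)]
    marg = _apply_correction(marg, config)
    for t in marg:
        cache[(t.var_index, ())] = t
        trace.append(t)
    marg_dep = {t.var_index for t in marg if t.verdict == "dependent"}
    marg_p = {t.var_index: t.p_value for t in marg}
    C = set(marg_dep)

    # Step 2 (star): spouse capture — features dependent given one candidate
    activators: dict[int, set[int]] = {}
    if star:
        cap = []
        for j in sorted(set(range(m)) - C):
            for c in sorted(C):
                cap.append(ci_test(j, (c,)))
        cap = _apply_correction(cap, config)
        for t in cap:
            cache[(t.var_index, t.condset)] = t
            trace.append(t)
            if t.verdict == "dependent":
                activators.setdefault(t.var_index, set()).add(t.condset[0])
    extras = set(activators)
    candidates = C | extras

    # Step 3: elimination over growing conditioning-set sizes. All size-n
    # tests are evaluated against the candidate set as it stood at the start
    # of the round; removals apply at round end. Spouse-captured candidates
    # are removable only by sets containing one of their activators (their
    # dependence is conditional by nature, so only supersets of an activating
    # context are informative), and those activators stay in their pool even
    # if eliminated from the candidate set.
    sep_sets: dict[int, list[tuple[int, ...]]] = defaultdict(list)
    removed: set[int] = set()
    n = 1
    while True:
        cur = sorted(candidates)
        bound = min(len(cur) - 1, max_k)
        if n > bound:
            break
        round_out: list[CITestOutcome] = []
        for i in cur:
            if i in extras:
                pool = sorted((candidates | activators[i]) - {i})
                subsets = [
                    S for S in combinations(pool, n)
                    if activators[i].intersection(S)
                ]
            else:
                pool = sorted(candidates - {i})
                subsets = list(combinations(pool, n))
            for S in subsets:
                round_out.append(test(i, S))
        newly = set()
        for t in round_out:
            if t.verdict == "independent" and t.condset:
                sep_sets[t.var_index].append(t.condset)
                newly.add(t.var_index)
        candidates -= newly
        removed |= newly
        n += 1

    labels = {name: DependenceLabel.NONE for name in names}
    for i in sorted(candidates):
        labels[names[i]] = (
            DependenceLabel.DIRECT if i in marg_dep else DependenceLabel.CONDITIONAL
        )

    # Step 4 (star): Markov-blanket consistency pass. Eliminated features are
    # re-tested against the retained set; a feature still dependent there
    # (e.g. a spouse whose collider a larger set re-opens) is rescued as
    # conditional. Grow to a fixpoint, then shrink: every retained feature
    # must stay dependent in the full retained context (captures additionally
    # conditioned on their activators, whose collapse may close the opened
    # collider). Requires a performable test: under finite-sample gating with
    # small k the pass is inert and the result equals plain elimination,
    # leaving the pattern heuristics of Steps 5-6 to act.
    rescued: set[int] = set()
    if star:
        retained = set(candidates)
        changed = True
        while changed:
            changed = False
            for v in sorted(removed - rescued):
                S = tuple(sorted((retained | rescued) - {v}))
                if not S or len(S) > max_k:
                    continue
                out = test(v, S)
                if out.performed and out.verdict == "dependent":
                    rescued.add(v)
                    changed = True
        demoted: set[int] = set()
        changed = True
        while changed:
            changed = False
            for v in sorted((retained | rescued) - demoted):
                ctx = ((retained | rescued) - demoted) | activators.get(v, set())
                S = tuple(sorted(ctx - {v}))
                if not S or len(S) > max_k:
                    continue
                out = test(v, S)
                if out.performed and out.verdict == "independent":
                    demoted.add(v)
                    changed = True
        rescued -= demoted
        for v in sorted(demoted):
            labels[names[v]] = (
                DependenceLabel.INDIRECT if v in marg_dep else DependenceLabel.NONE
            )
            candidates.discard(v)
            removed.add(v)
        for v in sorted(rescued):
            labels[names[v]] = DependenceLabel.CONDITIONAL
            removed.discard(v)

    # Step 5: joint dependency pattern among still-eliminated marginal
    # candidates (mutually explaining pairs)
    joint_pairs: list[tuple[str, str]] = []
    if detect_joint:
        for i, j in _greedy_pairs(removed & marg_dep, sep_sets, marg_p, names):
            labels[names[i]] = DependenceLabel.JOINT
            labels[names[j]] = DependenceLabel.JOINT
            joint_pairs.append((names[i], names[j]))

    # Step 6 (star): conditional joint pattern among still-eliminated captures
    cjoint_pairs: list[tuple[str, str]] = []
    if star and detect_conditional_joint:
        cap_p = {
            i: min(
                (t.p_value for t in trace
                 if t.var_index == i and len(t.condset) == 1
                 and t.verdict == "dependent" and t.performed),
                default=0.0,
            )
            for i in removed & extras
        }
        for i, j in _greedy_pairs(removed & extras, sep_sets, cap_p, names):
            labels[names[i]] = DependenceLabel.CONDITIONAL_JOINT
            labels[names[j]] = DependenceLabel.CONDITIONAL_JOINT
            cjoint_pairs.append((names[i], names[j]))

    # Edge p-value bookkeeping: attachment p is the weakest evidence that
    # kept a variable dependent; a removal edge carries the p of the first
    # removing test.
    edge_pvalues: dict[tuple[str, str], float] = {}
    attach: dict[int, float] = {}
    removal: dict[int, CITestOutcome] = {}
    for t in trace:
        if t.performed and t.verdict == "dependent":
            attach[t.var_index] = max(attach.get(t.var_index, 0.0), t.p_value)
        if t.verdict == "independent" and t.condset and t.var_index not in removal:
            removal[t.var_index] = t
    for i, name in enumerate(names):
        lbl = labels[name]
        if lbl in BLANKET_LABELS:
            edge_pvalues[(target, name)] = attach.get(i, 0.0)
        elif lbl is DependenceLabel.INDIRECT or (
            lbl is DependenceLabel.NONE and i in removal
        ):
            t = removal.get(i)
            if t is not None:
                for s in t.condset:
                    edge_pvalues[(names[s], name)] = t.p_value

    # Remaining eliminated marginal candidates are indirect.
    for i in sorted(removed & marg_dep):
        if labels[names[i]] is DependenceLabel.NONE:
            labels[names[i]] = DependenceLabel.INDIRECT
            t = removal.get(i)
            if t is not None:
                for s in t.condset:
                    edge_pvalues[(names[s], names[i])] = t.p_value

    return NCPCResult(
        labels=labels,
        trace=trace,
        edge_pvalues=edge_pvalues,
        algorithm=algorithm,
        config=config,
        joint_pairs=joint_pairs,
        conditional_joint_pairs=cjoint_pairs,
    )


def ncpc(
    data: BinaryDataset | None = None,
    config: NCPCConfig | None = None,
    detect_joint: bool = True,
    *,
    ci_test: Callable | None = None,
) -> NCPCResult:
    """Causal-neighbourhood search: direct/joint/indirect/none labels."""
    return _search(
        data, config, ci_test,
        star=False, detect_joint=detect_joint,
        detect_conditional_joint=False, algorithm="ncpc",
    )


def ncpc_star(
    data: BinaryDataset | None = None,
    config: NCPCConfig | None = None,
    detect_joint: bool = True,
    detect_conditional_joint: bool = True,
    *,
    ci_test: Callable | None = None,
) -> NCPCResult:
    """Markov-blanket search: adds conditional/conditional_joint labels."""
    return _search(
        data, config, ci_test,
        star=True, detect_joint=detect_joint,
        detect_conditional_joint=detect_conditional_joint, algorithm="ncpc_star",
    )


def pc_local_baseline(
    data: BinaryDataset | None = None,
    config: NCPCConfig | None = None,
    *,
    ci_test: Callable | None = None,
) -> NCPCResult:
    """Plain local PC-style elimination with no pattern rescue."""
    return _search(
        data, config, ci_test,
        star=False, detect_joint=False,
        detect_conditional_joint=False, algorithm="pc_local",
    )
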