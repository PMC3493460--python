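"""Conditional-independence tests for binary data.

Two stratified test statistics are provided — the Pearson chi-square and the
G statistic (mutual information) — with Monte-Carlo p-values obtained by
permuting the tested feature within each conditioning stratum while the
target stays fixed. For a 2x2 stratum with fixed margins this permutation
null makes the (1,1) cell hypergeometric, which is how the resampling is
carried out (vectorized over all B resamples).

Test power is controlled by two rules taken together:

* a *gate*: a test is performed only when every realized conditioning
  stratum holds at least ``min_stratum_count`` observations; otherwise the
  variables are conservatively declared dependent, and
* a cap on the conditioning-set size, k = floor(log2(T_min / l)) with
  T_min the minority count of the target and l the per-stratum minimum.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
from scipy.special import xlogy
from statsmodels.stats.multitest import multipletests

from .core import BinaryDataset, CITestOutcome, NCPCConfig

__all__ = [
    "stratify",
    "chisq_statistic",
    "mi_statistic",
    "gate_test",
    "max_condset_size",
    "mc_pvalue",
    "adjust_pvalues",
    "MonteCarloCITest",
]


def _stratum_codes(data: BinaryDataset, condset: Sequence[int]) -> np.ndarray:
    """Integer code of the conditioning assignment for every observation."""
    condset = tuple(condset)
    if not condset:
        return np.zeros(data.n_obs, dtype=np.int64)
    cols = data.X[:, list(condset)].astype(np.int64)
    weights = 1 << np.arange(len(condset), dtype=np.int64)
    return cols @ weights


def stratify(data: BinaryDataset, i: int, condset: Iterable[int]) -> list[np.ndarray]:
    """2x2 contingency tables of (X_i, T), one per realized conditioning stratum.

    ``table[x, t]`` counts observations with X_i = x and T = t. Strata with
    zero observations are omitted; an empty conditioning set yields a single
    table over all observations.
    """
    condset = tuple(condset)
    if i in condset:
        raise ValueError("tested variable cannot be in its conditioning set")
    codes = _stratum_codes(data, condset)
    xi = data.column(i)
    tables = []
    for code in np.unique(codes):
        mask = codes == code
        x, t = xi[mask], data.T[mask]
        tab = np.zeros((2, 2), dtype=np.int64)
        np.add.at(tab, (x, t), 1)
        tables.append(tab)
    return tables


def chisq_statistic(tables: Sequence[np.ndarray]) -> float:
    """Sum over strata of the Pearson chi-square statistic (no continuity
    correction); strata with a zero marginal contribute 0."""
    total = 0.0
    for tab in tables:
        tab = np.asarray(tab, dtype=float)
        rows = tab.sum(axis=1)
        cols = tab.sum(axis=0)
        n = tab.sum()
        if n == 0 or (rows == 0).any() or (cols == 0).any():
            continue
        expected = np.outer(rows, cols) / n
        total += float(((tab - expected) ** 2 / expected).sum())
    return total


def mi_statistic(tables: Sequence[np.ndarray]) -> float:
    """Stratified G statistic 2*sum n_xy*ln(n_xy*N/(n_x*n_y)), 0*ln(0)=0."""
    total = 0.0
    for tab in tables:
        tab = np.asarray(tab, dtype=float)
        rows = tab.sum(axis=1)
        cols = tab.sum(axis=0)
        n = tab.sum()
        if n == 0 or (rows == 0).any() or (cols == 0).any():
            continue
        expected = np.outer(rows, cols) / n
        total += 2.0 * float((xlogy(tab, tab) - xlogy(tab, expected)).sum())
    return total


def gate_test(data: BinaryDataset, condset: Iterable[int], config: NCPCConfig) -> bool:
    """True when the conditioning-set strata are well enough populated.

    Default ("per_stratum") reading: every realized stratum must hold at
    least ``min_stratum_count`` observations. The alternative "total"
    reading requires n_obs >= min_stratum_count * 2^|condset|.
    """
    condset = tuple(condset)
    if config.gate_mode == "total":
        return data.n_obs >= config.min_stratum_count * (1 << len(condset))
    codes = _stratum_codes(data, condset)
    counts = np.bincount(codes)
    counts = counts[counts > 0]
    return bool((counts >= config.min_stratum_count).all())


def max_condset_size(T: np.ndarray, config: NCPCConfig) -> int:
    """Resolve the conditioning-set size cap k from the target vector.

    k = floor(log2(T_min / l)) floored at 0, where T_min is the smaller of
    the target's one/zero counts and l = ``config.min_stratum_count``.
    """
    if config.max_condset_size is not None:
        return int(config.max_condset_size)
    T = np.asarray(T)
    ones = int(T.sum())
    t_min = min(ones, T.size - ones)
    if t_min == 0:
        raise ValueError("target has no variation")
    if t_min < config.min_stratum_count:
        return 0
    return int(math.floor(math.log2(t_min / config.min_stratum_count)))


def _stratum_margins(data: BinaryDataset, i: int, condset: tuple[int, ...]):
    """Per-stratum (N, r1, c1): total, #X_i=1, #T=1."""
    codes = _stratum_codes(data, condset)
    xi = data.column(i).astype(np.int64)
    t = data.T.astype(np.int64)
    uniq, inv = np.unique(codes, return_inverse=True)
    n = np.bincount(inv)
    r1 = np.bincount(inv, weights=xi).astype(np.int64)
    c1 = np.bincount(inv, weights=t).astype(np.int64)
    a = np.bincount(inv, weights=xi * t).astype(np.int64)
    return n, r1, c1, a


def _cell_stats(a: np.ndarray, n: int, r1: int, c1: int, kind: str) -> np.ndarray:
    """Statistic of a 2x2 table as a function of the (1,1) cell count ``a``
    with fixed margins. Degenerate margins give 0."""
    a = np.asarray(a, dtype=float)
    r0, c0 = n - r1, n - c1
    if n == 0 or 0 in (r1, r0, c1, c0):
        return np.zeros_like(a)
    if kind == "mc_chisq":
        return n * (a * n - r1 * c1) ** 2 / (r1 * r0 * c1 * c0)
    # G statistic
    n11 = a
    n10 = r1 - a
    n01 = c1 - a
    n00 = n - r1 - c1 + a
    out = np.zeros_like(a)
    for cell, r, c in ((n11, r1, c1), (n10, r1, c0), (n01, r0, c1), (n00, r0, c0)):
        out += xlogy(cell, cell * n) - xlogy(cell, r * c)
    return 2.0 * out


def mc_pvalue(
    data: BinaryDataset,
    i: int,
    condset: Iterable[int],
    config: NCPCConfig,
    rng: np.random.Generator | None = None,
) -> CITestOutcome:
    """Monte-Carlo permutation test of X_i vs T given the conditioning set.

    The null resamples permute X_i within each conditioning stratum while T
    stays fixed, which preserves the conditional independence null exactly;
    the p-value uses the add-one estimator (1 + #{stat_b >= stat_obs}) /
    (B + 1). Zero-variance X_i or T in all strata gives statistic 0 and
    p = 1 (verdict independent).
    """
    condset = tuple(sorted(set(condset)))
    if i in condset:
        raise ValueError("tested variable cannot be in its conditioning set")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, r1, c1, a_obs = _stratum_margins(data, i, condset)
    kind = config.test_kind
    degenerate = all(
        ns == 0 or r in (0, ns) or c in (0, ns) for ns, r, c in zip(n, r1, c1)
    )
    if degenerate:
        return CITestOutcome(i, condset, 0.0, 1.0, True, "independent")
    stat_obs = 0.0
    B = config.n_permutations
    stat_null = np.zeros(B)
    for ns, r, c, a in zip(n, r1, c1, a_obs):
        stat_obs += float(_cell_stats(np.array([a]), ns, r, c, kind)[0])
        if ns == 0 or r in (0, ns) or c in (0, ns):
            continue
        draws = rng.hypergeometric(r, ns - r, c, size=B)
        stat_null += _cell_stats(draws, ns, r, c, kind)
    exceed = int((stat_null >= stat_obs - 1e-12).sum())
    p = (1 + exceed) / (B + 1)
    verdict = "independent" if p > config.alpha else "dependent"
    return CITestOutcome(i, condset, stat_obs, p, True, verdict)


def adjust_pvalues(pvals: Sequence[float], method: str = "none") -> np.ndarray:
    """Multiple-testing adjustment: identity, Benjamini-Hochberg or
    Benjamini-Yekutieli step-up adjusted p-values."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return pvals
    if method == "none":
        return pvals.copy()
    if method not in ("bh", "by"):
        raise ValueError(f"unknown correction {method!r}")
    sm_method = {"bh": "fdr_bh", "by": "fdr_by"}[method]
    return multipletests(pvals, method=sm_method)[1]


class MonteCarloCITest:
    """Callable CI test bound to one dataset, configuration and RNG stream.

    Applies the power gate before testing; a gated-out test is recorded as
    unperformed with the conservative "dependent" verdict.
    """

    def __init__(self, data: BinaryDataset, config: NCPCConfig,
                 rng: np.random.Generator | None = None):
        self.data = data
        self.config = config
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)

    @property
    def m(self) -> int:
        return self.data.m

    @property
    def variable_names(self) -> tuple[str, ...]:
        return self.data.variable_names

    def __call__(self, i: int, condset: Iterable[int]) -> CITestOutcome:
        condset = tuple(sorted(set(condset)))
        if not gate_test(self.data, condset, self.config):
            return CITestOutcome(i, condset, 0.0, 0.0, False, "dependent")
        return mc_pvalue(self.data, i, condset, self.config, rng=self.rng)
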