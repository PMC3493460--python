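"""Enrichment of presence/absence combinations within a class of observations.

Given a handful of binary features (e.g. the TFs of an inferred causal
neighbourhood) and a binary class membership, every realized presence/
absence pattern is compared between the class and the remaining
observations with Fisher's exact test, adjusted across patterns by
Benjamini-Hochberg, and flagged enriched or depleted by the sign of the
frequency difference.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from .citest import adjust_pvalues
from .core import BinaryDataset

__all__ = ["combination_counts", "fisher_enrichment"]


def combination_counts(
    data: BinaryDataset, tf_subset: Sequence[str]
) -> pd.DataFrame:
    """Counts and frequencies of every realized feature pattern, in-class
    (target = 1) versus the rest (target = 0).

    Columns: one per feature (0/1), then count_class, count_rest, pct_class,
    pct_rest and their difference (percentage points, class minus rest).
    """
    if not 1 <= len(tf_subset) <= 6:
        raise ValueError("tf_subset must contain between 1 and 6 features")
    idx = [data.index_of(t) for t in tf_subset]
    sub = data.X[:, idx]
    in_class = data.T == 1
    n_class = int(in_class.sum())
    n_rest = int((~in_class).sum())
    if n_class == 0 or n_rest == 0:
        raise ValueError("both the class and the rest must be non-empty")
    patterns, inv = np.unique(sub, axis=0, return_inverse=True)
    rows = []
    for k, pat in enumerate(patterns):
        mask = inv == k
        a = int((mask & in_class).sum())
        b = int((mask & ~in_class).sum())
        rows.append(
            {
                **{t: int(v) for t, v in zip(tf_subset, pat)},
                "count_class": a,
                "count_rest": b,
                "pct_class": 100.0 * a / n_class,
                "pct_rest": 100.0 * b / n_rest,
            }
        )
    df = pd.DataFrame(rows)
    df["difference"] = df["pct_class"] - df["pct_rest"]
    df.attrs["n_class"] = n_class
    df.attrs["n_rest"] = n_rest
    df.attrs["features"] = list(tf_subset)
    return df


def fisher_enrichment(
    counts_table: pd.DataFrame,
    fdr_threshold: float = 0.15,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher's exact test per pattern with BH adjustment across patterns.

    Each pattern's 2x2 table is (pattern-in-class, pattern-in-rest,
    other-in-class, other-in-rest). A pattern is retained when its adjusted
    p-value is below ``fdr_threshold``; direction follows the sign of the
    class-vs-rest frequency difference (enriched / depleted).
    """
    df = counts_table.copy()
    n_class = df.attrs.get("n_class", int(df["count_class"].sum()))
    n_rest = df.attrs.get("n_rest", int(df["count_rest"].sum()))
    pvals = []
    for _, row in df.iterrows():
        a, b = int(row["count_class"]), int(row["count_rest"])
        table = [[a, b], [n_class - a, n_rest - b]]
        pvals.append(float(fisher_exact(table, alternative=alternative)[1]))
    df["p_value"] = pvals
    df["p_adjusted"] = adjust_pvalues(pvals, "bh")
    df["retained"] = df["p_adjusted"] < fdr_threshold
    df["direction"] = np.where(df["difference"] >= 0, "enriched", "depleted")
    return df
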