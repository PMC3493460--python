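"""Shared domain types, validation and serialization.

The central container is :class:`BinaryDataset`: an ``n_obs x m`` matrix of
binary features (e.g. transcription-factor binding profiles over a set of
cis-regulatory modules) together with one designated binary target vector
(e.g. the expression state of each module). Every statistical test in the
package runs on this universe.

Results of a local-structure search are carried by :class:`NCPCResult`,
which maps every feature to exactly one :class:`DependenceLabel` and keeps
the full audit trail of conditional-independence tests.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BinaryDataset",
    "NCPCConfig",
    "CITestOutcome",
    "DependenceLabel",
    "NCPCResult",
    "ValidationError",
    "validate_dataset",
    "read_table",
    "one_vs_rest_targets",
]


class ValidationError(ValueError):
    """Raised when an input table violates the binary-data contract."""


class DependenceLabel(str, enum.Enum):
    """Type of statistical dependence between a feature and the target.

    ``direct``            dependent given every tested conditioning set
    ``joint``             member of a joint dependency pattern (two correlated
                          candidates that explain each other away)
    ``conditional``       marginally independent but dependent given some set
    ``conditional_joint`` member of a conditional joint dependency pattern
    ``indirect``          marginally dependent but explained away by others
    ``none``              no detectable dependence
    """

    DIRECT = "direct"
    JOINT = "joint"
    CONDITIONAL = "conditional"
    CONDITIONAL_JOINT = "conditional_joint"
    INDIRECT = "indirect"
    NONE = "none"


#: labels constituting the reported causal neighbourhood
NEIGHBOURHOOD_LABELS = frozenset({DependenceLabel.DIRECT, DependenceLabel.JOINT})
#: labels constituting the reported Markov blanket
BLANKET_LABELS = frozenset(
    {
        DependenceLabel.DIRECT,
        DependenceLabel.JOINT,
        DependenceLabel.CONDITIONAL,
        DependenceLabel.CONDITIONAL_JOINT,
    }
)

_TRUTHY = {"1", "TRUE", "T", "YES"}
_FALSY = {"0", "FALSE", "F", "NO"}


@dataclass(frozen=True)
class BinaryDataset:
    """Binary observation matrix plus a designated binary target vector."""

    X: np.ndarray
    variable_names: tuple[str, ...]
    T: np.ndarray
    target_name: str = "target"

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.int8)
        T = np.asarray(self.T, dtype=np.int8)
        if X.ndim != 2:
            raise ValidationError("X must be a 2-d matrix")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValidationError("need at least one observation and one variable")
        if T.shape != (X.shape[0],):
            raise ValidationError(
                f"target length {T.shape} does not match n_obs={X.shape[0]}"
            )
        for arr, what in ((X, "X"), (T, self.target_name)):
            bad = ~np.isin(arr, (0, 1))
            if bad.any():
                idx = np.argwhere(bad)[0]
                raise ValidationError(f"non-binary value in {what} at row {idx[0]}")
        names = tuple(str(n) for n in self.variable_names)
        if len(names) != X.shape[1]:
            raise ValidationError("variable_names length does not match X columns")
        if len(set(names)) != len(names):
            raise ValidationError("duplicate variable names")
        if self.target_name in names:
            raise ValidationError("target_name collides with a variable name")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "T", T)
        object.__setattr__(self, "variable_names", names)

    @property
    def n_obs(self) -> int:
        return int(self.X.shape[0])

    @property
    def m(self) -> int:
        return int(self.X.shape[1])

    def column(self, i: int) -> np.ndarray:
        return self.X[:, i]

    def index_of(self, name: str) -> int:
        return self.variable_names.index(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.variable_names))
        df[self.target_name] = self.T
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame, target_name: str) -> "BinaryDataset":
        return validate_dataset(df, target_name)

    def write_csv(self, path, sep: str = ",") -> None:
        self.to_frame().to_csv(path, sep=sep, index=False)


def _coerce_binary_column(col: pd.Series, name: str) -> np.ndarray:
    """Coerce {0,1}, {TRUE,FALSE}, {"0","1"} style columns to int8 {0,1}."""
    if col.isna().any():
        row = int(np.argmax(col.isna().to_numpy()))
        raise ValidationError(f"missing value in column {name!r} at row {row}")
    out = np.empty(len(col), dtype=np.int8)
    for row, v in enumerate(col):
        if isinstance(v, (bool, np.bool_)):
            out[row] = int(v)
            continue
        if isinstance(v, (int, np.integer, float, np.floating)):
            if float(v) in (0.0, 1.0):
                out[row] = int(v)
                continue
            raise ValidationError(
                f"non-binary value {v!r} in column {name!r} at row {row}"
            )
        s = str(v).strip().upper()
        if s in _TRUTHY:
            out[row] = 1
        elif s in _FALSY:
            out[row] = 0
        else:
            raise ValidationError(
                f"non-binary value {v!r} in column {name!r} at row {row}"
            )
    return out


def validate_dataset(raw_table: pd.DataFrame, target_name: str) -> BinaryDataset:
    """Validate and coerce a tabular input into a :class:`BinaryDataset`.

    Columns may hold 0/1 integers, booleans, or the strings "0"/"1"/
    "TRUE"/"FALSE" (case-insensitive). Missing values and any other value
    are rejected with an error naming the offending row and column.
    """
    df = pd.DataFrame(raw_table)
    cols = [str(c) for c in df.columns]
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValidationError(f"duplicate column names: {dupes}")
    if target_name not in cols:
        raise ValidationError(f"target column {target_name!r} not in table")
    feature_names = [c for c in cols if c != target_name]
    if not feature_names:
        raise ValidationError("table has no feature columns besides the target")
    X = np.column_stack(
        [_coerce_binary_column(df[c], c) for c in feature_names]
    )
    T = _coerce_binary_column(df[target_name], target_name)
    return BinaryDataset(X=X, variable_names=tuple(feature_names), T=T,
                         target_name=target_name)


def read_table(path, target_name: str, sep: str | None = None,
               id_col: bool = False) -> BinaryDataset:
    """Read a CSV/TSV file with a header row into a :class:`BinaryDataset`.

    ``sep=None`` sniffs comma vs tab from the file extension/content;
    ``id_col=True`` drops the first column (row identifiers).
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    if id_col:
        df = df.iloc[:, 1:]
    return validate_dataset(df, target_name)


def one_vs_rest_targets(df: pd.DataFrame, class_col: str) -> dict[str, BinaryDataset]:
    """Expand a multi-class outcome column into one-vs-rest binary datasets.

    Each class value yields a dataset whose target is 1 for rows of that
    class and 0 for all other rows, with the remaining columns as features.
    """
    df = pd.DataFrame(df)
    if class_col not in df.columns:
        raise ValidationError(f"class column {class_col!r} not in table")
    classes = sorted(pd.unique(df[class_col]).tolist(), key=str)
    out: dict[str, BinaryDataset] = {}
    features = df.drop(columns=[class_col])
    for cls in classes:
        tname = str(cls)
        tbl = features.copy()
        if tname in tbl.columns:
            raise ValidationError(f"class value {tname!r} collides with a column")
        tbl[tname] = (df[class_col] == cls).astype(int)
        out[tname] = validate_dataset(tbl, tname)
    return out


@dataclass(frozen=True)
class NCPCConfig:
    """Configuration shared by the conditional-independence tests and searches.

    alpha              type-I error level of each CI test
    test_kind          "mc_chisq" (Monte-Carlo chi-square) or "mc_mi"
                       (Monte-Carlo mutual information / G statistic)
    n_permutations     Monte-Carlo resamples per test (B)
    min_stratum_count  minimum observations required in each realized
                       conditioning stratum before a test is performed;
                       an unperformed test conservatively counts as dependent
    max_condset_size   maximum conditioning-set size; None resolves to
                       floor(log2(T_min / min_stratum_count)) from the target
    correction         multiple-testing adjustment per test batch
    gate_mode          "per_stratum" (default) or "total" reading of the
                       test-power gate
    """

    alpha: float = 0.05
    test_kind: str = "mc_chisq"
    n_permutations: int = 5000
    min_stratum_count: int = 10
    max_condset_size: int | None = None
    correction: str = "none"
    seed: int = 0
    gate_mode: str = "per_stratum"

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.test_kind not in ("mc_chisq", "mc_mi"):
            raise ValueError(f"unknown test_kind {self.test_kind!r}")
        if self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if self.min_stratum_count < 1:
            raise ValueError("min_stratum_count must be >= 1")
        if self.max_condset_size is not None and self.max_condset_size < 0:
            raise ValueError("max_condset_size must be >= 0 or None")
        if self.correction not in ("none", "bh", "by"):
            raise ValueError(f"unknown correction {self.correction!r}")
        if self.gate_mode not in ("per_stratum", "total"):
            raise ValueError(f"unknown gate_mode {self.gate_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: Mapping) -> "NCPCConfig":
        return cls(**{k: d[k] for k in d if k in {f.name for f in dataclasses.fields(cls)}})


@dataclass(frozen=True)
class CITestOutcome:
    """Record of one conditional-independence test.

    ``performed=False`` means the power gate skipped the test; the verdict is
    then the conservative default "dependent".
    """

    var_index: int
    condset: tuple[int, ...]
    statistic: float
    p_value: float
    performed: bool
    verdict: str  # "dependent" | "independent"

    def __post_init__(self) -> None:
        object.__setattr__(self, "condset", tuple(self.condset))
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must be in [0, 1]")
        if self.verdict not in ("dependent", "independent"):
            raise ValueError(f"unknown verdict {self.verdict!r}")
        if not self.performed and self.verdict != "dependent":
            raise ValueError("skipped tests must default to 'dependent'")

    @property
    def independent(self) -> bool:
        return self.verdict == "independent"

    def to_dict(self) -> dict:
        return {
            "var_index": self.var_index,
            "condset": list(self.condset),
            "statistic": self.statistic,
            "p_value": self.p_value,
            "performed": self.performed,
            "verdict": self.verdict,
        }


@dataclass
class NCPCResult:
    """Per-variable dependence labels plus the full CI-test trace."""

    labels: dict[str, DependenceLabel]
    trace: list[CITestOutcome]
    edge_pvalues: dict[tuple[str, str], float]
    algorithm: str
    config: NCPCConfig | None = None
    joint_pairs: list[tuple[str, str]] = field(default_factory=list)
    conditional_joint_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def variable_names(self) -> list[str]:
        return list(self.labels)

    @property
    def causal_neighbourhood(self) -> set[str]:
        return {v for v, l in self.labels.items() if l in NEIGHBOURHOOD_LABELS}

    @property
    def markov_blanket(self) -> set[str]:
        return {v for v, l in self.labels.items() if l in BLANKET_LABELS}

    def separating_set(self, name: str) -> tuple[str, ...] | None:
        """First recorded conditioning set that rendered ``name`` independent."""
        names = self.variable_names
        i = names.index(name)
        for t in self.trace:
            if t.var_index == i and t.independent and t.condset:
                return tuple(names[j] for j in t.condset)
        return None

    def removal_pvalue(self, name: str) -> float | None:
        names = self.variable_names
        i = names.index(name)
        for t in self.trace:
            if t.var_index == i and t.independent and t.condset:
                return t.p_value
        return None

    def near_alpha_pvalues(self, window: float = 0.02) -> list[CITestOutcome]:
        """Performed tests whose p-value lies within ``window`` of alpha."""
        alpha = self.config.alpha if self.config is not None else 0.05
        return [
            t for t in self.trace
            if t.performed and abs(t.p_value - alpha) <= window
        ]

    # ---- serialization ---------------------------------------------------

    def to_json(self, **json_kwargs) -> str:
        payload = {
            "algorithm": self.algorithm,
            "labels": {k: v.value for k, v in self.labels.items()},
            "edge_pvalues": [[a, b, p] for (a, b), p in sorted(self.edge_pvalues.items())],
            "joint_pairs": [list(p) for p in self.joint_pairs],
            "conditional_joint_pairs": [list(p) for p in self.conditional_joint_pairs],
            "config": self.config.to_dict() if self.config is not None else None,
            "trace": [t.to_dict() for t in self.trace],
        }
        return json.dumps(payload, **json_kwargs)

    @classmethod
    def from_json(cls, text: str) -> "NCPCResult":
        d = json.loads(text)
        return cls(
            labels={k: DependenceLabel(v) for k, v in d["labels"].items()},
            trace=[CITestOutcome(**t) for t in d["trace"]],
            edge_pvalues={(a, b): p for a, b, p in d["edge_pvalues"]},
            algorithm=d["algorithm"],
            config=NCPCConfig.from_dict(d["config"]) if d.get("config") else None,
            joint_pairs=[tuple(p) for p in d.get("joint_pairs", [])],
            conditional_joint_pairs=[tuple(p) for p in d.get("conditional_joint_pairs", [])],
        )

    def labels_frame(self) -> pd.DataFrame:
        """Flat per-variable table: label, attachment/removal p-values."""
        rows = []
        for name, label in self.labels.items():
            attach = None
            for (a, b), p in self.edge_pvalues.items():
                if b == name:
                    attach = p if attach is None else max(attach, p)
            rows.append(
                {
                    "variable": name,
                    "label": label.value,
                    "p_value": attach if attach is not None else math.nan,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.labels_frame().to_csv(path, sep="\t", index=False)
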