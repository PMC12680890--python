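"""Model-ready matrix assembly: encodings, standardization, splits.

Five modeling approaches share one feature table (nine echo features plus
sample metadata) but differ in design matrix and target:

=========  =====================================  ======  ==================
approach   inputs                                 width   target
=========  =====================================  ======  ==================
1          echo features (one strain at a time)      9    cell count
2          echo features, all strains                9    cell count
3          + one-hot strain identity                12    cell count
4          + ordinal wort concentration             13    cell count
5          echo features                             9    strain class
=========  =====================================  ======  ==================

Standardization applies to the nine echo features only — encoded covariates
pass through — and is always fitted on training rows alone.  Splitting is
group-aware by default: all rows derived from one physical measurement stay
on the same side of the train/test boundary and inside a single CV fold,
preventing leakage between near-duplicate averaged signals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .processing import FEATURE_NAMES
from .simulate import Strain, WORT_LEVELS

__all__ = [
    "FEATURE_COLUMNS",
    "LABEL_COLUMNS",
    "one_hot_strain",
    "ordinal_wort",
    "assemble",
    "UltrasoundScaler",
    "SplitPlan",
    "make_split",
]

FEATURE_COLUMNS: tuple[str, ...] = FEATURE_NAMES
LABEL_COLUMNS: tuple[str, ...] = (
    "measurement_id",
    "signal_index",
    "strain",
    "wort_wt_pct",
    "yeast_wt_pct",
    "replicate",
    "measured_cell_count",
)

_ORDINAL_WORT = {10.0: -1.0, 12.0: 0.0, 14.0: 1.0}


def one_hot_strain(strain: Strain | str) -> np.ndarray:
    """Indicator vector over the fixed strain order (S. cerevisiae, WB-06, W 34/70)."""
    strain = Strain.coerce(strain)
    vec = np.zeros(len(Strain))
    vec[list(Strain).index(strain)] = 1.0
    return vec


def ordinal_wort(wort_wt_pct: float) -> float:
    """Ordinal code of the wort extract level: 10 -> -1, 12 -> 0, 14 -> +1."""
    key = float(wort_wt_pct)
    if key not in _ORDINAL_WORT:
        raise ValueError(f"wort_wt_pct must be one of {sorted(WORT_LEVELS)}, got {wort_wt_pct!r}")
    return _ORDINAL_WORT[key]


def _check_rows(rows: pd.DataFrame) -> None:
    missing = [c for c in (*FEATURE_COLUMNS, "strain", "wort_wt_pct", "measured_cell_count") if c not in rows.columns]
    if missing:
        raise ValueError(f"feature table lacks columns: {missing}")
    if rows[list(FEATURE_COLUMNS)].isna().any().any():
        raise ValueError("feature table contains missing values")


def assemble(approach: int, rows: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, dict]:
    """Design matrix, target and schema for one approach.

    Column order is the echo-feature block, then the one-hot strain block
    (approaches 3-4), then the ordinal wort scalar (approach 4).  Approach 1
    demands a single-strain table; approach 5 returns integer class indices.
    """
    if approach not in (1, 2, 3, 4, 5):
        raise ValueError("approach must be in 1..5")
    _check_rows(rows)
    strains = rows["strain"].map(lambda s: Strain.coerce(s))
    if approach == 1 and strains.nunique() > 1:
        raise ValueError("approach 1 is strain-specific; filter rows to one strain first")

    blocks = [rows[list(FEATURE_COLUMNS)].to_numpy(dtype=float)]
    columns = list(FEATURE_COLUMNS)
    if approach in (3, 4):
        blocks.append(np.stack([one_hot_strain(s) for s in strains]))
        columns += [f"strain_{s.value}" for s in Strain]
    if approach == 4:
        blocks.append(rows["wort_wt_pct"].map(ordinal_wort).to_numpy(dtype=float)[:, None])
        columns += ["wort_ordinal"]
    X = np.hstack(blocks)

    if approach == 5:
        order = list(Strain)
        y = strains.map(order.index).to_numpy(dtype=int)
        target = "strain_class"
    else:
        y = rows["measured_cell_count"].to_numpy(dtype=float)
        target = "measured_cell_count"
    schema = {
        "approach": approach,
        "columns": columns,
        "n_scaled": len(FEATURE_COLUMNS),
        "target": target,
        "class_order": [s.value for s in Strain] if approach == 5 else None,
    }
    return X, y, schema


class UltrasoundScaler(TransformerMixin, BaseEstimator):
    """Zero-mean/unit-variance scaling of the leading echo-feature block.

    Only the first ``n_scaled`` columns are standardized; trailing encoded
    covariates (one-hot strain, ordinal wort) pass through untouched.  A
    constant training column gets scale 1 (centered zeros) with a warning.
    The transform is a plain affine map, so applying a fitted scaler twice
    is deliberately not the same as applying it once.
    """

    def __init__(self, n_scaled: int = len(FEATURE_COLUMNS)):
        self.n_scaled = n_scaled

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < self.n_scaled:
            raise ValueError(f"X must be 2-D with at least {self.n_scaled} columns")
        block = X[:, : self.n_scaled]
        self.mean_ = block.mean(axis=0)
        std = block.std(axis=0)
        constant = std < 1e-15
        if constant.any():
            warnings.warn(
                f"{int(constant.sum())} constant feature column(s); scale set to 1",
                RuntimeWarning,
                stacklevel=2,
            )
            std = np.where(constant, 1.0, std)
        self.scale_ = std
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("column count differs from the fitting data")
        out = X.copy()
        out[:, : self.n_scaled] = (out[:, : self.n_scaled] - self.mean_) / self.scale_
        return out

    def to_dict(self) -> dict:
        return {
            "n_scaled": self.n_scaled,
            "mean": self.mean_.tolist(),
            "scale": self.scale_.tolist(),
            "n_features_in": int(self.n_features_in_),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "UltrasoundScaler":
        obj = cls(n_scaled=payload["n_scaled"])
        obj.mean_ = np.asarray(payload["mean"], dtype=float)
        obj.scale_ = np.asarray(payload["scale"], dtype=float)
        obj.n_features_in_ = payload["n_features_in"]
        return obj


@dataclass
class SplitPlan:
    """80:20 train/test partition plus fivefold assignment of training rows.

    Row ids index the feature table; ``fold_of`` maps each training row id
    to a fold in 0..n_folds-1.
    """

    train_ids: np.ndarray
    test_ids: np.ndarray
    fold_of: dict[int, int]
    seed: int
    policy: str
    n_folds: int = 5

    def fold_ids(self, fold: int) -> np.ndarray:
        return np.array([i for i in self.train_ids if self.fold_of[int(i)] == fold], dtype=int)

    def to_dict(self) -> dict:
        return {
            "train_ids": [int(i) for i in self.train_ids],
            "test_ids": [int(i) for i in self.test_ids],
            "fold_of": {str(k): int(v) for k, v in self.fold_of.items()},
            "seed": int(self.seed),
            "policy": self.policy,
            "n_folds": int(self.n_folds),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, payload: dict) -> "SplitPlan":
        return cls(
            train_ids=np.asarray(payload["train_ids"], dtype=int),
            test_ids=np.asarray(payload["test_ids"], dtype=int),
            fold_of={int(k): int(v) for k, v in payload["fold_of"].items()},
            seed=payload["seed"],
            policy=payload["policy"],
            n_folds=payload["n_folds"],
        )


def make_split(
    rows: pd.DataFrame,
    seed: int,
    *,
    group_aware: bool = True,
    test_fraction: float = 0.2,
    n_folds: int = 5,
) -> SplitPlan:
    """Deterministic stratified split and CV fold plan.

    Group-aware mode partitions physical measurements (``measurement_id``)
    and stratifies by strain, so every row of a measurement lands on one
    side and in one fold.  Row mode reproduces a literal random row split.
    """
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    if group_aware:
        if "measurement_id" not in rows.columns:
            raise ValueError("group-aware split requires a measurement_id column")
        groups = rows.groupby("measurement_id", sort=True)
        if groups.ngroups < 10:
            raise ValueError("group-aware split needs at least 10 measurements")
        group_rows = {gid: np.asarray(idx, dtype=int) for gid, idx in groups.groups.items()}
        group_strain = rows.groupby("measurement_id", sort=True)["strain"].first()
        train_ids: list[int] = []
        test_ids: list[int] = []
        fold_of: dict[int, int] = {}
        for stratum in sorted(group_strain.unique()):
            gids = sorted(g for g in group_rows if group_strain[g] == stratum)
            gids = [gids[i] for i in rng.permutation(len(gids))]
            n_test = int(round(test_fraction * len(gids)))
            for gid in gids[:n_test]:
                test_ids.extend(group_rows[gid].tolist())
            train_gids = gids[n_test:]
            if len(train_gids) < n_folds:
                raise ValueError("too few training measurements to form non-empty folds")
            for j, gid in enumerate(train_gids):
                fold = j % n_folds
                for rid in group_rows[gid]:
                    train_ids.append(int(rid))
                    fold_of[int(rid)] = fold
    else:
        ids = rows.index.to_numpy(dtype=int)
        perm = ids[rng.permutation(len(ids))]
        n_test = int(round(test_fraction * len(ids)))
        test_ids = perm[:n_test].tolist()
        train_ids = perm[n_test:].tolist()
        if len(train_ids) < n_folds:
            raise ValueError("too few training rows to form non-empty folds")
        fold_of = {int(rid): j % n_folds for j, rid in enumerate(train_ids)}

    return SplitPlan(
        train_ids=np.asarray(sorted(train_ids), dtype=int),
        test_ids=np.asarray(sorted(test_ids), dtype=int),
        fold_of=fold_of,
        seed=seed,
        policy="group" if group_aware else "row",
        n_folds=n_folds,
    )
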