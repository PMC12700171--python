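"""Gradient-boosted yield prediction and exhaustive descriptor-subset search.

The regressor is a histogram-binned gradient-boosted tree ensemble
(sklearn's ``HistGradientBoostingRegressor``); performance is reported as
test-set R^2 and RMSE averaged over repeated random train/test splits with
fixed per-run seeds, so that different descriptor sets are compared on
identical splits (paired comparison).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingRegressor
from sklearn.metrics import mean_squared_error, r2_score
from sklearn.model_selection import train_test_split

from .descriptors import (
    DescriptorMatrix,
    FeatureSpec,
    ReactionDataset,
    SensitizerRecord,
    assemble_features,
)

__all__ = [
    "FittedModel",
    "EvaluationResult",
    "SearchResult",
    "train_model",
    "evaluate_repeated",
    "subset_search",
    "enumerate_auxiliary_subsets",
]

MAX_POOL_SIZE = 15


@dataclass
class FittedModel:
    """A fitted gradient-boosted regressor plus its training context."""

    regressor: HistGradientBoostingRegressor
    feature_names: list[str]
    X_train: pd.DataFrame
    y_train: pd.Series
    spec: FeatureSpec | None = None

    def predict(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in rows.columns]
        if missing:
            raise ValueError(f"rows missing feature columns: {missing}")
        return self.regressor.predict(rows[self.feature_names])


def train_model(
    matrix: DescriptorMatrix,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> FittedModel:
    """Fit a histogram-gradient-boosting regressor on the full matrix.

    Hyperparameters default to the library defaults; ``seed`` fixes the
    histogram subsampling and hence makes refits bit-reproducible.
    """
    if len(matrix) < 10:
        raise ValueError("need at least 10 rows to train")
    X = matrix.X.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("feature matrix contains non-finite values")
    y = matrix.y.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("constant target: model will predict the constant")
    reg = HistGradientBoostingRegressor(random_state=seed, **dict(hyperparams or {}))
    reg.fit(matrix.X, matrix.y)
    return FittedModel(
        regressor=reg,
        feature_names=list(matrix.X.columns),
        X_train=matrix.X,
        y_train=matrix.y,
        spec=matrix.spec,
    )


@dataclass
class EvaluationResult:
    """Repeated-split test scores of one descriptor set."""

    spec: FeatureSpec
    per_run: list[tuple[int, float, float]]  # (seed, r2, rmse)
    mean_r2: float = field(init=False)
    sd_r2: float = field(init=False)
    mean_rmse: float = field(init=False)
    sd_rmse: float = field(init=False)

    def __post_init__(self) -> None:
        r2 = np.array([r for _, r, _ in self.per_run])
        rmse = np.array([m for _, _, m in self.per_run])
        self.mean_r2 = float(r2.mean())
        self.sd_r2 = float(r2.std(ddof=1)) if len(r2) > 1 else 0.0
        self.mean_rmse = float(rmse.mean())
        self.sd_rmse = float(rmse.std(ddof=1)) if len(rmse) > 1 else 0.0

    def to_row(self) -> dict:
        return {
            "descriptor_set": self.spec.label,
            "mean_r2": self.mean_r2,
            "sd_r2": self.sd_r2,
            "mean_rmse": self.mean_rmse,
            "sd_rmse": self.sd_rmse,
        }


def evaluate_repeated(
    matrix: DescriptorMatrix,
    n_runs: int = 10,
    test_fraction: float = 0.2,
    hyperparams: Mapping | None = None,
) -> EvaluationResult:
    """Mean/SD of test R^2 and RMSE over ``n_runs`` random splits.

    Run ``i`` uses split seed ``i`` (0..n_runs-1), so evaluations of
    different descriptor sets on the same dataset are paired.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not 0 < test_fraction < 1:
        raise ValueError("test_fraction must be in (0, 1)")
    if int(len(matrix) * test_fraction) < 2:
        raise ValueError("test split would have fewer than 2 rows")
    per_run = []
    for seed in range(n_runs):
        X_tr, X_te, y_tr, y_te = train_test_split(
            matrix.X, matrix.y, test_size=test_fraction, random_state=seed
        )
        reg = HistGradientBoostingRegressor(
            random_state=seed, **dict(hyperparams or {})
        )
        reg.fit(X_tr, y_tr)
        pred = reg.predict(X_te)
        r2 = r2_score(y_te, pred)
        rmse = float(np.sqrt(mean_squared_error(y_te, pred)))
        per_run.append((seed, float(r2), rmse))
    return EvaluationResult(spec=matrix.spec, per_run=per_run)


def enumerate_auxiliary_subsets(
    pool: Sequence[str], include_empty: bool = False
) -> list[tuple[str, ...]]:
    """All subsets of the auxiliary pool, in deterministic bitmask order.

    Non-empty subsets only unless ``include_empty``; a pool of d
    descriptors yields 2^d - 1 subsets.
    """
    pool = list(pool)
    if len(pool) > MAX_POOL_SIZE:
        raise ValueError(
            f"pool of {len(pool)} descriptors exceeds the exhaustive-search "
            f"guard ({MAX_POOL_SIZE}); a heuristic mode is not implemented"
        )
    subsets = []
    for mask in range(0 if include_empty else 1, 2 ** len(pool)):
        subsets.append(tuple(p for j, p in enumerate(pool) if mask & (1 << j)))
    return subsets


@dataclass
class SearchResult:
    """Ranked outcome of the exhaustive descriptor-combination search."""

    entries: list[EvaluationResult]

    def __post_init__(self) -> None:
        self.entries = sorted(
            self.entries,
            key=lambda e: (-e.mean_r2, e.mean_rmse, e.spec.label),
        )

    @property
    def best(self) -> EvaluationResult:
        return self.entries[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([e.to_row() for e in self.entries])

    def __len__(self) -> int:
        return len(self.entries)


def subset_search(
    dataset: ReactionDataset,
    sensitizers: Sequence[SensitizerRecord],
    base_sets: Sequence[str] = ("s_RC",),
    auxiliary_pool: Sequence[str] | None = None,
    n_runs: int = 10,
    test_fraction: float = 0.2,
    hyperparams: Mapping | None = None,
    include_base_only: bool = False,
    rate_transform: str = "log10",
) -> SearchResult:
    """Evaluate every non-empty auxiliary subset for each base set.

    A pool of d auxiliary descriptors gives 2^d - 1 combinations per base
    set (plus the base-only entry when ``include_base_only``); all
    evaluations share the same split seeds, so rankings reflect descriptor
    content rather than split luck.  Entries are ranked by mean R^2
    descending, ties broken by mean RMSE then label.
    """
    from .descriptors import ELECTRONIC_COLUMNS

    pool = list(auxiliary_pool if auxiliary_pool is not None else ELECTRONIC_COLUMNS)
    subsets = enumerate_auxiliary_subsets(pool, include_empty=include_base_only)
    entries = []
    for base in base_sets:
        for aux in subsets:
            spec = FeatureSpec(
                base_set=base, auxiliary=aux, rate_transform=rate_transform
            )
            matrix = assemble_features(dataset, sensitizers, spec)
            entries.append(
                evaluate_repeated(
                    matrix,
                    n_runs=n_runs,
                    test_fraction=test_fraction,
                    hyperparams=hyperparams,
                )
            )
    return SearchResult(entries=entries)
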