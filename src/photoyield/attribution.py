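"""Shapley-value interpretation of fitted yield models.

Attributions are *interventional*: the payoff of a coalition S is the mean
model output over background rows with the features in S replaced by the
explained row's values.  This definition makes the attributions exactly
computable both by coalition enumeration (:func:`exact_shapley`, the
reference oracle, exponential in the number of features) and by the
polynomial per-leaf algorithm used for gradient-boosted trees
(:func:`explain`).  Every explanation is additive: base value plus the sum
of the per-feature attributions equals the model prediction for the row.

The pairwise decomposition (:func:`pairwise_attribution`) explains the
*difference* between two predictions from the same model: the base values
cancel, so the per-feature attribution deltas sum exactly to the
predicted-yield difference, and any named feature subset can be assigned
its share of that difference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._hgbtrees import extract_trees, hgb_raw_predict, interventional_shap

__all__ = [
    "ShapExplanation",
    "PairwiseAttribution",
    "explain",
    "exact_shapley",
    "summarize",
    "pairwise_attribution",
    "pairwise_from_values",
    "waterfall",
]

ADDITIVITY_TOL = 1e-6


@dataclass(frozen=True)
class ShapExplanation:
    """Additive attribution of one model prediction.

    ``base_value`` is the expected model output over the background;
    ``phi`` maps feature name -> attribution (yield percentage points);
    ``prediction`` is the model output for the row.  ``feature_values``
    carries the explained row itself for scatter/summary exports.
    """

    row_id: str
    base_value: float
    phi: Mapping[str, float]
    prediction: float
    feature_values: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        gap = self.base_value + sum(self.phi.values()) - self.prediction
        if abs(gap) > ADDITIVITY_TOL:
            raise ValueError(
                f"additivity violated for {self.row_id!r}: base + sum(phi) "
                f"differs from prediction by {gap:.3e}"
            )

    @property
    def features(self) -> list[str]:
        return list(self.phi)


@dataclass(frozen=True)
class PairwiseAttribution:
    """Decomposition of a predicted-yield difference between two rows."""

    id_a: str
    id_b: str
    total_delta: float
    per_feature_delta: Mapping[str, float]
    subset: tuple[str, ...]
    subset_delta: float
    subset_share: float  # subset_delta / total_delta; nan when undefined

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"feature": f, "delta_phi": v, "in_subset": f in self.subset}
            for f, v in self.per_feature_delta.items()
        ]
        return pd.DataFrame(rows)


def explain(model, rows: pd.DataFrame, background: pd.DataFrame) -> list[ShapExplanation]:
    """Interventional Tree-Shapley attributions for HGB predictions.

    ``model`` is a :class:`photoyield.modeling.FittedModel` (or any object
    exposing ``regressor`` and ``feature_names``); ``rows`` and
    ``background`` are feature frames on the model's schema.
    """
    feature_names = list(model.feature_names)
    for name, frame in (("rows", rows), ("background", background)):
        missing = [c for c in feature_names if c not in frame.columns]
        if missing:
            raise ValueError(f"{name} is missing feature columns: {missing}")
    if len(background) == 0:
        raise ValueError("background must be non-empty")
    X = rows[feature_names].to_numpy(dtype=float)
    Z = background[feature_names].to_numpy(dtype=float)

    baseline, trees = extract_trees(model.regressor)
    phi = interventional_shap(baseline, trees, X, Z)
    base_value = float(hgb_raw_predict(baseline, trees, Z).mean())
    predictions = model.regressor.predict(rows[feature_names])

    out = []
    for i in range(len(rows)):
        rid = rows.index[i]
        rid = "/".join(map(str, rid)) if isinstance(rid, tuple) else str(rid)
        out.append(
            ShapExplanation(
                row_id=rid,
                base_value=base_value,
                phi=dict(zip(feature_names, phi[i])),
                prediction=float(predictions[i]),
                feature_values=dict(zip(feature_names, X[i])),
            )
        )
    return out


def exact_shapley(
    predict: Callable[[np.ndarray], np.ndarray],
    row: np.ndarray | Sequence[float],
    background: np.ndarray,
    feature_names: Sequence[str],
) -> dict[str, float]:
    """Classic Shapley values by full coalition enumeration (the oracle).

    The value of a coalition S is the mean of ``predict`` over background
    rows with the features in S overwritten by ``row``.  Exponential in the
    number of features; limited to 15.
    """
    row = np.asarray(row, dtype=float)
    Z = np.asarray(background, dtype=float)
    d = row.size
    if d != len(feature_names):
        raise ValueError("row length must match feature_names")
    if d > 15:
        raise ValueError("exact enumeration limited to 15 features")
    m = Z.shape[0]

    # v[mask] = mean over background of predict(hybrid); evaluate all 2^d
    # hybrid matrices in one batched predict call.
    masks = np.arange(2**d)
    hybrids = np.repeat(Z[None, :, :], 2**d, axis=0)  # (2^d, m, d)
    for j in range(d):
        sel = (masks >> j) & 1 == 1
        hybrids[sel, :, j] = row[j]
    values = predict(hybrids.reshape(-1, d)).reshape(2**d, m).mean(axis=1)

    fact = [math.factorial(k) for k in range(d + 1)]
    phi = np.zeros(d)
    for mask in range(2**d):
        s = bin(mask).count("1")
        for j in range(d):
            if mask & (1 << j):
                continue
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[j] += w * (values[mask | (1 << j)] - values[mask])
    return dict(zip(feature_names, phi))


def summarize(
    explanations: Sequence[ShapExplanation],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Bar-plot and scatter-plot data from a batch of explanations.

    Returns ``(bar, scatter)``: ``bar`` ranks features by mean absolute
    attribution (ties broken lexicographically); ``scatter`` has one row
    per (explained row, feature) with the feature value and its
    attribution, preserving row order.
    """
    if not explanations:
        raise ValueError("need at least one explanation")
    features = explanations[0].features
    mean_abs = {
        f: float(np.mean([abs(e.phi[f]) for e in explanations])) for f in features
    }
    bar = (
        pd.DataFrame(
            {"feature": list(mean_abs), "mean_abs_phi": list(mean_abs.values())}
        )
        .sort_values(["mean_abs_phi", "feature"], ascending=[False, True])
        .reset_index(drop=True)
    )
    scatter = pd.DataFrame(
        [
            {
                "row_id": e.row_id,
                "feature": f,
                "value": e.feature_values.get(f, math.nan),
                "phi": e.phi[f],
            }
            for e in explanations
            for f in features
        ]
    )
    return bar, scatter


def waterfall(explanation: ShapExplanation, top_k: int | None = None) -> pd.DataFrame:
    """Waterfall-plot data: features by descending |phi| with a remainder.

    ``top_k`` limits the number of individually listed features; the rest
    are lumped into a single ``(remaining)`` bucket so the rows still sum
    from the base value to the prediction.
    """
    items = sorted(
        explanation.phi.items(), key=lambda kv: (-abs(kv[1]), kv[0])
    )
    if top_k is not None and top_k < len(items):
        head, tail = items[:top_k], items[top_k:]
        items = head + [("(remaining)", sum(v for _, v in tail))]
    cum = explanation.base_value
    rows = []
    for f, v in items:
        rows.append(
            {"feature": f, "phi": v, "cumulative": cum + v}
        )
        cum += v
    frame = pd.DataFrame(rows)
    frame.attrs["base_value"] = explanation.base_value
    frame.attrs["prediction"] = explanation.prediction
    return frame


def pairwise_attribution(
    expl_a: ShapExplanation,
    expl_b: ShapExplanation,
    subset: Sequence[str],
) -> PairwiseAttribution:
    """Attribute the predicted-yield difference B - A to a feature subset.

    Requires both explanations to come from the same model and background
    (equal base values), so the difference of predictions equals the sum of
    per-feature attribution deltas.
    """
    if list(expl_a.phi) != list(expl_b.phi):
        raise ValueError("explanations have different feature schemas")
    if abs(expl_a.base_value - expl_b.base_value) > ADDITIVITY_TOL:
        raise ValueError(
            "explanations have different base values: were they computed "
            "with the same model and background?"
        )
    unknown = [f for f in subset if f not in expl_a.phi]
    if unknown:
        raise ValueError(f"subset names not in the feature schema: {unknown}")

    per_feature = {f: expl_b.phi[f] - expl_a.phi[f] for f in expl_a.phi}
    total = expl_b.prediction - expl_a.prediction
    subset_delta = sum(per_feature[f] for f in subset)
    share = subset_delta / total if abs(total) > ADDITIVITY_TOL else math.nan
    return PairwiseAttribution(
        id_a=expl_a.row_id,
        id_b=expl_b.row_id,
        total_delta=total,
        per_feature_delta=per_feature,
        subset=tuple(subset),
        subset_delta=subset_delta,
        subset_share=share,
    )


def pairwise_from_values(
    prediction_a: float,
    prediction_b: float,
    phi_a: Mapping[str, float],
    phi_b: Mapping[str, float],
    subset: Sequence[str] | None = None,
    id_a: str = "A",
    id_b: str = "B",
) -> PairwiseAttribution:
    """Pairwise difference arithmetic on explicitly supplied attributions.

    Convenience entry point for attributions that are only partially
    reported (e.g. a published waterfall listing a few features): the
    full-schema additivity check is skipped, since the unlisted features'
    deltas are unknown.  ``subset`` defaults to all supplied features.
    """
    if set(phi_a) != set(phi_b):
        raise ValueError("phi_a and phi_b must cover the same features")
    subset = tuple(subset) if subset is not None else tuple(phi_a)
    unknown = [f for f in subset if f not in phi_a]
    if unknown:
        raise ValueError(f"subset names not among supplied features: {unknown}")
    per_feature = {f: phi_b[f] - phi_a[f] for f in phi_a}
    total = prediction_b - prediction_a
    subset_delta = sum(per_feature[f] for f in subset)
    share = subset_delta / total if abs(total) > ADDITIVITY_TOL else math.nan
    return PairwiseAttribution(
        id_a=id_a,
        id_b=id_b,
        total_delta=total,
        per_feature_delta=per_feature,
        subset=subset,
        subset_delta=subset_delta,
        subset_share=share,
    )
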