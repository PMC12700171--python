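"""Interventional Tree-Shapley for histogram-gradient-boosting regressors.

For a single decision tree and a single background row ``z``, the model
restricted to a coalition S (features in S read from the explained row
``x``, the rest from ``z``) reaches a given leaf iff every grouped path
condition holds under the hybrid row.  Grouping the path splits by feature,
each distinct path feature falls into one of four classes: passes under
both ``x`` and ``z`` (irrelevant), passes only under ``x`` (must be IN S),
passes only under ``z`` (must be OUT of S), or passes under neither (leaf
unreachable for this pair).  With ``a`` features of the x-only class and
``b`` of the z-only class, the exact Shapley contribution of the leaf value
``v`` is ``+v * (a-1)! b! / (a+b)!`` for each x-only feature and
``-v * a! (b-1)! / (a+b)!`` for each z-only feature (all other features get
zero).  Summing over leaves, trees and background rows yields the exact
interventional Shapley values — the same quantity the brute-force coalition
enumeration computes, in polynomial time.
"""

from __future__ import annotations

import numpy as np

__all__ = ["extract_trees", "hgb_raw_predict", "interventional_shap"]

_MAX_PATH_FEATURES = 64


def extract_trees(model) -> tuple[float, list[list[dict]]]:
    """Extract leaf paths from a fitted HistGradientBoostingRegressor.

    Returns ``(baseline, trees)`` where each tree is a list of leaves, each
    leaf a dict with ``value`` and ``paths``: a mapping
    ``feature_idx -> (lo, hi)`` interval such that the leaf is reached iff
    ``lo < x[f] <= hi`` for every path feature (split rule ``x <= threshold``
    goes left).
    """
    if not hasattr(model, "_predictors"):
        raise TypeError(
            "expected a fitted sklearn HistGradientBoosting model with _predictors"
        )
    baseline = float(np.squeeze(model._baseline_prediction))
    trees = []
    for predictor_pair in model._predictors:
        nodes = predictor_pair[0].nodes
        leaves: list[dict] = []

        def descend(i: int, intervals: dict[int, tuple[float, float]]) -> None:
            node = nodes[i]
            if node["is_leaf"]:
                leaves.append({"value": float(node["value"]), "paths": dict(intervals)})
                return
            f = int(node["feature_idx"])
            thr = float(node["num_threshold"])
            lo, hi = intervals.get(f, (-np.inf, np.inf))
            # left branch: x[f] <= thr
            if min(hi, thr) > lo:
                intervals[f] = (lo, min(hi, thr))
                descend(int(node["left"]), intervals)
            # right branch: x[f] > thr
            if hi > max(lo, thr):
                intervals[f] = (max(lo, thr), hi)
                descend(int(node["right"]), intervals)
            if lo == -np.inf and hi == np.inf:
                del intervals[f]
            else:
                intervals[f] = (lo, hi)

        descend(0, {})
        trees.append(leaves)
    return baseline, trees


def hgb_raw_predict(baseline: float, trees: list[list[dict]], X: np.ndarray) -> np.ndarray:
    """Re-predict from extracted leaves (fidelity check for the extraction)."""
    X = np.asarray(X, dtype=float)
    out = np.full(X.shape[0], baseline)
    for leaves in trees:
        for leaf in leaves:
            mask = np.ones(X.shape[0], dtype=bool)
            for f, (lo, hi) in leaf["paths"].items():
                mask &= (X[:, f] > lo) & (X[:, f] <= hi)
            out += np.where(mask, leaf["value"], 0.0)
    return out


def _weight_tables(n: int) -> tuple[np.ndarray, np.ndarray]:
    """W_A[a, b] = (a-1)! b! / (a+b)! and W_B[a, b] = a! (b-1)! / (a+b)!.

    Index 0 rows/columns are defined as 0; they are never selected by the
    class masks (a >= 1 whenever an x-only feature exists, likewise b).
    """
    lg = np.zeros(2 * n + 2)
    lg[1:] = np.cumsum(np.log(np.arange(1, 2 * n + 2)))  # lg[k] = log(k!)
    a = np.arange(n + 1)[:, None]
    b = np.arange(n + 1)[None, :]
    with np.errstate(invalid="ignore"):
        WA = np.exp(lg[np.maximum(a - 1, 0)] + lg[b] - lg[a + b])
        WB = np.exp(lg[a] + lg[np.maximum(b - 1, 0)] - lg[a + b])
    WA[0, :] = 0.0
    WB[:, 0] = 0.0
    return WA, WB


def interventional_shap(
    baseline: float,
    trees: list[list[dict]],
    X: np.ndarray,
    Z: np.ndarray,
) -> np.ndarray:
    """Exact interventional Shapley values of extracted trees.

    ``X``: rows to explain, shape (n, d); ``Z``: background rows, shape
    (m, d).  Returns ``phi`` of shape (n, d) with
    ``baseline_mean + phi.sum(1) == prediction`` where ``baseline_mean`` is
    the mean raw prediction over ``Z``.
    """
    X = np.asarray(X, dtype=float)
    Z = np.asarray(Z, dtype=float)
    n, d = X.shape
    m = Z.shape[0]
    if Z.shape[1] != d:
        raise ValueError("X and Z must have the same number of columns")
    WA, WB = _weight_tables(_MAX_PATH_FEATURES)
    phi = np.zeros((n, d))

    for leaves in trees:
        for leaf in leaves:
            feats = list(leaf["paths"].keys())
            P = len(feats)
            if P == 0:  # single-leaf tree: constant, no attribution
                continue
            if P > _MAX_PATH_FEATURES:  # pragma: no cover - paths are shallow
                raise ValueError("tree path deeper than supported")
            XP = np.empty((P, n), dtype=np.float64)
            ZP = np.empty((P, m), dtype=np.float64)
            for k, f in enumerate(feats):
                lo, hi = leaf["paths"][f]
                XP[k] = (X[:, f] > lo) & (X[:, f] <= hi)
                ZP[k] = (Z[:, f] > lo) & (Z[:, f] <= hi)
            # per-pair counts of x-only (a) and z-only (b) path features
            a_mat = (XP.T @ (1.0 - ZP)).astype(np.intp)
            b_mat = ((1.0 - XP).T @ ZP).astype(np.intp)
            dead = ((1.0 - XP).T @ (1.0 - ZP)) > 0.5
            wa = WA[a_mat, b_mat]
            wb = WB[a_mat, b_mat]
            wa[dead] = 0.0
            wb[dead] = 0.0
            v_over_m = leaf["value"] / m
            for k, f in enumerate(feats):
                xp = XP[k].astype(bool)
                zp = ZP[k].astype(bool)
                # x-only class: xp_i & ~zp_j ; z-only class: ~xp_i & zp_j
                contrib = (
                    wa[xp][:, ~zp].sum(axis=1) if xp.any() else None
                )
                if contrib is not None:
                    phi[xp, f] += v_over_m * contrib
                if (~xp).any():
                    phi[~xp, f] -= v_over_m * wb[~xp][:, zp].sum(axis=1)
    return phi
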