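"""Shapley attributions: oracle agreement, axioms, summaries, pairwise deltas."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import HistGradientBoostingRegressor

from photoyield.attribution import (
    ShapExplanation,
    exact_shapley,
    explain,
    pairwise_attribution,
    pairwise_from_values,
    summarize,
    waterfall,
)
from photoyield.modeling import FittedModel


def _fit_model(X: pd.DataFrame, y: np.ndarray, **kw) -> FittedModel:
    reg = HistGradientBoostingRegressor(random_state=0, **kw).fit(X, y)
    return FittedModel(
        regressor=reg,
        feature_names=list(X.columns),
        X_train=X,
        y_train=pd.Series(y),
    )


def _frame(rng, n, d):
    return pd.DataFrame(
        rng.normal(size=(n, d)), columns=[f"f{i}" for i in range(d)]
    )


class TestExplainVsOracle:
    @pytest.mark.parametrize(
        "d,target,max_iter",
        [
            (3, lambda X: 10 * X[:, 0] + np.sin(3 * X[:, 1]), 8),
            (4, lambda X: X[:, 0] * X[:, 1] + X[:, 2] ** 2, 30),
            (6, lambda X: X[:, 0] - 2 * X[:, 3] + X[:, 4] * X[:, 5], 25),
        ],
    )
    def test_tree_shap_matches_coalition_enumeration(self, d, target, max_iter):
        """The polynomial tree algorithm equals the exact Shapley oracle."""
        rng = np.random.default_rng(d)
        X = _frame(rng, 150, d)
        y = target(X.to_numpy()) + rng.normal(0, 0.1, 150)
        model = _fit_model(X, y, max_iter=max_iter)
        rows = X.iloc[:5]
        background = X.iloc[10 : 10 + 16]
        expl = explain(model, rows, background)
        for i, e in enumerate(expl):
            oracle = exact_shapley(
                model.regressor.predict,
                rows.iloc[i].to_numpy(),
                background.to_numpy(),
                list(X.columns),
            )
            for f in X.columns:
                assert e.phi[f] == pytest.approx(oracle[f], abs=1e-8)

    def test_additivity_on_every_row(self, explanations):
        for e in explanations:
            assert e.base_value + sum(e.phi.values()) == pytest.approx(
                e.prediction, abs=1e-6
            )

    def test_constant_model_gives_zero_attributions(self):
        rng = np.random.default_rng(1)
        X = _frame(rng, 60, 3)
        model = _fit_model(X, np.full(60, 5.0))
        for e in explain(model, X.iloc[:4], X):
            assert e.base_value == pytest.approx(5.0, abs=1e-9)
            assert all(abs(v) < 1e-9 for v in e.phi.values())

    def test_single_feature_model_gets_full_attribution(self):
        rng = np.random.default_rng(2)
        X = _frame(rng, 200, 1)
        y = np.where(X["f0"] > 0, 10.0, -10.0)
        model = _fit_model(X, y)
        for e in explain(model, X.iloc[:5], X):
            assert e.phi["f0"] == pytest.approx(e.prediction - e.base_value, abs=1e-9)

    def test_schema_mismatch_reported(self, trained_model, best_matrix):
        with pytest.raises(ValueError, match="missing feature columns"):
            explain(trained_model, best_matrix.X.iloc[:2, :3], best_matrix.X)


class TestExactShapleyAxioms:
    def test_additive_model_separates_exactly(self):
        """For f(x) = sum g_j(x_j), phi_j = g_j(x_j) - mean g_j."""
        rng = np.random.default_rng(3)
        Z = rng.normal(size=(12, 3))
        gs = [lambda v: 2 * v, lambda v: v**2, lambda v: np.sin(v)]
        predict = lambda A: sum(g(A[:, j]) for j, g in enumerate(gs))
        row = rng.normal(size=3)
        phi = exact_shapley(predict, row, Z, ["a", "b", "c"])
        for j, (name, g) in enumerate(zip("abc", gs)):
            assert phi[name] == pytest.approx(
                g(row[j]) - g(Z[:, j]).mean(), abs=1e-10
            )

    def test_symmetric_duplicate_features_share_equally(self):
        rng = np.random.default_rng(4)
        Z = rng.normal(size=(10, 2))
        Z[:, 1] = Z[:, 0]
        predict = lambda A: A[:, 0] + A[:, 1]
        phi = exact_shapley(predict, np.array([1.5, 1.5]), Z, ["a", "b"])
        assert phi["a"] == pytest.approx(phi["b"], abs=1e-12)

    def test_feature_limit_guard(self):
        with pytest.raises(ValueError, match="15"):
            exact_shapley(
                lambda A: A.sum(1), np.zeros(16), np.zeros((2, 16)),
                [f"f{i}" for i in range(16)],
            )


class TestSummarize:
    def _expl(self, rid, phi, base=10.0):
        return ShapExplanation(
            row_id=rid,
            base_value=base,
            phi=phi,
            prediction=base + sum(phi.values()),
            feature_values={k: 0.0 for k in phi},
        )

    def test_all_zero_attributions_rank_lexicographically(self):
        expl = [self._expl("r0", {"b": 0.0, "a": 0.0, "c": 0.0})]
        bar, _ = summarize(expl)
        assert list(bar["feature"]) == ["a", "b", "c"]
        assert (bar["mean_abs_phi"] == 0).all()

    def test_dominant_feature_ranks_first(self):
        """A feature engineered to carry the signal tops the ranking."""
        rng = np.random.default_rng(5)
        X = _frame(rng, 200, 4)
        y = 50 * X["f2"].to_numpy() + rng.normal(0, 0.5, 200)
        model = _fit_model(X, y)
        bar, scatter = summarize(explain(model, X.iloc[:30], X))
        assert bar["feature"].iloc[0] == "f2"
        assert set(scatter.columns) == {"row_id", "feature", "value", "phi"}

    def test_ranking_invariant_under_row_permutation(self):
        rng = np.random.default_rng(6)
        expl = [
            self._expl(f"r{i}", {"a": rng.normal(), "b": rng.normal() * 3})
            for i in range(10)
        ]
        bar1, _ = summarize(expl)
        bar2, _ = summarize(expl[::-1])
        pd.testing.assert_frame_equal(bar1, bar2)


class TestWaterfall:
    def test_cumulative_walk_ends_at_prediction(self, explanations):
        e = explanations[0]
        wf = waterfall(e)
        assert wf["cumulative"].iloc[-1] == pytest.approx(e.prediction, abs=1e-9)
        assert list(wf["phi"].abs().sort_values(ascending=False)) == list(
            wf["phi"].abs()
        )

    def test_top_k_remainder_preserves_total(self, explanations):
        e = explanations[0]
        wf = waterfall(e, top_k=3)
        assert len(wf) == 4
        assert wf["feature"].iloc[-1] == "(remaining)"
        assert wf["phi"].sum() == pytest.approx(e.prediction - e.base_value, abs=1e-9)


class TestPairwise:
    def test_identical_explanations_give_zero_deltas(self, explanations):
        e = explanations[0]
        pw = pairwise_attribution(e, e, list(e.phi)[:2])
        assert pw.total_delta == 0.0
        assert all(v == 0.0 for v in pw.per_feature_delta.values())

    def test_full_subset_share_is_one(self, explanations):
        a, b = explanations[0], explanations[7]
        pw = pairwise_attribution(a, b, list(a.phi))
        assert pw.subset_share == pytest.approx(1.0, abs=1e-6)
        assert sum(pw.per_feature_delta.values()) == pytest.approx(
            pw.total_delta, abs=1e-6
        )

    def test_mismatched_base_values_rejected(self, explanations):
        e = explanations[0]
        other = ShapExplanation(
            row_id="x",
            base_value=e.base_value + 1.0,
            phi=dict(e.phi),
            prediction=e.prediction + 1.0,
            feature_values=dict(e.feature_values),
        )
        with pytest.raises(ValueError, match="base values"):
            pairwise_attribution(e, other, [])

    def test_published_co_bond_worked_example(self):
        """Reported OPS1/OPS7 attributions: the two T1-exit descriptors
        account for 18.16 points of the 31.30-point predicted-yield gap."""
        pw = pairwise_from_values(
            prediction_a=53.85,
            prediction_b=85.15,
            phi_a={"s_k_risc_T1S1": -1.17, "s_k_isc_T1S0": -2.69},
            phi_b={"s_k_risc_T1S1": +6.17, "s_k_isc_T1S0": +8.13},
        )
        assert pw.total_delta == pytest.approx(31.30, abs=1e-9)
        assert pw.subset_delta == pytest.approx(18.16, abs=1e-9)

    def test_published_radical_addition_worked_example(self):
        """OPS1/OPS5 in the cyclohexyl reaction: internal conversion and
        reverse ISC account for 28.50 of the 41.59-point difference."""
        pw = pairwise_from_values(
            prediction_a=44.11,
            prediction_b=2.52,
            phi_a={"s_k_ic_S1S0": 0.0, "s_k_risc_T1S1": 0.0, "E_T1_eV": 3.17},
            phi_b={"s_k_ic_S1S0": -17.17, "s_k_risc_T1S1": -11.33, "E_T1_eV": -4.24},
            subset=["s_k_ic_S1S0", "s_k_risc_T1S1"],
        )
        assert pw.total_delta == pytest.approx(-41.59, abs=1e-9)
        assert abs(pw.subset_delta) == pytest.approx(28.50, abs=1e-9)
        assert pw.per_feature_delta["E_T1_eV"] == pytest.approx(-7.41, abs=1e-9)

    def test_zero_total_with_nonzero_subset_flagged(self):
        pw = pairwise_from_values(
            prediction_a=10.0, prediction_b=10.0,
            phi_a={"a": 1.0, "b": -1.0}, phi_b={"a": 2.0, "b": -2.0},
            subset=["a"],
        )
        assert math.isnan(pw.subset_share)
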