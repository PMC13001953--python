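"""Stacked meta-learning and pseudo-BMA weighting against exact oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.model_selection import KFold

from growthstack.ensembles import (EnsembleWeights, bma_predict, fit_stack,
                                   make_oof_predictions, pseudo_bma_weights)
from growthstack.preprocessing import DesignMatrices


def make_design(X, y):
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return DesignMatrices(
        Xc=pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])]),
        Xd=pd.DataFrame(index=range(len(y))),
        y=pd.Series(np.asarray(y, dtype=float)),
    )


class MeanLearner:
    """Predicts the training-fold response mean; trivially refittable."""

    def __init__(self):
        self.mean_ = None

    def fit(self, design):
        self.mean_ = float(design.y.mean())
        return self

    def predict(self, design):
        return np.full(len(design.y), self.mean_)


class LinearLearner:
    """Least-squares fit on the continuous columns."""

    def __init__(self):
        self.coef_ = None

    def fit(self, design):
        A = np.column_stack([np.ones(len(design.y)), design.Xc.to_numpy(float)])
        self.coef_, *_ = np.linalg.lstsq(A, design.y.to_numpy(float), rcond=None)
        return self

    def predict(self, design):
        A = np.column_stack([np.ones(len(design.y)), design.Xc.to_numpy(float)])
        return A @ self.coef_


class TestOutOfFold:
    def test_fold_mean_oracle(self):
        """Each validation row must get the complementary folds' mean."""
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        design = make_design(rng.normal(size=(20, 2)), y)
        oof = make_oof_predictions({"m": MeanLearner()}, {"m": design}, folds=4, seed=5)
        for tr_pos, va_pos in KFold(4, shuffle=True, random_state=5).split(np.arange(20)):
            np.testing.assert_allclose(oof.iloc[va_pos, 0], y[tr_pos].mean(), atol=1e-12)

    def test_every_row_predicted_exactly_once(self):
        design = make_design(np.arange(10.0), np.arange(10.0))
        oof = make_oof_predictions({"m": MeanLearner()}, {"m": design}, folds=5, seed=0)
        assert oof.shape == (10, 1)
        assert oof.notna().all().all()

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        design = make_design(rng.normal(size=(30, 3)), rng.normal(size=30))
        a = make_oof_predictions({"m": LinearLearner()}, {"m": design}, folds=3, seed=2)
        b = make_oof_predictions({"m": LinearLearner()}, {"m": design}, folds=3, seed=2)
        pd.testing.assert_frame_equal(a, b)

    def test_misaligned_designs_rejected(self):
        d1 = make_design(np.arange(10.0), np.arange(10.0))
        d2 = make_design(np.arange(12.0), np.arange(12.0))
        with pytest.raises(ValueError):
            make_oof_predictions({"a": MeanLearner(), "b": MeanLearner()},
                                 {"a": d1, "b": d2})

    def test_oof_never_uses_own_row(self):
        """A memorizing learner cannot leak its own row through OOF predictions.

        The learner below returns the exact training response for rows it saw
        and NaN otherwise; leakage would surface as a non-NaN self-prediction.
        """

        class Memorizer:
            def fit(self, design):
                self.seen = dict(zip(design.ids, design.y))
                return self

            def predict(self, design):
                return np.array([self.seen.get(i, np.nan) for i in design.ids])

        y = np.random.default_rng(3).normal(size=15)
        design = make_design(np.arange(15.0), y)
        oof = make_oof_predictions({"m": Memorizer()}, {"m": design}, folds=3, seed=0)
        assert oof["m"].isna().all()


class TestStack:
    def test_exact_two_base_recovery(self):
        """y an exact linear blend of the bases -> weights recovered to 1e-8."""
        rng = np.random.default_rng(4)
        p1, p2 = rng.normal(size=200), rng.normal(size=200)
        y = 0.3 * p1 + 0.7 * p2
        oof = pd.DataFrame({"a": p1, "b": p2})
        stack = fit_stack(oof, y)
        # independent oracle: normal equations on the same design
        A = np.column_stack([np.ones(200), p1, p2])
        ref = np.linalg.solve(A.T @ A, A.T @ y)
        assert stack.intercept == pytest.approx(ref[0], abs=1e-8)
        np.testing.assert_allclose(stack.weights, [0.3, 0.7], atol=1e-8)
        np.testing.assert_allclose(stack.weights, ref[1:], atol=1e-10)

    def test_perfect_base_gets_unit_weight(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=100)
        oof = pd.DataFrame({"perfect": y, "noise": rng.normal(size=100)})
        stack = fit_stack(oof, y)
        pred = stack.predict(oof)
        assert np.abs(pred - y).max() < 1e-6
        assert stack.weights[0] == pytest.approx(1.0, abs=1e-6)

    def test_meta_rss_never_worse_than_best_base(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=300)
        oof = pd.DataFrame({"a": y + rng.normal(0, 1, 300),
                            "b": y + rng.normal(0, 2, 300)})
        stack = fit_stack(oof, y)
        rss_meta = float(np.sum((y - stack.predict(oof)) ** 2))
        rss_bases = [float(np.sum((y - oof[c]) ** 2)) for c in oof]
        assert rss_meta <= min(rss_bases) + 1e-9

    def test_collinear_bases_fall_back_to_ridge(self, caplog):
        rng = np.random.default_rng(7)
        p = rng.normal(size=100)
        y = p + rng.normal(0, 0.1, 100)
        oof = pd.DataFrame({"a": p, "b": p})  # exactly collinear
        with caplog.at_level("WARNING"):
            stack = fit_stack(oof, y)
        assert "ridge" in caplog.text
        assert np.all(np.isfinite(stack.weights))
        # ridge splits the weight symmetrically across the duplicated columns
        assert stack.weights[0] == pytest.approx(stack.weights[1], abs=1e-6)
        # and the combined fit matches OLS on a single copy of the column
        A = np.column_stack([np.ones(100), p])
        ref = A @ np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(stack.predict(oof), ref, atol=1e-3)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fit_stack(pd.DataFrame({"a": [1.0, 2.0]}), np.zeros(3))

    def test_predict_accepts_dict_and_frame(self):
        oof = pd.DataFrame({"a": [0.0, 1.0], "b": [1.0, 0.0]})
        stack = fit_stack(oof, np.array([0.5, 0.5]))
        frame = stack.predict(oof)
        dct = stack.predict({"a": oof["a"].to_numpy(), "b": oof["b"].to_numpy()})
        np.testing.assert_allclose(frame, dct)


class TestPseudoBma:
    def test_equal_criteria_give_uniform_weights(self):
        w = pseudo_bma_weights({"a": 100.0, "b": 100.0, "c": 100.0})
        np.testing.assert_allclose(list(w.weights.values()), 1 / 3, atol=1e-12)

    def test_delta_aic_of_two_gives_textbook_weights(self):
        w = pseudo_bma_weights({"a": 10.0, "b": 12.0}).weights
        assert w["a"] == pytest.approx(0.7311, abs=5e-5)
        assert w["b"] == pytest.approx(0.2689, abs=5e-5)

    def test_weights_form_a_simplex(self):
        rng = np.random.default_rng(8)
        crit = {f"m{i}": float(c) for i, c in enumerate(100 + 10 * rng.normal(size=6))}
        w = np.array(list(pseudo_bma_weights(crit).weights.values()))
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert (w >= 0).all()

    def test_cv_logscore_mode_prefers_larger(self):
        w = pseudo_bma_weights({"a": -1.0, "b": -3.0}, mode="cv_logscore").weights
        assert w["a"] > w["b"]
        assert w["a"] == pytest.approx(np.exp(0) / (np.exp(0) + np.exp(-2)), abs=1e-12)

    def test_nonfinite_criteria_dropped(self):
        w = pseudo_bma_weights({"a": 10.0, "b": 12.0, "c": float("inf")}).weights
        assert "c" not in w
        with pytest.raises(ValueError):
            pseudo_bma_weights({"a": 1.0, "b": float("nan")})

    def test_strongly_dominant_gap_matches_dominant_rmse(self):
        """Criterion gap >= 20 -> averaged RMSE within 0.01 mm of the winner."""
        rng = np.random.default_rng(9)
        y = 300 + 20 * rng.normal(size=500)
        good = y + rng.normal(0, 5, 500)
        bad = y + rng.normal(0, 60, 500)
        w = pseudo_bma_weights({"good": 100.0, "bad": 140.0})
        blend = bma_predict(w, {"good": good, "bad": bad})
        rmse_blend = np.sqrt(np.mean((y - blend) ** 2))
        rmse_good = np.sqrt(np.mean((y - good) ** 2))
        assert abs(rmse_blend - rmse_good) < 0.01

    def test_weight_one_is_identity(self):
        preds = np.array([1.0, 2.0, 3.0])
        w = EnsembleWeights(weights={"only": 1.0})
        np.testing.assert_array_equal(bma_predict(w, {"only": preds}), preds)

    def test_half_half_average(self):
        w = EnsembleWeights(weights={"a": 0.5, "b": 0.5})
        out = bma_predict(w, {"a": np.array([100.0]), "b": np.array([200.0])})
        assert out[0] == pytest.approx(150.0)

    def test_blend_bounded_by_member_range(self):
        rng = np.random.default_rng(10)
        preds = {f"m{i}": rng.normal(size=50) for i in range(4)}
        w = pseudo_bma_weights({f"m{i}": float(100 + i) for i in range(4)})
        blend = bma_predict(w, preds)
        stackd = np.stack(list(preds.values()))
        assert (blend >= stackd.min(axis=0) - 1e-12).all()
        assert (blend <= stackd.max(axis=0) + 1e-12).all()

    def test_invalid_simplex_rejected(self):
        with pytest.raises(ValueError):
            EnsembleWeights(weights={"a": 0.6, "b": 0.6})
        with pytest.raises(ValueError):
            EnsembleWeights(weights={"a": 1.2, "b": -0.2})

    def test_missing_member_prediction_raises(self):
        w = EnsembleWeights(weights={"a": 0.5, "b": 0.5})
        with pytest.raises(KeyError):
            bma_predict(w, {"a": np.zeros(3)})

    def test_mixture_draws_share_member_support(self):
        rng = np.random.default_rng(11)
        w = EnsembleWeights(weights={"a": 0.5, "b": 0.5})
        draws = {"a": np.zeros((10, 4)), "b": np.ones((10, 4))}
        point, mix = bma_predict(w, {"a": np.zeros(4), "b": np.ones(4)},
                                 draws=draws, n_mixture_draws=200, seed=3)
        np.testing.assert_allclose(point, 0.5)
        assert mix.shape == (200, 4)
        assert set(np.unique(mix)) <= {0.0, 1.0}
        assert 0.3 < mix.mean() < 0.7
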