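"""The double-coefficient quadratic softmax model: expansion, forward pass
against a naive triple-loop oracle, collapse identity, analytic gradients,
and training behaviour."""

import numpy as np
import pandas as pd
import pytest

from sepsis_phenoscope import dcqmff as dc
from sepsis_phenoscope.evaluation import roc_auc

PAIRS = [(i, j) for i in range(11) for j in range(i, 11)]


def naive_forward(p: dc.DCQMFFParams, x: np.ndarray) -> np.ndarray:
    """Triple-loop evaluation of the printed double sums."""
    y1 = y2 = 0.0
    for l in range(p.L):
        s1, s2 = p.a[l, 0], p.d[l, 0]
        for i in range(11):
            s1 += p.a[l, 1 + i] * x[i]
            s2 += p.d[l, 1 + i] * x[i]
        for k, (i, j) in enumerate(PAIRS):
            s1 += p.a[l, 12 + k] * x[i] * x[j]
            s2 += p.d[l, 12 + k] * x[i] * x[j]
        y1 += p.b[l] * s1
        y2 += p.c[l] * s2
    m = max(y1, y2)
    e1, e2 = np.exp(y1 - m), np.exp(y2 - m)
    return np.array([e1 / (e1 + e2), e2 / (e1 + e2)])


class TestQuadFeatures:
    def test_zero_vector_keeps_only_intercept(self):
        phi = dc.quad_features(np.zeros(11))
        assert phi[0] == 1.0 and np.all(phi[1:] == 0.0)

    def test_ones_vector_fills_all_78_terms(self):
        phi = dc.quad_features(np.ones(11))
        assert phi.shape == (78,) and np.all(phi == 1.0)

    def test_one_hot_activates_linear_and_square_terms(self):
        phi = dc.quad_features(np.eye(11)[0])
        assert phi[0] == 1.0 and phi[1] == 1.0
        assert phi[12] == 1.0  # x_1 * x_1 is the first pair term
        assert phi.sum() == 3.0

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            dc.quad_features(np.zeros(10))


class TestForward:
    def test_zero_parameters_give_even_odds(self):
        p = dc.DCQMFFParams(
            b=np.zeros(5), a=np.zeros((5, 78)), c=np.zeros(5), d=np.zeros((5, 78))
        )
        out = dc.forward(p, np.random.default_rng(0).random(11))
        assert out[0] == 0.5 and out[1] == 0.5

    def test_symmetric_heads_give_even_odds_everywhere(self, rng):
        p = dc.DCQMFFParams.init_random(L=7, seed=3)
        sym = dc.DCQMFFParams(b=p.b, a=p.a, c=p.b.copy(), d=p.a.copy())
        for _ in range(10):
            out = dc.forward(sym, rng.random(11))
            assert out[0] == pytest.approx(0.5, abs=1e-14)

    def test_matches_triple_loop_oracle(self, rng):
        p = dc.DCQMFFParams.init_random(L=33, seed=1)
        for _ in range(100):
            x = rng.standard_normal(11)
            np.testing.assert_allclose(dc.forward(p, x), naive_forward(p, x), atol=1e-10)

    def test_probabilities_sum_to_one(self, rng):
        p = dc.DCQMFFParams.init_random(L=33, seed=2)
        out = dc.forward(p, rng.random((500, 11)))
        assert np.abs(out.sum(axis=1) - 1.0).max() < 1e-12

    def test_numerically_stable_for_huge_logits(self):
        p = dc.DCQMFFParams(
            b=np.array([1e4]), a=np.ones((1, 78)), c=np.array([-1e4]),
            d=np.ones((1, 78)),
        )
        out = dc.forward(p, np.ones(11))
        assert np.isfinite(out).all() and out[0] == pytest.approx(1.0)

    def test_non_finite_params_rejected(self):
        with pytest.raises(ValueError):
            dc.DCQMFFParams(
                b=np.array([np.nan]), a=np.zeros((1, 78)),
                c=np.zeros(1), d=np.zeros((1, 78)),
            )


class TestCollapse:
    def test_single_channel_intercept(self):
        a = np.zeros((1, 78))
        a[0, 0] = 3.0
        p = dc.DCQMFFParams(b=np.array([2.0]), a=a, c=np.zeros(1), d=np.zeros((1, 78)))
        w1, w2 = dc.collapse(p)
        assert w1[0] == 6.0 and np.all(w2 == 0.0)

    def test_collapsed_form_reproduces_double_form(self, rng):
        p = dc.DCQMFFParams.init_random(L=33, seed=4)
        w1, w2 = dc.collapse(p)
        x = rng.random((100, 11))
        np.testing.assert_allclose(
            dc.forward(p, x), dc.forward_collapsed(w1, w2, x), atol=1e-10
        )

    def test_zero_gains_collapse_to_zero(self):
        p = dc.DCQMFFParams(
            b=np.zeros(4), a=np.random.default_rng(0).normal(size=(4, 78)),
            c=np.zeros(4), d=np.ones((4, 78)),
        )
        w1, w2 = dc.collapse(p)
        assert np.all(w1 == 0.0) and np.all(w2 == 0.0)

    def test_any_quadratic_logit_is_representable(self, rng):
        """Constructively: one channel with unit gain carries arbitrary
        78-coefficient heads."""
        w1 = rng.normal(size=78)
        w2 = rng.normal(size=78)
        p = dc.DCQMFFParams(
            b=np.ones(1), a=w1[None, :], c=np.ones(1), d=w2[None, :]
        )
        x = rng.random((50, 11))
        np.testing.assert_allclose(
            dc.forward(p, x), dc.forward_collapsed(w1, w2, x), atol=1e-12
        )


class TestGradients:
    def test_analytic_matches_central_differences(self, rng):
        p = dc.DCQMFFParams.init_random(L=3, seed=5)
        phi = dc.quad_features(rng.random((6, 11)))
        t = np.array([0.0, 1.0, 1.0, 0.0, 1.0, 0.0])
        _, grads = dc.loss_and_gradients(p, phi, t)
        eps = 1e-6
        for name in ("b", "a", "c", "d"):
            arr = getattr(p, name)
            flat = arr.ravel()
            idxs = rng.choice(flat.size, size=min(20, flat.size), replace=False)
            for i in idxs:
                old = flat[i]
                flat[i] = old + eps
                lp, _ = dc.loss_and_gradients(p, phi, t)
                flat[i] = old - eps
                lm, _ = dc.loss_and_gradients(p, phi, t)
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[name].ravel()[i]
                denom = max(abs(num), abs(ana), 1e-8)
                assert abs(num - ana) / denom < 1e-5


class TestFitPredict:
    def test_separable_toy_reaches_training_accuracy(self, rng):
        x = np.vstack([rng.normal(0.2, 0.05, (150, 11)), rng.normal(0.8, 0.05, (150, 11))])
        y = np.r_[np.zeros(150), np.ones(150)]
        params, trace = dc.fit(x, y, dc.DCQMFFConfig(epochs=200, seed=0))
        pred = dc.predict(params, x)["pred_death"].to_numpy()
        assert (pred == y).mean() >= 0.99
        assert trace[-1] <= trace[0]

    def test_deterministic_under_seed(self, rng):
        x = rng.random((80, 11))
        y = (rng.random(80) < 0.4).astype(float)
        p1, _ = dc.fit(x, y, dc.DCQMFFConfig(epochs=20, seed=9))
        p2, _ = dc.fit(x, y, dc.DCQMFFConfig(epochs=20, seed=9))
        np.testing.assert_array_equal(p1.a, p2.a)
        np.testing.assert_array_equal(p1.b, p2.b)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            dc.fit(rng.random((20, 11)), np.zeros(20), dc.DCQMFFConfig(epochs=1))

    def test_tie_at_half_predicts_survival(self):
        p = dc.DCQMFFParams(
            b=np.zeros(1), a=np.zeros((1, 78)), c=np.zeros(1), d=np.zeros((1, 78))
        )
        out = dc.predict(p, np.random.default_rng(0).random((5, 11)))
        assert (out.p_death == 0.5).all()
        assert (out.pred_death == 0).all()

    def test_monotone_response_to_positive_coefficient_feature(self):
        # death head loads positively on x_1 only: raising x_1 raises p_death
        d = np.zeros((1, 78))
        d[0, 1] = 5.0
        p = dc.DCQMFFParams(b=np.zeros(1), a=np.zeros((1, 78)), c=np.ones(1), d=d)
        x = np.tile(0.5, (3, 11))
        x[:, 0] = [0.1, 0.5, 0.9]
        pd_ = dc.forward(p, x)[:, 1]
        assert pd_[0] < pd_[1] < pd_[2]

    def test_overparameterized_and_minimal_models_agree(self, rng):
        """L=33 and L=1 trained on the same quadratic-logit labels reach
        held-out AUCs within 0.03."""
        x = rng.random((1200, 11))
        w = rng.normal(0, 1, 78)
        logit = dc.quad_features(x) @ w
        logit = 5 * (logit - np.median(logit)) / logit.std()
        y = (rng.random(1200) < 1 / (1 + np.exp(-logit))).astype(float)
        aucs = []
        for L in (33, 1):
            params, _ = dc.fit(
                x[:800], y[:800], dc.DCQMFFConfig(L=L, epochs=400, seed=0)
            )
            pred = dc.predict(params, x[800:])["p_death"].to_numpy()
            aucs.append(roc_auc(pred, y[800:].astype(int)))
        assert abs(aucs[0] - aucs[1]) < 0.03

    def test_params_json_round_trip(self, tmp_path):
        p = dc.DCQMFFParams.init_random(L=4, seed=8)
        path = tmp_path / "params.json"
        p.to_json(path)
        q = dc.DCQMFFParams.from_json(path)
        np.testing.assert_array_equal(p.a, q.a)
        np.testing.assert_array_equal(p.c, q.c)

    def test_cohort_table_interface(self, cohort_normalized):
        sub = cohort_normalized.head(300)
        params, _ = dc.fit(sub, config=dc.DCQMFFConfig(epochs=10, seed=0))
        out = dc.predict(params, sub)
        assert {"p_survive", "p_death", "pred_death"} <= set(out.columns)
        assert np.abs(out.p_survive + out.p_death - 1).max() < 1e-12
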