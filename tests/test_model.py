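"""Gated-MLP mechanics: gate function, initialisation, forward pass, training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import gfsmlp as g
from gfsmlp.model import GATE_CLOSED, GATE_NEARLY_CLOSED, GATE_OPEN, TrainingConfig


class TestGateFunction:
    def test_bounded_and_monotone(self):
        lams = np.linspace(-50, 50, 201)
        vals = g.gate_value(lams)
        assert np.all((vals >= 0) & (vals <= 1))
        assert np.all(np.diff(vals) >= 0)

    def test_limits_and_midpoint(self):
        assert g.gate_value(1e3) == pytest.approx(1.0)
        assert g.gate_value(-1e3) == pytest.approx(0.0)
        assert g.gate_value(0.0) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(lam=st.floats(min_value=-30, max_value=30))
    def test_logistic_symmetry(self, lam):
        assert g.gate_value(-lam) == pytest.approx(1.0 - g.gate_value(lam), abs=1e-12)


class TestInitialisation:
    def test_default_init_has_all_gates_nearly_closed(self, small_model):
        res = small_model.fit(iterations=0, seed=0)
        assert res.gates == pytest.approx(np.full(8, 0.05))
        assert len(res.gates) == 8

    def test_open_clamped_gate_reads_exactly_one(self, small_model):
        plan = g.gate_plan(8, open_clamped=[8])
        res = small_model.fit(iterations=0, gate_init=plan, seed=0)
        assert res.gates[7] == 1.0
        assert res.gates[:7] == pytest.approx(np.full(7, 0.05))

    def test_invalid_group_index_rejected(self):
        with pytest.raises(ValueError):
            g.gate_plan(8, open_clamped=[9])
        with pytest.raises(ValueError):
            g.gate_plan(8, closed=[0])

    def test_custom_g0(self, small_model):
        res = small_model.fit(iterations=0, seed=0, g0=0.2)
        assert res.gates == pytest.approx(np.full(8, 0.2))


class TestForward:
    def test_closed_gate_makes_output_invariant_to_that_group(self, small_model):
        plan = g.gate_plan(8, closed=[3])
        res = small_model.fit(iterations=5, gate_init=plan, seed=1, mu=0.0)
        X = small_model.exog.copy()
        base = res.predict(X)
        X[:, 40:60] = np.random.default_rng(0).uniform(-5, 5, size=(X.shape[0], 20))
        assert np.array_equal(res.predict(X), base)

    def test_fully_open_gates_match_plain_mlp(self, small_model):
        plan = g.gate_plan(8, open_clamped=list(range(1, 9)))
        res = small_model.fit(iterations=3, gate_init=plan, seed=2, mu=0.0)
        X = small_model.exog
        hidden = 1.0 / (1.0 + np.exp(-(X @ res.W1.T + res.b1)))
        plain = 1.0 / (1.0 + np.exp(-(hidden @ res.w2 + res.b2[0])))
        assert res.predict(X) == pytest.approx(plain, abs=1e-12)

    def test_all_gates_closed_gives_constant_output(self, small_model):
        plan = g.gate_plan(8, closed=list(range(1, 9)))
        res = small_model.fit(iterations=2, gate_init=plan, seed=3, mu=0.0)
        scores = res.predict(small_model.exog)
        assert np.allclose(scores, scores[0])


class TestTraining:
    def test_mu_zero_leaves_lambdas_bit_identical(self, small_model):
        before = small_model.fit(iterations=0, seed=11)
        after = small_model.fit(iterations=50, seed=11, mu=0.0)
        assert np.array_equal(before.lam, after.lam)
        assert np.array_equal(before.gates, after.gates)

    def test_zero_iterations_returns_initial_weights(self, small_model):
        a = small_model.fit(iterations=0, seed=4)
        b = small_model.fit(iterations=0, seed=4)
        assert np.array_equal(a.W1, b.W1)
        assert a.loss_trace.size == 0

    def test_same_seed_reproduces_fit_exactly(self, small_model):
        a = small_model.fit(iterations=30, seed=9)
        b = small_model.fit(iterations=30, seed=9)
        assert np.array_equal(a.W1, b.W1)
        assert np.array_equal(a.lam, b.lam)
        assert np.array_equal(a.loss_trace, b.loss_trace)

    def test_gates_stay_bounded_during_training(self, small_model):
        res = small_model.fit(iterations=100, seed=5, mu=5.0, eta=1.0)
        assert np.all((res.gates >= 0) & (res.gates <= 1))

    def test_loss_trace_is_finite(self, small_model):
        res = small_model.fit(iterations=200, seed=6)
        assert np.all(np.isfinite(res.loss_trace))
        assert res.loss_trace.size == 200

    def test_training_reduces_loss_on_separable_data(self, small_model):
        res = small_model.fit(iterations=200, seed=7)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_batch_mode_runs_and_freezes_gates_with_mu_zero(self, small_model):
        res = small_model.fit(iterations=20, seed=8, mode="batch", mu=0.0)
        assert np.all(np.isfinite(res.loss_trace))
        assert res.gates == pytest.approx(np.full(8, 0.05))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            TrainingConfig(eta=-0.1)
        with pytest.raises(ValueError):
            TrainingConfig(n_hidden=0)
        with pytest.raises(ValueError):
            TrainingConfig(g0=0.0)
        with pytest.raises(ValueError):
            TrainingConfig(mode="minibatch")


class TestResultsApi:
    def test_selected_groups_thresholding(self, small_model):
        res = small_model.fit(iterations=0, seed=0)
        assert res.selected_groups(0.5) == set()
        assert res.selected_groups(0.0) == set(range(1, 9))
        clamped = small_model.fit(
            iterations=0, gate_init=g.gate_plan(8, open_clamped=[2]), seed=0
        )
        assert 2 in clamped.selected_groups(0.5)

    def test_misclassification_toy_count(self):
        # 4 records, one deliberately mislabelled relative to a separable rule
        X = np.zeros((4, 20))
        X[:2, 0] = 1.0
        y = np.array([1, 0, 0, 0])  # records 0,1 identical in X -> one must err
        model = g.GFSMLP(y, X, group_size=20)
        res = model.fit(iterations=300, seed=0, mu=0.0,
                        gate_init=g.gate_plan(1, open_clamped=[1]))
        assert res.misclassification_rate() == pytest.approx(25.0)

    def test_constant_model_on_balanced_data_errs_fifty_percent(self, small_model):
        plan = g.gate_plan(8, closed=list(range(1, 9)))
        res = small_model.fit(iterations=0, gate_init=plan, seed=1)
        assert res.misclassification_rate() == pytest.approx(50.0)

    def test_summary_mentions_selected_groups(self, small_model):
        res = small_model.fit(iterations=10, seed=0)
        text = res.summary()
        assert "gate" in text and "beta_turn_chou" in text

    def test_checkpoint_roundtrip(self, tmp_path, small_model):
        res = small_model.fit(iterations=20, seed=13)
        path = tmp_path / "ckpt.json"
        res.to_json(path)
        back = g.GFSMLPResults.from_json(path, small_model)
        assert np.array_equal(back.W1, res.W1)
        assert np.array_equal(back.lam, res.lam)
        assert back.selected_groups() == res.selected_groups()
        assert back.misclassification_rate() == res.misclassification_rate()


def test_empty_dataset_rejected():
    with pytest.raises(ValueError):
        g.GFSMLP(np.zeros(0), np.zeros((0, 20)))


def test_non_binary_labels_rejected():
    with pytest.raises(ValueError):
        g.GFSMLP(np.array([0, 2]), np.zeros((2, 20)))
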