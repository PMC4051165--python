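"""Fusion network: forward pass, ELM training, persistence."""

import json
import math

import numpy as np
import pytest

import mirfuse as mf
from mirfuse.fusion_network import (
    InvalidInputError,
    InvalidModelError,
    ParseError,
    TrainingRecord,
)


def oracle_forward(net, x):
    """Scalar-loop forward pass with no matrix operations."""
    total = net.output_bias
    for k in range(net.n_hidden):
        pre = net.hidden_biases[k]
        for i in range(net.n_inputs):
            pre += net.hidden_weights[k][i] * x[i]
        total += net.output_weights[k] * (1.0 / (1.0 + math.exp(-pre)))
    return total


def random_network(rng, n_inputs=4, n_hidden=3):
    return mf.FusionNetwork(
        hidden_weights=rng.normal(size=(n_hidden, n_inputs)),
        hidden_biases=rng.normal(size=n_hidden),
        output_weights=rng.normal(size=n_hidden),
        output_bias=float(rng.normal()),
    )


class TestForward:
    def test_frozen_network_at_origin(self):
        net = mf.table2_network()
        assert mf.forward(net, [0, 0, 0, 0]) == pytest.approx(-0.4435, abs=1e-3)

    def test_frozen_network_all_positive_inputs(self):
        net = mf.table2_network()
        assert mf.forward(net, [1, 1, 1, 1]) == pytest.approx(-0.2727, abs=1e-3)

    def test_zero_output_layer_gives_zero_score(self):
        net = mf.FusionNetwork(
            hidden_weights=np.ones((3, 4)),
            hidden_biases=np.ones(3),
            output_weights=np.zeros(3),
            output_bias=0.0,
        )
        for x in ([0, 0, 0, 0], [1, -1, 1, -1], [3.5, -2, 0, 1]):
            assert mf.forward(net, x) == 0.0

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            net = random_network(rng)
            x = rng.normal(size=4)
            assert mf.forward(net, x) == pytest.approx(
                oracle_forward(net, x), abs=1e-12
            )

    def test_batch_agrees_with_single(self):
        rng = np.random.default_rng(1)
        net = random_network(rng)
        X = rng.normal(size=(10, 4))
        batch = mf.forward_batch(net, X)
        for row, score in zip(X, batch):
            assert score == pytest.approx(mf.forward(net, row), abs=1e-12)

    def test_non_finite_input_rejected(self):
        net = mf.table2_network()
        with pytest.raises(InvalidInputError):
            mf.forward(net, [0, 0, 0, np.nan])
        with pytest.raises(InvalidInputError):
            mf.forward(net, [0, 0, np.inf, 0])

    def test_parameter_count(self):
        assert mf.table2_network().n_parameters == 19


class TestClassify:
    def test_tie_maps_to_positive(self):
        net = mf.FusionNetwork(
            np.zeros((3, 4)), np.zeros(3), np.zeros(3), 0.5
        )
        assert mf.classify(net, [0, 0, 0, 0], threshold=0.5) == +1

    def test_infinite_threshold_always_negative(self):
        net = mf.table2_network()
        rng = np.random.default_rng(2)
        for _ in range(10):
            assert mf.classify(net, rng.normal(size=4), threshold=math.inf) == -1

    def test_polarity_flip(self):
        net = mf.table2_network()
        x = [1, 1, 1, 1]
        assert mf.classify(net, x, polarity=+1) == -mf.classify(net, x, polarity=-1)

    def test_threshold_sweep_reproduces_roc_points(self):
        """Confusion rates from classify() land exactly on the scan's curve."""
        rng = np.random.default_rng(3)
        net = random_network(rng)
        X = rng.choice([-1.0, 1.0], size=(40, 4))
        truth = rng.choice([-1, 1], size=40)
        scores = mf.forward_batch(net, X)
        curve = mf.roc_linear_scan(scores, truth)
        curve_pts = {(round(f, 12), round(t, 12)) for f, t, _ in curve.points}
        m = (truth == 1).sum()
        n = (truth == -1).sum()
        for thr in scores:
            pred = np.array([mf.classify(net, row, threshold=thr) for row in X])
            c = mf.confusion(truth, pred)
            assert (round(c.fp / n, 12), round(c.tp / m, 12)) in curve_pts

    def test_calibrate_polarity_picks_better_orientation(self):
        rng = np.random.default_rng(4)
        net = random_network(rng)
        X = rng.choice([-1.0, 1.0], size=(200, 4))
        scores = mf.forward_batch(net, X)
        y_aligned = np.where(scores >= 0, 1, -1)
        assert mf.calibrate_polarity(net, X, y_aligned) == +1
        assert mf.calibrate_polarity(net, X, -y_aligned) == -1


class TestTrainElm:
    def test_interpolates_three_distinct_points(self):
        """3 hidden neurons fit 3 distinct samples with zero error."""
        rng = np.random.default_rng(5)
        X = np.array([[1, 1, 1, 1], [1, -1, 1, -1], [-1, -1, -1, -1]], dtype=float)
        y = np.array([1.0, -1.0, 1.0])
        net, record = mf.train_elm(X, y, n_hidden=3, restarts=10, rng=rng)
        assert record.selected_sse <= 1e-12

    def test_constant_targets_fit_exactly(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(50, 4))
        _, record = mf.train_elm(X, np.full(50, 0.7), restarts=3, rng=rng)
        assert record.selected_sse <= 1e-12

    def test_beats_zero_network_on_noisy_committee(self):
        spec = mf.CommitteeSimSpec(
            sens_spec=((0.57, 0.89), (0.74, 0.97), (0.76, 0.73), (0.78, 0.72)),
            n_samples=1000,
        )
        decisions, truth = mf.gen_committee_table(spec, rng=7)
        y = truth.astype(float)
        _, record = mf.train_elm(decisions.astype(float), y, restarts=20, rng=7)
        sse_zero_net = float(np.sum((y - y.mean()) ** 2))  # best constant fit
        assert record.selected_sse <= sse_zero_net

    def test_normal_equation_residual(self):
        """[H|1]^T ([H|1] beta - y) vanishes at the least-squares optimum."""
        rng = np.random.default_rng(8)
        X = rng.choice([-1.0, 1.0], size=(1000, 4))
        y = rng.choice([-1.0, 1.0], size=1000)
        net, _ = mf.train_elm(X, y, restarts=1, rng=rng)
        H = 1.0 / (1.0 + np.exp(-(X @ net.hidden_weights.T + net.hidden_biases)))
        design = np.column_stack([H, np.ones(len(y))])
        beta = np.concatenate([net.output_weights, [net.output_bias]])
        residual = design.T @ (design @ beta - y)
        assert np.abs(residual).max() <= 1e-8

    def test_selected_restart_is_minimum(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 4))
        y = rng.choice([-1.0, 1.0], size=30)
        _, record = mf.train_elm(X, y, restarts=25, rng=rng)
        assert record.selected_sse == min(record.sse_per_restart)
        assert record.n_restarts == 25

    def test_empty_data_rejected(self):
        with pytest.raises(InvalidInputError):
            mf.train_elm(np.empty((0, 4)), np.empty(0))

    def test_integer_seed_recorded_and_reproducible(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        y = np.where(X.sum(axis=1) > 0, 1.0, -1.0)
        net_a, rec_a = mf.train_elm(X, y, restarts=5, rng=123)
        net_b, rec_b = mf.train_elm(X, y, restarts=5, rng=123)
        assert rec_a.seed == 123
        np.testing.assert_array_equal(net_a.hidden_weights, net_b.hidden_weights)
        assert rec_a.sse_per_restart == rec_b.sse_per_restart

    def test_record_rejects_inconsistent_selection(self):
        with pytest.raises(InvalidModelError):
            TrainingRecord(sse_per_restart=(1.0, 2.0), selected_index=1)


class TestPersistence:
    def test_round_trip_identity_on_frozen_network(self, tmp_path):
        net = mf.table2_network()
        path = tmp_path / "net.json"
        mf.save_network(net, path)
        loaded = mf.load_network(path)
        np.testing.assert_array_equal(loaded.hidden_weights, net.hidden_weights)
        np.testing.assert_array_equal(loaded.hidden_biases, net.hidden_biases)
        np.testing.assert_array_equal(loaded.output_weights, net.output_weights)
        assert loaded.output_bias == net.output_bias

    def test_shipped_frozen_values(self):
        net = mf.table2_network()
        np.testing.assert_array_equal(
            net.hidden_weights,
            [
                [0.8523, 0.7190, 0.0156, 0.3914],
                [-0.4030, -0.3190, 0.7133, 0.2558],
                [-0.03238, -0.7238, -0.2314, -0.0992],
            ],
        )
        np.testing.assert_array_equal(net.hidden_biases, [-0.0528, 0.8994, -0.8330])
        np.testing.assert_array_equal(net.output_weights, [-0.0877, -0.0166, -1.1731])
        assert net.output_bias == -0.0336

    def test_five_input_file_rejected(self, tmp_path):
        payload = {
            "hidden_weights": np.zeros((3, 5)).tolist(),
            "hidden_biases": [0, 0, 0],
            "output_weights": [0, 0, 0],
            "output_bias": 0.0,
            "activation": "logistic",
        }
        path = tmp_path / "five.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(InvalidModelError):
            mf.load_network(path)

    def test_malformed_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text("{not json")
        with pytest.raises(ParseError):
            mf.load_network(path)
        path.write_text(json.dumps({"hidden_weights": "oops"}))
        with pytest.raises((ParseError, InvalidModelError)):
            mf.load_network(path)
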