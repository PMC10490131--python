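"""Sampling, dataset generation, the network forward pass, loss and training."""

import numpy as np
import pytest
from scipy import stats

from rheoinverse import NetConfig, RoliePolyParams, TrainingConfig, steady_curve, train
from rheoinverse.surrogate import (
    FeatureScaler,
    SurrogateNet,
    architecture_scan,
    evaluate_relative_error,
    generate_dataset,
    input_scaler,
    loss,
    net_forward,
    sample_parameter_array,
    sample_parameters,
)


class TestSampling:
    def test_reproducible_under_seed(self, bounds):
        a = sample_parameters(bounds, 50, seed=99)
        b = sample_parameters(bounds, 50, seed=99)
        assert a == b

    def test_draws_respect_bounds_and_types(self, bounds):
        for p in sample_parameters(bounds, 100, seed=3):
            assert isinstance(p, RoliePolyParams)
            assert bounds.contains(p.free_vector())

    def test_log_scaled_marginal_is_uniform_in_log10(self, bounds):
        # Kolmogorov-Smirnov on log10(tau_D) against the uniform law
        theta = sample_parameter_array(bounds, 10_000, np.random.default_rng(17))
        x = np.log10(theta[:, 1])
        ks = stats.kstest(x, stats.uniform(loc=0.0, scale=np.log10(5000.0)).cdf)
        assert ks.pvalue > 1e-3

    def test_linear_scaled_marginal_is_uniform(self, bounds):
        theta = sample_parameter_array(bounds, 10_000, np.random.default_rng(18))
        ks = stats.kstest(theta[:, 4], stats.uniform(loc=1.0, scale=24.0).cdf)
        assert ks.pvalue > 1e-3


class TestDataset:
    def test_cardinality(self, bounds):
        ds = generate_dataset(bounds, 2, np.array([0.1, 1.0, 10.0]), seed=0, split=(1, 1, 1))
        assert len(ds) == 6

    def test_rows_reproduce_forward_model(self, small_dataset):
        df = small_dataset.frame.sample(12, random_state=0)
        for set_id, grp in df.groupby("set_id"):
            p = RoliePolyParams(*grp.iloc[0][["eta_p", "tau_D", "tau_R", "chi_max", "beta"]])
            for _, row in grp.iterrows():
                s, n1 = (
                    steady_curve(p, [row["shear_rate"]]).sigma_xy[0],
                    steady_curve(p, [row["shear_rate"]]).N1[0],
                )
                assert s == pytest.approx(row["sigma_xy"], rel=1e-8)
                assert n1 == pytest.approx(row["N1"], rel=1e-8)

    def test_bit_reproducible(self, bounds):
        rates = np.logspace(-2, 2, 3)
        a = generate_dataset(bounds, 30, rates, seed=5, split=(3, 1, 1))
        b = generate_dataset(bounds, 30, rates, seed=5, split=(3, 1, 1))
        assert a.frame.equals(b.frame)

    def test_split_assignment_per_parameter_set(self, small_dataset):
        # all rows of one sampled fluid share a split: no leakage across rates
        per_set = small_dataset.frame.groupby("set_id")["split"].nunique()
        assert (per_set == 1).all()
        counts = small_dataset.frame.groupby("split")["set_id"].nunique()
        assert counts.sum() == 200
        assert counts["val"] == 40 and counts["test"] == 27


def _manual_net(weights, biases, n_in=6):
    """Assemble a SurrogateNet with identity scalers for scaled-space tests."""
    ident_in = FeatureScaler(np.zeros(n_in, bool), np.zeros(n_in), np.ones(n_in))
    n_out = biases[-1].size
    ident_out = FeatureScaler(np.zeros(n_out, bool), np.zeros(n_out), np.ones(n_out))
    return SurrogateNet(weights, biases, ident_in, ident_out)


class TestNetForward:
    def test_zero_weights_give_output_bias(self):
        net = _manual_net(
            [np.zeros((6, 4)), np.zeros((4, 2))],
            [np.zeros(4), np.array([0.7, -0.3])],
        )
        out = net_forward(net, np.ones((5, 6)))
        assert np.allclose(out, [0.7, -0.3], rtol=0, atol=0)

    def test_zero_preactivation_hidden_layer(self):
        # weights cancel the input, bias zero: tanh(0) = 0 so only final bias remains
        W1 = np.zeros((6, 3))
        net = _manual_net([W1, np.ones((3, 1))], [np.zeros(3), np.array([0.25])])
        out = net_forward(net, np.full((1, 6), 9.9))
        assert out[0, 0] == 0.25

    def test_hand_computed_2_2_1(self):
        # frozen pencil-and-paper forward pass
        W1 = np.array([[0.5, -0.3], [0.2, 0.1]])
        b1 = np.array([0.1, -0.2])
        W2 = np.array([[1.0], [-2.0]])
        b2 = np.array([0.05])
        net = _manual_net([W1, W2], [b1, b2], n_in=2)
        out = net_forward(net, np.array([[0.3, -0.7]]))
        assert out[0, 0] == pytest.approx(0.8499865384854713, rel=1e-14)

    def test_shape_mismatch_raises(self, small_net):
        with pytest.raises(ValueError):
            net_forward(small_net, np.ones((3, 4)))


class TestLoss:
    def setup_method(self):
        self.net = _manual_net(
            [np.zeros((6, 4)), np.zeros((4, 2))],
            [np.zeros(4), np.array([1.0, 2.0])],
        )
        self.X = np.zeros((3, 6))

    def test_perfect_predictions_no_penalty(self):
        Y = np.tile([1.0, 2.0], (3, 1))
        assert loss(self.net, (self.X, Y), l2_rate=0.0) == 0.0

    def test_perfect_predictions_pure_penalty(self):
        net = _manual_net(
            [np.full((6, 4), 0.5), np.zeros((4, 2))],
            [np.zeros(4), np.zeros(2)],
        )
        Y = np.tile(net.forward_scaled(self.X)[0], (3, 1))
        expected = 1e-2 * (24 * 0.25)
        assert loss(net, (self.X, Y), l2_rate=1e-2) == pytest.approx(expected, rel=1e-12)

    def test_single_sample_squared_error(self):
        net = _manual_net([np.zeros((6, 1))], [np.array([0.0])], n_in=6)
        Y = np.array([[0.3]])
        assert loss(net, (np.zeros((1, 6)), Y), l2_rate=0.0) == pytest.approx(0.09)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            loss(self.net, (np.zeros((0, 6)), np.zeros((0, 2))), 0.0)


class TestRelativeErrorMetric:
    def test_oracle_predictions_score_zero(self, small_dataset, small_net):
        df = small_dataset.rows("test").head(4).copy()
        pred = small_net.predict_rows(df[["eta_p", "tau_D", "tau_R", "chi_max", "beta", "shear_rate"]].to_numpy())
        df["sigma_xy"], df["N1"] = pred[:, 0], pred[:, 1]
        assert evaluate_relative_error(small_net, df) == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictor_hand_value(self, small_dataset, small_net):
        # two rows with known truths: the metric is the plain mean of the
        # four componentwise relative deviations, in percent
        df = small_dataset.rows("test").head(2).copy()
        pred = small_net.predict_rows(df[["eta_p", "tau_D", "tau_R", "chi_max", "beta", "shear_rate"]].to_numpy())
        truth = df[["sigma_xy", "N1"]].to_numpy()
        expected = np.mean(np.abs(pred - truth) / np.abs(truth)) * 100.0
        assert evaluate_relative_error(small_net, df) == pytest.approx(expected, rel=1e-12)


class TestTraining:
    def test_overfits_tiny_dataset(self, bounds):
        # universal-approximation sanity: a 10-row memorizable set is
        # memorized to well below 0.1% relative stress error.  All splits
        # duplicate the same rows so validation-based model selection keeps
        # the best-fitting epoch.
        import pandas as pd

        from rheoinverse.surrogate import StressDataset

        base = generate_dataset(bounds, 5, np.array([0.1, 10.0]), seed=8, split=(1, 1, 1))
        f = base.frame.copy()
        f["split"] = "train"
        parts = [f]
        for name in ("val", "test"):
            dup = f.copy()
            dup["split"] = name
            parts.append(dup)
        ds = StressDataset(pd.concat(parts, ignore_index=True), bounds, base.rates, seed=8)
        net, _ = train(
            NetConfig(n_hidden_layers=2, neurons_per_layer=48),
            ds,
            TrainingConfig(
                learning_rate=2e-3, l2_rate=0.0, n_epochs=4000, batch_size=16,
                seed=0, n_repeats=1, patience=4000, lr_patience=400,
            ),
        )
        assert evaluate_relative_error(net, ds.rows("train")) < 0.1

    def test_regularization_shrinks_weight_norm(self, bounds):
        # identical runs except for the penalty: the regularized net ends
        # with a markedly smaller summed squared weight norm
        small = generate_dataset(bounds, 50, np.logspace(-2, 2, 5), seed=11, split=(3, 1, 1))
        norms = {}
        for l2 in (0.0, 30.0):
            net, _ = train(
                NetConfig(n_hidden_layers=1, neurons_per_layer=16),
                small,
                TrainingConfig(l2_rate=l2, n_epochs=80, batch_size=64, seed=9, n_repeats=1, patience=80),
            )
            norms[l2] = sum(float(np.sum(W**2)) for W in net.weights)
        assert norms[30.0] < 0.5 * norms[0.0]

    def test_architecture_scan_mechanics(self, small_dataset):
        table = architecture_scan(
            small_dataset,
            hidden_layer_grid=[1],
            neuron_grid=[4, 8],
            training_config=TrainingConfig(n_epochs=10, batch_size=256, seed=2, n_repeats=1),
        )
        assert len(table) == 2
        assert {"n_hidden_layers", "neurons_per_layer", "test_rel_err_pct"} <= set(table.columns)

    def test_checkpoint_roundtrip(self, small_net, tmp_path, rates91):
        path = tmp_path / "net.npz"
        small_net.save(path)
        loaded = SurrogateNet.load(path)
        theta = np.array([50.0, 200.0, 5.0, 18.0, 10.0])
        assert np.array_equal(loaded.predict(theta, rates91), small_net.predict(theta, rates91))
        assert loaded.provenance == small_net.provenance


class TestInputScaler:
    def test_maps_bounds_to_unit_box(self, bounds):
        sc = input_scaler(bounds)
        lo = np.append(bounds.lower, 1e-4)
        hi = np.append(bounds.upper, 1e4)
        assert np.allclose(sc.transform(lo[None, :]), -1.0)
        assert np.allclose(sc.transform(hi[None, :]), 1.0)

    def test_inverse_roundtrip(self, bounds):
        sc = input_scaler(bounds)
        x = np.array([[12.4, 87.0, 11.0, 18.0, 20.0, 0.37]])
        assert np.allclose(sc.inverse(sc.transform(x)), x, rtol=1e-12)
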