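"""Model contracts: shapes, gradients, closed-form OLS, training behaviour."""

import numpy as np
import pandas as pd
import pytest

import activeness as act
from activeness.models import _backward, _forward, _mse_loss, num_parameters
from activeness.preprocessing import ActivenessSeries
from oracles import normal_equations

T0 = pd.Timestamp("2016-01-04")


def windows_from(values, n, m, channels="heart_rate"):
    series = ActivenessSeries(T0, values)
    return act.make_windows(series, n, m, channels_in=channels)


class TestConfigValidation:
    def test_univariate_needs_one_channel(self):
        with pytest.raises(ValueError):
            act.ModelConfig(act.Architecture.UNI_MO, channels_in=3, channels_out=3)

    def test_many_to_many_ties_lengths(self):
        with pytest.raises(ValueError):
            act.ModelConfig(act.Architecture.UNI_MM, input_len=15, output_len=30)

    def test_multivariate_needs_three_channels(self):
        with pytest.raises(ValueError):
            act.ModelConfig(act.Architecture.MULTI_MO)  # defaults to 1 channel


class TestShapes:
    def test_uni_mo_output_window(self, rng):
        cfg = act.ModelConfig(act.Architecture.UNI_MO, input_len=15, output_len=15)
        handle = act.build_model(cfg)
        handle.trained = True
        out = act.predict_window(handle, rng.random((15, 1)))
        assert out.shape == (15, 1)

    def test_multi_mm_output_window(self, rng):
        cfg = act.ModelConfig(
            act.Architecture.MULTI_MM, input_len=15, output_len=15,
            channels_in=3, channels_out=3,
        )
        handle = act.build_model(cfg)
        handle.trained = True
        assert act.predict_window(handle, rng.random((15, 3))).shape == (15, 3)

    def test_untrained_model_refuses_to_predict(self, rng):
        handle = act.build_model(act.ModelConfig(act.Architecture.UNI_MO))
        with pytest.raises(ValueError, match="not trained"):
            act.predict_window(handle, rng.random((15, 1)))

    def test_inference_is_deterministic(self, rng):
        cfg = act.ModelConfig(act.Architecture.UNI_MO, dropout=0.5)
        handle = act.build_model(cfg)
        handle.trained = True
        x = rng.random((15, 1))
        np.testing.assert_array_equal(
            act.predict_window(handle, x), act.predict_window(handle, x)
        )


class TestGradients:
    @pytest.mark.parametrize(
        "arch,ci,n,m",
        [
            (act.Architecture.UNI_MO, 1, 4, 3),
            (act.Architecture.UNI_MM, 1, 4, 4),
            (act.Architecture.MULTI_MO, 3, 4, 2),
            (act.Architecture.MULTI_MM, 3, 3, 3),
            (act.Architecture.DNN_BASELINE, 1, 5, 2),
        ],
    )
    def test_backprop_matches_numerical_gradient(self, rng, arch, ci, n, m):
        cfg = act.ModelConfig(
            architecture=arch, input_len=n, output_len=m,
            channels_in=ci, channels_out=ci, hidden_units=5, dropout=0.0, seed=3,
        )
        handle = act.build_model(cfg)
        X = rng.normal(size=(6, n, ci))
        y = rng.normal(size=(6, m, ci))
        out, cache = _forward(cfg, handle.params, X)
        _, dout = _mse_loss(out, y)
        grads = _backward(cfg, handle.params, X, dout, cache)
        eps = 1e-6
        for key, grad in grads.items():
            p = handle.params[key]
            num = np.zeros_like(p)
            it = np.nditer(p, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p[i]
                p[i] = orig + eps
                lp, _ = _mse_loss(_forward(cfg, handle.params, X)[0], y)
                p[i] = orig - eps
                lm, _ = _mse_loss(_forward(cfg, handle.params, X)[0], y)
                p[i] = orig
                num[i] = (lp - lm) / (2 * eps)
            scale = np.abs(num).max() + 1e-12
            assert np.abs(num - grad).max() / scale < 1e-5, key


class TestOls:
    def test_parameter_count(self):
        cfg = act.ModelConfig(
            act.Architecture.OLS_BASELINE, input_len=15, output_len=10,
        )
        assert num_parameters(act.build_model(cfg)) == (15 * 1 + 1) * 10 * 1

    def test_exact_on_linear_targets(self, rng):
        n, m = 8, 4
        W = rng.normal(size=(n, m))
        X = rng.normal(size=(200, n, 1))
        y = np.einsum("sni,nm->smi", X, W) + 0.7
        data = act.WindowedDataset(
            inputs=X, targets=y, stride=1, offsets=np.arange(200),
            channels_in=("heart_rate",), channels_out=("heart_rate",),
        )
        cfg = act.ModelConfig(act.Architecture.OLS_BASELINE, input_len=n, output_len=m)
        handle = act.train(act.build_model(cfg), data)
        assert handle.training_history[0]["train_loss"] < 1e-10

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(120, 6, 1))
        y = rng.normal(size=(120, 3, 1))
        data = act.WindowedDataset(
            inputs=X, targets=y, stride=1, offsets=np.arange(120),
            channels_in=("steps",), channels_out=("steps",),
        )
        cfg = act.ModelConfig(act.Architecture.OLS_BASELINE, input_len=6, output_len=3)
        handle = act.train(act.build_model(cfg), data)
        design = np.concatenate([X.reshape(120, -1), np.ones((120, 1))], axis=1)
        expected = normal_equations(design, y.reshape(120, -1))
        np.testing.assert_allclose(handle.params["coef"], expected, atol=1e-8)

    def test_prediction_is_the_affine_formula(self, rng):
        X = rng.normal(size=(50, 5, 1))
        y = rng.normal(size=(50, 2, 1))
        data = act.WindowedDataset(
            inputs=X, targets=y, stride=1, offsets=np.arange(50),
            channels_in=("steps",), channels_out=("steps",),
        )
        cfg = act.ModelConfig(act.Architecture.OLS_BASELINE, input_len=5, output_len=2)
        handle = act.train(act.build_model(cfg), data)
        x = rng.normal(size=(5, 1))
        manual = (
            np.concatenate([x.ravel(), [1.0]]) @ handle.params["coef"]
        ).reshape(2, 1)
        np.testing.assert_allclose(act.predict_window(handle, x), manual, rtol=1e-12)


class TestTraining:
    def test_constant_series_learned_to_under_one_percent_smape(self, rng):
        values = np.full((300, 3), 0.5)
        data = windows_from(values, 10, 5)
        # dropout keeps injecting gradient noise, so convergence to the
        # representable constant needs a generous patience
        cfg = act.ModelConfig(
            act.Architecture.UNI_MO, input_len=10, output_len=5,
            max_epochs=600, early_stopping_patience=50, seed=1,
        )
        handle = act.train(act.build_model(cfg), data)
        pred = act.predict_window(handle, np.full((10, 1), 0.5))
        assert act.smape(np.full(5, 0.5), pred.ravel()) < 1.0

    def test_history_bookkeeping(self, norm_series):
        data = act.make_windows(norm_series.slice(0, 400), 10, 5, channels_in="heart_rate")
        cfg = act.ModelConfig(
            act.Architecture.UNI_MO, input_len=10, output_len=5,
            hidden_units=8, max_epochs=8, seed=2,
        )
        handle = act.train(act.build_model(cfg), data)
        assert handle.training_history
        best = min(h["val_loss"] for h in handle.training_history)
        assert best <= handle.training_history[0]["val_loss"]

    def test_same_seed_same_training_outcome(self, norm_series):
        data = act.make_windows(norm_series.slice(0, 300), 10, 5, channels_in="steps")
        cfg = act.ModelConfig(
            act.Architecture.UNI_MO, input_len=10, output_len=5,
            hidden_units=6, max_epochs=5, seed=9,
        )
        h1 = act.train(act.build_model(cfg), data)
        h2 = act.train(act.build_model(cfg), data)
        assert h1.training_history == h2.training_history
        for k in h1.params:
            np.testing.assert_array_equal(h1.params[k], h2.params[k])

    def test_empty_dataset_rejected(self):
        data = act.WindowedDataset(
            inputs=np.empty((0, 10, 1)), targets=np.empty((0, 5, 1)), stride=1,
            offsets=np.array([]), channels_in=("steps",), channels_out=("steps",),
        )
        cfg = act.ModelConfig(act.Architecture.UNI_MO, input_len=10, output_len=5)
        with pytest.raises(ValueError, match="empty"):
            act.train(act.build_model(cfg), data)


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path, rng):
        values = rng.random((120, 3))
        data = windows_from(values, 8, 4, channels="calories")
        cfg = act.ModelConfig(
            act.Architecture.UNI_MO, input_len=8, output_len=4,
            hidden_units=6, max_epochs=3, seed=4,
        )
        handle = act.train(act.build_model(cfg), data)
        act.save_model(handle, tmp_path / "model.npz")
        loaded = act.load_model(tmp_path / "model.npz")
        assert loaded.config == handle.config
        assert loaded.trained
        x = rng.random((8, 1))
        np.testing.assert_array_equal(
            act.predict_window(loaded, x), act.predict_window(handle, x)
        )
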