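"""Architecture arithmetic, cross extraction, resampling, training behavior."""

import numpy as np
import pytest

from p3nmr.network import (ModelSpec, TrainConfig, build_model, count_parameters,
                           extract_cross, extract_crosses, resample_training_points,
                           train, save_model, load_model)
from p3nmr.spectra import AcqGrid, Spectrum
from p3nmr.seeding import substream


class TestArchitecture:
    def test_parameter_count_3d_about_8000(self):
        spec = ModelSpec(n_dims=3)
        n = build_model(spec, 0).n_parameters()
        assert n == count_parameters(spec)
        assert abs(n - 8000) <= 500

    def test_parameter_count_2d_matches_closed_form(self):
        spec = ModelSpec(n_dims=2)
        assert build_model(spec, 0).n_parameters() == count_parameters(spec)

    def test_wnn_shape_arithmetic(self):
        # 64 halves five times to 2 positions -> 20 features per branch
        spec = ModelSpec(n_dims=2)
        assert spec.n_layers == 5
        assert spec.branch_features == 20

    def test_output_in_unit_interval(self):
        m = build_model(ModelSpec(n_dims=2), seed=3)
        x = substream(1, "x").normal(size=(100, 2, 64)).astype(np.float32)
        p = m.predict(x)
        assert np.all((p > 0) & (p < 1))

    def test_gradients_match_finite_differences(self):
        spec = ModelSpec(n_dims=2, cross_length=8, channels=3, hidden=(4, 3))
        m = build_model(spec, 1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 2, 8)).astype(np.float32)
        y = np.array([1, 0, 1, 0, 0, 1], dtype=np.float32)
        _, grads = m.loss_and_grads(X, y)
        params = m.parameters()
        rngi = np.random.default_rng(2)
        for pi in range(len(params)):
            p = params[pi]
            flat = int(rngi.integers(p.size))
            eps = 1e-2
            orig = p.ravel()[flat].copy()
            p.ravel()[flat] = orig + eps
            lp, _ = m.loss_and_grads(X, y)
            p.ravel()[flat] = orig - eps
            lm, _ = m.loss_and_grads(X, y)
            p.ravel()[flat] = orig
            fd = (lp - lm) / (2 * eps)
            assert grads[pi].ravel()[flat] == pytest.approx(fd, abs=2e-4)

    def test_save_load_round_trip(self, tmp_path):
        m = build_model(ModelSpec(n_dims=2), seed=4)
        x = substream(2, "x").normal(size=(10, 2, 64)).astype(np.float32)
        p1 = m.predict(x)
        save_model(m, tmp_path / "m.json")
        m2 = load_model(tmp_path / "m.json")
        assert np.allclose(m2.predict(x), p1, atol=1e-6)


def constant_spectrum(value, shape=(64, 256)):
    grid = AcqGrid((shape[0] // 2, shape[1] // 2))
    return Spectrum(data=np.full(shape, float(value)), grid=grid, sigma_noise=1.0)


class TestExtractCross:
    def test_constant_spectrum(self):
        s = constant_spectrum(3.0)
        c = extract_cross(s, (30, 100))
        # median centering removes the constant level inside the grid
        assert c.shape == (2, 64)
        assert np.allclose(c[:, 32], 0.0)

    def test_corner_zero_padding(self):
        s = constant_spectrum(1.0)
        c = extract_cross(s, (0, 0))
        # positions before the grid start take the scaled-space pad value
        # zero — the baseline of a noise-free region after median/sigma
        # scaling
        assert np.allclose(c[:, :32], 0.0, atol=1e-6)
        assert c[0, 32] == 0.0

    def test_center_is_probed_point(self):
        rng = substream(3, "x")
        data = rng.normal(size=(64, 256))
        s = Spectrum(data=data, grid=AcqGrid((32, 128)), sigma_noise=1.0)
        idx = (17, 93)
        c = extract_cross(s, idx)
        exp = lambda v: np.arcsinh(v - np.median(data))
        assert c[0, 32] == pytest.approx(exp(data[idx]), abs=1e-5)
        assert c[1, 32] == pytest.approx(exp(data[idx]), abs=1e-5)
        assert c[0, 33] == pytest.approx(exp(data[18, 93]), abs=1e-5)
        assert c[1, 33] == pytest.approx(exp(data[17, 94]), abs=1e-5)

    def test_out_of_grid_rejected(self):
        with pytest.raises(ValueError):
            extract_cross(constant_spectrum(1.0), (64, 0))

    def test_batch_matches_single(self):
        rng = substream(4, "x")
        data = rng.normal(size=(64, 256))
        s = Spectrum(data=data, grid=AcqGrid((32, 128)), sigma_noise=1.0)
        idx = np.array([[5, 7], [60, 250], [31, 128]])
        batch = extract_crosses(s, idx)
        for k, i in enumerate(idx):
            assert np.allclose(batch[k], extract_cross(s, i))


class TestResampling:
    def mask(self, n_pos, n_total, rng):
        m = np.zeros(n_total, dtype=np.uint8)
        m[rng.choice(n_total, n_pos, replace=False)] = 1
        return m.reshape(-1, 100)

    def test_ratio_rule(self):
        rng = substream(5, "r")
        m = self.mask(100, 1_000_000, rng)
        idx = resample_training_points(m, 0.01, rng)
        assert len(idx) == 100 + 100 * 100

    def test_equal_ratio(self):
        rng = substream(6, "r")
        m = self.mask(50, 10_000, rng)
        idx = resample_training_points(m, 1.0, rng)
        labels = m[tuple(idx.T)]
        assert labels.sum() == 50 and (1 - labels).sum() == 50

    def test_insufficient_negatives(self):
        rng = substream(7, "r")
        m = self.mask(90, 100, rng)
        idx = resample_training_points(m, 0.01, rng)
        assert len(idx) == 100  # everything kept, no oversampling

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            resample_training_points(np.zeros((10, 10), dtype=np.uint8), 0.01,
                                     substream(8, "r"))


class TestTraining:
    def toy_set(self, n=2000):
        # two Gaussian-blob classes in cross space: linearly separable
        rng = substream(9, "toy")
        y = rng.integers(0, 2, n).astype(np.float32)
        X = rng.normal(size=(n, 2, 64)).astype(np.float32)
        X[y == 1, :, 28:36] += 4.0
        return X, y

    def test_separable_blobs_high_accuracy(self):
        X, y = self.toy_set()
        m = build_model(ModelSpec(n_dims=2), seed=5)
        cfg = TrainConfig(batch_size=256, max_epochs=50, patience=50, seed=5)
        m, hist = train(m, X, y, cfg)
        acc = np.mean((m.predict(X) > 0.5) == (y > 0.5))
        assert acc >= 0.99
        assert hist["val_bce"][-1] <= hist["val_bce"][0]

    def test_perfect_predictions_zero_bce(self):
        m = build_model(ModelSpec(n_dims=2), seed=6)
        z = np.array([100.0, -100.0])
        y = np.array([1.0, 0.0])
        bce = np.mean(np.log1p(np.exp(-np.abs(z))) + np.maximum(z, 0) - z * y)
        assert bce == pytest.approx(0.0, abs=1e-12)

    def test_constant_base_rate_predictor_bce(self):
        # BCE of the constant predictor p = pi equals the binary entropy
        pi = 0.2
        y = np.concatenate([np.ones(200), np.zeros(800)])
        p = np.full(1000, pi)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        assert bce == pytest.approx(-(pi * np.log(pi) + (1 - pi) * np.log(1 - pi)))

    def test_single_class_rejected(self):
        X = np.zeros((10, 2, 64), dtype=np.float32)
        with pytest.raises(ValueError):
            train(build_model(ModelSpec(n_dims=2), 0), X, np.ones(10),
                  TrainConfig(max_epochs=1))

    def test_bit_reproducible(self):
        X, y = self.toy_set(400)
        outs = []
        for _ in range(2):
            m = build_model(ModelSpec(n_dims=2), seed=7)
            cfg = TrainConfig(batch_size=128, max_epochs=3, patience=3, seed=7)
            m, _ = train(m, X, y, cfg)
            outs.append(m.predict(X[:50]))
        assert np.array_equal(outs[0], outs[1])
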