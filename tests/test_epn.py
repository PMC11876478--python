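"""EPN forward pass, pooling, phase decoding, training and serialization."""

import numpy as np
import pytest

from eegphase import epn
from eegphase._utils import wrap_phase
from eegphase import windowing as win
from conftest import tone


def tiny_cfg(**kw):
    kw.setdefault("seed", 3)
    kw.setdefault("epochs", 120)
    return epn.EPNConfig.desk_scale(**kw)


def tone_dataset(n_windows=200, freq=10.0, rate=500.0, seed=0):
    """Labeled EPN inputs cut from a long clean tone with random phases."""
    rng = np.random.default_rng(seed)
    X, theta = [], []
    for _ in range(n_windows):
        phi = rng.uniform(-np.pi, np.pi)
        t = (np.arange(win.WINDOW_LEN) - win.CENTER_INDEX) / rate
        w = win.TrialWindow(raw=10 * np.cos(2 * np.pi * freq * t + phi))
        X.append(win.build_model_inputs(w, "epn", rate))
        theta.append(phi)
    return np.array(X), np.array(theta)


class TestAvgPool:
    def test_hand_enumeration_with_tail_repeat(self):
        out = epn.avg_pool(np.array([1.0, 2, 3, 4]), 3)
        assert np.allclose(out, [2.0, 3.0, 11 / 3, 4.0])

    def test_constant_preserved(self):
        assert np.allclose(epn.avg_pool(np.full(20, 3.3), 13), 3.3)

    def test_kernel_one_is_identity(self, rng):
        x = rng.normal(size=50)
        assert np.array_equal(epn.avg_pool(x, 1), x)

    def test_length_preserved(self, rng):
        x = rng.normal(size=250)
        assert epn.avg_pool(x, 13).shape == x.shape

    def test_shift_equivariance_away_from_tail(self, rng):
        x = rng.normal(size=100)
        a = epn.avg_pool(x, 7)
        b = epn.avg_pool(np.roll(x, 5), 7)
        assert np.allclose(a[5:80], b[10:85])

    def test_bad_kernel(self):
        with pytest.raises(ValueError):
            epn.avg_pool(np.zeros(10), 0)


class TestForward:
    def _zero_weights(self, cfg, d=(0.3, -0.4)):
        return epn.EPNWeights(W=np.zeros((cfg.hidden_dim, cfg.input_len)),
                              B=np.zeros(cfg.hidden_dim),
                              U=np.zeros((2, cfg.hidden_dim)),
                              D=np.array(d))

    def test_zero_weights_pass_bias_through(self, rng):
        cfg = tiny_cfg()
        w = self._zero_weights(cfg)
        z = epn.forward(rng.normal(size=250), w, cfg)
        assert np.allclose(z, [0.3, -0.4])

    def test_inference_deterministic(self, rng):
        cfg = tiny_cfg()
        w = epn.EPNWeights.init(cfg, np.random.default_rng(0))
        x = rng.normal(size=250)
        assert np.array_equal(epn.forward(x, w, cfg), epn.forward(x, w, cfg))

    def test_relu_gates_negative_preactivations(self):
        cfg = tiny_cfg()
        w = self._zero_weights(cfg, d=(1.5, 2.5))
        w.B[:] = -1.0  # all pre-activations negative -> hidden output zero
        w.U[:] = 7.0
        z = epn.forward(np.ones(250), w, cfg)
        assert np.allclose(z, [1.5, 2.5])

    def test_shape_mismatch(self):
        cfg = tiny_cfg()
        w = epn.EPNWeights.init(cfg, np.random.default_rng(0))
        with pytest.raises(ValueError):
            epn.forward(np.zeros(100), w, cfg)

    def test_dropout_expectation_preserved(self, rng):
        # inverted scaling: train-time mean output ~ inference output
        cfg = tiny_cfg()
        w = epn.EPNWeights.init(cfg, np.random.default_rng(1))
        x = rng.normal(size=250)
        z_inf = epn.forward(x, w, cfg)
        g = np.random.default_rng(99)
        z_train = np.mean([epn.forward(x, w, cfg, training=True, rng=g)
                           for _ in range(3000)], axis=0)
        assert np.allclose(z_train, z_inf, atol=0.1 * np.abs(z_inf).max())


class TestPhaseDecoding:
    @pytest.mark.parametrize("z,theta", [
        ((1, 0), 0.0), ((0, -1), -np.pi / 2), ((-1, 1), 3 * np.pi / 4)])
    def test_quadrants(self, z, theta):
        assert epn.phase_from_output(np.array(z, float)) == pytest.approx(theta)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            epn.phase_from_output(np.zeros(2))


class TestTraining:
    def test_loss_decreases_on_clean_tone(self):
        X, theta = tone_dataset(200)
        cfg = tiny_cfg(epochs=100)
        _, trace = epn.train((X, theta), None, cfg)
        assert trace["train"][-1] < trace["train"][0]

    def test_seed_reproducibility(self):
        X, theta = tone_dataset(60)
        cfg = tiny_cfg(epochs=20)
        w1, t1 = epn.train((X, theta), None, cfg)
        w2, t2 = epn.train((X, theta), None, cfg)
        assert np.array_equal(w1.W, w2.W) and np.array_equal(w1.U, w2.U)
        assert t1["train"] == t2["train"]

    def test_noiseless_parameter_recovery(self):
        X, theta = tone_dataset(400, seed=1)
        Xh, th = tone_dataset(80, seed=2)
        cfg = tiny_cfg(epochs=250)
        w, _ = epn.train((X, theta), (Xh, th), cfg)
        pred = epn.predict_phase(Xh, w, cfg)
        mace = np.mean(np.abs(wrap_phase(pred - th)))
        assert mace < 0.3

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            epn.train((np.empty((0, 250)), np.empty(0)), None, tiny_cfg())


class TestSerialization:
    def test_roundtrip_preserves_outputs(self, tmp_path, rng):
        cfg = tiny_cfg()
        w = epn.EPNWeights.init(cfg, np.random.default_rng(5))
        path = tmp_path / "w.npz"
        epn.save_weights(w, path, cfg)
        w2, cfg2 = epn.load_weights(path)
        assert cfg2 == cfg
        for _ in range(100):
            x = rng.normal(size=250)
            dz = epn.forward(x, w, cfg) - epn.forward(x, w2, cfg2)
            assert np.max(np.abs(dz)) < 1e-6

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            epn.load_weights(tmp_path / "absent.npz")

    def test_corrupt_file(self, tmp_path):
        p = tmp_path / "bad.npz"
        p.write_bytes(b"not a zip archive")
        with pytest.raises(ValueError):
            epn.load_weights(p)
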