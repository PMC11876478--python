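"""AR, ETP and MLOF comparators."""

import numpy as np
import pytest

from eegphase import baselines as bl
from eegphase._utils import wrap_phase
from conftest import tone
from test_epn import tone_dataset


class TestARFit:
    def test_sinusoid_recurrence_recovered(self):
        # a pure cosine obeys x_t = 2 cos(w) x_{t-1} - x_{t-2} exactly;
        # the Yule-Walker solution converges onto it with record length
        rate, f = 500.0, 10.0
        w0 = 2 * np.pi * f / rate
        x = np.cos(w0 * np.arange(100000))
        fit = bl.ar_fit(x, 2)
        pred = fit.a[0] * x[1:-1] + fit.a[1] * x[:-2]
        assert np.sqrt(np.mean((x[2:] - pred) ** 2)) < 1e-3
        assert fit.a[0] == pytest.approx(2 * np.cos(w0), abs=0.01)
        assert fit.a[1] == pytest.approx(-1.0, abs=0.01)

    def test_white_noise_order_one(self, rng):
        fit = bl.ar_fit(rng.normal(size=500), 1)
        assert abs(fit.a[0]) < 0.1

    def test_all_zero_segment(self):
        with pytest.raises(ValueError):
            bl.ar_fit(np.zeros(500), 5)

    def test_too_short(self):
        with pytest.raises(ValueError):
            bl.ar_fit(np.ones(50), 30)


class TestARPhase:
    def test_clean_tone_known_phase(self):
        rate = 500.0
        t = (np.arange(500) - 499) / rate  # last sample is time 0
        phi = 1.1
        th = bl.ar_phase_from_raw(np.cos(2 * np.pi * 10 * t + phi),
                                  bl.ARConfig(), rate)
        assert abs(np.degrees(wrap_phase(th - phi))) < 3

    def test_phase_sweep_unbiased(self):
        rate = 500.0
        t = (np.arange(500) - 499) / rate
        errs = []
        for phi in np.linspace(-np.pi, np.pi, 16, endpoint=False):
            th = bl.ar_phase_from_raw(np.cos(2 * np.pi * 10 * t + phi),
                                      bl.ARConfig(), rate)
            errs.append(wrap_phase(th - phi))
        mean_err = np.angle(np.mean(np.exp(1j * np.array(errs))))
        assert abs(np.degrees(mean_err)) < 2
        assert max(abs(np.degrees(e)) for e in errs) < 3

    def test_zero_input_degenerate(self):
        with pytest.raises(ValueError):
            bl.ar_phase_from_raw(np.zeros(500), bl.ARConfig(), 500.0)

    def test_explosive_fit_detected(self):
        fit = bl.ARFit(a=np.array([1.5]), noise_var=0.0)  # pole at 1.5
        with pytest.raises(FloatingPointError):
            bl.ar_extend(fit, np.ones(100), 200)


@pytest.fixture(scope="module")
def tone_state():
    rate = 1000.0
    n = int(240 * rate)
    t = np.arange(n) / rate
    x = np.cos(2 * np.pi * 10.0 * t)
    truth = wrap_phase(2 * np.pi * 10.0 * t)
    return bl.etp_learn(x, rate, ground_truth_phase=truth), x, truth


class TestETP:
    def test_iaf_recovered(self, tone_state):
        state, _, _ = tone_state
        assert state.iaf == pytest.approx(10.0, abs=0.1)
        assert state.t_adj_ms == pytest.approx(100.0, abs=1.0)

    def test_bias_near_zero_for_tone(self, tone_state):
        state, _, _ = tone_state
        assert abs(np.degrees(state.phase_bias)) < 2

    def test_iaf_interpolated_between_bins(self):
        rate = 1000.0
        t = np.arange(int(200 * rate)) / rate
        assert bl.estimate_iaf(np.cos(2 * np.pi * 11.3 * t), rate) == \
            pytest.approx(11.3, abs=0.1)

    def test_broadband_noise_has_no_rhythm(self, rng):
        with pytest.raises(ValueError):
            bl.estimate_iaf(rng.normal(size=200 * 1000), 1000.0)

    @pytest.mark.parametrize("theta,expected_ms", [
        (2 * np.pi, 100.0), (np.pi, 50.0)])
    def test_target_time_substitution(self, theta, expected_ms):
        state = bl.ETPState(iaf=10.0, t_adj_ms=100.0, phase_bias=0.0)
        assert state.target_offset_ms(theta) == pytest.approx(expected_ms)

    def test_interpolation_from_last_peak(self, tone_state):
        # 30 ms after a peak of a 10 Hz rhythm -> phase 2 pi * 0.3
        state, x, truth = tone_state
        t_eval = 100000 + 30  # a peak of the 10 Hz tone sits at each 100 ms
        th = bl.etp_predict_phase(x[:t_eval], state, 1000.0)
        assert abs(np.degrees(wrap_phase(th - 2 * np.pi * 0.3))) < \
            1 + 360 * 10 / 1000  # 1 deg + one-sample quantization

    def test_periodic_rhythm_prediction_exact(self, tone_state):
        state, x, truth = tone_state
        quant = np.radians(360 * 10 / 1000)  # one sample at 10 Hz, 1 kHz
        for t_eval in range(50000, 50700, 61):
            th = bl.etp_predict_phase(x[:t_eval], state, 1000.0)
            assert abs(wrap_phase(th - truth[t_eval])) < np.radians(1) + quant

    def test_no_peak_error(self):
        state = bl.ETPState(iaf=10.0, t_adj_ms=100.0, phase_bias=0.0)
        with pytest.raises(ValueError):
            bl.etp_predict_phase(np.zeros(2000), state, 1000.0)

    def test_state_json_roundtrip(self, tmp_path):
        state = bl.ETPState(iaf=10.5, t_adj_ms=95.2, phase_bias=0.12)
        state.to_json(tmp_path / "etp.json")
        assert bl.ETPState.from_json(tmp_path / "etp.json") == state

    def test_too_short_resting(self):
        with pytest.raises(ValueError):
            bl.etp_learn(np.zeros(1000), 1000.0)


class TestMLOF:
    def test_one_hot_gate_selects_candidate(self, rng):
        cfg = bl.MLOFConfig(n_banks=4)
        w = bl.MLOFWeights.init(cfg, rng)
        w.Wb[:] = 0.0
        w.bb[:] = np.array([0, 0, 50.0, 0])  # effectively one-hot at k=2
        x = rng.normal(size=250)
        z, gates = bl.mlof_forward(x, w, cfg)
        cand = (w.Wa @ x + w.ba).reshape(4, 2)
        assert gates[2] > 0.999999
        assert np.allclose(z, cand[2], atol=1e-6)

    def test_equal_candidates_gate_invariant(self, rng):
        cfg = bl.MLOFConfig(n_banks=3)
        w = bl.MLOFWeights.init(cfg, rng)
        w.Wa[:] = np.tile(w.Wa[:2], (3, 1))
        w.ba[:] = np.tile(w.ba[:2], 3)
        x = rng.normal(size=250)
        z, _ = bl.mlof_forward(x, w, cfg)
        assert np.allclose(z, w.Wa[:2] @ x + w.ba[:2])

    def test_gates_are_probabilities_and_output_in_hull(self, rng):
        cfg = bl.MLOFConfig(n_banks=8)
        w = bl.MLOFWeights.init(cfg, rng)
        for _ in range(20):
            x = rng.normal(size=250)
            z, gates = bl.mlof_forward(x, w, cfg)
            assert gates.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all(gates >= 0)
            cand = (w.Wa @ x + w.ba).reshape(cfg.n_banks, 2)
            assert np.all(z >= cand.min(axis=0) - 1e-12)
            assert np.all(z <= cand.max(axis=0) + 1e-12)

    def test_clean_tone_recovery(self):
        X, theta = tone_dataset(400, seed=4)
        Xh, th = tone_dataset(80, seed=5)
        cfg = bl.MLOFConfig.desk_scale(seed=2, epochs=250)
        w, _ = bl.mlof_train((X, theta), (Xh, th), cfg)
        pred = bl.mlof_predict_phase(Xh, w, cfg)
        assert np.mean(np.abs(wrap_phase(pred - th))) < 0.5

    def test_seed_reproducibility(self):
        X, theta = tone_dataset(60)
        cfg = bl.MLOFConfig.desk_scale(seed=9, epochs=15)
        w1, _ = bl.mlof_train((X, theta), None, cfg)
        w2, _ = bl.mlof_train((X, theta), None, cfg)
        assert np.array_equal(w1.Wa, w2.Wa) and np.array_equal(w1.Wb, w2.Wb)

    def test_empty_dataset(self):
        with pytest.raises(ValueError):
            bl.mlof_train((np.empty((0, 250)), np.empty(0)), None,
                          bl.MLOFConfig())

    def test_weights_roundtrip(self, tmp_path, rng):
        cfg = bl.MLOFConfig(n_banks=5)
        w = bl.MLOFWeights.init(cfg, rng)
        bl.save_mlof(w, tmp_path / "m.npz", cfg)
        w2, cfg2 = bl.load_mlof(tmp_path / "m.npz")
        assert cfg2 == cfg
        x = rng.normal(size=250)
        assert np.allclose(bl.mlof_forward(x, w, cfg)[0],
                           bl.mlof_forward(x, w2, cfg2)[0], atol=1e-12)
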