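"""Synthetic EEG generator: aperiodic fit/synthesis, Kuramoto rhythm,
SNR-calibrated composition."""

import numpy as np
import pytest
from scipy import signal as sps

from eegphase import simulate as sim
from eegphase.metrics import estimate_snr


FREQS = np.linspace(2, 45, 80)


class TestFitAperiodic:
    def test_exact_model_recovered(self):
        truth = sim.AperiodicParams(offset=1.0, knee=0.0, exponent=2.0)
        fit = sim.fit_aperiodic(FREQS, truth.psd(FREQS))
        assert fit.exponent == pytest.approx(2.0, abs=0.05)

    def test_robust_to_injected_peak(self):
        truth = sim.AperiodicParams(offset=1.0, knee=0.0, exponent=2.0)
        psd = truth.psd(FREQS).copy()
        peak = np.abs(FREQS - 10).argmin()
        psd[peak - 1:peak + 2] *= 10.0
        fit = sim.fit_aperiodic(FREQS, psd)
        assert fit.exponent == pytest.approx(2.0, abs=0.1)

    def test_nonpositive_psd_rejected(self):
        psd = np.ones_like(FREQS)
        psd[3] = 0.0
        with pytest.raises(ValueError):
            sim.fit_aperiodic(FREQS, psd)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            sim.fit_aperiodic(FREQS[:5], np.ones(5))

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            sim.AperiodicParams(exponent=-1.0)


class TestGenAperiodic:
    def _logpsd(self, x, rate=500.0):
        f, p = sps.welch(x, fs=rate, window="hann", nperseg=int(rate) * 4)
        sel = (f >= 2) & (f <= 45)
        return f[sel], np.log10(p[sel])

    def test_flat_limit_is_white(self):
        params = sim.AperiodicParams(offset=0.0, knee=0.0, exponent=1e-3)
        x = sim.gen_aperiodic(params, 200 * 500, 500, seed=0)
        f, logp = self._logpsd(x)
        assert np.all(np.abs(logp - np.median(logp)) < 0.15)

    def test_power_law_slope(self):
        params = sim.AperiodicParams(offset=1.0, knee=0.0, exponent=2.0)
        x = sim.gen_aperiodic(params, 200 * 500, 500, seed=1)
        f, logp = self._logpsd(x)
        sel = (f >= 4) & (f <= 40)
        slope = np.polyfit(np.log10(f[sel]), logp[sel], 1)[0]
        assert slope == pytest.approx(-2.0, abs=0.2)

    def test_psd_matches_model_absolutely(self):
        params = sim.AperiodicParams(offset=1.0, knee=0.0, exponent=1.5)
        x = sim.gen_aperiodic(params, 300 * 500, 500, seed=2)
        f, logp = self._logpsd(x)
        assert np.all(np.abs(logp - np.log10(params.psd(f))) < 0.15)

    def test_seed_reproducible(self):
        params = sim.AperiodicParams()
        a = sim.gen_aperiodic(params, 1000, 500, seed=3)
        b = sim.gen_aperiodic(params, 1000, 500, seed=3)
        assert np.array_equal(a, b)

    def test_too_short(self):
        with pytest.raises(ValueError):
            sim.gen_aperiodic(sim.AperiodicParams(), 100, 500)


class TestGenKuramoto:
    def test_single_uncoupled_oscillator_is_pure_tone(self):
        cfg = sim.KuramotoConfig(n_osc=1, mean_freq=10.0, freq_sd=0.0,
                                 coupling=0.0, seed=0)
        rhythm, phase = sim.gen_kuramoto(cfg, 5000, 500.0)
        slope = np.polyfit(np.arange(1000, 4000) / 500.0,
                           np.unwrap(phase)[1000:4000], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 10.0, rel=1e-3)

    def test_incoherent_limit(self):
        # K = 0 with spread frequencies: the ensemble stays dephased and
        # the mean field is far below the fully synchronized amplitude
        cfg = sim.KuramotoConfig(n_osc=100, mean_freq=10.0, freq_sd=1.0,
                                 coupling=0.0, seed=1)
        rhythm, _ = sim.gen_kuramoto(cfg, 4000, 500.0, burn_s=4.0)
        assert np.percentile(np.abs(rhythm), 95) < 0.4

    def test_synchronized_limit(self):
        cfg = sim.KuramotoConfig(n_osc=100, mean_freq=10.0, freq_sd=0.5,
                                 coupling=10 * 0.5 * 2 * np.pi, seed=2)
        rhythm, _ = sim.gen_kuramoto(cfg, 3000, 500.0, burn_s=4.0)
        # order parameter ~ amplitude of the mean field
        assert np.percentile(np.abs(rhythm), 95) > 0.9

    def test_step_halving_convergence(self):
        cfg = sim.KuramotoConfig(seed=5)
        r1, _ = sim.gen_kuramoto(cfg, 2500, 500.0)
        r2, _ = sim.gen_kuramoto(cfg, 5000, 1000.0)
        rms1 = np.sqrt(np.mean(r1 ** 2))
        rms2 = np.sqrt(np.mean(r2 ** 2))
        assert abs(rms1 - rms2) / rms2 < 0.01

    def test_rate_too_low(self):
        with pytest.raises(ValueError):
            sim.gen_kuramoto(sim.KuramotoConfig(), 1000, 30.0)


@pytest.fixture(scope="module")
def parts():
    n, rate = 60 * 500, 500.0
    cfg = sim.KuramotoConfig(seed=11)
    rhythm, phase = sim.gen_kuramoto(cfg, n, rate)
    rhythm *= 10.0
    noise = sim.gen_aperiodic(sim.AperiodicParams(), n, rate, seed=12)
    return rhythm, phase, noise, rate


class TestCompose:
    def test_snr_calibration_grid(self, parts):
        rhythm, phase, noise, rate = parts
        for target in (1.5, 2.0, 3.0, 5.0):
            rec = sim.compose(rhythm, phase, noise, target, rate)
            assert abs(rec.snr - target) / target <= 0.10

    def test_true_phase_invariant_to_noise(self, parts):
        rhythm, phase, noise, rate = parts
        a = sim.compose(rhythm, phase, noise, 1.5, rate)
        b = sim.compose(rhythm, phase, noise, 4.0, rate)
        assert np.array_equal(a.true_phase, b.true_phase)
        assert np.array_equal(a.true_phase, phase)

    def test_noise_monotonically_lowers_snr(self, parts):
        rhythm, phase, noise, rate = parts
        snrs = [estimate_snr(rhythm + alpha * noise, rate).snr
                for alpha in (0.0, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(snrs, snrs[1:]))

    def test_target_above_ceiling_rejected(self, parts):
        rhythm, phase, noise, rate = parts
        with pytest.raises(ValueError):
            sim.compose(rhythm, phase, noise, 1000.0, rate)

    def test_zero_rhythm_rejected(self, parts):
        _, phase, noise, rate = parts
        with pytest.raises(ValueError):
            sim.compose(np.zeros_like(noise), phase, noise, 2.0, rate)


class TestSyntheticSubject:
    def test_reproducible_and_calibrated(self):
        a = sim.synthetic_subject(42, duration_s=40.0, target_snr=2.0)
        b = sim.synthetic_subject(42, duration_s=40.0, target_snr=2.0)
        assert np.array_equal(a.signal, b.signal)
        assert abs(a.snr - 2.0) / 2.0 <= 0.10
        assert len(a.signal) == len(a.true_phase) == 40000

    def test_resample_recomputes_phase_from_clean_rhythm(self):
        rec = sim.synthetic_subject(43, duration_s=40.0, target_snr=2.0)
        r5 = rec.resample_to(500.0)
        assert len(r5.signal) == 20000
        assert np.all(r5.true_phase > -np.pi) and np.all(r5.true_phase <= np.pi)
        # the clean rhythm's spectral peak survives the rate change
        f, p = sps.welch(r5.rhythm, fs=500, nperseg=4096)
        assert 8 <= f[np.argmax(p)] <= 13
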