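import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swdeeg import swd
from swdeeg.swd import (NoComponentError, SWDError, SWDParams,
                        SwarmInstabilityError, calibrate_swarm,
                        decompose_batch, dominant_frequency, extract_ocm,
                        get_calibration_table, select_ocms, swarm_filter,
                        swd_decompose, welch_psd)

FS = 128.0
T = np.arange(128) / FS


def tone(freq, amp=1.0, phase=0.0):
    return amp * np.sin(2 * np.pi * freq * T + phase)


class TestWelch:
    def test_peak_at_tone_frequency(self):
        freqs, psd = welch_psd(tone(16.0), fs=FS)
        assert freqs.shape == (SWDParams().welch_nfft // 2 + 1,)
        assert freqs[np.argmax(psd)] == pytest.approx(16.0)

    def test_integrates_to_variance_scale(self, rng):
        # Parseval-style sanity: integrated PSD tracks sample variance
        x = rng.standard_normal(128)
        freqs, psd = welch_psd(x, fs=FS)
        total = np.trapezoid(psd, freqs)
        assert total / np.var(x) == pytest.approx(1.0, abs=2.0)

    def test_zero_signal_gives_zero_psd(self):
        _, psd = welch_psd(np.zeros(128))
        np.testing.assert_array_equal(psd, 0.0)

    def test_short_signal_rejected(self):
        with pytest.raises(SWDError):
            welch_psd(np.ones(32))


class TestDominantFrequency:
    def test_ratio_to_nyquist(self):
        freqs, psd = welch_psd(tone(16.0), fs=FS)
        assert dominant_frequency(freqs, psd) == pytest.approx(16.0 / 64.0)

    def test_tie_breaks_to_lower_frequency(self):
        freqs = np.linspace(0.0, 1.0, 33)
        psd = np.zeros(33)
        psd[[5, 9]] = 1.0
        assert dominant_frequency(freqs, psd) == pytest.approx(freqs[5])

    def test_nyquist_bin_maps_to_one(self):
        freqs = np.linspace(0.0, 1.0, 33)
        psd = np.zeros(33)
        psd[-1] = 2.0
        assert dominant_frequency(freqs, psd) == 1.0

    def test_all_zero_rejected(self):
        freqs = np.linspace(0.0, 1.0, 33)
        with pytest.raises(NoComponentError):
            dominant_frequency(freqs, np.zeros(33))


class TestSwarmFilter:
    def test_zero_in_zero_out(self):
        np.testing.assert_array_equal(swarm_filter(np.zeros(64), 4, 0.5), 0.0)

    @given(st.floats(-5.0, 5.0).filter(lambda a: abs(a) > 1e-3))
    @settings(max_examples=25, deadline=None)
    def test_linearity(self, a):
        x = np.sin(2 * np.pi * 10 * T)
        y1 = swarm_filter(a * x, 4, 0.7)
        y2 = a * swarm_filter(x, 4, 0.7)
        np.testing.assert_allclose(y1, y2, rtol=1e-10, atol=1e-12)

    def test_matches_member_recursion_reference(self, rng):
        x = rng.standard_normal(128)
        for M, delta in [(2, 0.3), (4, 0.7), (8, 1.5)]:
            fast = swarm_filter(x, M, delta)
            ref = swd._member_recursion_reference(x, M, delta)
            np.testing.assert_allclose(fast, ref, rtol=1e-9, atol=1e-9)

    def test_band_selectivity_at_calibrated_center(self):
        M, delta = calibrate_swarm(20.0 / 64.0)
        center = swarm_filter(tone(20.0), M, delta)
        octave = swarm_filter(tone(10.0), M, delta)
        gain_c = np.sqrt(np.mean(center[32:] ** 2))
        gain_o = np.sqrt(np.mean(octave[32:] ** 2))
        assert gain_c >= gain_o

    def test_instability_detected(self):
        with pytest.raises(SwarmInstabilityError):
            # delta far outside the admissible region blows up quickly
            swarm_filter(np.sin(2 * np.pi * 30 * np.arange(512) / 128), 100, 4.2)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SWDError):
            swarm_filter(np.ones(16), 1, 0.5)
        with pytest.raises(SWDError):
            swarm_filter(np.ones(16), 4, -0.1)


class TestCalibration:
    def test_table_covers_coarse_grid(self):
        table = get_calibration_table()
        for f_bin in np.round(np.arange(0.05, 0.951, 0.05), 2):
            assert float(f_bin) in table
            M, delta = table[float(f_bin)]
            assert M >= 2 and delta > 0

    def test_grid_point_returns_exact_entry(self):
        table = get_calibration_table()
        assert calibrate_swarm(0.25) == table[0.25]

    def test_between_points_returns_nearest_bin(self):
        assert calibrate_swarm(0.2501) == calibrate_swarm(0.25)

    def test_out_of_range_rejected(self):
        with pytest.raises(SWDError):
            calibrate_swarm(0.0)
        with pytest.raises(SWDError):
            calibrate_swarm(1.2)


class TestExtractOCM:
    def test_pure_tone_energy_capture(self):
        x = tone(10.0)
        ocm, residual = extract_ocm(x)
        assert np.sum(ocm**2) / np.sum(x**2) >= 0.8
        assert np.sum(residual**2) / np.sum(x**2) <= 0.2

    def test_residual_identity(self, rng):
        x = rng.standard_normal(128)
        ocm, residual = extract_ocm(x)
        np.testing.assert_allclose(ocm + residual, x, atol=1e-12)

    def test_zero_signal_rejected(self):
        with pytest.raises(NoComponentError):
            extract_ocm(np.zeros(128))


class TestDecompose:
    def test_two_tone_separation(self):
        x = tone(10.0, phase=0.3) + tone(25.0, phase=1.1)
        ocms, _ = swd_decompose(x)
        assert len(ocms) >= 2
        energies = [np.sum(o**2) for o in ocms]
        top2 = np.argsort(energies)[-2:]
        doms = []
        for i in top2:
            freqs, psd = welch_psd(ocms[i], fs=FS)
            doms.append(dominant_frequency(freqs, psd) * 64.0)
        assert sorted(np.round(doms)) == [10.0, 24.0] or \
            sorted(np.round(doms)) == [10.0, 26.0]  # 25 Hz sits between bins

    def test_exact_reconstruction(self, rng):
        x = rng.standard_normal(128)
        ocms, residual = swd_decompose(x)
        recon = np.sum(ocms, axis=0) + residual
        np.testing.assert_allclose(recon, x, atol=1e-10)

    def test_white_noise_respects_cap(self, rng):
        params = SWDParams(Pth=0.01, max_ocms=5)
        ocms, _ = swd_decompose(rng.standard_normal(128), params)
        assert len(ocms) <= 5

    def test_band_localization_of_modes(self):
        x = tone(10.0) + tone(20.0, amp=0.8) + tone(30.0, amp=0.6)
        ocms, _ = swd_decompose(x)
        for o in ocms[:3]:
            freqs, psd = welch_psd(o, fs=FS)
            k = int(np.argmax(psd))
            lo, hi = max(k - 2, 0), min(k + 3, psd.size)
            assert psd[lo:hi].sum() / psd.sum() >= 0.6

    def test_determinism(self, rng):
        x = rng.standard_normal(128)
        a_ocms, a_res = swd_decompose(x)
        b_ocms, b_res = swd_decompose(x.copy())
        assert len(a_ocms) == len(b_ocms)
        for a, b in zip(a_ocms, b_ocms):
            np.testing.assert_array_equal(a, b)


class TestSelectOCMs:
    def test_keeps_first_three(self, rng):
        ocms = [rng.standard_normal(128) for _ in range(5)]
        out = select_ocms(ocms, keep=3)
        assert out.shape == (128, 3)
        for j in range(3):
            np.testing.assert_array_equal(out[:, j], ocms[j])

    def test_pads_missing_planes_with_zeros(self, rng):
        ocms = [rng.standard_normal(128) for _ in range(2)]
        out = select_ocms(ocms, keep=3)
        np.testing.assert_array_equal(out[:, 2], 0.0)

    def test_identity_when_exact(self, rng):
        ocms = [rng.standard_normal(128) for _ in range(3)]
        out = select_ocms(ocms, keep=3)
        np.testing.assert_array_equal(out, np.stack(ocms, axis=1))


class TestBatchEquivalence:
    def test_batch_matches_per_signal_decomposition(self, rng):
        signals = rng.standard_normal((40, 128))
        modes, res_frac = decompose_batch(signals)
        params = SWDParams()
        for i in range(signals.shape[0]):
            ocms, _ = swd_decompose(signals[i], params)
            expected = select_ocms(ocms, params.keep, 128) if ocms \
                else np.zeros((128, 3))
            np.testing.assert_allclose(modes[i], expected, atol=1e-9)
        assert res_frac.shape == (40,)
        assert np.all(res_frac >= 0)
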