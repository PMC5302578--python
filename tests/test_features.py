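"""Spectral, wavelet and envelope feature extraction."""

import numpy as np
import pytest
from scipy.signal.windows import hann

from nanoecho import (FEATURE_NAMES, WindowSpec, default_band_mhz,
                      envelope_params, feature_map, feature_vector,
                      grid_shape, spectral_params, wavelet_params,
                      window_spectrum)
from nanoecho.features import (DegenerateWindowError, NFFT,
                               WELCH_SEGMENT_SAMPLES, WELCH_HOP_SAMPLES)

FS = 50.0  # MHz


def tone_segment(freq_mhz, n_tracks=6, n_samples=70, fs=FS, phase=0.3):
    t = np.arange(n_samples) / fs
    return np.tile(np.cos(2 * np.pi * freq_mhz * t + phase), (n_tracks, 1))


class TestWindowSpectrum:
    def test_tone_peaks_at_carrier_bin(self):
        freqs, db = window_spectrum(tone_segment(10.0), FS)
        assert abs(freqs[np.argmax(db)] - 10.0) <= freqs[1] - freqs[0]

    def test_parseval_per_segment(self):
        """Bin sum equals the mean energy of the Hann-windowed Welch
        sub-segments (the estimator's normalization contract)."""
        rng = np.random.default_rng(5)
        seg = rng.standard_normal((6, 70))
        freqs, p = window_spectrum(seg, FS, scale="linear")
        L = WELCH_SEGMENT_SAMPLES
        win = hann(L, sym=False)
        energies = []
        for tr in seg:
            for s in range(0, 70 - L + 1, WELCH_HOP_SAMPLES):
                energies.append(np.sum((tr[s:s + L] * win) ** 2))
        assert p.sum() == pytest.approx(np.mean(energies), rel=1e-6)

    def test_all_zero_flagged(self):
        with pytest.raises(DegenerateWindowError):
            window_spectrum(np.zeros((6, 70)), FS)

    def test_white_noise_flatness_approaches_one(self):
        """Averaging many independent windows drives the flatness of the
        mean periodogram toward the flat-spectrum limit."""
        rng = np.random.default_rng(6)
        acc = 0.0
        for _ in range(200):
            freqs, p = window_spectrum(rng.standard_normal((6, 70)), FS,
                                       scale="linear")
            acc = acc + p
        band = (2.0, 23.0)
        f9 = spectral_params(freqs, acc, band)[8]
        assert f9 > 0.95


class TestSpectralParams:
    def test_flat_spectrum(self):
        freqs = np.fft.rfftfreq(NFFT, d=1 / FS)
        flat = np.ones_like(freqs)
        p = spectral_params(freqs, flat, (4.0, 16.0))
        assert p[0] == pytest.approx(0.0, abs=1e-9)   # slope
        assert p[8] == pytest.approx(1.0, rel=1e-9)   # flatness

    def test_synthetic_line_slope_refit(self):
        freqs = np.fft.rfftfreq(NFFT, d=1 / FS)
        db_line = -2.0 * freqs + 5.0
        power = 10 ** (db_line / 10)
        p = spectral_params(freqs, power, (4.0, 16.0))
        # spectra are parameterized relative to total power: slope is
        # offset-invariant, so it must be recovered exactly
        assert p[0] == pytest.approx(-2.0, abs=0.01)

    def test_single_bin_impulse_entropy_zero(self):
        freqs = np.fft.rfftfreq(NFFT, d=1 / FS)
        power = np.zeros_like(freqs)
        power[40] = 1.0
        p = spectral_params(freqs, power, (4.0, 16.0))
        assert p[7] == pytest.approx(0.0, abs=1e-9)

    def test_band_narrower_than_3_bins_rejected(self):
        freqs = np.fft.rfftfreq(NFFT, d=1 / FS)
        with pytest.raises(ValueError):
            spectral_params(freqs, np.ones_like(freqs), (10.0, 10.1))


class TestWaveletParams:
    def test_relative_energies_sum_to_one(self, rng):
        p = wavelet_params(rng.standard_normal((6, 70)))
        assert p[:5].sum() == pytest.approx(1.0, rel=1e-12)

    def test_tone_concentrates_in_level2(self):
        # 10 MHz at 50 MHz sampling lies in the 6.25-12.5 MHz dyadic band
        p = wavelet_params(tone_segment(10.0, n_samples=128))
        assert np.argmax(p[:5]) == 1
        assert p[1] > 0.5

    def test_white_noise_entropy_matches_dyadic_band_widths(self, rng):
        """White noise spreads energy in proportion to sub-band width:
        p = (1/2, 1/4, 1/8, 1/16, 1/16) over (d1..d4, a4), whose
        normalized entropy is -sum(p ln p)/ln 5 = 0.8083."""
        p = np.array([0.5, 0.25, 0.125, 0.0625, 0.0625])
        expected = -(p * np.log(p)).sum() / np.log(5)
        vals = [wavelet_params(rng.standard_normal((6, 128)))[5]
                for _ in range(50)]
        assert np.mean(vals) == pytest.approx(expected, abs=0.03)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateWindowError):
            wavelet_params(np.zeros((6, 70)))


class TestEnvelopeParams:
    def test_rayleigh_nakagami_shape_is_one(self, rng):
        # circular-Gaussian RF -> Rayleigh envelope -> Nakagami m = 1
        ms = []
        for _ in range(30):
            seg = rng.standard_normal((6, 500))
            ms.append(envelope_params(seg, FS)[5])
        assert np.mean(ms) == pytest.approx(1.0, abs=0.1)

    def test_constant_envelope_guarded(self):
        p = envelope_params(tone_segment(10.0, n_samples=200), FS)
        assert np.isfinite(p[2])     # SNR capped, not inf
        assert p[2] > 100            # near-constant envelope
        assert p[5] > 100            # Nakagami m large

    def test_tone_zero_crossing_rate(self):
        p = envelope_params(tone_segment(10.0), FS)
        # two crossings per carrier period -> 20 crossings/us
        assert p[7] == pytest.approx(20.0, abs=0.8)


class TestFeatureMap:
    def test_grid_shape_formula(self):
        assert grid_shape(WindowSpec(6, 70, 1, 1), 152, 2980) == (147, 2911)
        assert grid_shape(WindowSpec(6, 70, 2, 10), 152, 2980) == (74, 292)

    def test_window_equal_to_frame_gives_single_vector(self, rng):
        frame = rng.standard_normal((6, 70))
        fm = feature_map(frame, WindowSpec(6, 70), fs_mhz=FS)
        assert fm.shape == (1, 1)
        assert np.isfinite(fm.values).all()

    def test_deterministic_on_identical_frames(self, small_sim, small_window):
        a = feature_map(small_sim.frame(0), small_window)
        b = feature_map(small_sim.frame(0), small_window)
        assert np.array_equal(a.values, b.values)

    def test_all_features_finite_on_simulated_frame(self, small_sim,
                                                    small_window):
        fm = feature_map(small_sim.frame(0), small_window)
        assert np.isfinite(fm.values).all()
        assert fm.values.shape[-1] == len(FEATURE_NAMES) == 25

    def test_matches_single_window_spectral_path(self, small_sim):
        """The vectorized map agrees with the public per-window functions
        for the spectral and wavelet families (the envelope family uses
        frame-level analytic signals, so boundaries differ slightly)."""
        frame = small_sim.frame(0)
        rf = frame.as_float()
        w = WindowSpec(6, 70, 21, 400)
        fm = feature_map(frame, w)
        band = fm.band_mhz
        for i in (0, 1):
            for j in (0, 1):
                t0, s0 = i * 21, j * 400
                seg = rf[t0:t0 + 6, s0:s0 + 70]
                ref = feature_vector(seg, FS, band)
                assert fm.values[i, j, :17] == pytest.approx(ref[:17],
                                                             rel=1e-5)

    def test_centroid_higher_in_loaded_layer(self, small_sim):
        """Rayleigh-weighted nanotube scatterers shift the in-layer
        spectral centroid up relative to plain gel (Mann-Whitney)."""
        from scipy.stats import mannwhitneyu
        fm = feature_map(small_sim.frame(0), WindowSpec(6, 70, 2, 10))
        acq = small_sim.acquisition
        depth = fm.ax_centers * acq.depth_per_sample_mm
        b = small_sim.phantom.layer_boundaries_mm
        in_l = (depth >= b[1] + 0.5) & (depth < b[2] - 0.5)
        out_l = ((depth >= b[0] + 0.5) & (depth < b[1] - 0.5)
                 | (depth >= b[2] + 0.5) & (depth < b[3] - 0.5))
        f5 = fm.values[..., 4]
        x, y = f5[:, in_l].ravel(), f5[:, out_l].ravel()
        assert x.size >= 100 and y.size >= 100
        res = mannwhitneyu(x, y, alternative="greater")
        assert res.pvalue < 0.01
        assert x.mean() > y.mean()
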