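"""RF phantom simulator: pulse, scatterer field, frame synthesis."""

import dataclasses

import numpy as np
import pytest
from scipy.signal import hilbert

from nanoecho import (AcquisitionSpec, GroundTruthMask, PhantomSpec,
                      build_scatterer_field, make_pulse, rayleigh_pulse,
                      simulate_acquisition, synthesize_frame)
from nanoecho.rfsim import MAX_HNT_PER_CELL, acquisition_seeds


class TestPulse:
    def test_spectrum_peaks_at_center_frequency(self):
        acq = AcquisitionSpec()
        p = make_pulse(acq)
        f = np.fft.rfftfreq(4096, d=1 / acq.sampling_rate_mhz)
        mag = np.abs(np.fft.rfft(p, 4096))
        assert abs(f[np.argmax(mag)] - 10.0) < 0.2

    def test_minus6db_bandwidth_matches_fractional_bandwidth(self):
        acq = AcquisitionSpec()
        p = make_pulse(acq)
        f = np.fft.rfftfreq(4096, d=1 / acq.sampling_rate_mhz)
        pw = np.abs(np.fft.rfft(p, 4096)) ** 2
        above = f[pw > pw.max() * 10 ** (-0.6)]
        bw = above.max() - above.min()
        assert bw == pytest.approx(6.0, abs=0.5)

    def test_support_and_energy(self):
        acq = AcquisitionSpec()
        p = make_pulse(acq)
        assert np.isfinite(p).all()
        assert len(p) / (acq.sampling_rate_mhz) < 1.0  # duration < 1 us
        assert p.max() == pytest.approx(1.0, abs=0.05)

    def test_rayleigh_weighting_upshifts_spectrum(self):
        acq = AcquisitionSpec()
        f = np.fft.rfftfreq(4096, d=1 / acq.sampling_rate_mhz)

        def centroid(x):
            pw = np.abs(np.fft.rfft(x, 4096)) ** 2
            return (f * pw).sum() / pw.sum()

        assert centroid(rayleigh_pulse(acq)) > centroid(make_pulse(acq)) + 0.5


class TestScattererField:
    def test_zero_concentration_only_background(self, small_acq,
                                                small_phantom):
        ph = dataclasses.replace(small_phantom, hnt_number_conc=0.0)
        fld = build_scatterer_field(ph, small_acq, seed=1)
        assert not fld.rayleigh.any()
        assert len(fld) > 0

    def test_hnt_count_proportional_to_concentration(self, small_acq,
                                                     small_phantom):
        counts = {}
        for conc in (10e10, 20e10):
            n = []
            for seed in range(8):
                ph = dataclasses.replace(small_phantom,
                                         hnt_number_conc=conc,
                                         clustering_coefficient=0.0)
                fld = build_scatterer_field(ph, small_acq, seed=seed)
                n.append(fld.rayleigh.sum())
            counts[conc] = np.mean(n)
        assert counts[20e10] / counts[10e10] == pytest.approx(2.0, rel=0.05)

    def test_power_conserved_across_density_cap(self, small_acq,
                                                small_phantom):
        """Doubling the concentration across the computational cap must
        still double the mean backscattered power (amplitude rescaling
        under the cap), within 5% over a Monte-Carlo seed set."""
        conc_lo = MAX_HNT_PER_CELL * 0.8e10   # below cap
        conc_hi = MAX_HNT_PER_CELL * 1.6e10   # capped
        dz = small_acq.depth_per_sample_mm
        b = small_phantom.layer_boundaries_mm
        s0, s1 = int((b[1] + 0.7) / dz), int((b[2] - 0.7) / dz)
        ratios = []
        for seed in range(6):
            powers = {}
            for conc in (conc_lo, conc_hi):
                ph = dataclasses.replace(
                    small_phantom, hnt_number_conc=conc,
                    background_scatterer_density=0.0,
                    clustering_coefficient=0.0,
                    echogenicity_jitter_db=0.0)
                fld = build_scatterer_field(ph, small_acq, seed=seed)
                acq = dataclasses.replace(small_acq, noise_snr_db=None)
                fr = synthesize_frame(fld, acq, seed=seed)
                env = np.abs(hilbert(fr.as_float(), axis=-1))
                powers[conc] = np.mean(env[:, s0:s1] ** 2)
            ratios.append(powers[conc_hi] / powers[conc_lo])
        assert np.mean(ratios) == pytest.approx(2.0, rel=0.05)

    def test_cluster_merging_reduces_rayleigh_tagged_fraction(
            self, small_acq, small_phantom):
        ph0 = dataclasses.replace(small_phantom, hnt_number_conc=66e10,
                                  clustering_coefficient=0.0)
        ph1 = dataclasses.replace(small_phantom, hnt_number_conc=66e10,
                                  clustering_coefficient=0.5)
        f0 = build_scatterer_field(ph0, small_acq, seed=5)
        f1 = build_scatterer_field(ph1, small_acq, seed=5)
        assert f1.rayleigh.sum() < 0.8 * f0.rayleigh.sum()


class TestSynthesis:
    def test_empty_field_zero_noise_gives_all_zero_frame(self, small_acq):
        ph = PhantomSpec(layer_boundaries_mm=(1.5, 4.0, 9.5, 12.5),
                         hnt_number_conc=0.0,
                         background_scatterer_density=0.0)
        acq = dataclasses.replace(small_acq, noise_snr_db=None)
        fld = build_scatterer_field(ph, acq, seed=1)
        fr = synthesize_frame(fld, acq, seed=1)
        assert not fr.samples.any()

    def test_quantization_within_signed_16bit(self, small_sim):
        assert small_sim.frames.dtype == np.int16
        assert np.abs(small_sim.frames).max() <= 32767

    def test_determinism_bit_identical(self, small_acq, small_phantom):
        a = simulate_acquisition(small_phantom, small_acq, 2, seed=33)
        b = simulate_acquisition(small_phantom, small_acq, 2, seed=33)
        assert np.array_equal(a.frames, b.frames)
        assert a.scale == b.scale

    def test_single_frame_matches_synthesize_frame(self, small_acq,
                                                   small_phantom):
        sim = simulate_acquisition(small_phantom, small_acq, 1, seed=9)
        field_ss, frame_ss = acquisition_seeds(9, 1)
        fld = build_scatterer_field(small_phantom, small_acq, seed=field_ss)
        fr = synthesize_frame(fld, small_acq, lateral_offset=0.0,
                              seed=frame_ss[0])
        assert np.array_equal(sim.frames[0], fr.samples)

    def test_mask_rows_span_layer_thickness(self):
        acq = AcquisitionSpec()
        ph = PhantomSpec()
        mask = GroundTruthMask.from_phantom(ph, acq)
        rows = mask.values[0]
        assert (mask.values == rows).all()  # horizontal layer
        span_mm = rows.sum() * acq.depth_per_sample_mm
        assert span_mm == pytest.approx(15.0, abs=0.1)

    def test_nyquist_validation(self):
        with pytest.raises(ValueError):
            AcquisitionSpec(center_frequency_mhz=30.0)
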