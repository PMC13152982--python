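"""Simulator: physiology trains, waveforms, k-space forward model, ECG channel."""

import numpy as np
import pytest

from ztepulse.geometry import AcquisitionConfig, build_spoke_table
from ztepulse.simulate import (Compartment, PhantomSpec, cardiac_waveform,
                               default_phantom, resp_waveform, sample_kspace,
                               simulate_physiology, synthesize_ecg)

from conftest import brute_force_dft


class TestPhysiology:
    def test_deterministic_limit(self):
        phy = simulate_physiology(60.0, heart_rate=300, hr_jitter_cv=0.0,
                                  resp_rate=50, resp_jitter_cv=0.0, seed=0)
        assert phy.r_peak_times.size == 301           # 300 intervals of 0.2 s
        np.testing.assert_allclose(np.diff(phy.r_peak_times), 0.2, atol=1e-9)

    def test_jitter_cv_recovered(self):
        phy = simulate_physiology(120.0, heart_rate=342.1, hr_jitter_cv=0.022,
                                  seed=42)
        iv = np.diff(phy.r_peak_times)
        assert iv.size >= 500
        assert np.std(iv, ddof=1) / np.mean(iv) == pytest.approx(0.022, abs=0.005)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            simulate_physiology(0.0)
        with pytest.raises(ValueError):
            simulate_physiology(10.0, hr_jitter_cv=0.7)

    def test_reproducible(self):
        a = simulate_physiology(30.0, seed=7)
        b = simulate_physiology(30.0, seed=7)
        np.testing.assert_array_equal(a.r_peak_times, b.r_peak_times)


class TestWaveforms:
    def test_cardiac_peak_support_and_half_value(self):
        assert cardiac_waveform(0.3, delay=0.3, width=0.4) == pytest.approx(1.0)
        assert cardiac_waveform(0.3 + 0.2, delay=0.3, width=0.4) == 0.0
        assert cardiac_waveform(0.3 + 0.1, delay=0.3, width=0.4) == pytest.approx(0.5)
        # circular distance: phase just below 1 is close to delay 0.05
        assert cardiac_waveform(0.99, delay=0.05, width=0.4) > 0.5

    def test_cardiac_width_validation(self):
        with pytest.raises(ValueError):
            cardiac_waveform(0.1, delay=0.0, width=0.0)

    def test_resp_peak(self):
        assert resp_waveform(0.0) == pytest.approx(1.0)
        assert resp_waveform(0.5) == pytest.approx(0.0, abs=1e-12)


def _static_phantom(cfg, **spec_kw):
    comps = tuple(
        Compartment(c.name, c.shape, c.center_mm, c.radii_mm,
                    baseline=c.baseline)
        for c in default_phantom(cfg).compartments)
    return PhantomSpec(compartments=comps, resp_shift_mm=0.0,
                       resp_phase_rad=0.0, noise_sd=0.0, **spec_kw)


@pytest.fixture(scope="module")
def static_setup():
    cfg = AcquisitionConfig(matrix_size=8, readout_samples=6,
                            dead_time_gap=0, spokes_per_volume=50,
                            n_volumes=1, fov=35.0)
    phantom = _static_phantom(cfg)
    spokes = build_spoke_table(cfg)
    physio = simulate_physiology(cfg.duration + 2, seed=0)
    ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
    return cfg, phantom, spokes, physio, ks


class TestKSpace:
    def test_matches_direct_dft_oracle(self, static_setup):
        """Forward model equals a brute-force voxel-sum DFT on 8^3."""
        cfg, phantom, spokes, _, ks = static_setup
        img = phantom.ground_truth_image(cfg)
        kpts = (spokes.directions[:, None, :]
                * ks.radii[None, :, None]).reshape(-1, 3)
        expect = brute_force_dft(img, kpts)
        got = ks.samples.ravel()
        assert (np.linalg.norm(got - expect)
                / np.linalg.norm(expect)) < 1e-3

    def test_shift_theorem(self, static_setup):
        """Translating the phantom multiplies samples by a linear phase."""
        cfg, _, spokes, physio, _ = static_setup
        blob = ((lambda r: Compartment("blob", "ellipsoid", (0, 0, 0),
                                       (r, r, r), baseline=1.0))
                (0.15 * cfg.fov),)
        base = PhantomSpec(compartments=blob, resp_shift_mm=0.0,
                           resp_phase_rad=0.0, noise_sd=0.0)
        dz_mm = cfg.voxel_size        # one voxel: rasterization shifts exactly
        shifted = PhantomSpec(
            compartments=(Compartment("blob", "ellipsoid", (0, 0, dz_mm),
                                      blob[0].radii_mm, baseline=1.0),),
            resp_shift_mm=0.0, resp_phase_rad=0.0, noise_sd=0.0)
        ks1 = sample_kspace(base, spokes, physio, cfg, seed=0)
        ks2 = sample_kspace(shifted, spokes, physio, cfg, seed=0)
        kz = spokes.directions[:, 2:3] * ks1.radii[None, :]
        expect = ks1.samples * np.exp(-2j * np.pi * kz * dz_mm / cfg.fov)
        scale = np.abs(ks1.samples).max()
        np.testing.assert_allclose(ks2.samples / scale, expect / scale,
                                   atol=1e-6)

    def test_zero_phantom_and_linearity(self, static_setup):
        cfg, phantom, spokes, physio, ks = static_setup
        zero = PhantomSpec(compartments=tuple(
            Compartment(c.name, c.shape, c.center_mm, c.radii_mm, baseline=0.0)
            for c in phantom.compartments),
            resp_shift_mm=0.0, resp_phase_rad=0.0, noise_sd=0.0)
        ks0 = sample_kspace(zero, spokes, physio, cfg, seed=0)
        assert np.all(ks0.samples == 0)
        doubled = PhantomSpec(compartments=tuple(
            Compartment(c.name, c.shape, c.center_mm, c.radii_mm,
                        baseline=2 * c.baseline)
            for c in phantom.compartments),
            resp_shift_mm=0.0, resp_phase_rad=0.0, noise_sd=0.0)
        ks2 = sample_kspace(doubled, spokes, physio, cfg, seed=0)
        np.testing.assert_allclose(ks2.samples, 2 * ks.samples, rtol=1e-12)

    def test_dc_sample_is_volume_integral(self, static_setup):
        """With no gap, the k=0 sample is the summed image intensity."""
        cfg, phantom, spokes, _, ks = static_setup
        dc = ks.samples[:, 0]
        total = phantom.ground_truth_image(cfg).sum()
        np.testing.assert_allclose(dc.real, total, rtol=1e-9)
        np.testing.assert_allclose(dc.imag, 0.0, atol=1e-6 * total)

    def test_seed_determinism(self, tiny_cfg):
        phantom = default_phantom(tiny_cfg)
        spokes = build_spoke_table(tiny_cfg)
        physio = simulate_physiology(tiny_cfg.duration + 2, seed=1)
        a = sample_kspace(phantom, spokes, physio, tiny_cfg, seed=4)
        b = sample_kspace(phantom, spokes, physio, tiny_cfg, seed=4)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_short_physiology_rejected(self, tiny_cfg):
        phantom = default_phantom(tiny_cfg)
        spokes = build_spoke_table(tiny_cfg)
        short = simulate_physiology(tiny_cfg.duration / 2, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            sample_kspace(phantom, spokes, short, tiny_cfg, seed=0)


class TestECGSynthesis:
    def test_clean_qrs_peaks_at_r_times(self, tiny_cfg):
        physio = simulate_physiology(tiny_cfg.duration + 1, seed=2)
        onsets = np.arange(tiny_cfg.n_volumes) * tiny_cfg.volume_tr
        rec = synthesize_ecg(physio, onsets, tiny_cfg, artifact_amplitude=0.0,
                             noise_sd=0.0, line_amplitude=0.0,
                             wander_amplitude=0.0, seed=0)
        fs = rec.sampling_rate
        for rt in physio.r_peak_times[1:-1]:
            if rt > tiny_cfg.duration - 0.1:
                break
            i = int(round(rt * fs))
            w = rec.signal[i - 40:i + 41]
            assert abs(int(np.argmax(w)) - 40) <= 1

    def test_artifact_volume_periodicity(self, tiny_cfg):
        physio = simulate_physiology(tiny_cfg.duration + 1, seed=2)
        onsets = np.arange(tiny_cfg.n_volumes) * tiny_cfg.volume_tr
        rec = synthesize_ecg(physio, onsets, tiny_cfg, artifact_amplitude=5.0,
                             qrs_amplitude=0.0, noise_sd=0.0,
                             line_amplitude=0.0, wander_amplitude=0.0,
                             drift=0.0, seed=0)
        L = int(round(tiny_cfg.volume_tr * rec.sampling_rate))
        v0 = rec.signal[:L]
        v1 = rec.signal[L:2 * L]
        assert np.std(v0 - v1) < 0.01 * np.std(v0)

    def test_50hz_component_present(self, tiny_cfg):
        physio = simulate_physiology(tiny_cfg.duration + 1, seed=2)
        onsets = np.arange(tiny_cfg.n_volumes) * tiny_cfg.volume_tr
        rec = synthesize_ecg(physio, onsets, tiny_cfg, artifact_amplitude=0.0,
                             qrs_amplitude=0.0, noise_sd=0.0,
                             wander_amplitude=0.0, seed=0)
        spec = np.abs(np.fft.rfft(rec.signal))
        freqs = np.fft.rfftfreq(rec.signal.size, 1 / rec.sampling_rate)
        assert abs(freqs[np.argmax(spec[1:]) + 1] - 50.0) < 0.5
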