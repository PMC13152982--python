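"""k-space self-gating: center phase surrogate, bias removal, respiratory peaks."""

import numpy as np
import pytest

from ztepulse.geometry import AcquisitionConfig, build_spoke_table
from ztepulse.selfgate import (SurrogateSeries, detect_resp_peaks,
                               extract_center_phase, remove_direction_bias,
                               respiratory_events_from_kspace,
                               respiratory_waveform)
from ztepulse.simulate import KSpaceData, default_phantom, sample_kspace, \
    simulate_physiology


class TestCenterPhase:
    def test_phase_definition(self, tiny_cfg):
        spokes = build_spoke_table(tiny_cfg)
        n = len(spokes)
        samples = np.ones((n, tiny_cfg.readout_samples), dtype=complex)
        samples[0, 0] = 2.0          # positive real -> 0
        samples[1, 0] = 3.0j         # positive imaginary -> pi/2
        ks = KSpaceData(samples=samples, gap=tiny_cfg.dead_time_gap,
                        radii=tiny_cfg.sample_radii(), config=tiny_cfg)
        sur = extract_center_phase(ks, spokes)
        assert sur.value[0] == pytest.approx(0.0)
        assert sur.value[1] == pytest.approx(np.pi / 2)

    def test_zero_sample_warns_and_zeroes(self, tiny_cfg, caplog):
        spokes = build_spoke_table(tiny_cfg)
        samples = np.ones((len(spokes), tiny_cfg.readout_samples),
                          dtype=complex)
        samples[5, 0] = 0.0
        ks = KSpaceData(samples=samples, gap=2,
                        radii=tiny_cfg.sample_radii(), config=tiny_cfg)
        sur = extract_center_phase(ks, spokes)
        assert sur.value[5] == 0.0

    def test_intensity_scale_invariance(self, tiny_run):
        ks = tiny_run["kspace"]
        spokes = tiny_run["spokes"]
        scaled = KSpaceData(samples=3.7 * ks.samples, gap=ks.gap,
                            radii=ks.radii, config=ks.config)
        a = extract_center_phase(ks, spokes).value
        b = extract_center_phase(scaled, spokes).value
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_translation_phase_oracle(self):
        """Bulk z-shift changes the center phase by -2*pi*k1*(d.z)*dz/FOV."""
        cfg = AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                           n_volumes=2, spokes_per_volume=100)
        phantom = default_phantom(cfg).with_(resp_shift_mm=0.0,
                                             resp_phase_rad=0.0, noise_sd=0.0)
        spokes = build_spoke_table(cfg)
        physio = simulate_physiology(cfg.duration + 2, seed=0)
        ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
        dz = 2 * cfg.voxel_size
        shifted = KSpaceData(
            samples=ks.samples * np.exp(
                -2j * np.pi * (spokes.directions[:, 2:3] * ks.radii[None, :])
                * dz / cfg.fov),
            gap=ks.gap, radii=ks.radii, config=cfg)
        p0 = extract_center_phase(ks, spokes).value
        p1 = extract_center_phase(shifted, spokes).value
        k1 = ks.radii[0]
        expect = -2 * np.pi * k1 * spokes.directions[:, 2] * dz / cfg.fov
        dphi = np.angle(np.exp(1j * (p1 - p0 - expect)))
        assert np.max(np.abs(dphi)) < 1e-3


class TestBiasRemoval:
    def test_static_object_residual_noise_only(self):
        cfg = AcquisitionConfig.desk_scale(matrix_size=12, readout_samples=8,
                                           n_volumes=80, spokes_per_volume=100)
        phantom = default_phantom(cfg).with_(resp_shift_mm=0.0,
                                             resp_phase_rad=0.0,
                                             noise_sd=0.001)
        phantom = phantom.replace_compartment("artery_early", cardiac_amp=0.0)
        phantom = phantom.replace_compartment("artery_late", cardiac_amp=0.0)
        phantom = phantom.replace_compartment("cortex", cardiac_amp=0.0)
        spokes = build_spoke_table(cfg)
        physio = simulate_physiology(cfg.duration + 2, seed=0)
        ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
        raw = extract_center_phase(ks, spokes)
        out = remove_direction_bias(raw, spokes)
        assert np.sqrt(np.mean(out.value ** 2)) < 0.02

    def test_constant_offset_absorbed(self, tiny_run):
        raw = extract_center_phase(tiny_run["kspace"], tiny_run["spokes"])
        shifted = SurrogateSeries(value=raw.value + 0.3,
                                  timestamps=raw.timestamps, stage="raw")
        a = remove_direction_bias(raw, tiny_run["spokes"]).value
        b = remove_direction_bias(shifted, tiny_run["spokes"]).value
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_slow_modulation_preserved(self):
        """A 0.8 Hz phase modulation passes the 40-volume sliding template
        with <10% amplitude loss (window cut-off is far below 0.8 Hz)."""
        # full-scale volume TR (0.545 s) so the 40-volume window spans ~22 s
        cfg = AcquisitionConfig.desk_scale(matrix_size=12, readout_samples=8,
                                           n_volumes=200, spokes_per_volume=100,
                                           spoke_tr=5.45e-3)
        spokes = build_spoke_table(cfg)
        rng = np.random.default_rng(0)
        bias = rng.uniform(-np.pi / 2, np.pi / 2, cfg.spokes_per_volume)
        mod = 0.2 * np.sin(2 * np.pi * 0.8 * spokes.timestamps)
        raw = SurrogateSeries(value=np.tile(bias, cfg.n_volumes) + mod,
                              timestamps=spokes.timestamps, stage="raw")
        out = remove_direction_bias(raw, spokes).value
        # least-squares amplitude of the recovered 0.8 Hz sinusoid
        ref = np.sin(2 * np.pi * 0.8 * spokes.timestamps)
        amp = 2 * (out @ ref) / ref.size / 0.2
        assert amp > 0.90

    def test_oversized_window_clipped(self, tiny_run, caplog):
        raw = extract_center_phase(tiny_run["kspace"], tiny_run["spokes"])
        out = remove_direction_bias(raw, tiny_run["spokes"],
                                    window_volumes=10_000)
        assert np.all(np.isfinite(out.value))


class TestFiltering:
    def _series(self, values, dt=280e-6):
        return SurrogateSeries(value=values,
                               timestamps=np.arange(values.size) * dt,
                               stage="bias-removed")

    def test_white_noise_variance_reduction(self):
        rng = np.random.default_rng(1)
        x = self._series(rng.standard_normal(40000))
        y = respiratory_waveform(x)
        nyq = 1 / 280e-6 / 2
        assert np.var(x.value) / np.var(y.value) >= (nyq / 10.0) / 2

    def test_passband_amplitude_preserved(self):
        t = np.arange(40000) * 280e-6
        x = self._series(np.sin(2 * np.pi * 0.8 * t))
        y = respiratory_waveform(x)
        assert np.max(np.abs(y.value)) == pytest.approx(1.0, rel=0.02)

    def test_50hz_attenuated(self):
        t = np.arange(40000) * 280e-6
        x = self._series(np.sin(2 * np.pi * 50.0 * t))
        y = respiratory_waveform(x)
        mid = slice(5000, 35000)
        att = 20 * np.log10(np.max(np.abs(y.value[mid])))
        assert att <= -40


class TestRespPeaks:
    def test_rate_and_cv_recovery(self, resp_run):
        ev = respiratory_events_from_kspace(resp_run["kspace"],
                                            resp_run["spokes"])
        truth = resp_run["physio"].resp_peak_times
        truth = truth[truth <= resp_run["config"].duration]
        det_rate = 60 / np.mean(np.diff(ev.event_times))
        true_rate = 60 / np.mean(np.diff(truth))
        assert abs(det_rate - true_rate) / true_rate < 0.01
        tcv = np.std(np.diff(truth), ddof=1) / np.mean(np.diff(truth))
        dcv = (np.std(np.diff(ev.event_times), ddof=1)
               / np.mean(np.diff(ev.event_times)))
        assert dcv == pytest.approx(tcv, abs=0.015)

    def test_constant_series_rejected(self, tiny_run):
        flat = SurrogateSeries(value=np.zeros(len(tiny_run["spokes"])),
                               timestamps=tiny_run["spokes"].timestamps,
                               stage="filtered")
        with pytest.raises(ValueError):
            detect_resp_peaks(flat, tiny_run["spokes"])

    def test_events_carry_spoke_coordinates(self, resp_run):
        ev = respiratory_events_from_kspace(resp_run["kspace"],
                                            resp_run["spokes"])
        assert ev.source == "kspace"
        ts = resp_run["spokes"].timestamps
        np.testing.assert_allclose(ts[ev.event_spoke], ev.event_times)
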