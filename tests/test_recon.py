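"""NUFFT operator, density compensation, center completion, FISTA recon."""

import numpy as np
import pytest

from ztepulse.binning import GatingConfig, assign_bins, segment_cycles
from ztepulse.ecg import CycleEvents
from ztepulse.geometry import AcquisitionConfig, build_spoke_table
from ztepulse.nufft import Nufft3
from ztepulse.pulsation import roi_waveform
from ztepulse.recon import (ReconConfig, complete_center, density_weights,
                            reconstruct_series, reconstruct_volume)
from ztepulse.simulate import (cardiac_waveform, default_phantom,
                               sample_kspace, simulate_physiology)

from conftest import brute_force_dft


class TestNufftOperator:
    def test_adjoint_identity(self):
        """<A x, y> == <x, A^H y> to near machine precision on 8^3."""
        rng = np.random.default_rng(0)
        n, m = 8, 150
        k = rng.uniform(-n / 2 + 0.5, n / 2 - 0.5, (m, 3))
        op = Nufft3(k, n)
        x = rng.standard_normal((n, n, n)) + 1j * rng.standard_normal((n, n, n))
        y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        lhs = np.vdot(op.forward(x), y)
        rhs = np.vdot(x, op.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-6

    def test_forward_matches_brute_force(self):
        rng = np.random.default_rng(1)
        n, m = 8, 60
        k = rng.uniform(-n / 2 + 0.5, n / 2 - 0.5, (m, 3))
        img = np.zeros((n, n, n))
        img[2:6, 3:6, 2:5] = rng.uniform(0.5, 1.5, (4, 3, 3))
        got = Nufft3(k, n).forward(img)
        expect = brute_force_dft(img, k)
        assert np.linalg.norm(got - expect) / np.linalg.norm(expect) < 1e-3

    def test_linearity(self):
        rng = np.random.default_rng(2)
        n, m = 8, 40
        op = Nufft3(rng.uniform(-3, 3, (m, 3)), n)
        y = rng.standard_normal(m) + 1j * rng.standard_normal(m)
        np.testing.assert_allclose(op.adjoint(2.0 * y), 2.0 * op.adjoint(y),
                                   rtol=1e-12)


class TestDensityWeights:
    def test_r_squared_law(self):
        w = density_weights(np.array([1.0, 2.0]), delta_k=1.0)
        assert w[1] / w[0] == pytest.approx(4.0)

    def test_equal_radii_equal_weights(self):
        w = density_weights(np.full(7, 2.5), delta_k=1.0)
        np.testing.assert_allclose(w, 1 / 7)

    def test_normalization_and_center(self):
        w = density_weights(np.array([0.0, 1.0, 2.0, 3.0]), delta_k=1.0)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert w[0] > 0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            density_weights(np.array([]))


@pytest.fixture(scope="module")
def recon_setup():
    cfg = AcquisitionConfig(matrix_size=16, readout_samples=10,
                            dead_time_gap=2, spokes_per_volume=600,
                            n_volumes=1)
    phantom = default_phantom(cfg).with_(noise_sd=0.0, resp_shift_mm=0.0,
                                         resp_phase_rad=0.0)
    for name in ("artery_early", "artery_late", "cortex"):
        phantom = phantom.replace_compartment(name, cardiac_amp=0.0)
    spokes = build_spoke_table(cfg)
    physio = simulate_physiology(cfg.duration + 2, seed=0)
    ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
    return cfg, phantom, spokes, ks


class TestReconstructVolume:
    def test_zero_data_zero_image(self, recon_setup):
        cfg, _, spokes, ks = recon_setup
        img = reconstruct_volume(np.zeros_like(ks.samples), spokes.directions,
                                 ks.radii, cfg)
        assert np.all(img == 0)

    def test_static_phantom_recovered(self, recon_setup):
        """Fully-sampled (no dead-time gap) static 16^3 phantom, 600 spokes."""
        _, phantom0, _, _ = recon_setup
        cfg = AcquisitionConfig(matrix_size=16, readout_samples=12,
                                dead_time_gap=0, spokes_per_volume=600,
                                n_volumes=1)
        phantom = default_phantom(cfg).with_(noise_sd=0.0, resp_shift_mm=0.0,
                                             resp_phase_rad=0.0)
        for name in ("artery_early", "artery_late", "cortex"):
            phantom = phantom.replace_compartment(name, cardiac_amp=0.0)
        spokes = build_spoke_table(cfg)
        physio = simulate_physiology(cfg.duration + 2, seed=0)
        ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
        img = reconstruct_volume(ks.samples, spokes.directions, ks.radii, cfg,
                                 ReconConfig(center_completion="off"))
        gt = phantom.ground_truth_image(cfg)
        r = np.corrcoef(img.ravel(), gt.ravel())[0, 1]
        assert r >= 0.95

    def test_objective_non_increasing(self, recon_setup):
        cfg, _, spokes, ks = recon_setup
        hist = []
        reconstruct_volume(ks.samples, spokes.directions, ks.radii, cfg,
                           ReconConfig(center_completion="off"),
                           objective_history=hist)
        assert len(hist) == 4                  # init + 3 iterations
        assert all(b <= a + 1e-9 * abs(a) for a, b in zip(hist, hist[1:]))


class TestCenterCompletion:
    def test_gap_zero_identity(self, recon_setup):
        cfg, _, spokes, ks = recon_setup
        cfg0 = cfg.with_(dead_time_gap=0, readout_samples=12)
        samples = np.pad(ks.samples, ((0, 0), (2, 0)))
        full, radii = complete_center(samples, spokes.directions, cfg0,
                                      ReconConfig())
        np.testing.assert_array_equal(full, samples)

    def test_measured_samples_bit_identical(self, recon_setup):
        cfg, _, spokes, ks = recon_setup
        full, _ = complete_center(ks.samples, spokes.directions, cfg,
                                  ReconConfig())
        assert np.array_equal(full[:, cfg.dead_time_gap:], ks.samples)

    def test_completion_beats_zero_filling(self, recon_setup):
        cfg, phantom, spokes, ks = recon_setup
        gt = phantom.ground_truth_image(cfg)
        radii_full = np.arange(cfg.n_radial_slots) * cfg.delta_k
        off = ReconConfig(center_completion="off")

        def nrmse(img):
            s = np.sum(img * gt) / np.sum(img * img)
            return np.linalg.norm(s * img - gt) / np.linalg.norm(gt)

        zf = np.zeros((len(spokes), cfg.n_radial_slots), dtype=complex)
        zf[:, cfg.dead_time_gap:] = ks.samples
        img_zf = reconstruct_volume(zf, spokes.directions, radii_full, cfg, off)
        full, radii = complete_center(ks.samples, spokes.directions, cfg,
                                      ReconConfig())
        img_cc = reconstruct_volume(full, spokes.directions, radii, cfg, off)
        assert nrmse(img_cc) < nrmse(img_zf)

    def test_poor_coverage_rejected(self, recon_setup):
        cfg, _, spokes, ks = recon_setup
        few = slice(0, 8)
        with pytest.raises(ValueError, match="coverage"):
            complete_center(ks.samples[few], spokes.directions[few], cfg,
                            ReconConfig())


class TestReconstructSeries:
    def test_gated_series_frames_and_waveform(self, small_gated):
        series = small_gated["series"]
        assert series.n_frames == 40
        assert series.frame_duration == pytest.approx(
            small_gated["assignment"].mean_bin_duration)
        wf = roi_waveform(series, small_gated["phantom"].roi_mask(
            "artery_early", small_gated["config"]))
        inj = cardiac_waveform((np.arange(40) % 20 + 0.5) / 20, 0.15)
        assert np.corrcoef(wf.values, inj)[0, 1] >= 0.9

    def test_peak_ordering_early_before_late(self, small_gated):
        series = small_gated["series"]
        cfg = small_gated["config"]
        phantom = small_gated["phantom"]
        early = roi_waveform(series, phantom.roi_mask("artery_early", cfg))
        late = roi_waveform(series, phantom.roi_mask("artery_late", cfg))
        assert (np.argmax(early.values) % 20) < (np.argmax(late.values) % 20)

    def test_standard_mode_frame_count(self):
        cfg = AcquisitionConfig.desk_scale(matrix_size=12, readout_samples=8,
                                           n_volumes=3, spokes_per_volume=300)
        phantom = default_phantom(cfg)
        spokes = build_spoke_table(cfg)
        physio = simulate_physiology(cfg.duration + 2, seed=0)
        ks = sample_kspace(phantom, spokes, physio, cfg, seed=0)
        series = reconstruct_series(ks, spokes, None, cfg, ReconConfig(),
                                    mode="standard")
        assert series.n_frames == 3
        assert series.frame_duration == pytest.approx(cfg.volume_tr)

    def test_empty_bin_raises(self, small_gated):
        cfg = small_gated["config"]
        g = GatingConfig()
        # only one cycle's worth of events -> the odd-population bins empty
        ev = CycleEvents(
            event_times=small_gated["physio"].r_peak_times[:2], source="ecg")
        asg = assign_bins(small_gated["spokes"], segment_cycles(ev, g), g)
        with pytest.raises(ValueError, match="bin"):
            reconstruct_series(small_gated["kspace"], small_gated["spokes"],
                               asg, cfg, ReconConfig())

    def test_full_scale_standard_resolution_printed(self):
        assert AcquisitionConfig().volume_tr == pytest.approx(0.54516)
        assert round(AcquisitionConfig().volume_tr, 2) == 0.55
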