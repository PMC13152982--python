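"""Shared fixtures: reduced-size synthetic acquisitions reused across tests."""

import numpy as np
import pytest

from ztepulse.geometry import AcquisitionConfig, build_spoke_table
from ztepulse.simulate import (default_phantom, sample_kspace,
                               simulate_physiology, simulate_run)


@pytest.fixture(scope="session")
def tiny_cfg():
    """Smallest config with a workable ECG chain (~3.4 s acquisition)."""
    return AcquisitionConfig.desk_scale(matrix_size=12, readout_samples=8,
                                        n_volumes=80, spokes_per_volume=150)


@pytest.fixture(scope="session")
def tiny_run(tiny_cfg):
    return simulate_run(tiny_cfg, seed=5)


@pytest.fixture(scope="session")
def small_cfg():
    """16^3 acquisition long enough for gated reconstruction tests (~3.4 s)."""
    return AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                        n_volumes=60, spokes_per_volume=200)


@pytest.fixture(scope="session")
def small_gated(small_cfg):
    """Cardiac-gated 40-bin series reconstructed from ground-truth R events."""
    from ztepulse import binning
    from ztepulse.ecg import CycleEvents
    from ztepulse.recon import ReconConfig, reconstruct_series

    phantom = default_phantom(small_cfg)
    spokes = build_spoke_table(small_cfg)
    physio = simulate_physiology(small_cfg.duration + 2.0, seed=3)
    kspace = sample_kspace(phantom, spokes, physio, small_cfg, seed=3)
    events = CycleEvents(event_times=physio.r_peak_times, source="ecg")
    gating = binning.GatingConfig()
    cycles = binning.segment_cycles(events, gating)
    assignment = binning.assign_bins(spokes, cycles, gating)
    series = reconstruct_series(kspace, spokes, assignment, small_cfg,
                                ReconConfig(), mode="cardiac_gated")
    return dict(config=small_cfg, phantom=phantom, spokes=spokes,
                physio=physio, kspace=kspace, events=events, gating=gating,
                assignment=assignment, series=series)


@pytest.fixture(scope="session")
def resp_cfg():
    """Longer run (~14 s) holding enough respiratory cycles for self-gating."""
    return AcquisitionConfig.desk_scale(matrix_size=16, readout_samples=10,
                                        n_volumes=250, spokes_per_volume=200)


@pytest.fixture(scope="session")
def resp_run(resp_cfg):
    phantom = default_phantom(resp_cfg)
    spokes = build_spoke_table(resp_cfg)
    physio = simulate_physiology(resp_cfg.duration + 2.0, seed=9)
    kspace = sample_kspace(phantom, spokes, physio, resp_cfg, seed=9)
    return dict(config=resp_cfg, phantom=phantom, spokes=spokes,
                physio=physio, kspace=kspace)


def brute_force_dft(image: np.ndarray, kpoints: np.ndarray) -> np.ndarray:
    """Independent direct-sum DFT oracle: loops over voxels, no FFT, no NUFFT."""
    n = image.shape[0]
    out = np.zeros(kpoints.shape[0], dtype=complex)
    for a, k in enumerate(kpoints):
        acc = 0.0 + 0.0j
        for i in range(n):
            for j in range(n):
                for l in range(n):
                    v = image[i, j, l]
                    if v == 0:
                        continue
                    x = (i - n / 2) / n
                    y = (j - n / 2) / n
                    z = (l - n / 2) / n
                    acc += v * np.exp(-2j * np.pi * (k[0] * x + k[1] * y + k[2] * z))
        out[a] = acc
    return out
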