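"""Respiratory self-gating from the k-space center phase.

The ZTE acquisition revisits the k-space center every 280 us, and a bulk
respiratory displacement appears — by the Fourier shift theorem — as a
linear phase across k-space.  The phase of the first acquired sample after
the dead-time gap (the highest-SNR point of each spoke) therefore tracks
respiration at the spoke rate.  Each spoke direction carries a static
direction-dependent phase offset; it is removed by subtracting a sliding
40-volume circular-mean template per direction slot, after which the series
is low-pass filtered at 10 Hz, yielding a respiratory waveform from which
breathing peaks are detected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .ecg import CycleEvents
from .geometry import SpokeTable
from .simulate import KSpaceData

log = logging.getLogger(__name__)


@dataclass
class SurrogateSeries:
    """One scalar surrogate value per spoke (phase in rad, or filtered units)."""

    value: np.ndarray
    timestamps: np.ndarray
    stage: str = "raw"            # raw phase | bias-removed | filtered

    def __len__(self) -> int:
        return self.value.size


def extract_center_phase(kspace: KSpaceData, spokes: SpokeTable) -> SurrogateSeries:
    """Phase angle of the first post-gap sample of every spoke."""
    first = kspace.samples[:, 0]
    zero = first == 0
    if np.any(zero):
        log.warning("%d zero-magnitude center samples; phase set to 0",
                    int(np.sum(zero)))
    val = np.where(zero, 0.0, np.angle(first))
    return SurrogateSeries(value=val, timestamps=spokes.timestamps, stage="raw")


def remove_direction_bias(raw: SurrogateSeries, spokes: SpokeTable,
                          window_volumes: int = 40) -> SurrogateSeries:
    """Subtract the sliding per-direction circular-mean phase template.

    Phases are averaged on the unit circle (arithmetic averaging is wrong
    near +/-pi); the output is the circular difference between each spoke's
    phase and its direction's windowed template.
    """
    spv = spokes.config.spokes_per_volume
    nv = raw.value.size // spv
    if nv * spv != raw.value.size:
        raise ValueError("surrogate length is not a whole number of volumes")
    if window_volumes > nv:
        log.warning("bias-removal window (%d volumes) clipped to run length %d",
                    window_volumes, nv)
        window_volumes = nv
    u = np.exp(1j * raw.value.reshape(nv, spv))
    csum = np.cumsum(u, axis=0)
    half = window_volumes // 2
    a = np.clip(np.arange(nv) - half, 0, nv)
    b = np.clip(np.arange(nv) + half + (window_volumes % 2), 0, nv)
    tot = csum[b - 1] - np.where(a[:, None] > 0, csum[np.maximum(a - 1, 0)], 0)
    tpl = tot / (b - a)[:, None]
    mag = np.abs(tpl)
    tpl_unit = np.where(mag > 0, tpl / np.where(mag > 0, mag, 1.0), 1.0)
    out = np.angle(u * np.conj(tpl_unit)).reshape(-1)
    return SurrogateSeries(value=out, timestamps=raw.timestamps,
                           stage="bias-removed")


def respiratory_waveform(biasfree: SurrogateSeries, lowpass_hz: float = 10.0,
                         order: int = 4) -> SurrogateSeries:
    """Zero-phase Butterworth low-pass on the spoke-rate surrogate series.

    Spokes are uniformly spaced at the spoke TR, so treating the series as
    uniformly sampled is exact.
    """
    dt = float(np.median(np.diff(biasfree.timestamps)))
    fs = 1.0 / dt
    sos = sps.butter(order, lowpass_hz / (fs / 2.0), btype="low", output="sos")
    out = sps.sosfiltfilt(sos, biasfree.value)
    return SurrogateSeries(value=out, timestamps=biasfree.timestamps,
                           stage="filtered")


def detect_resp_peaks(filtered: SurrogateSeries, spokes: SpokeTable,
                      min_distance_fraction: float = 0.5,
                      prominence_sds: float = 0.5,
                      invert_surrogate: bool = False) -> CycleEvents:
    """Respiratory peaks (inspiration = surrogate maximum by default).

    On real data the sign of the surrogate depends on the displacement
    direction relative to the gradient axes; ``invert_surrogate`` flips it.
    """
    val = -filtered.value if invert_surrogate else filtered.value
    if np.ptp(val) == 0:
        raise ValueError("constant surrogate series: no respiratory peaks")
    prom = prominence_sds * float(np.std(val))
    peaks, _ = sps.find_peaks(val, prominence=prom)
    if peaks.size == 0:
        raise ValueError("no respiratory peaks found")
    if peaks.size >= 3:
        med_iv = float(np.median(np.diff(peaks)))
        dist = max(1, int(round(min_distance_fraction * med_iv)))
        peaks, _ = sps.find_peaks(val, prominence=prom, distance=dist)
    spv = spokes.config.spokes_per_volume
    return CycleEvents(event_times=filtered.timestamps[peaks], source="kspace",
                       event_spoke=peaks, event_volume=peaks // spv)


def respiratory_events_from_kspace(kspace: KSpaceData, spokes: SpokeTable,
                                   window_volumes: int = 40,
                                   lowpass_hz: float = 10.0,
                                   invert_surrogate: bool = False) -> CycleEvents:
    """Full self-gating chain: center phase -> bias removal -> filter -> peaks."""
    raw = extract_center_phase(kspace, spokes)
    bias = remove_direction_bias(raw, spokes, window_volumes=window_volumes)
    filt = respiratory_waveform(bias, lowpass_hz=lowpass_hz)
    return detect_resp_peaks(filt, spokes, invert_surrogate=invert_surrogate)
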