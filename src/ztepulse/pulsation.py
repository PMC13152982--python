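"""ROI pulsation waveforms and the stability/consistency/robustness metrics.

A pulsation waveform is the mean gated-series intensity over an ROI,
expressed as percent signal change about its temporal mean, one value per
fractional-phase bin.  Waveform shape comparisons (leave-one-out and
cross-condition Pearson correlations) are computed over bin index, i.e. as a
function of fractional cycle phase, so subjects with different absolute
cycle durations remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .binning import BinAssignment, reduce_dataset
from .ecg import CycleEvents
from .geometry import AcquisitionConfig, SpokeTable
from .recon import ReconConfig, VolumeSeries, reconstruct_series
from .simulate import KSpaceData


@dataclass
class Waveform:
    """Percent-signal-change ROI waveform (zero temporal mean by construction)."""

    values: np.ndarray            # one value per bin, percent
    bin_duration: float           # s
    roi: str = ""
    subject: str = ""
    condition: str = ""

    def __len__(self) -> int:
        return self.values.size


@dataclass
class WaveformStats:
    peak_amplitude: float         # max - min, percent
    peak_time: float              # argmax bin * bin duration, s
    peak_bin: int


def roi_waveform(series: VolumeSeries, mask: np.ndarray,
                 cycle_index: int | None = None,
                 n_bins_per_cycle: int | None = None,
                 roi: str = "", subject: str = "", condition: str = "") -> Waveform:
    """Mean-over-mask intensity per frame as percent change about the mean.

    With ``cycle_index`` (and the per-cycle bin count) only that cycle's bins
    of the interleaved gated series are returned; default pools all frames.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    if mask.shape != series.data.shape[:3]:
        raise ValueError("mask dimensions do not match the series")
    ts = series.data[mask].mean(axis=0)
    if cycle_index is not None:
        if n_bins_per_cycle is None:
            raise ValueError("cycle_index requires n_bins_per_cycle")
        a = cycle_index * n_bins_per_cycle
        ts = ts[a:a + n_bins_per_cycle]
    m = ts.mean()
    vals = np.zeros_like(ts) if m == 0 else 100.0 * (ts - m) / m
    return Waveform(values=vals, bin_duration=series.frame_duration,
                    roi=roi, subject=subject, condition=condition)


def peak_metrics(waveform: Waveform) -> WaveformStats:
    """Peak-to-trough amplitude and time of the (first) maximum."""
    v = waveform.values
    if v.size < 2:
        raise ValueError("need at least 2 bins")
    pk = int(np.argmax(v))
    return WaveformStats(peak_amplitude=float(v.max() - v.min()),
                         peak_time=pk * waveform.bin_duration, peak_bin=pk)


def cycle_cv(events: CycleEvents) -> float:
    """Coefficient of variation of successive event intervals (sample SD)."""
    if len(events) < 3:
        raise ValueError("need at least 3 events for a CV")
    iv = events.intervals()
    return float(np.std(iv, ddof=1) / np.mean(iv))


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(a @ b / (na * nb))


def loo_shape_correlation(profiles: list) -> np.ndarray:
    """Leave-one-out consistency: r_i = corr(profile_i, mean of the others).

    Zero-variance profiles give NaN for that subject.
    """
    if len(profiles) < 3:
        raise ValueError("need at least 3 subjects")
    arr = np.array([np.asarray(p.values if isinstance(p, Waveform) else p, dtype=float)
                    for p in profiles])
    if arr.ndim != 2:
        raise ValueError("profiles must share the same bin count")
    out = np.empty(arr.shape[0])
    for i in range(arr.shape[0]):
        rest = np.delete(arr, i, axis=0).mean(axis=0)
        out[i] = _pearson(arr[i], rest)
    return out


def cross_condition_correlation(pairs: list) -> np.ndarray:
    """Within-subject correlation between two condition waveforms per subject."""
    out = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        va = np.asarray(a.values if isinstance(a, Waveform) else a, dtype=float)
        vb = np.asarray(b.values if isinstance(b, Waveform) else b, dtype=float)
        out[i] = _pearson(va, vb)
    return out


def reduction_robustness(kspace: KSpaceData, spokes: SpokeTable,
                         assignment: BinAssignment,
                         roi_masks: dict, config: AcquisitionConfig,
                         fractions=(1.0, 0.5, 0.25, 0.125, 0.0625),
                         recon: ReconConfig = ReconConfig(),
                         mode: str = "cardiac_gated") -> pd.DataFrame:
    """Correlation of reduced-data ROI waveforms with the full-data waveform.

    For each fraction the initial contiguous subset of volumes is rebinned,
    reconstructed, and each ROI waveform Pearson-correlated with its
    full-data counterpart.  Returns a tidy (fraction, roi, r) table; an
    empty bin at some fraction records r as NaN for that fraction.
    """
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    full_series = reconstruct_series(kspace, spokes, assignment, config, recon,
                                     mode=mode)
    full_wf = {name: roi_waveform(full_series, m, roi=name).values
               for name, m in roi_masks.items()}
    rows = []
    for frac in fractions:
        if frac == 1.0:
            wf = full_wf
        else:
            try:
                red = reduce_dataset(assignment, spokes, frac)
                series = reconstruct_series(kspace, spokes, red, config, recon,
                                            mode=mode)
                wf = {name: roi_waveform(series, m, roi=name).values
                      for name, m in roi_masks.items()}
            except ValueError:
                wf = None
        for name in roi_masks:
            r = (1.0 if frac == 1.0 else
                 (_pearson(full_wf[name], wf[name]) if wf is not None
                  else float("nan")))
            rows.append(dict(fraction=frac, roi=name, r=r))
    return pd.DataFrame(rows)
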