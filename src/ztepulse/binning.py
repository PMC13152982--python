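"""Fractional-phase retrospective binning of spokes into cardiac/respiratory bins.

Each physiological cycle (R-R interval, or respiratory peak-to-peak
interval) is divided into ``n_bins_per_cycle`` equal fractional-phase bins,
so a bin is a fixed fraction of the cycle rather than a fixed absolute
duration — beat-to-beat variability is absorbed per cycle.  Two interleaved
cycle populations (even kept cycles -> bins 0..19, odd -> 20..39) yield the
40-bin output series spanning two consecutive cycles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ecg import CycleEvents
from .geometry import SpokeTable

log = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass(frozen=True)
class GatingConfig:
    """Binning parameters.

    min/max_cycle_s gate implausible cycle durations (missed or false
    peaks); when None they default to 0.5x / 1.5x the median cycle.
    """

    n_bins_per_cycle: int = 20
    cycles_per_output: int = 2
    min_cycle_s: float | None = None
    max_cycle_s: float | None = None

    def __post_init__(self):
        if self.n_bins_per_cycle < 2:
            raise ValueError("n_bins_per_cycle must be >= 2")
        if self.cycles_per_output < 1:
            raise ValueError("cycles_per_output must be >= 1")

    @property
    def n_output_bins(self) -> int:
        return self.n_bins_per_cycle * self.cycles_per_output


@dataclass
class BinAssignment:
    """Spoke -> output-bin mapping (UNASSIGNED marks spokes outside cycles)."""

    bin_index: np.ndarray
    n_output_bins: int
    mean_bin_duration: float      # seconds
    n_cycles: int

    def counts(self) -> np.ndarray:
        assigned = self.bin_index[self.bin_index >= 0]
        return np.bincount(assigned, minlength=self.n_output_bins)

    @property
    def n_unassigned(self) -> int:
        return int(np.sum(self.bin_index == UNASSIGNED))


def bin_duration_ms(rate_per_min: float, n_bins: int = 20) -> float:
    """Mean bin duration in ms at a given cycle rate (bpm or breaths/min)."""
    return 60.0 / rate_per_min / n_bins * 1e3


def segment_cycles(events: CycleEvents, gating: GatingConfig) -> list:
    """Consecutive event pairs as (start_s, end_s), duration-gated.

    Cycles outside [min_cycle_s, max_cycle_s] are rejected with a log entry;
    data before the first and after the last event fall outside all cycles.
    """
    t = events.event_times
    if t.size < 2:
        raise ValueError("need at least 2 events to segment cycles")
    dur = np.diff(t)
    med = float(np.median(dur))
    lo = gating.min_cycle_s if gating.min_cycle_s is not None else 0.5 * med
    hi = gating.max_cycle_s if gating.max_cycle_s is not None else 1.5 * med
    keep = (dur >= lo) & (dur <= hi)
    if np.any(~keep):
        log.info("rejected %d/%d cycles outside [%.4g, %.4g] s",
                 int(np.sum(~keep)), dur.size, lo, hi)
    return [(float(t[i]), float(t[i + 1])) for i in np.nonzero(keep)[0]]


def assign_bins(spokes: SpokeTable, cycles: list,
                gating: GatingConfig) -> BinAssignment:
    """Assign every spoke an output bin from its fractional phase.

    Within cycle c (ordinal among kept cycles), phase phi = (t-start)/(end-start),
    within-cycle bin = floor(phi * n_bins) clipped to n_bins-1 (half-open
    bins, right edge clipped), output bin = (c mod cycles_per_output)*n_bins
    + within-cycle bin.
    """
    if not cycles:
        raise ValueError("no valid cycles to bin into")
    starts = np.array([c[0] for c in cycles])
    ends = np.array([c[1] for c in cycles])
    if np.any(starts[1:] < ends[:-1] - 1e-12):
        raise ValueError("cycles must be sorted and non-overlapping")
    t = spokes.timestamps
    nb = gating.n_bins_per_cycle
    ci = np.searchsorted(starts, t, side="right") - 1
    cic = np.clip(ci, 0, len(cycles) - 1)
    inside = (ci >= 0) & (t < ends[cic])
    phi = (t - starts[cic]) / (ends[cic] - starts[cic])
    wbin = np.minimum((phi * nb).astype(int), nb - 1)
    obin = (cic % gating.cycles_per_output) * nb + wbin
    out = np.where(inside, obin, UNASSIGNED)
    mean_cycle = float(np.mean(ends - starts))
    return BinAssignment(bin_index=out, n_output_bins=gating.n_output_bins,
                         mean_bin_duration=mean_cycle / nb,
                         n_cycles=len(cycles))


def reduce_dataset(assignment: BinAssignment, spokes: SpokeTable,
                   fraction: float) -> BinAssignment:
    """Keep only the initial contiguous ``fraction`` of acquired volumes.

    Emulates a shorter scan: spokes with volume_index >= fraction * n_volumes
    become unassigned; the bin structure is unchanged.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    n_volumes = int(spokes.volume_index.max()) + 1
    keep_vols = int(round(fraction * n_volumes))
    keep = spokes.volume_index < keep_vols
    new = np.where(keep, assignment.bin_index, UNASSIGNED)
    if not np.any(new >= 0):
        raise ValueError(f"fraction {fraction} leaves no assigned spokes")
    return BinAssignment(bin_index=new, n_output_bins=assignment.n_output_bins,
                         mean_bin_duration=assignment.mean_bin_duration,
                         n_cycles=assignment.n_cycles)
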