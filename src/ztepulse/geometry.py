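"""Acquisition geometry and timing for 3D center-out radial (ZTE) scans.

A zero-echo-time acquisition reads one radial spoke per excitation, starting
at the k-space center immediately after the RF pulse.  The first
``dead_time_gap`` samples of every spoke are lost to transmit/receive
switching.  Spokes are played back-to-back at a fixed ``spoke_tr``; a fixed
set of ``spokes_per_volume`` directions is repeated identically for every
imaging volume, so any temporal subset of the run samples the same angular
pattern.

k-space convention
------------------
Dimensionless k in cycles per field of view.  Radial sample slot ``m``
(``m = 0 .. gap + readout_samples - 1``) sits at radius ``m * delta_k`` with
the outermost slot on the Nyquist edge ``kmax = matrix_size / 2``, i.e.
``delta_k = kmax / (gap + readout_samples - 1)``.  Image coordinates are in
FOV units, voxel ``j`` at ``(j - n/2) / n``, so the transform kernel is
``exp(-2*pi*i * k . x)`` with no extra scale factors.  Physical k in
cycles/mm is ``k / fov``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class AcquisitionConfig:
    """Parameters of one ZTE functional acquisition.

    Defaults reproduce the full-scale rat protocol: spoke TR 280 us, 1947
    spokes per volume, 4000 volumes, 64^3 matrix over a 35 mm isotropic FOV,
    2x readout oversampling, flip angle ~3 deg (metadata only).
    """

    spoke_tr: float = 280e-6
    spokes_per_volume: int = 1947
    n_volumes: int = 4000
    matrix_size: int = 64
    fov: float = 35.0
    oversampling: int = 2
    dead_time_gap: int = 2
    flip_angle_deg: float = 3.0
    readout_samples: int = 32

    def __post_init__(self) -> None:
        for name in ("spokes_per_volume", "n_volumes", "matrix_size",
                     "oversampling", "readout_samples"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.spoke_tr <= 0:
            raise ValueError("spoke_tr must be positive")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        if self.dead_time_gap < 0:
            raise ValueError("dead_time_gap must be >= 0")
        if not self.dead_time_gap < self.readout_samples + self.dead_time_gap:
            raise ValueError("dead_time_gap inconsistent with readout_samples")

    # --- derived timing -------------------------------------------------
    @property
    def volume_tr(self) -> float:
        """Duration of one imaging volume in seconds."""
        return self.spokes_per_volume * self.spoke_tr

    @property
    def duration(self) -> float:
        """Total acquisition duration in seconds."""
        return self.n_volumes * self.volume_tr

    @property
    def n_spokes_total(self) -> int:
        return self.n_volumes * self.spokes_per_volume

    # --- derived k-space geometry --------------------------------------
    @property
    def n_radial_slots(self) -> int:
        """Radial sample slots per spoke, missing gap slots included."""
        return self.dead_time_gap + self.readout_samples

    @property
    def kmax(self) -> float:
        """Nyquist edge in cycles/FOV."""
        return self.matrix_size / 2.0

    @property
    def delta_k(self) -> float:
        return self.kmax / (self.n_radial_slots - 1)

    @property
    def voxel_size(self) -> float:
        """Isotropic voxel size in mm."""
        return self.fov / self.matrix_size

    def sample_radii(self, include_gap: bool = False) -> np.ndarray:
        """Radii of the radial slots in cycles/FOV.

        By default only the acquired (post-gap) slots are returned.
        """
        r = np.arange(self.n_radial_slots, dtype=float) * self.delta_k
        return r if include_gap else r[self.dead_time_gap:]

    @classmethod
    def desk_scale(cls, **overrides) -> "AcquisitionConfig":
        """Reduced problem size used throughout the test suite and examples.

        32^3 matrix, 16 readout samples, 200 volumes of 400 spokes — the same
        sampling structure as the full protocol at a fraction of the cost.
        """
        base = dict(matrix_size=32, readout_samples=16, n_volumes=200,
                    spokes_per_volume=400)
        base.update(overrides)
        return cls(**base)

    def with_(self, **overrides) -> "AcquisitionConfig":
        return replace(self, **overrides)


@dataclass
class SpokeTable:
    """Geometric/temporal skeleton of the acquisition: one row per spoke."""

    directions: np.ndarray      # (N, 3) unit vectors
    timestamps: np.ndarray      # (N,) seconds from acquisition start
    volume_index: np.ndarray    # (N,) int
    spoke_in_volume: np.ndarray  # (N,) int
    direction_id: np.ndarray    # (N,) int, equals spoke_in_volume
    config: AcquisitionConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return self.directions.shape[0]

    def validate(self) -> None:
        norms = np.linalg.norm(self.directions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("spoke directions must be unit vectors")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")


def spherical_fibonacci(n: int) -> np.ndarray:
    """Near-uniform point set on the unit sphere (spherical Fibonacci lattice)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = GOLDEN_ANGLE * i
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _coprime_stride(n: int) -> int:
    """Stride near n/phi^2 that is coprime to n (full-cycle traversal)."""
    target = max(1, round(n * 0.381966))
    for d in range(n):
        for s in (target + d, target - d):
            if 1 <= s < n and math.gcd(s, n) == 1:
                return s
    return 1


def generate_spoke_directions(config: AcquisitionConfig,
                              scheme: str = "uniform-interleaved") -> np.ndarray:
    """Direction set of one volume, (spokes_per_volume, 3).

    The "uniform-interleaved" scheme traverses a spherical-Fibonacci lattice
    with a stride coprime to the count, so temporally adjacent spokes are
    angularly dispersed and any contiguous temporal subset still covers the
    sphere quasi-uniformly — the property retrospective binning relies on.
    """
    if scheme != "uniform-interleaved":
        raise ValueError(f"unknown spoke-ordering scheme {scheme!r}")
    n = config.spokes_per_volume
    if n < 2:
        raise ValueError("spokes_per_volume must be >= 2")
    pts = spherical_fibonacci(n)
    order = (np.arange(n) * _coprime_stride(n)) % n
    return pts[order]


def build_spoke_table(config: AcquisitionConfig,
                      scheme: str = "uniform-interleaved") -> SpokeTable:
    """Full spoke table for the whole acquisition (directions + timestamps)."""
    dirs_vol = generate_spoke_directions(config, scheme)
    n_total = config.n_spokes_total
    g = np.arange(n_total)
    tab = SpokeTable(
        directions=np.tile(dirs_vol, (config.n_volumes, 1)),
        timestamps=g * config.spoke_tr,
        volume_index=g // config.spokes_per_volume,
        spoke_in_volume=g % config.spokes_per_volume,
        direction_id=g % config.spokes_per_volume,
        config=config,
    )
    return tab


def spoke_timestamps(config: AcquisitionConfig) -> np.ndarray:
    """Timestamps of all spokes: global spoke g starts at g * spoke_tr."""
    return np.arange(config.n_spokes_total) * config.spoke_tr


def max_nn_gap(directions: np.ndarray) -> float:
    """Maximum over points of the angle (rad) to its nearest neighbour."""
    d = np.asarray(directions, dtype=float)
    m = d.shape[0]
    if m < 2:
        raise ValueError("need at least two directions")
    dots = np.clip(d @ d.T, -1.0, 1.0)
    np.fill_diagonal(dots, -1.0)
    return float(np.max(np.arccos(np.max(dots, axis=1))))


def ideal_spacing(n: int) -> float:
    """Angular spacing (rad) of a perfectly uniform n-point sphere covering."""
    return math.sqrt(4.0 * math.pi / n)


def coverage_ok(directions: np.ndarray, factor: float = 8.0,
                max_gap_rad: float = math.pi / 3) -> bool:
    """Check the angular coverage of a direction subset.

    True when the maximum nearest-neighbour gap is below ``factor`` times the
    ideal uniform spacing for the subset size and below an absolute cap
    (the relative bound is vacuous for very small subsets); gated
    reconstructions refuse to run on subsets that fail this.
    """
    uniq = np.unique(np.asarray(directions, dtype=float), axis=0)
    if uniq.shape[0] < 4:
        return False
    gap = max_nn_gap(uniq)
    return gap < factor * ideal_spacing(uniq.shape[0]) and gap < max_gap_rad
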