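"""Synthetic pulsatile ZTE acquisition: digital phantom, physiology, k-space, ECG.

The phantom is a set of rigid compartments (ellipsoids / z-axis cylinders in
mm).  In a ZTE inflow-contrast experiment, systolic arterial wall expansion
lets unsaturated spins flow into the voxel and raises the signal; the
simulator models this as a multiplicative cardiac modulation of each
compartment's intensity, with a vessel-specific delay within the cardiac
cycle (early vs late arteries mimic pulse-wave propagation).  Respiration
contributes a small intensity modulation plus a bulk translation of the
whole object; by the Fourier shift theorem the translation appears as a
linear phase across k-space, which is exactly what the k-space self-gating
module later reads back out.

Because compartments are rigid and only their amplitudes and a bulk shift
vary in time, each compartment's k-space transform is evaluated once (exact
non-uniform DFT over its nonzero voxels) at the per-volume sample positions
and reused for the whole run with per-spoke scalar weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .geometry import AcquisitionConfig, SpokeTable

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Compartment:
    """One rigid phantom compartment.

    cardiac_amp / resp_amp are fractional intensity modulations; cardiac_delay
    is the fraction of the cardiac cycle at which the compartment peaks.
    fluct_amp adds a slow band-limited "neural" fluctuation whose correlation
    with the shared group signal is fluct_coupling (connectivity ground truth).
    """

    name: str
    shape: str                      # "ellipsoid" | "cylinder"
    center_mm: tuple
    radii_mm: tuple                 # ellipsoid semi-axes; cylinder (r, r, half-length)
    baseline: float = 1.0
    cardiac_amp: float = 0.0
    cardiac_delay: float = 0.0
    cardiac_width: float = 0.4
    resp_amp: float = 0.0
    fluct_amp: float = 0.0
    fluct_coupling: float = 0.0

    def mask(self, config: AcquisitionConfig) -> np.ndarray:
        n = config.matrix_size
        c = (np.arange(n) - n / 2.0) / n * config.fov
        x, y, z = np.meshgrid(c, c, c, indexing="ij")
        dx = x - self.center_mm[0]
        dy = y - self.center_mm[1]
        dz = z - self.center_mm[2]
        rx, ry, rz = self.radii_mm
        if self.shape == "ellipsoid":
            return (dx / rx) ** 2 + (dy / ry) ** 2 + (dz / rz) ** 2 <= 1.0
        if self.shape == "cylinder":
            return ((dx / rx) ** 2 + (dy / ry) ** 2 <= 1.0) & (np.abs(dz) <= rz)
        raise ValueError(f"unknown compartment shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    """Digital phantom: compartments + respiratory bulk motion + noise level.

    resp_shift_mm is the peak bulk translation along resp_axis; noise_sd is the
    complex-noise standard deviation relative to the DC (k=0) signal.
    resp_phase_rad is the peak of a direction-independent global phase
    modulation (respiratory B0 shift from chest motion) — the carrier the
    k-space self-gating surrogate actually reads, since the translation term
    -2*pi*k.Delta changes sign with the spoke direction and averages out.
    """

    compartments: tuple
    resp_shift_mm: float = 0.3
    resp_axis: tuple = (0.0, 0.0, 1.0)
    resp_phase_rad: float = 0.1
    noise_sd: float = 0.003

    def with_(self, **overrides) -> "PhantomSpec":
        return replace(self, **overrides)

    def replace_compartment(self, name: str, **overrides) -> "PhantomSpec":
        comps = tuple(replace(c, **overrides) if c.name == name else c
                      for c in self.compartments)
        return replace(self, compartments=comps)

    def ground_truth_image(self, config: AcquisitionConfig) -> np.ndarray:
        img = np.zeros((config.matrix_size,) * 3)
        for c in self.compartments:
            img += c.baseline * c.mask(config)
        return img

    def label_volume(self, config: AcquisitionConfig) -> np.ndarray:
        """Integer ROI labels (1-based, later compartments overwrite earlier)."""
        lab = np.zeros((config.matrix_size,) * 3, dtype=np.int16)
        for i, c in enumerate(self.compartments, start=1):
            lab[c.mask(config)] = i
        return lab

    def roi_mask(self, name: str, config: AcquisitionConfig) -> np.ndarray:
        lab = self.label_volume(config)
        for i, c in enumerate(self.compartments, start=1):
            if c.name == name:
                return lab == i
        raise KeyError(name)


def default_phantom(config: AcquisitionConfig) -> PhantomSpec:
    """Default pulsatile phantom scaled to the FOV.

    Static tissue, an early artery (cycle delay 0.15) and a late artery
    (0.35) mimicking the earlier internal-carotid vs later pterygopalatine
    pulsation peak, and weakly pulsatile cortex.
    """
    f = config.fov
    comps = (
        Compartment("tissue", "ellipsoid", (0, 0, 0),
                    (0.42 * f, 0.42 * f, 0.34 * f),
                    baseline=1.0, resp_amp=0.01),
        Compartment("artery_early", "cylinder", (-0.18 * f, 0, 0),
                    (0.08 * f, 0.08 * f, 0.28 * f),
                    baseline=1.5, cardiac_amp=0.15, cardiac_delay=0.15,
                    resp_amp=0.02),
        Compartment("artery_late", "cylinder", (0.18 * f, 0, 0),
                    (0.08 * f, 0.08 * f, 0.28 * f),
                    baseline=1.5, cardiac_amp=0.15, cardiac_delay=0.35,
                    resp_amp=0.02),
        Compartment("cortex", "ellipsoid", (0, 0.22 * f, 0),
                    (0.14 * f, 0.12 * f, 0.14 * f),
                    baseline=1.0, cardiac_amp=0.02, cardiac_delay=0.25),
    )
    return PhantomSpec(compartments=comps)


# ---------------------------------------------------------------------------
# physiology
# ---------------------------------------------------------------------------

@dataclass
class PhysioTrace:
    """Ground-truth physiological event trains."""

    r_peak_times: np.ndarray
    resp_peak_times: np.ndarray
    heart_rate: float = float("nan")      # bpm
    hr_jitter_cv: float = float("nan")
    resp_rate: float = float("nan")       # per minute
    resp_jitter_cv: float = float("nan")


def _event_train(duration: float, rate_per_min: float, jitter_cv: float,
                 rng: np.random.Generator) -> np.ndarray:
    mean_iv = 60.0 / rate_per_min
    times = [0.0]
    while times[-1] <= duration:
        eps = rng.normal(0.0, jitter_cv) if jitter_cv > 0 else 0.0
        iv = mean_iv * max(1.0 + eps, 0.1)
        times.append(times[-1] + iv)
    t = np.array(times)
    return t[t <= duration + 1e-12]


def simulate_physiology(duration: float, heart_rate: float = 342.1,
                        hr_jitter_cv: float = 0.022, resp_rate: float = 47.3,
                        resp_jitter_cv: float = 0.076,
                        seed: int = 0) -> PhysioTrace:
    """Jittered cardiac and respiratory event trains covering ``duration``.

    Successive intervals are i.i.d. (60/rate)*(1+eps), eps ~ N(0, jitter_cv),
    truncated positive.  Defaults emulate isoflurane-anesthesia rat rates
    (heart ~342 bpm CV 2.2%, breathing ~47 /min CV 7.6%).
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if heart_rate <= 0 or resp_rate <= 0:
        raise ValueError("rates must be positive")
    if not (0 <= hr_jitter_cv < 0.5 and 0 <= resp_jitter_cv < 0.5):
        raise ValueError("jitter CV must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    return PhysioTrace(
        r_peak_times=_event_train(duration, heart_rate, hr_jitter_cv, rng),
        resp_peak_times=_event_train(duration, resp_rate, resp_jitter_cv, rng),
        heart_rate=heart_rate, hr_jitter_cv=hr_jitter_cv,
        resp_rate=resp_rate, resp_jitter_cv=resp_jitter_cv,
    )


def cardiac_waveform(phase, delay: float, width: float = 0.4):
    """Raised-cosine pulse on the circle: 1 at phase==delay, 0 outside width/2."""
    if not 0 < width <= 1:
        raise ValueError("width must be in (0, 1]")
    phase = np.asarray(phase, dtype=float)
    d = np.abs((phase - delay) % 1.0)
    d = np.minimum(d, 1.0 - d)
    out = np.where(d < width / 2.0, 0.5 * (1.0 + np.cos(2.0 * np.pi * d / width)), 0.0)
    return out if out.ndim else float(out)


def resp_waveform(phase):
    """Squared raised cosine peaking at phase 0 (narrowed inspiration peak)."""
    phase = np.asarray(phase, dtype=float) % 1.0
    out = (0.5 * (1.0 + np.cos(2.0 * np.pi * phase))) ** 2
    return out if out.ndim else float(out)


def cycle_phase(times: np.ndarray, events: np.ndarray) -> np.ndarray:
    """Fractional phase in [0,1) of each time within its enclosing cycle.

    Times before the first / after the last event use the adjacent interval
    extended outward.
    """
    e = np.asarray(events, dtype=float)
    if e.size < 2:
        raise ValueError("need at least two events to define a phase")
    ext = np.concatenate([[e[0] - (e[1] - e[0])], e, [e[-1] + (e[-1] - e[-2])]])
    idx = np.clip(np.searchsorted(ext, times, side="right") - 1, 0, ext.size - 2)
    ph = (np.asarray(times) - ext[idx]) / (ext[idx + 1] - ext[idx])
    return np.clip(ph, 0.0, 1.0 - 1e-12)


# ---------------------------------------------------------------------------
# k-space sampling
# ---------------------------------------------------------------------------

@dataclass
class KSpaceData:
    """Complex readout samples per spoke for the acquired (post-gap) slots."""

    samples: np.ndarray           # (n_spokes, readout_samples) complex
    gap: int
    radii: np.ndarray             # (readout_samples,) cycles/FOV, post-gap
    config: AcquisitionConfig = field(repr=False, default=None)

    def __post_init__(self):
        if self.samples.ndim != 2:
            raise ValueError("samples must be (n_spokes, readout)")


def nudft3(values: np.ndarray, coords: np.ndarray, kpoints: np.ndarray,
           chunk: int = 512) -> np.ndarray:
    """Exact type-2 non-uniform DFT: sum_j v_j exp(-2*pi*i k.x_j), chunked.

    coords in FOV units, kpoints in cycles/FOV.
    """
    out = np.empty(kpoints.shape[0], dtype=complex)
    ct = coords.T  # (3, N)
    for a in range(0, kpoints.shape[0], chunk):
        ph = kpoints[a:a + chunk] @ ct
        out[a:a + chunk] = np.exp(-2j * np.pi * ph) @ values
    return out


def compartment_spectra(phantom: PhantomSpec, spoke_dirs: np.ndarray,
                        radii: np.ndarray, config: AcquisitionConfig) -> np.ndarray:
    """F_c(k) of each unit-intensity compartment at (spoke_in_volume, slot).

    Returns (n_compartments, spokes_per_volume, n_slots) complex.
    """
    n = config.matrix_size
    kpts = (spoke_dirs[:, None, :] * radii[None, :, None]).reshape(-1, 3)
    grid = (np.arange(n) - n / 2.0) / n
    out = np.empty((len(phantom.compartments), spoke_dirs.shape[0], radii.size),
                   dtype=complex)
    for ci, comp in enumerate(phantom.compartments):
        m = comp.mask(config)
        ij = np.argwhere(m)
        coords = grid[ij]  # (Nvox, 3) FOV units
        vals = np.ones(ij.shape[0])
        out[ci] = nudft3(vals, coords, kpts).reshape(spoke_dirs.shape[0], radii.size)
    return out


def band_limited_noise(n: int, fs: float, band: tuple, rng) -> np.ndarray:
    """Unit-variance noise band-limited to ``band`` Hz (volume-rate series)."""
    x = rng.standard_normal(n)
    lo, hi = band
    nyq = fs / 2.0
    hi = min(hi, 0.95 * nyq)
    if hi <= lo or n < 12:
        return x / (x.std() + 1e-30)
    sos = sps.butter(2, [lo / nyq, hi / nyq], btype="band", output="sos")
    y = sps.sosfiltfilt(sos, x)
    return y / (y.std() + 1e-30)


def compartment_fluctuations(phantom: PhantomSpec, config: AcquisitionConfig,
                             band: tuple, rng) -> np.ndarray:
    """Slow shared/independent fluctuation per compartment at volume rate.

    signal_c = coupling * shared + sqrt(1-coupling^2) * independent, unit SD.
    Returns (n_compartments, n_volumes).
    """
    fs = 1.0 / config.volume_tr
    nv = config.n_volumes
    shared = band_limited_noise(nv, fs, band, rng)
    out = np.empty((len(phantom.compartments), nv))
    for ci, comp in enumerate(phantom.compartments):
        indep = band_limited_noise(nv, fs, band, rng)
        r = float(np.clip(comp.fluct_coupling, -1.0, 1.0))
        out[ci] = r * shared + np.sqrt(1.0 - r * r) * indep
    return out


def sample_kspace(phantom: PhantomSpec, spokes: SpokeTable, physio: PhysioTrace,
                  config: AcquisitionConfig, seed: int = 0,
                  fluct_band: tuple = (0.01, 0.1),
                  include_gap: bool = False) -> KSpaceData:
    """Simulate complex k-space samples along the spoke table.

    S(k, t) = exp(-2*pi*i k . D(t)) * sum_c m_c(t) F_c(k) + noise, with the
    modulation held constant within one spoke readout (<=280 us versus a
    >=160 ms cardiac cycle).  Gap samples are dropped unless ``include_gap``
    (used only for oracle tests with gap=0 semantics).
    """
    t = spokes.timestamps
    if physio.r_peak_times[-1] < t[-1] - 1e-9 or physio.resp_peak_times[-1] < t[-1] - 1e-9:
        raise ValueError("physiological trace shorter than the acquisition")
    rng = np.random.default_rng(seed)
    radii_all = (np.arange(config.n_radial_slots) * config.delta_k)
    dirs_vol = spokes.directions[:config.spokes_per_volume]
    spectra = compartment_spectra(phantom, dirs_vol, radii_all, config)

    cph = cycle_phase(t, physio.r_peak_times)
    rph = cycle_phase(t, physio.resp_peak_times)
    rwave = resp_waveform(rph)

    fluct = None
    if any(c.fluct_amp for c in phantom.compartments):
        fluct = compartment_fluctuations(phantom, config, fluct_band, rng)

    # per-spoke per-compartment weights (n_spokes, n_comp)
    w = np.empty((len(spokes), len(phantom.compartments)))
    for ci, comp in enumerate(phantom.compartments):
        mod = np.ones(len(spokes))
        if comp.cardiac_amp:
            mod = mod + comp.cardiac_amp * cardiac_waveform(
                cph, comp.cardiac_delay, comp.cardiac_width)
        if comp.resp_amp:
            mod = mod + comp.resp_amp * rwave
        if fluct is not None and comp.fluct_amp:
            mod = mod + comp.fluct_amp * fluct[ci][spokes.volume_index]
        w[:, ci] = comp.baseline * mod

    nv, spv = config.n_volumes, config.spokes_per_volume
    # samples[s, m] = sum_c w[s, c] * spectra[c, d_s, m]
    samples = np.einsum("vsc,csm->vsm", w.reshape(nv, spv, -1),
                        spectra, optimize=True).reshape(len(spokes), -1)

    # respiratory B0 shift -> global (direction-independent) phase
    if phantom.resp_phase_rad:
        samples = samples * np.exp(1j * phantom.resp_phase_rad * rwave)[:, None]

    # respiratory bulk shift -> linear phase (Fourier shift theorem)
    if phantom.resp_shift_mm:
        axis = np.asarray(phantom.resp_axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        shift_fov = phantom.resp_shift_mm * rwave / config.fov  # (n_spokes,)
        kz = (spokes.directions @ axis)[:, None] * radii_all[None, :]
        samples = samples * np.exp(-2j * np.pi * kz * shift_fov[:, None])

    if phantom.noise_sd:
        dc = abs(sum(c.baseline * np.count_nonzero(c.mask(config))
                     for c in phantom.compartments))
        sd = phantom.noise_sd * dc / np.sqrt(2.0)
        samples = samples + sd * (rng.standard_normal(samples.shape)
                                  + 1j * rng.standard_normal(samples.shape))

    gap = 0 if include_gap else config.dead_time_gap
    return KSpaceData(samples=samples[:, gap:], gap=gap,
                      radii=radii_all[gap:], config=config)


# ---------------------------------------------------------------------------
# ECG synthesis
# ---------------------------------------------------------------------------

@dataclass
class ECGRecording:
    """Single-lead ECG with per-volume MRI trigger times."""

    signal: np.ndarray
    sampling_rate: float          # Hz
    trigger_times: np.ndarray     # (n_volumes,) seconds

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.signal.size) / self.sampling_rate


def _qrs_template(fs: float, sigma: float = 0.004) -> np.ndarray:
    """Mexican-hat QRS complex, unit peak, ~6 sigma support."""
    t = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
    return (1.0 - (t / sigma) ** 2) * np.exp(-t * t / (2 * sigma * sigma))


def _artifact_template(n: int, rng) -> np.ndarray:
    """Volume-periodic gradient-artifact epoch: decaying kHz oscillations.

    Cosine-phased so the artifact starts abruptly at full amplitude, as a
    gradient switch does; the sharp leading edge is what onset refinement
    anchors on.
    """
    t = np.arange(n)
    out = np.zeros(n)
    for _ in range(5):
        f = rng.uniform(0.002, 0.04)          # cycles/sample (160 Hz - 3.2 kHz at 80 kHz)
        tau = rng.uniform(0.1, 0.6) * n
        out += rng.uniform(0.3, 1.0) * np.cos(2 * np.pi * f * t) * np.exp(-t / tau)
    return out / np.max(np.abs(out))


def synthesize_ecg(physio: PhysioTrace, volume_onsets: np.ndarray,
                   config: AcquisitionConfig, artifact_amplitude: float = 5.0,
                   seed: int = 0, sampling_rate: float = 80e3,
                   qrs_amplitude: float = 1.0,
                   line_amplitude: float = 0.3, noise_sd: float = 0.02,
                   wander_amplitude: float = 0.15, drift: float = 0.1,
                   trigger_offset: float = 0.5e-3) -> ECGRecording:
    """Gradient-artifact-contaminated ECG channel.

    signal = QRS train + respiratory baseline wander + volume-periodic
    gradient artifact (amplitude in multiples of the unit QRS peak, with a
    linear ±drift amplitude ramp across the run) + 50 Hz line noise + white
    noise.  Returned trigger times are the true onsets plus a fixed offset,
    so onset refinement has something to correct.
    """
    onsets = np.asarray(volume_onsets, dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("volume onsets must be sorted")
    fs = sampling_rate
    duration = config.duration
    n = int(np.ceil(duration * fs))
    rng = np.random.default_rng(seed)
    sig = np.zeros(n)

    qrs = qrs_amplitude * _qrs_template(fs)
    half = qrs.size // 2
    for rt in physio.r_peak_times:
        i = int(round(rt * fs))
        a, b = i - half, i - half + qrs.size
        qa, qb = max(0, -a), qrs.size - max(0, b - n)
        a, b = max(a, 0), min(b, n)
        if a < b:
            sig[a:b] += qrs[qa:qb]

    t = np.arange(n) / fs
    if wander_amplitude:
        sig += wander_amplitude * resp_waveform(cycle_phase(t, physio.resp_peak_times))

    if artifact_amplitude:
        epoch_len = int(round(config.volume_tr * fs))
        tpl = _artifact_template(epoch_len, rng)
        for v, on in enumerate(onsets):
            amp = artifact_amplitude * (1.0 + drift * (2.0 * v / max(1, len(onsets) - 1) - 1.0))
            i = int(round(on * fs))
            b = min(i + epoch_len, n)
            if i < b:
                sig[i:b] += amp * tpl[:b - i]

    if line_amplitude:
        sig += line_amplitude * np.sin(2 * np.pi * 50.0 * t)
    if noise_sd:
        sig += noise_sd * rng.standard_normal(n)

    return ECGRecording(signal=sig, sampling_rate=fs,
                        trigger_times=onsets + trigger_offset)


def simulate_run(config: AcquisitionConfig, phantom: PhantomSpec | None = None,
                 heart_rate: float = 342.1, hr_jitter_cv: float = 0.022,
                 resp_rate: float = 47.3, resp_jitter_cv: float = 0.076,
                 artifact_amplitude: float = 5.0, seed: int = 0,
                 fluct_band: tuple = (0.01, 0.1)):
    """Simulate one full acquisition (spoke table, k-space, ECG, ground truth).

    Returns a dict bundle shared by the pipeline, container I/O and tests.
    """
    from .geometry import build_spoke_table
    if phantom is None:
        phantom = default_phantom(config)
    spokes = build_spoke_table(config)
    physio = simulate_physiology(config.duration + 2.0, heart_rate, hr_jitter_cv,
                                 resp_rate, resp_jitter_cv, seed=seed)
    kspace = sample_kspace(phantom, spokes, physio, config, seed=seed + 1,
                           fluct_band=fluct_band)
    onsets = np.arange(config.n_volumes) * config.volume_tr
    ecg = synthesize_ecg(physio, onsets, config,
                         artifact_amplitude=artifact_amplitude, seed=seed + 2)
    return dict(config=config, phantom=phantom, spokes=spokes, physio=physio,
                kspace=kspace, ecg=ecg)
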