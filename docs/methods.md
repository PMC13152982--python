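# Methods

## Overview

`ztepulse` implements retrospectively gated pulsation mapping for 3D
center-out radial (zero-echo-time, ZTE) fMRI, together with a synthetic
acquisition simulator that makes the whole chain testable without animal
data.  The pipeline is: (1) recover cardiac timing from a simultaneously
recorded, gradient-artifact-contaminated ECG; (2) recover respiratory timing
from the phase of the k-space center (self-gating); (3) assign every radial
spoke a fractional-phase bin within its physiological cycle; (4) reconstruct
one 3D volume per bin from the pooled spokes with a gridding NUFFT and a few
iterations of monotone FISTA; (5) extract ROI pulsation waveforms and their
stability/consistency statistics, and sliding-window functional connectivity
from the ungated series.

## Acquisition model and conventions

A ZTE acquisition reads one radial spoke per excitation, center-out, at a
fixed spoke TR.  Full-scale defaults follow the rat protocol: spoke TR
280 µs, 1947 spokes per volume, 4000 volumes (36.3 min), 64³ matrix,
35 mm isotropic FOV, 2× readout oversampling, flip angle ≈3° (metadata
only).  The protocol leaves the number of readout points per spoke open; the
default is 32 acquired points after a 2-sample dead-time gap, both
configurable.

k-space is measured in cycles per FOV.  Radial slot *m*
(*m* = 0 … gap+readout−1) sits at radius *m*·Δk with the outermost slot on
the Nyquist edge k_max = matrix/2, i.e. Δk = k_max/(gap+readout−1).  Image
coordinates are FOV fractions with voxel *j* at (j−n/2)/n, so the transform
kernel is exp(−2πi k·x) with no hidden scale factors.

The spoke ordering is a stand-in for the "tennis ball" trajectory family
used in silent ZTE protocols, whose exact ordering is proprietary to the
original implementation: a spherical-Fibonacci point set
traversed with a stride coprime to the count.  This reproduces the property
the gating actually relies on — any temporal subset of spokes covers the
sphere quasi-uniformly (measured: contiguous 1/40 subsets of a 1947-spoke
volume have a maximum nearest-neighbour gap ≈0.4 rad versus an ideal spacing
of 0.51 rad).

## The simulator

The digital phantom is a set of rigid compartments (ellipsoids and z-axis
cylinders in mm): static tissue, an early artery (cardiac delay 0.15 of the
cycle), a late artery (delay 0.35) and weakly pulsatile cortex.  The two
arterial delays mimic pulse-wave propagation (an earlier pulsation peak in
proximal arteries, later in distal ones).  In ZTE the functional contrast is
inflow-driven: systolic wall expansion admits unsaturated spins and raises
the signal, which the simulator models as a multiplicative raised-cosine
modulation of compartment intensity (default amplitude 0.15 of baseline in
arteries; the literature gives no percent figure, so this is a free,
exposed choice).  Cardiac and respiratory event trains have i.i.d. jittered
intervals, (60/rate)(1+ε), ε ~ N(0, CV), defaults 342.1 bpm at CV 0.022 and
47.3 breaths/min at CV 0.076 (isoflurane-anesthesia rat values).

Because compartments are rigid and only amplitudes and a bulk shift vary,
each compartment's k-space transform is evaluated once — an exact chunked
non-uniform DFT over its nonzero voxels at the per-volume sample positions —
and reused for the entire run with per-spoke scalar weights.  Modulation is
held constant within one readout (≤280 µs against a ≥160 ms cardiac cycle,
an error below 0.2 % of the cycle).

Respiration enters three ways:

* a bulk translation along z (default 0.3 mm peak), applied as the exact
  Fourier-shift linear phase;
* a direction-independent global phase (default 0.1 rad peak), physically a
  respiratory B0 shift from chest motion.  This term is essential: the
  translation phase is proportional to d·ẑ and alternates sign with the
  spoke direction, so the self-gating chain (which low-pass filters the
  spoke-indexed series) would average a translation-only surrogate to zero.
  The B0 term is the carrier the center-phase surrogate actually reads, on
  synthetic and — by the same physics — real data;
* a small multiplicative intensity modulation per compartment.

The respiratory waveform shape is a squared raised cosine (narrowed
inspiration peak); no standard analytic shape exists for rodent breathing.

The synthetic ECG is a Mexican-hat QRS train plus respiratory baseline
wander, a volume-periodic gradient-artifact template (default 5× the QRS
amplitude with a ±10 % linear drift across the run — making the sliding
template genuinely better than a global one), 50 Hz line noise and white
noise.  The artifact template is cosine-phased so it starts abruptly at
full amplitude, as a gradient switch does; returned trigger times carry a
fixed +0.5 ms offset so onset refinement has something to correct.

Complex Gaussian noise is added at `noise_sd` (default 0.003) times the DC
signal.  Fixed seeds give bit-identical outputs.

### What the simulator does *not* emulate

No Bloch-equation physics (flip-angle- or TR-dependent inflow saturation,
T1/oxygenation contrast), no gradient-hardware imperfections or eddy
currents, no multi-coil reception, no subject motion beyond the rigid
respiratory shift, no arrhythmias, and compartments are geometric idealized
shapes rather than vasculature.  Passing tests therefore demonstrate that
the *processing chain* is correct and self-consistent under the stated
signal model — not that the model captures every property of in-vivo ZTE
data.

## ECG gating

1. **Onset refinement.**  The signal is upsampled fivefold by linear
   interpolation (80 kHz → 400 kHz effective).  An artifact template is the
   mean of the first 10 trigger-aligned volume epochs, high-pass filtered at
   200 Hz so each epoch's own QRS does not bias the lag (artifact energy is
   in the hundreds of Hz to kHz).  The template is circularly anchored to
   the artifact's energy onset (coarse-to-fine step detector on the
   envelope, snapped to the original sample grid to cancel the
   interpolation-ramp bias); each trigger then moves to the lag within ± half
   a volume maximizing the normalized cross-correlation.  A uniform trigger
   offset is thereby corrected rather than inherited.
2. **Template regression.**  Per volume, the artifact template is the mean
   of up to 40 epochs centred on it (trailing at the edges).  The template
   is mean-centred and subtracted with a per-epoch least-squares gain —
   "regressed from", which also absorbs the amplitude drift.  The gain is
   hard-gated on the squared template/epoch correlation (>0.6): epochs the
   template clearly explains are fully corrected, artifact-free data passes
   untouched, which makes the denoiser idempotent.  The result is
   downsampled to 80 kHz and residual line noise removed by a steep
   elliptic band-stop of half-width 50/(2·30) Hz around 50 Hz, applied only
   while a 50 Hz spectral peak is present (a shallow-skirted biquad would
   keep eroding QRS energy on every pass).
3. **R-peak detection.**  The cleaned signal is band-passed to the QRS
   energy band (5–45 Hz, zero phase), peaks found above an adaptive
   prominence threshold (4× MAD, raised to half the 95th-percentile
   first-pass prominence), spacing-constrained at half the median interval,
   then snapped to the apex of the unfiltered cleaned signal within
   ±2.5 ms so R-R intervals are not blurred by the band-pass.  Events are
   mapped to (spoke, volume) coordinates by timestamp.

## k-space self-gating

The respiratory surrogate is the phase of the first post-gap sample of
every spoke — the highest-SNR point of a ZTE readout.  The static
spoke-direction-dependent phase offset is removed by subtracting a sliding
40-volume per-direction template; phases are averaged on the unit circle
(circular mean), since arithmetic averaging fails near ±π.  The series,
uniformly sampled at the spoke rate (the spoke TR is constant, so this is
exact), is low-pass filtered at 10 Hz with a 4th-order zero-phase
Butterworth (family and order are our choice; only the cut-off is given),
and breathing peaks are detected as prominent local maxima with half-median
spacing.  Inspiration is taken as a surrogate maximum; on real data the
sign depends on geometry, so an `invert_surrogate` flag is exposed.

## Retrospective binning

Cycles are consecutive event pairs, gated to [0.5, 1.5]× the median
duration (rejecting missed/false peaks without manual curation).  Within a
cycle, a spoke at fractional phase φ gets bin ⌊φ·20⌋ (half-open bins,
right edge clipped), so a bin is a fixed fraction of its cycle — per-cycle
normalization that absorbs beat-to-beat variability by construction.  Even
kept cycles fill bins 0–19 and odd ones 20–39, giving the 40-bin output
spanning two consecutive cycles while keeping every bin a genuine average
over many cycles.  The gated time axis is bin index × mean bin duration
(bin-start convention).  Data reduction keeps the initial contiguous
fraction of volumes (a shorter scan), leaving the bin structure unchanged.

## Reconstruction

* **NUFFT.**  Kaiser–Bessel gridding on a 2× oversampled grid, kernel width
  4, Beatty shape parameter; the adjoint is the exact conjugate transpose
  of the forward (same kernel taps), so ⟨Ax, y⟩ = ⟨x, Aᴴy⟩ holds to machine
  precision by construction, while the forward agrees with a direct DFT to
  ≈10⁻³ relative error.  The global kernel scale is calibrated against a
  centered unit impulse, whose exact transform is 1 everywhere.
* **Density compensation.**  w ∝ r² (3D radial), with an r = 0 sample given
  the volume-equivalent weight Δk²/24 so the weight stays finite at the
  center; weights are normalized per subset.
* **Center completion.**  The dead-time gap removes the innermost samples.
  They are estimated by projection iterations: one gradient step on the
  measured-data least-squares objective alternated with the image-domain
  realness/non-negativity projection (projected gradient descent, 10
  passes), after which the transform of the final image is evaluated at the
  gap positions.  Measured samples are returned bit-identical.  This is a
  documented stand-in for algebraic completion schemes; its contract is
  *improvement over zero-filling*, which the tests verify, not exact
  replication.  (A literal re-insertion of gap estimates into the adjoint
  was measured to have a loop gain ≈2.5 per iteration through the gap
  samples and diverges; the projected-gradient form decreases the gap error
  monotonically, 0.20 → 0.04 relative over 10 iterations on a 16³ test.)
  A coverage check (maximum nearest-neighbour gap below 8× the ideal
  spacing and below π/3 absolute) refuses pathologically thin subsets.
* **FISTA.**  After a global zeroth-order phase alignment (innermost-sample
  phase), the image is initialized with the density-compensated adjoint,
  scaled by a least-squares fit to the data, and refined by 3 iterations of
  *monotone* FISTA (best-iterate bookkeeping) on ‖Ax−y‖² with a
  non-negativity proximal step; the step size is 1/L with L from power
  iteration (6 steps, +5 % margin).  Plain FISTA is not monotone; the
  monotone variant guarantees the non-increasing objective the tests
  assert.  No sparsity/TV penalty is used, since none is named for the
  method being modelled.
* **Modes.**  `standard` reconstructs one volume per acquisition volume
  (0.545 s ≈ 0.55 s at full scale); gated modes reconstruct one volume per
  bin from all its pooled spokes.  Pooling spokes per bin across the run is
  mathematically the data-weighted average of per-cycle reconstructions and
  differs from image-averaging only through the per-reconstruction
  non-linearity; pooling was chosen (better-conditioned, one reconstruction
  per bin).

## Analytics

ROI waveforms are mask means per frame in percent change about the temporal
mean (scale-invariant, rather than arbitrary scanner units).  Peak
amplitude is max−min of the percent waveform; peak time is the argmax bin ×
bin duration (first bin on ties; a max-only amplitude variant is exposed).
Cycle stability is the CV of successive event intervals (sample SD).
Waveform consistency uses leave-one-out Pearson correlations over bin index
(fractional phase, not absolute time) and within-subject cross-condition
correlations.  Data-reduction robustness correlates reduced-data waveforms
against the full-data waveform per ROI and fraction.

Connectivity: Pearson correlations per ROI pair in sliding windows
(defaults 250 volumes, 125 step; count = ⌊(frames−window)/step⌋+1),
averaged over windows as raw r (Fisher-z averaging is available but off,
matching "average correlation values"; whether z-averaging was used is not
stated).  Two-condition comparisons use two-sided paired t-tests with
Benjamini–Hochberg FDR across measures; zero-variance differences give
p = 1.  Since the package has no ICA, connectivity ROI time series come from
phantom compartment labels carrying injected band-limited (0.01–0.1 Hz,
configurable) shared fluctuations with known coupling — a connectivity
ground truth replacing ICA components.  Group-level analysis is the
bin-wise mean of per-subject waveforms; subjects share phantom geometry,
which replaces coregistration.

## Problem sizes

Full-scale parameters are available throughout, but tests and the
acceptance computation run at a desk scale chosen as the package's default
test geometry: 32³ matrix, 16 readout samples, 200 volumes of 400 spokes
(≈22 s of acquisition, ≈128 cardiac cycles), with smaller 12³/16³ variants
for unit tests.  The data-reduction experiment compares the full desk-scale
run against its first eighth (25 volumes).

## Known limitations

* The tennis-ball ordering and algebraic center completion are documented
  stand-ins, not replications of the original algorithms.
* Phase correction is a single global (zeroth-order) rotation; no
  per-channel or spatially varying phase model (single-coil assumption).
* The ECG denoiser assumes a volume-periodic artifact with slow amplitude
  drift; it has no model for arrhythmia or electrode motion.
* Self-gating assumes a dominant direction-independent respiratory phase
  carrier; objects whose respiratory signal is purely translational would
  need the surrogate built per-hemisphere of spoke directions instead.
* Percent-change amplitudes are not calibrated to physical units; only
  within-package comparisons are meaningful.
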