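# Methods

## Waveform model

One recording is laid out on a single sample grid (default 98 kHz, giving
1000 samples per frame at the 98 Hz reference plane rate). The plane rate is
adjusted to the nearest value that makes samples-per-frame an integer;
`TimeBase.rate_was_adjusted` reports when this happened. Within each frame
the X mirror executes `scans_per_frame` symmetric out-and-back triangle
sweeps centred on 0 V (the galvo's energized rest position); a sawtooth
option is deliberately not the default because an out-and-back sweep returns
the mirror to its start value at every frame boundary, keeping frames
identically illuminated. The camera trigger raises one edge on the first
sample of every plane frame, with a pulse width of min(1 ms, 10 % of a
frame) — the downstream camera only needs the rising edge, so the width is a
robustness choice, not a timing one.

Depth is defined with plane 0 at the **top** of the volume (depth 0), and
increasing depth maps to increasing piezo voltage; plane indices are
0-based and label depth (so a scan-up volume carries descending labels).
The flyback is a linear ramp spread over the configured flyback frames,
ending exactly at the next volume's starting depth; a cosine-smoothed
variant was considered and left out of v1 since the virtual-scope
experiments show the linear ramp already removes essentially all of the
post-return ringing (see below). Bidirectional mode alternates down/up
volumes with zero flyback samples; configuring flyback frames there is
answered with a warning and ignored. Bidirectional acquisition implies an
unequal effective inter-frame interval at the turnaround volumes; the
engine exposes this only through phase labels and does not alter exposure.

Sessions concatenate, per recording: an optional light-adaptation segment
(sheet parked at a configurable depth with the shutter open, no triggers —
so a light-sensitive animal never experiences a sudden light change), the
recording, and an inter-recording gap in which adaptation continues if
enabled and all shutters close otherwise. The session plan carries an
`adaptation_duration_s` (default 0.5 s); segment durations are rounded up to
whole frames to keep the X sweep phase-locked. Channel order is fixed:
trigger, shutters, X mirrors, Z mirrors (path 1 before path 2), piezo —
8 channels dual-path, 5 single-path. Every voltage sample is checked against
the configured output range (±10 V default) before a waveform is returned.

## Shutter masks and lag compensation

The shutter opens when the *lag-corrected* mirror position — the commanded
position evaluated `lag` seconds earlier, which is where a delay-lagged
mirror actually sits — lies inside the unmasked sheet extent. Edge masks
close beyond |x| > (1 − 2f)·w/2; because a triangle sweep's position is
uniform in time, the open fraction per sweep is 1 − 2f up to the four
mask-boundary samples of each scan (the tolerance used in the tests). The
eye mask closes a chosen interior interval; blank-return closes all
flyback samples. Mirror commands are never modified by lag compensation —
only the shutter timing moves.

The lag itself is estimated automatically, replacing the manual
adjust-until-the-masks-overlap procedure: the virtual scope sweeps a
distinctive mask forward-only and reverse-only and accumulates dose versus
position. A mirror delay of k samples makes the dose trail the command —
toward −x going forward, toward +x in reverse — so the two profiles separate
by 2k position bins when the bin width equals one sample of mirror travel
(which the profile generator guarantees, and constructs both sweep
directions from one shared value grid so the separation is exact in floating
point). Exhaustive search over integer shifts (±100, covering lags to 50
samples — generous for a 1 kHz-bandwidth galvo) then recovers a pure sample
delay exactly, and applying the estimate drives the forward/reverse
mismatch to zero. For a first-order mirror the estimator returns an
effective delay close to the time constant τ, as expected.

## Calibration

* **Pixel size** = sensor side / pixel count / magnification (13 mm, 2048 px,
  16× → 0.397 μm/px, a ~0.16 μm² footprint).
* **X scale** is corrected in one multiplicative step from a commanded-vs-
  measured sheet width; under a linear mirror model the closed loop
  converges in a single iteration.
* **Z-mirror scale** is an ordinary least-squares line through
  (stage depth, in-focus Z voltage) pairs. The mirror is assumed linear in
  depth — the residual standard deviation is reported precisely so that a
  nonlinear response is visible to the user; no spline option in v1. The
  scale's standard error comes from the standard OLS formula and the
  noisy-recovery tests assert the estimate lands within 3 SE of truth.
* **Piezo scale/offset** are factory numbers (40 mV/μm for the reference
  objective scanner) — entered, validated for range feasibility, never
  estimated.

## Virtual microscope

Galvos are ideal, pure-delay, or first-order (`y[n] = y[n−1] + α(x[n]−y[n−1])`,
α = 1 − e^(−Ts/τ), τ defaulting to 1/(2π·1000) s for a 1 kHz bandwidth).
A first-order mirror rounds the triangle peak by ln 2·(sweep slope)·τ — about
13 % at the default 3-scans-per-frame geometry — which is why edge masks
exist. The piezo is ideal or a bilinear-discretized damped oscillator
ωn²/(s² + 2ζωn s + ωn²); the defaults fn = 150 Hz, ζ = 0.2 are plausible
values for an objective-loaded scanner used as synthetic ground truth only
(they match the textbook 52.7 % step overshoot and reproduce the motivation
for flyback: a 10-frame ramp leaves sub-μm tracking error in the first
post-return frame where an instant return leaves tens of μm).

Frame rendering deposits one unit of dose per open-shutter sample at the
simulated mirror position and applies a Gaussian defocus penalty
exp(−Δ²/2σ²) with σ = waist/2 on the sheet-to-objective depth mismatch Δ,
rather than a full per-frame PSF convolution — sufficient to reproduce the
in-focus/out-of-focus contrast that the Z calibration relies on (a 20 %
z-scale error makes frame intensity fall monotonically with depth; a
correct calibration keeps frames equal to better than 1 %). The scope
converts command voltages to physical positions through its own "true"
calibration state, so miscalibration experiments simply inject a truth that
differs from the state used to build the waveforms.

## Synthetic beads and the resolution pipeline

The bead generator renders 0.1 μm beads as anisotropic Gaussian spots
(σ = FWHM/2.3548 per axis; at 7× below the lateral PSF width the bead is a
point source, so the spot *is* the PSF sampled at voxel centres), adds a
constant background (0.1 of unit bead amplitude) and Gaussian noise, and is
byte-deterministic under its seed. The default scene places 22 beads on a
jittered lateral grid with random depths inside a 20×20×30 μm volume —
spacing chosen so every pair stays farther apart than the fitting windows,
emulating the hand-selected isolated beads of a real measurement. Defaults
mirror a realistic acquisition: 0.16 μm lateral pitch, 0.5 μm z-step, 2 %
noise, truth FWHMs 0.7 μm lateral / 5.4 μm axial.

Detection finds 3×3×3 local maxima on a 1-voxel-Gaussian-smoothed copy
(raw pixel noise on a bead's axial flank otherwise splits one bead into
several candidates), thresholds at median + 5×MAD-σ of the raw data (robust,
hence scale-invariant), and greedily enforces a minimum physical separation,
strongest first. Fitting follows the classical protocol: a 1-D Gaussian
(amplitude, centre, σ, offset) to the z-profile through the brightest voxel;
the fitted centre selects the plane for a 2-D isotropic Gaussian
(σx = σy shared). Windows are ±4 expected σ (axial and lateral); offsets are
free parameters in every fit since background subtraction is not assumed.
Beads are excluded when a fit fails, the window clips a border, or the rms
residual exceeds 20 % of the fitted amplitude. The summary reports
mean ± sample sd (ddof = 1) of FWHM per axis; a single bead reports sd 0
with an explicit flag.

What passing these tests shows — and does not: the pipeline recovers known
Gaussian truths within 5 % under realistic sampling and noise, and the
full chain is deterministic under a seed. Real bead stacks add
non-Gaussian PSF tails, refractive-index aberrations, uneven illumination
across the sheet (a 200 μm sheet is not uniform to its edges) and camera
noise structure, none of which the generator emulates; recovered accuracy
on real data is therefore not implied, only the correctness of the
estimator on its stated model.

## Planning arithmetic

All calculators are pure: volume rate = plane rate / (planes + flyback)
(98, 50, 10 → 1.6 volumes/s), frame period 1000/rate ms, camera throughput
with decimal MB (10⁶ bytes; 2048²×2 bytes×100 Hz → 838.9 MB/s, beyond the
600 MB/s SATA3 ceiling), storage splitting with a 4×10⁹-byte default limit
(2³² available as the classic-TIFF option), channel budget 3 per modulated
path + piezo + trigger. The Rayleigh-range calculator exposes the standard
z_R = πw₀²/λ only; note that some published sheet-uniformity figures (e.g.
a ~440 μm Rayleigh length alongside a ~7 μm waist *thickness*) are not
reproduced by this formula under any obvious waist convention — a 488 nm
beam would need an 8.27 μm waist *radius* for 440 μm — so the number is
documented rather than targeted.

## Problem sizes and numerical choices

The test suite and acceptance script run the waveform property checks on
~10⁶-sample blocks (17 volumes of 60 000 samples), dose audits on 5×10⁵
samples, and the bead pipeline on a 60×125×125-voxel stack — sizes chosen as
the package's own desk-scale defaults that still exercise every code path at
full sample rate. Dose-uniformity assertions use bin counts incommensurate
with the per-sample travel (e.g. 40 or 49 bins for 1000-sample frames) so
that histogram aliasing between the sample grid and bin grid does not
masquerade as non-uniformity. Gaussian fits use `scipy.optimize.curve_fit`
with moment-based initial values and positivity bounds on amplitude and σ;
non-convergence is recorded, never raised. Flat profiles, zero-width
sheets, single-plane volumes and all-closed shutters are all defined,
degenerate-but-valid inputs.

## Known limitations

No real-time streaming, GUI, camera SDK or DAC driver interfacing; no
rolling-shutter trigger pattern; no wave-optics or shot-noise-accurate
camera simulation (optional Poisson noise only); no deconvolution or
non-Gaussian PSF models; dual-path systems share one depth trajectory
(one sample volume), with each path's Z mirror calibrated independently.
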