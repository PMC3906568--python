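# Methods

This note documents the models, numerical methods, and design decisions behind
`neurorig`. All quantities are SI unless stated otherwise (rig configuration
files may use unit suffixes such as `um`, `MOhm`, `kHz`, which are normalized
on load).

## Coordinate model (`neurorig.rig`)

Devices form a forest: each device carries a local 4×4 homogeneous affine
transform mapping its own coordinates into its parent's, and the global
transform of a device is the product of local transforms up to its root
(column-vector convention). Pixel or scan coordinates map to physical
coordinates through `RigConfig.map_point(device, p, "to_global")`; the inverse
route uses the inverted composed matrix. Singularity is tested on the ratio of
extreme singular values of the linear part (relative threshold 1e-12) rather
than the absolute determinant, because micrometer-scale transforms have tiny
determinants while being perfectly well conditioned.

Objectives are modeled as `translate(offset) ∘ scale`; switching the active
objective replaces the microscope's local transform, which transparently
rescales every device beneath it in the hierarchy (camera pixels, scanner
targets). Stage motion rewrites the stage's translation. Both emit change
events to registered listeners.

## Simulated devices (`neurorig.simdevices`)

**Patch-clamp cell.** The cell is a passive RC circuit: access resistance
`Ra` in series with the parallel pair (`Rm`, `Cm`), resting at `Vrest`. For a
voltage-clamp step of amplitude ΔV the current is

    I(t) = I_hold + ΔV/(Ra+Rm) + (ΔV/Ra − ΔV/(Ra+Rm)) · exp(−t/τ),
    τ = Cm · Ra·Rm/(Ra+Rm)

and for a current-clamp step ΔI,

    V(t) = Vrest + ΔI·Ra + ΔI·Rm · (1 − exp(−t/(Rm·Cm))).

Arbitrary piecewise-constant commands are handled by superposition over the
step changes, so responses are exact (not numerically integrated). Optional
Gaussian recording noise is seeded.

**Spiking option.** An integrate-and-fire mode (threshold −40 mV, reset
−65 mV, 2 ms refractory, spike painted at +30 mV) exists so that supra-threshold
IV protocols produce spike trains with well-defined statistics (constant drive
→ constant inter-spike intervals). This is a deliberately synthetic spike
generator, not a biophysical action-potential model; tests treat it as such.

**Camera.** Frames are rendered by mapping the pixel grid through the camera's
global transform and sampling a user-supplied scene function of global (x, y),
so stage motion and objective switches displace image features exactly as the
coordinate model predicts. Frame start times are quantized to the DAQ sample
grid and a TTL exposure trace is emitted that is high during each exposure —
frame starts equal TTL rising edges exactly.

**Scanner ground truth.** The simulator holds a hidden quadratic voltage map
(see below) and answers "where does the spot land for voltages (Vx, Vy)?" by
inverting it numerically: a linear-part initial guess, `scipy.optimize.root`,
then a short analytic-Jacobian Newton polish to residuals below 1e-15 V.
Optional spot-observation noise is seeded.

**Reservations.** Devices are claimed atomically in sets (all-or-nothing, no
hold-and-wait, FIFO queueing under a single condition variable), eliminating
deadlock by construction; a claim ledger supports auditing that no device is
ever co-held.

## Task engine (`neurorig.taskengine`)

A task is a mapping from device names to configuration blocks plus a
`protocol` block (duration, storage flags). Validation resolves the DAQ sample
rate / sample count / duration consistency, checks that every `triggerDevice`
reference stays within the task, and rejects trigger cycles.

Two orders are planned by topological sort (Kahn's algorithm with a priority
tie-break):

- **configure order** honors per-device `configure_before` preferences, with
  longer `arming_latency` devices configured first;
- **start order** places every triggered device before its trigger source, so
  a device is always armed before the pulse that starts it can fire.

Execution reserves all participating devices atomically, configures, starts,
then polls a simulated clock at 10 ms intervals until the protocol duration
elapses (timeout 10×duration + 5 s). Aborting stops devices in reverse start
order. Amplifier mode changes always pass through I=0 with zeroed holding.
Sequences expand a base task over an n-dimensional parameter grid; each grid
point gets a derived seed (base + linear index) and records its parameter
values in the result and in storage metadata.

## Scanner calibration (`neurorig.scanner`)

The mirror voltage map is quadratic in position:

    Vx = A·x² + B·y² + C·x + D·y + E
    Vy = F·x² + G·y² + H·x + I·y + J

This model is *linear in its coefficients*, so ordinary least squares on the
design [x², y², x, y, 1] reaches the same optimum as an iterative
(Levenberg–Marquardt-style) solver; we use `numpy.linalg.lstsq`. Positions are
rescaled to unit range before solving: with meter-scale coordinates the raw
design matrix mixes magnitudes 1e-8 … 1 (condition number ~1e7), costing ~7
digits; normalization brings noise-free coefficient recovery to ~1e-13
relative. Fits require ≥ 5 non-degenerate samples (rank check) and are stored
per (laser, objective) pair in a JSON calibration store.

Scan patterns (raster with fractional overscan and bidirectional field-shift
compensation, line, circle, Archimedean spiral r = pitch·θ/2π, point lists)
expand to timed position series with a boolean keep-mask flagging overscan
samples. Laser dosimetry converts a requested pulse energy into a duration
using the expected sample-plane power (source power × per-configuration
attenuation).

## Electrophysiology analysis (`neurorig.ephys`)

**Frame timing.** Exposure TTL traces are thresholded at the midpoint of
their dynamic range with a ±10% hysteresis band (noise within the band cannot
create spurious edges). An exposure already in progress at the first sample
counts as starting there; one still high at the end is closed at the trace
end.

**Membrane test.** For a voltage-clamp pulse: fit a single exponential to the
decay (log-linear initial guess refined by `scipy.optimize.curve_fit`),
extrapolate the peak current to pulse onset, then

    Raccess = ΔV/(I_peak − I_0),  Rin = ΔV/(I_ss − I_0),
    Rm = Rin − Raccess,           Cm = τ·Rin/(Raccess·Rm).

On noiseless simulated data these recover ground truth to ~1e-14 relative.
Current clamp yields Rin = ΔV_ss/ΔI and the resting potential.

**IV metrics.** Input resistance is the least-squares slope of
(ΔI, ΔV_steady) over subthreshold steps; τ_m is fitted on the smallest
hyperpolarizing step; sag ratio on the largest; spike-train metrics (ISIs,
latency, adaptation = mean of the last two ISIs over the first) come from the
step with the most spikes.

**Event detection.** Zero-phase Butterworth low-pass (default 0.4×Nyquist) →
FFT deconvolution by a single-exponential kernel (regularized by 1e-6 of the
kernel-spectrum peak) → 1 ms boxcar smoothing of the deconvolved signal
(deconvolution amplifies high-frequency noise; events remain pulses wider than
1 ms) → robust threshold at k × 1.4826×MAD, floored at 1e-3 of the signal
peak to reject deconvolution ringing on noise-free data → onsets at threshold
crossings separated by a minimum interval. Each event is then measured on the
filtered trace: baseline (median of the preceding 5 ms), amplitude, 10–90%
rise time, fitted decay τ. At SNR 10 this achieves recall 1.0 with zero false
detections at ±2 ms matching.

**Charge transfer** is the trapezoidal integral of the baseline-subtracted
current over a window.

**Photostimulation maps.** The spontaneous event rate λ is pooled over all
sites' baseline windows; each site's test-window count k is scored by the
Poisson upper tail P[K ≥ k] with mean λ·test_window·n_trials, and sites are
flagged under Benjamini–Hochberg FDR control. When λ̂ = 0 the null is
degenerate: any test event yields p = 0, none yields p = 1. Exports to CSV and
SQLite.

## Imaging analysis (`neurorig.imaging`)

- **Rolling background subtraction:** exponential running mean,
  `bg_t = (1−α)·bg_{t−1} + α·frame_t` with α = Δt/time-constant; the output is
  `frame_t − bg_{t−1}`, so static structure decays while fast transients pass.
- **Bleach correction:** fit `A·exp(−t/τ_b) + C` and rescale multiplicatively
  by `F̂(0)/F̂(t)`, preserving fractional (ΔF/F) transient amplitudes.
- **Registration:** integer-pixel translation by FFT cross-correlation
  against the first (or mean) frame; corrected frames are shifted back with
  the wrapped margin zeroed.
- **ΔF/F:** ROI masks are computed in global coordinates through each frame's
  transform; F₀ is the mean over a baseline window. A ratiometric variant
  divides two channels' ROI series before normalization, cancelling
  common-mode fluctuations.
- **Event-triggered average:** windows around event times, partial windows
  skipped; noise averages down as 1/√N.
- **Mosaics:** frames are placed through `adjustment ∘ transform` (manual
  alignment adjustments are metadata and never modify the stored frames) and
  resampled nearest-neighbor onto a global grid; overlaps resolve last-on-top
  or mean. Nearest-neighbor was chosen for exact testability of placement.

## Data storage (`neurorig.datastore`)

Sessions are directory trees. Every directory holds a `.index.json` (written
atomically via a temp file and `os.replace`) listing typed children and their
metadata; directory types carry required-metadata schemas; name collisions
get numeric suffixes (`run`, `run_000`, …). Arrays are stored one per HDF5
file: payload at `/data`, frame times and per-frame transforms as datasets,
sampling/units metadata and a SHA-256 content checksum as attributes —
verified on read. `fsck` recursively checks index/disk agreement.

## What the simulators do *not* emulate

Analog hardware imperfections (amplifier filtering, pipette capacitance
compensation, mirror dynamics/settling, camera shutter roll, photon shot
noise statistics), multi-process timing jitter, and real trigger
propagation delays. The simulated clock advances deterministically, so test
outcomes depend only on the seed.

## Problem sizes and runtime

The acceptance script (200 random cells, 500 null maps, 1000 random DAGs and
hierarchies, 40 noise traces) completes in a few seconds; the full test suite
(~190 tests including property-based suites) runs in well under a minute.
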