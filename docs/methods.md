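# Methods

## Signal model and preprocessing

A demodulated photometry export is treated as a uniform time grid with one
trace per excitation channel. The sampling rate is always inferred from the
median time step and the grid is required to be uniform within a relative
tolerance (default 1e-6); metadata rates are never trusted, because exports
disagree with their own time columns often enough that silent acceptance is
worse than a load-time error.

Each sensor channel passes through four stages:

1. **Low-pass Butterworth filter**, default cutoff 10 Hz, order 2, applied
   forward-backward (`filtfilt`). Zero-phase filtering is the default because
   event-locked analysis hinges on "time point 0": a causal filter's group
   delay would systematically shift every onset-locked feature. The effective
   magnitude response is then |H(f)|² = 1/(1 + (f/f_c)^(2n)); for the default
   order-2 filter a 1 Hz tone passes with <0.01% loss and a 50 Hz tone is
   attenuated below 0.2% amplitude. Both cutoff and order are exposed, and a
   single-pass (causal) mode exists for workflows that need causality over
   phase fidelity.
2. **Isosbestic regression.** The filtered sensor trace is regressed on the
   single filtered isosbestic trace by two-parameter OLS (closed form:
   a = cov/var, b from the means), giving the predicted non-neuronal baseline
   F_fit = a·F_iso + b. The same isosbestic regressor serves both sensor
   channels. The isosbestic is filtered with the same filter before fitting,
   so the regression compares like with like; regressing filtered against raw
   would leak high-frequency isosbestic noise into the baseline. A constant
   isosbestic is rejected as degenerate rather than producing an arbitrary
   slope.
3. **ΔF/F** = (F_filtered − F_fit)/F_fit, elementwise. The division is
   guarded by a floor (default 1e-12 × median|F_fit|): demodulated
   fluorescence is strictly positive, so a fitted baseline near zero signals
   a corrupt fit, not a small signal. ΔF/F is invariant to common rescaling
   of both traces, which is what makes it comparable across fibers and
   sessions; a percent variant (100 × ΔF/F) is provided as a convenience.
4. **Z-score** = (ΔF/F − μ)/σ with the *population* standard deviation
   (divide by n). With μ, σ over the full recording the output has exactly
   mean 0 and SD 1, which is the property the rest of the pipeline (AUC in
   z·s, heatmaps in z) relies on. Normalizing over the whole recording rather
   than a pre-stimulus baseline is the right default for self-paced
   exploration, where no stimulation-free pre-event baseline exists; a
   `[t0, t1]` baseline window option computes μ, σ on that window only and
   applies them to the whole trace, for designs that do have one. Whether the
   window includes or excludes a home-cage connection period is therefore
   entirely the caller's choice of window; no intent is guessed.

## Event referencing and alignment

Event sheets follow a one-row convention: `start`/`end` bound the behavioral
trial, each event i contributes a matched `starti`/`endi` pair (suffixes must
be contiguous 1..N; order in the file is the canonical order), and free-text
labels (`odorant`, `hedonics`, `condition`, per-event `typei` or a shared
`type`) ride along verbatim. Headers are case-insensitive; CSV and xlsx are
accepted. All event times are seconds on the photometry clock — acquisition
and video start simultaneously in the supported rigs — with an optional
constant offset for rigs where they do not. Intervals are closed-open
[t_start, t_end) when converted to sample or frame indices, so adjacent
events never double-count a boundary sample.

Alignment maps each event onset to the nearest sample *at or before* t_start
(floor, no interpolation). This preserves causality — no post-onset value can
appear at a nominally pre-onset position — at the cost of an onset
quantization bias of at most one sample (half a sample on average), which is
negligible at tens-of-Hz sampling against behavioral timescales. Rows whose
[−pre, +post] window leaves the recording are dropped and counted, never
padded: sentinel padding would bias ensemble means. Ensembles carry their
event provenance, and averaging is offered both per event (each event weighs
equally) and per animal (each session's mean weighs equally); the two differ
whenever animals contribute unequal event counts, and neither is asserted as
canonical.

## AUC windows and the gated paired test

AUC is the trapezoidal integral of the Z-score trace over a window relative
to onset, with the trace linearly interpolated at window endpoints that fall
between samples. This makes the integral exact for piecewise-linear traces,
additive over adjacent windows, and independent of how the window endpoints
sit on the sample grid. Defaults: before = [−0.6, −0.3] s, during =
[0, +0.3] s; the 0.3 s length corresponds to one sniff cycle. AUC is
computed on the Z-score trace, after normalization.

Before/during pairs (one per unit; unit = animal mean trace by default, per
event optionally, with the choice flagged in output) are compared with a
normality-gated paired test: Shapiro–Wilk on the paired differences at
α = 0.05 (configurable) routes to a paired t-test when normality is not
rejected and to a paired Wilcoxon signed-rank test otherwise. Sidedness is
always caller-specified — no default is silently applied. Degenerate inputs
are handled explicitly: all-zero differences report p = 1 with a flag;
a constant non-zero shift (zero variance, Shapiro–Wilk undefined) is reported
as the paired-t limit (|t| → ∞, p → 0 in the matching direction), flagged
degenerate. No multiple-testing correction is applied.

## Spatial analysis

Two reference markers at the bottom corners of the square board define an
affine frame: P1 → (0,0), P2 → (1,0), y increasing upward, uniform scale.
Pixel input is image-convention (y down) by default. Because the board is
square, two points suffice; the transform is invariant to camera translation
and rotation, which is the point of the markers. Points outside the unit
square are clamped and counted.

Zone-entry events are maximal runs of consecutive in-zone frames (disc zone
for the odorized hole, default center (0.5, 0.5), radius 0.08; border band of
width 0.1 for the board edge — both defaults are declared conventions, since
head-over-edge posture is not recoverable from point coordinates). Tracking
gaps (missing coordinates or missing frame indices) break runs; runs shorter
than a minimum duration are discarded. Event times are frame-accurate with
the closed-open convention, so total event duration equals in-zone frame
count / frame rate exactly.

Maps bin the normalized board into an n×n grid (default 32; bins half-open
with the top/right edge closed, so every point lands in exactly one bin).
Occupancy is seconds per bin and sums exactly to tracked (non-gap) time. Each
photometry sample is assigned to the bin of its temporally nearest tracking
frame; samples nearest a gap frame or outside the tracked span by more than
half a frame are skipped. `signal_sum` accumulates z per bin; `signal_norm`
divides by the number of photometry samples accumulated there — the
per-sample mean z, equivalent to normalizing the accumulated signal by
occupancy time × sampling rate, but computed from the actual sample count so
the identity "constant z = 1 ⇒ signal_norm = 1 on every visited bin" holds
exactly rather than up to rounding of samples-per-frame. Unvisited bins are
NaN, never zero: zero is a valid mean z and must remain distinguishable.

## Synthetic sessions

The generator emulates the session structure the pipeline assumes: a 2-min
home-cage connection period followed by a 2-min board trial (defaults
duration 240 s, trial [120, 240] s), photometry at 100 Hz, video at 25 Hz,
8 investigation ("hole") events of 0.5–3 s separated by ≥2 s plus 2 escape
("edge") events.

Channel model:

    F_role(t) = B_role · exp(−t/τ_bleach) · (1 + c_role·A(t) + T_role(t)) + ε(t)

with per-channel baseline B (defaults 1.0 / 0.9 / 0.6 V for 465 / 565 /
405 nm), shared bleaching τ = 2000 s, shared artifact A(t) a unit-variance
low-pass-filtered Gaussian process (bandwidth 2 Hz) scaled by the artifact
amplitude (default 5% of baseline) and a per-channel coupling c (default 1
for all channels), white noise ε (SD 0.002 V), and event transients T only on
sensor channels. The artifact couples multiplicatively to the instantaneous
baseline rather than additively: with proportional coupling the sensor is an
affine function of the isosbestic up to signal and noise, which is precisely
the model under which single-regressor isosbestic OLS is the correct
correction — an additive artifact with unequal channel baselines and a shared
bleaching trend would leave no single slope able to cancel both.

Transients use the standard double-exponential kernel exp(−t/τ_d) −
exp(−t/τ_r), normalized to unit peak (defaults τ_r = 0.05 s, τ_d = 0.4 s —
generator conventions for fast-sensor responses, not claims about any
particular dataset). Each hole event receives an independent per-event,
per-sensor amplitude (default peak ΔF/F 0.03, jittered ±30%) so amplitude
ordering can be tested by rank correlation; edge events receive none, so
event-type dissociations can be emulated. The trajectory is a bounded random
walk (reflected at the walls, held off both zones) that is placed inside the
hole disc exactly during hole events and on the border band during edge
events; home-cage frames are gaps, plus a 2% random dropout. All randomness
flows from one integer seed through one generator, so a fixed seed gives
byte-identical sessions.

What the generator does **not** model — sensor kinetics and nonlinearity,
hemodynamics, spectral cross-talk between the two emission bands, photon shot
noise, non-exponential bleaching, posture — bounds what passing tests show:
they validate the pipeline's arithmetic and its estimator under the model the
correction assumes, not robustness to physiological confounds the correction
is not designed for (the workflow deliberately performs no spectral
demixing).

## Validation experiment sizes

Replicated statistical checks (type-I error of the gated test: 500 null
replicates of 6 animals; power: 200 replicates at each of three amplitude
scales 0.25×/0.5×/1×; artifact rejection: 20 seeds) run on a scaled session
configuration — 60 s with a 50 s trial at 50 Hz, 5 hole events, no tracking —
chosen so thousands of full pipeline runs complete in seconds while keeping
the generative structure identical. Alignment fidelity is measured on a
group ensemble pooling 8 sessions' events, mirroring how group averages are
formed in practice; the injected kernel's analytic peak time is the
reference, and the single-session peak estimate is additionally reported per
session in the recovery report. Power at these amplitudes saturates near
rejection rate 1.0 (the default transient is large against the noise floor),
so the monotonicity property is additionally anchored by the strictly
increasing mean during-window AUC across amplitude levels.

## Known limitations

* One isosbestic channel corrects both sensors; channel-specific artifacts
  (e.g. chromatic motion sensitivity) are not separable.
* The regression is global; slow drifts that change the sensor/isosbestic
  relationship mid-session are only partially removed.
* Zone geometry is a declared convention (disc radius, band width), not
  inferred from video content.
* The Wilcoxon branch is exact only without ties; heavily tied AUC pairs fall
  back to scipy's tie handling.
* Ensemble alignment assumes a common sampling rate across pooled sessions;
  resampling across heterogeneous rigs is out of scope.
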