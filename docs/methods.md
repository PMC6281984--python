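# Methods

This note documents the models, the synthetic study conditions, the
numerical choices and the known limitations of `hybridphase`.

## Signal model and preprocessing

**Modified Beer–Lambert law (MBLL).** Optical-density change per
wavelength is ΔOD(t) = −log10(I(t)/Ī_baseline) with Ī_baseline the mean
intensity over the 60-s pre-rest. Concentration changes follow from the
2×2 extinction system ΔOD = E·Δc·d·DPF with E =
[[0.95, 4.93], [2.135, 1.791]] mM⁻¹cm⁻¹ (rows: 690, 830 nm; columns:
HbO, HbR), source–detector distance d (default 3.0 cm) and differential
pathlength factor DPF (default 6.0, standard CW-NIRS practice; the
source acquisition does not publish either, so both are configurable).
With d·DPF applied the output unit is mM; setting both to 1 leaves the
molar-absorbance (mM·cm) scale. Forward and inverse transforms are
exact inverses, which the generator exploits: ground truth is injected
in concentration space and folded through the forward model into
intensities, so conversion is validated by round trip.

**Filtering.** Hemodynamics: 4th-order Butterworth band-pass,
0.01–0.15 Hz. The default is *causal* — the detector is an online
method and the LDA comparison uses the same causally filtered data, so
neither sees future samples. The causal filter is initialised at steady
state with respect to the first sample; without this the 0.01 Hz
high-pass pole rings for tens of seconds and its startup transient
dominates the baseline that defines R1. Zero-phase filtering
(`FilterSpec(mode="zero-phase")`) exists for offline re-analysis but is
deliberately not the pipeline default: its non-causal smear leaks the
response into pre-response windows and flatters any fixed-window
classifier with information no online system has. EEG: the four bands
are 0.5–4 (high-pass + low-pass cascade), 4–8, 8–12 and 12–28 Hz,
4th-order Butterworth each.

## Vector-phase detector

Phase octants are numbered counterclockwise from the +ΔHbO axis, each
half-open and closed on its counterclockwise edge (phase 1 = (0°, 45°],
…, phase 8 = (−45°, 0°]); the boundary rule is arbitrary but fixed, and
the classifier is tested against a brute-force octant oracle including
every boundary angle. The 45° rotation prefactor is 1/√2, making the
transform an isometry — this is forced by the phase identity
∠p = atan2(ΔCOE, ΔHbT) + 45°. A transcription quirk in the reference
sign table (phase 6 marked ΔHbT-positive) is resolved in favour of the
geometry: ΔHbT < 0 exactly on octants 4–7.

**R1** is the maximum per-sample paired magnitude over the pre-rest;
**R2** uses separate per-component maxima with absolute values —
without the absolute value a signed maximum of ΔHbR would collapse the
radius in the fourth quadrant where ΔHbR < 0.

**Crossings are outward transitions.** A crossing of radius r requires
the previous sample at or below r and the arrival sample strictly above
it (fourth quadrant at arrival), with the crossing time linearly
interpolated between the bracketing samples. An elevated trajectory
that merely decays past a circle never "crosses": without this rule,
every rest-period EEG burst on a channel still carrying the decaying
response of the previous trial would produce a false command —
inverting the method's central claim. A pair straddling the monitoring
start counts as a crossing observed at the gate.

**Gate.** Beta power is the mean squared band-passed amplitude in a 1-s
window sliding at the fNIRS sample period (~0.109 s), so gate events and
trajectory samples share a clock. The threshold is 15% above the
maximum power over the sixty *non-overlapping* 1-s windows of the
pre-rest (a maximum over all ~550 sliding windows would take the max of
hundreds of correlated estimates and systematically overshoot). Both
selected electrodes must exceed their own thresholds in the same window
(configurable to either-of). Electrode selection is the per-group
argmax of task-epoch power on the first trial, ties to the lowest id,
then fixed for the session.

**Detection and scoring.** After a gate at window end t_g, the
trajectory must cross R2 and then R1, both outward in Q4, with the R1
crossing within 3 s of t_g (the timeout matches the −2…+3 s horizon over
which trajectories are meaningfully examined). If an unusually large
EEG-window excursion makes R2 ≥ R1, crossing R2 already proves R1 was
passed and the detection completes at that moment. A trial is scored
"task" iff any monitored channel completed a detection whose gate fired
inside the 10-s task block; the matched negative is the last 10 s of
the same trial's rest period (the pre-cue baseline of the next trial).
Mid-rest negatives were rejected: with a 10-s block design they sit on
the decaying response peak, so the class label would encode response
decay rather than absence of activity. Accuracy is percent correct over
the 24 balanced decisions, one decimal (10/12 → 83.3, 11/12 → 91.7).
The per-gate record keeps the gate time, both crossing times, their
difference (the R2→R1 latency) and the command time (= the R1
crossing), so the headline "1-s window + ~0.5-s crossing = command in
1.5 s" bookkeeping is preserved exactly on analytic fixtures and
reported as measured (~1 s mean) on noisy synthetic sessions.

## Hemodynamic response model

The canonical HRF is the two-gamma difference

    h(t) = α₁ [ (t/τ₁)^(φ₁−1) e^(−t/τ₁) / (τ₁ (φ₁−1)!)
              − α₂ (t/τ₂)^(φ₂−1) e^(−t/τ₂) / (τ₂ (φ₂−1)!) ]

with defaults φ₁ = 6, φ₂ = 16, τ₁ = τ₂ = 1 s, α₂ = 1/6 (the standard
canonical parameterisation; the source publishes none) and α₁ chosen to
peak-normalise h. Shapes are integers in the factorial form;
`generalized=True` swaps (φ−1)! for Γ(φ) and accepts non-integer
shapes. The designed HRF is the causal discrete convolution
u(k) = k₁ Σₙ h(n) s(k−n) with the task boxcar s and k₁ = 10, evaluated
on the fNIRS clock. The ideal trajectory pairs hbo = u with
hbr = −r·u (default r = 1/3, a typical empirical HbR/HbO ratio; the
source states none): a perfect straight line through the origin
confined to the hemodynamic octants while u > 0 — the testable form of
the "ideal trajectory is a straight line" statement.

## Activation mapping

Each channel's per-trial 30-s epoch (N = int(30 × 9.19) = 275 samples,
the truncating convention; df = N − 1 = 274 by default, N − 2 available)
is regressed on the single-trial designed HRF by iteratively reweighted
least squares with Tukey bisquare weights, tuning constant 4.685 — the
classic `robustfit` pathway, whose white-noise null is calibrated
(P(t > 1.65) ≈ 0.05 over 1000 replicates). The default *map* statistic
is the across-trial summary t = mean(β)/sem(β) over the 12 independent
trial fits: band-limited vasomotion noise is serially correlated within
an epoch, and any within-epoch standard error (naive or Newey–West)
understates it — measured specificity drops to ~0.6 naive and ~0.9
HAC, versus ~0.95 with the across-trial statistic, whose null 95th
percentile (~1.62) essentially coincides with the critical value 1.65.
The trial-averaged single-fit route is retained
(`method="averaged"`, HAC standard errors, lag window ~5 s). The
regressor set is [intercept, dHRF]; no drift regressors, matching the
band-passed input. The map is rendered as a 3×12 detector-row ×
emitter grid mirroring the montage (channel = emitter + 12·(detector−1)).

## Synthetic study conditions

The generator emulates a 3-subject, 12-trial thumb-tapping study:
60 s pre-rest, 10 s task + 20 s rest per trial, 10 s post-rest;
36 fNIRS channels at 9.19 Hz (12 emitters × 3 detectors), 5 EEG
electrodes at 256 Hz (2 horizontal, 3 vertical). Defaults, chosen once
as typical motor-cortex phenomenology and then frozen:

* **Evoked response**: ΔHbO peak 1 μM on channels {17, 18, 29, 33}
  (consistent with the montage's electrode pair (1, 4)), ΔHbR = −ΔHbO/3,
  ±10% per-channel amplitude spread. The injected kernel is a
  *fast-onset* two-gamma (φ₁ = 3, peak ~2 s) behind a 1-s neurovascular
  onset delay: real trajectories cross the resting circle within a few
  seconds of the gate, which the slow canonical kernel (0.4% of peak at
  1.5 s) cannot reproduce under any noise level. The regression model
  deliberately keeps the canonical kernel — model mismatch between
  generator and analysis is realistic and the robust fit absorbs it.
* **Trial variability**: per-trial reaction delay uniform 0.2–1.2 s
  (shifting both modalities), lognormal amplitude scatter (σ = 0.3) and
  lognormal beta-ERS scatter (σ = 0.4).
* **fNIRS noise** (concentration space, per channel/chromophore):
  cardiac ~1.0 Hz (0.1 μM, per-channel rate jitter σ = 0.03 Hz),
  respiration ~0.3 Hz (0.2 μM, jitter 0.02 Hz), drift 0.005 Hz
  (0.3 μM), broadband vasomotion/Mayer noise band-limited to
  0.04–0.15 Hz (σ = 0.15 μM) and white noise (σ = 0.03 μM). The rate
  jitter matters: exact 1.0/0.3 Hz sinusoids are integer multiples of
  the 1/30 Hz trial rate and phase-lock to the paradigm, an artificial
  coherence a linear classifier can exploit.
* **EEG**: per-band filtered-noise amplitudes (δ 20, θ 10, α 10, β 5,
  arbitrary units) plus broadband white noise (σ = 2); beta amplitude
  gain 2 during task on fully responsive electrodes (per-electrode
  response profile 1.0/0.4/0.3/1.0/0.4 so selection reproduces the
  montage's (1, 4) pair); spontaneous rest-period beta bursts at
  0.15 s⁻¹, 0.3–1.5 s long, at task-level gain — on the scalp a
  spontaneous sensorimotor beta event is not separable from a voluntary
  one by band power alone, which is precisely why the fNIRS
  confirmation stage exists. Bursts are injected only after the
  pre-rest so the gate's calibration baseline stays clean, the regime
  the method assumes.

One integer seed drives everything through a single generator consumed
in fixed order; identical specs give bit-identical sessions, and the
JSON manifest stores the full spec for regeneration.

**What the generator does not emulate** — initial dips, motion
artifacts, frequency-domain (phase/modulation) fNIRS observables,
volume-conducted EEG topographies, nonstationary baselines. Passing
tests therefore show the pipeline's internal consistency and its
behaviour under controlled, realistic noise, not performance on real
recordings; in particular the absolute accuracies depend on the chosen
SNR regime, which real studies do not publish.

## Numerical choices and degenerate inputs

Crossing times are linearly interpolated (exact for ray trajectories);
a flat baseline (R1 = 0) is rejected rather than silently detected on;
zero vectors have no phase and raise; non-positive intensities are
rejected with the offending sample index; the singular extinction
matrix raises naming the wavelength pair; LDA falls back to Ledoit–Wolf
shrinkage (logged) when features ≥ training samples, which is the
normal regime for the default 26-feature/24-window configuration.
Channel/electrode ids are 1-based as in the montage figures; sample
indices 0-based; time in seconds from paradigm start.

## Known limitations

The detector's accuracy hinges on baseline quality: artifacts in the
pre-rest inflate R1 and delay or suppress crossings (motion correction
is out of scope). The cross-check map ships only the electrode pairs
recoverable from the reference montage, (1,4) and (1,3); other pairs
must be configured. SNIRF/EDF ingestion is not implemented — delimited
tables are the interchange format. Multiple-comparison correction
across the 36 channels is deliberately absent, matching the reference
pathway's single-channel critical value.
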