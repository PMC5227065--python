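# Methods

This note records the models, parameter choices and numerical decisions
behind `lamflow`, what the synthetic world does and does not emulate, and
what a green test therefore establishes.

## Signals and preprocessing

MUA is the envelope of high-frequency extracellular activity: band-pass
500 Hz–5 kHz, full-wave rectification, low-pass 200 Hz, resampled to 763 Hz
so MUA and LFP share one time base. All filters are 4th-order Butterworth
applied forward–backward (`sosfiltfilt`): the corner frequencies are the
published recipe, the filter design is ours, and the zero-phase choice
exists so that filtering cannot bias the latency estimates. Resampling is
polyphase with linear edge extension (`padtype="line"`); DC survives to
within the resampler's passband ripple (~1e-4 relative).

Channel quality control follows the evoked-SNR rule: the peak of the
trial-averaged response above the pre-stimulus mean, divided by the SD of
the trial-averaged pre-stimulus activity; channels with SNR < 3 are
excluded and their LFP replaced by linear interpolation in depth between
the nearest good neighbours (nearest-neighbour extension at the probe
ends), to avoid fabricating CSD artifacts. A hook for hardware
preamplifier amplitude/phase correction exists but is the identity: the
correction's transfer function is hardware-specific and not part of this
package.

## CSD estimation and its exact inverse

The CSD is the three-point second spatial difference of the laminar LFP,
scaled by −σ/h² with σ = 0.4 S/m and h = 0.2 mm (two contacts at 0.1 mm
spacing; h is configurable down to one contact). Channels within h of
either probe end get no estimate and are masked invalid rather than
zero-padded — zero-padding would fabricate sinks at the boundaries. No
spatial smoothing is applied.

The simulator generates LFP from a known CSD by inverting this operator.
With a step of k contacts the discrete operator splits into k independent
second-difference chains and therefore has 2k degrees of freedom; pinning
the potential at the first and last contact fixes two of them and the
remainder is resolved by the minimum-norm (pseudoinverse) solution. This
keeps the forward map linear and makes the roundtrip
`compute_csd(lfp_from_csd(C))` exact at interior channels to machine
precision — the oracle on which the CSD tests rest. For k = 1 the two
boundary values fix the solution completely.

Derived CSD statistics: the laminar template is the window-averaged
profile scaled so the strongest sink has weight −1; the nCSD is the inner
product of that template with the momentary CSD; the absolute CSD
modulation takes the time-mean condition difference per channel first,
then the absolute value, then the channel mean, so that sinks and sources
do not cancel. Per-penetration CSD normalisation divides by the maximum
absolute CSD across layers during the stimulus period of the
target-curve condition.

## Laminar alignment

The layer-4C/5 boundary is the polarity reversal from the early sink in
layer 4C (negative CSD above the boundary) to the return source in the
deep layers, read from the CSD averaged over 40 ± 10 ms after onset of a
full-field checkerboard. When noise creates multiple sign changes, the
transition at the deep edge of the contiguous sink run containing the
strongest sink wins — tie-breaking on the sink *run* rather than the
single strongest sample is what makes recovery robust when the sink
plateau is flat. The boundary is placed midway between the two straddling
contacts.

Compartments by depth relative to the boundary: deep 0.05–0.55 mm below,
layer 4 0.05–0.55 mm above, superficial 0.65–1.15 mm above; bands are
closed at the lower printed bound and open at the upper, so each depth
maps to at most one compartment and the 0.55–0.65 mm strip between
layer 4 and the superficial band, depths beyond the bands, and presumed
layer-6 channels below the deep band are left unassigned. Penetrations
are co-registered by integer channel offset on the 0.1 mm relative-depth
grid (channels sit at half-integer offsets from the boundary, so no
interpolation is needed) and averaged with per-depth counts.

## Metrics

MUA normalisation per site: subtract the spontaneous mean (−150–0 ms),
divide by the peak (max in 50–90 ms) of the site's trial-averaged
distractor response above baseline. Sites with a non-positive reference
peak are flagged invalid. Modulation values therefore read as fractions
of the visual peak. Latency is the earliest time the fitted
Gaussian + cumulative-Gaussian curve reaches 33% of its maximum above its
fitted offset; the fit is bounded least squares initialised from the
half-peak crossing (cumulative mean) and the raw peak (Gaussian mean),
and the crossing is located by bisection on the continuous model, so the
estimate is not quantised to the sampling grid. Band power integrates a
Welch periodogram (segments of half the analysis window, 50% overlap)
over the band; the analysis window defaults to the modulation window.
Receptive fields from moving-bar responses use opposing-direction
midpoints: response latency shifts onset/offset positions along the
direction of motion, so averaging the onset position from one direction
with the offset position from the opposite direction cancels the bias;
the centre is the least-squares intersection of the four axis centres.

Analysis windows (ms after stimulus onset): baseline −150–0, peak 50–90,
modulation 200–750, mask windows 450–550 and 650–750, capacity window
900–1150. All are configurable in `AnalysisWindows`.

## Statistics

Every test consumes one value (or one compartment triple, or one map) per
penetration; channels are averaged within a penetration first because
they share noise and would otherwise pseudo-replicate. Paired comparisons
use the exact Wilcoxon signed-rank test (normal approximation for large
n), cross-task comparisons the rank-sum test, and multiple comparisons a
Bonferroni factor.

The laminar ANOVA is a one-way repeated-measures ANOVA over the three
compartments (via `pingouin`). The Greenhouse–Geisser correction is
applied when Mauchly's test rejects sphericity (`gg_mode="mauchly"`, the
default) rather than whenever the sample epsilon falls below 1: under
true sphericity the always-on correction is measurably conservative
(type-I error 0.041 vs 0.048 at n = 10 in a 3000-run calibration), and
a correction "for deviations from sphericity" is naturally read as
conditional on such a deviation. The always-on variant remains available
as `gg_mode="always"`.

Profile consistency computes Pearson correlations over all N(N−1)/2
penetration pairs within a task, or the N matched pairs between tasks;
significance is a signed-rank test of the pairwise r against zero (the
pairs are not independent, so this follows the field's convention rather
than a strict exchangeability argument — the shuffle control, which
permutes the channels of one profile per pair, is the honest null). The
cluster test thresholds the across-penetration t-map at |t| > 2, scores
contiguous channel × time clusters by summed t, and builds the null from
random sign flips of whole penetrations; cluster p-values use add-one
smoothing and control the family-wise error. Threshold and permutation
count are config-exposed defaults, not published values.

Decoding trains a linear SVM (C = 1, features standardised per training
fold) on window-averaged MUA per site and scores ROC area from continuous
decision values on stratified held-out 10% splits, 10 repeats averaged.
Stratification is a choice (the original splits may not have been) and is
recorded on the result object.

Microsaccade detection: speed is the central-difference velocity
magnitude at 250 Hz, unsmoothed; the threshold is 5× the speed SD
computed over the whole trial by default (a pre-cue fixation epoch can be
passed instead via `baseline_slice`); runs of ≥ 5 suprathreshold samples
are events and any event excludes the trial.

## The synthetic world

The simulator is a stated world, not a dial. Its defaults:

- 24 channels, 0.1 mm spacing, LFP/MUA at 763 Hz, eye traces at 250 Hz,
  trials from −300 to 900 ms (1250 ms in the capacity task), 30 trials
  per condition.
- True boundary below channel 8 (the probe is placed so the reversal sits
  near the eighth contact); evoked CSD: sink across the layer-4 band,
  source across the deep band, Gaussian time course peaking ~55 ms.
- Modulation CSD (target condition only): sinks in the superficial band
  and upper deep channels (layer 5), weak return source in layer 4 —
  the feedback signature — with a task-independent amplitude, since the
  synaptic modulation is similar with and without the stimulus.
- MUA per channel: baseline 0.2, transient of height ~1 at the channel's
  latency (layer 4C and the deepest contacts at 40 ms, deep 48 ms,
  superficial 50 ms), sustained component 0.4 of peak (decaying with
  τ = 300 ms after stimulus offset in the memory-family tasks — the
  off-decay is a free parameter, not a published value), plus the
  compartment-specific modulation for targets: (superficial, layer4,
  deep) = (0.30, 0.10, 0.30) under attention and half that in the memory
  family. Adjacent-curve conditions get a weak (25%), delayed (+30 ms)
  transient and no modulation. The mask task adds a large transient at
  400–450 ms in both conditions and gates the modulation off over
  450–550 ms and back on by 650 ms; the capacity task delays modulation
  onset to the 900 ms cue.
- The modulation envelope equals exactly 1 across each task's analysis
  window (ramps complete outside it), so window means are unbiased
  estimators of the configured amplitudes.
- Noise: white Gaussian on the LFP (SD 0.02), zero-truncated white
  Gaussian on the MUA (SD 0.15), and a multiplicative per-penetration
  modulation gain jitter (SD 0.15, mean 1) that creates realistic
  between-penetration scatter. Eye traces are smoothed jitter around a
  small (<0.05°) lower-left bias, with optional injected 1° excursions.

What it does not emulate: spiking point processes (MUA is generated as a
rate envelope because the measured signal is itself an envelope), 1/f or
oscillatory LFP structure (band-power condition differences are not in
the stated world; `band_power` is validated on constructed tones and
noise), correlated noise across channels, eye-movement kinematics beyond
the injected excursions, and the actual magnitudes of real recordings.
A green recovery test therefore establishes correctness of the estimators
against this world's ground truth, not the published effect sizes, which
derive from unreleased recordings. One visible consequence: single-trial
decoding of the simulator's clean sustained modulation saturates near
accuracy 1.0, where real data yielded ~0.6–0.8.

## Calibration designs (frozen)

The null-calibration test uses 1000 simulations of 10 null penetrations
(8 trials/condition each): 10 penetrations because the exact signed-rank
test's attained two-sided size at n = 10 is 0.0488, the closest to the
nominal 0.05 among desk-scale n (the test is discrete; at n = 8 the
attained size is 0.039). Cluster maps are the valid-channel CSD
difference maps over the modulation window, decimated 8× in time, with
200 sign-flip permutations — sizes chosen for the CPU budget before the
criterion was run. The decoder's closed-form check (ROC area Φ(d′/√2)
for equal-covariance Gaussian classes) averages four independent data
sets per d′ because a single data set's ten held-out splits carry ~0.03
sampling noise at chance.

## Known limitations

- `lfp_from_csd` returns the minimum-norm potential; real potentials also
  contain components invisible to the second-difference operator, so LFP
  magnitudes are not biophysically meaningful (the CSD is).
- The polarity-reversal search assumes the early sink/source pattern is
  the dominant feature of its 40 ± 10 ms window; gross artifacts inside
  that window would need manual review, as in practice.
- `compute_snr` measures baseline variability on the trial-averaged
  trace; with very few trials the SNR estimate is itself noisy.
- The session container is an internal directory format (arrays + JSON
  sidecar + CSV trials); it is deliberately dependency-free rather than a
  standard archive format, and carries append-only provenance.
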