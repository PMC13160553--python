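# Methods

This note documents the models, parameters and numerical choices behind
`alphatag`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

An `EpochSet` holds a `trials × channels × samples` tensor with a uniform
time axis in seconds relative to cue onset (cue = 0 s; the default paradigm
presents the target at +3 s, with tagging active throughout the
cue-to-target interval).  Channel geometry is a 2-D `SensorLayout` on the
normalised head circle (Cz at the origin, equatorial ring at radius 1),
built at runtime from the idealised 10-05 montage for the packaged
64-channel 10–10 set.  Sensor adjacency is a distance threshold in layout
coordinates; the default `max_dist = 0.33` gives a median degree of 4 on
the packaged layout (the neighbourhood definition is a documented default,
not a claim about any particular recording system — template-based
adjacency would be an equally valid plug-in via `NeighborGraph`).

On-disk format: one zip container per participant with a JSON metadata
header, raw little-endian array payloads and a TSV behaviour table.
Round trips are bit-exact (fixed zip timestamps, so identical content is
byte-identical on disk).

## Synthetic cohort generator

Each trial is a sum of:

* **1/f background noise**, independent per channel, shaped in the
  frequency domain (`PSD ∝ 1/f^exponent`, default exponent 1) and scaled
  to unit standard deviation — all component amplitudes below are in units
  of the per-channel noise SD;
* **posterior alpha**: a sinusoid at `alpha_center_hz = 10` with a
  per-trial frequency jitter (`alpha_bandwidth = 2` Hz, uniform) and a
  per-trial random phase shared across channels, weighted by a Gaussian
  occipital topography; base amplitude 1.5, multiplied by the per-trial
  latent and, during the cue-to-target interval, by the per-condition
  `alpha_gain` (default auditory 1.3, visual 1.0, non-specific 1.15,
  ramping in 0.5–1.0 s after the cue);
* **tagged components**: 36 Hz (occipital topography, amplitude 0.7),
  40 Hz (fronto-central, 0.7) and their 4 Hz intermodulation (broad
  centro-posterior, 0.45), all *phase-locked* — the phases are drawn once
  per participant and reused on every trial — active during the
  cue-to-target interval, with the per-condition `tag_pretarget_gain`
  (default auditory 1.2, visual 1.0) applied over the final 500 ms before
  target onset.

Two transition choices matter numerically.  The pre-target gain ramps in
over 300 ms and the stimulus off-ramp is a 400 ms raised cosine *starting
at* target onset: abrupt amplitude steps are phase-locked broadband AM
splatter, and with 4 Hz between the tagged frequencies a sharp offset
leaks condition-dependent energy into every neighbouring band (including
the 43.5–44.5 Hz control band) inside the pre-target window.  With the
default ramps the residual leakage is ≈ 1% of the tag amplitude.

**Latent coupling.**  Per-trial amplitudes are log-normal,
`amp = exp(0.35 z)`, with the standard-normal latents drawn from a
Gaussian copula: `corr(z_alpha, z_tag) = 2 sin(π ρ_s / 6)` so that the
*Spearman* correlation between the alpha and tag amplitudes equals the
configured `coupling_rho` (default 0.4) regardless of the marginals; both
tag components share one latent, and the intermodulation latent is
correlated with it at 0.5.  Any monotone envelope read-out preserves the
injected rank correlation, which is what makes rank-based recovery
testable end-to-end.

**Behaviour.**  RT = 550 ms + condition offset (auditory −30, visual −45,
non-specific 0) − 40 ms × z_im + 35 ms if a distractor is present
+ N(0, 80 ms), floored at 120 ms; correctness is Bernoulli with
per-condition rates (0.75 / 0.90 / 0.82, minus 0.08 with a distractor).
The negative RT–latent slope makes trials with stronger pre-target
activity faster, and the condition offsets are large enough that the
attentional-benefit sign is recovered from 80-trial tables in nearly every
simulation.  No psychometric model is intended.

What the generator does **not** emulate: volume conduction and realistic
field spread (topographies are parametric Gaussians), eye movements and
artifacts, non-stationary noise, evoked transients at cue/target onset,
and any perceptual decision process.  Passing tests therefore show that
the *analysis machinery* is correct and calibrated under the assumed
statistical structure, not that the pipeline is robust to real-world EEG
artifacts.

Determinism: every output is a pure function of `(config, seed)`;
participant seeds and all stage seeds derive from one master seed via
`numpy.random.SeedSequence.spawn`.

## Filtering and envelopes

Band-pass kernels are differences of two Blackman-windowed sinc low-pass
kernels (unit DC gain each, so the band-pass has exactly zero DC response)
and are normalised to unit magnitude response at band centre.  Orders are
quoted at a 500 Hz reference rate and rescaled proportionally (kept even,
so the kernel stays symmetric and zero-phase application is exact).

Preset bands: 35.5–36.5, 39.5–40.5, 43.5–44.5 Hz (order 400 ≙ 0.8 s),
3.5–4.5 Hz (order 344) and 7.5–12.5 Hz alpha (order 276).  The tag and
control bands use 0.8 s kernels because components 4 Hz apart must be
isolated: the first spectral null sits at 3.75 Hz, leakage at ±4 Hz is
< 1%.  Short kernels favouring temporal resolution (order 116 at the tag
frequencies) are available via `band_preset(name, short_kernels=True)`;
direct evaluation of those taps shows ≈ 0.64 gain at ±4 Hz, i.e. heavy
mutual leakage between 36, 40 and 44 Hz — usable for fast envelope
tracking of a single band, unsuitable for the bleed-over control.  The
alpha preset is the 7.5–12.5 Hz filter specification; narrower presets and
a per-participant individual-alpha-peak centre are configuration switches.

Filtering is zero-phase: the symmetric kernel is applied with full group
delay compensation and mirror padding of half a kernel length at the epoch
edges.  The analytic signal is computed in the same FFT pass (negative
frequencies zeroed, linear-convolution-safe zero padding), in single
precision; `filter_array`/`apply_zero_phase` provide the time-domain
reference path, and the two agree to ~1e-7 of the signal amplitude.  Two
kernel half-lengths at each epoch edge are flagged as transient and are
excluded from statistics windows by default.

Evoked path: per trial, subtract the scalar mean of the filtered waveform
over the baseline window (−0.7 to −0.2 s before the cue), average the
corrected waveforms over trials, take the envelope.  (Subtraction of a
real constant commutes with the analytic-signal map, so this is computed
on the analytic signal directly.)  Induced path: envelope per trial, then
the trial mean; the per-trial envelopes are retained for the correlation
analyses.

TFR: Hanning-tapered sliding-window power, window length 3 cycles per
frequency, default 5–20 Hz in 0.5 Hz steps at 10 ms time steps, normalised
so a stationary amplitude-A sinusoid yields A²/4.  Normalisations:
relative change `(x − baseline)/baseline` and the bounded contrast
`Δ/∑ = (a − b)/(a + b)`.

## Cluster statistics

Pointwise one-sample t over participant difference maps (paired contrast)
or participant maps (one-sample/correlation contrast); two-sided p < 0.05
defines supra-threshold points.  Zero-variance points are flagged: t = 0
when the mean is also zero, otherwise a finite cap of sign(mean)·100 — a
point where every participant shows the identical nonzero value is
maximally significant, and the cap keeps cluster masses finite.

Clusters connect same-sign supra-threshold points sharing a channel at
adjacent time steps or neighbouring channels at the same time step, and
are *retained* only if at some time step they contain two channels that
are graph neighbours (the two-neighbouring-channels rule; whether the rule
gates cluster formation or retention is ambiguous in common usage, so the
stricter pointwise "formation" variant is available via `rule=`).

Surrogates: per permutation, each participant's condition pair is
independently swapped (paired) or the participant's whole map is
sign-flipped (one-sample); the surrogate statistic is the extreme retained
cluster mass, with permutations lacking any retained cluster contributing
mass 0.  Significance compares |mass| with the 95th percentile of the
per-permutation extreme |mass| over both tails (a two-sided max
statistic; measured family-wise error 0.05).  The per-tail convention —
positive masses against the 95th percentile of positive extremes and
symmetrically for negative — is available via `tails="per_tail"` but is
anti-conservative (~0.10 family-wise, two 0.05 tails) and is not the
default.  Per-cluster p-values use the add-one estimator
`(1 + k)/(1 + n_perm)`, which can never return zero.  When `n_perm`
exceeds the 2^n distinct sign patterns a warning notes that permutations
are drawn with replacement.

## Trial correlations and follow-ups

Seed values are per-trial means of the induced band envelope over the seed
channels × window; windows lying wholly inside the filter-transient region
are rejected.  Spearman correlation uses mid-ranks (average ranks on
ties); |ρ| = 1 is clipped to 1 − 1e-12 before the Fisher z-transform and
flagged.  Channels with zero rank variance are reported missing and enter
the group test as z = 0 (no evidence).  Correlation maps are computed
within condition; the interaction test is the paired cluster test on
per-participant z-differences.

Median split: trials with seed value ≤ median form the low half (ties go
low; odd counts leave the middle trial low).  Outlier exclusion for
participant-level statistics is a single pass dropping values more than
2 SD (full-sample mean and SD) from the mean.  Note an arithmetic
consequence of that convention: with n values the largest attainable
deviation is (n−1)/√n SD, so no point can ever be excluded from a
five-value set — the rule only bites for n ≥ 7.

The Bayes factor is the default-prior (JZS) BF10 for the one-sample t:
Cauchy prior on the standardised effect with scale √2/2 (configurable),
computed by adaptive quadrature over the Zellner–Siow g-mixture with a
(0, ∞) → (0, 1) substitution; non-convergence raises with diagnostics.
An independent oracle (noncentral-t integral over the Cauchy prior) agrees
to 1e-6 relative; the conventional evidence thresholds are 3.2
(substantial) and 10 (strong).

## Behavioural conventions

Accuracy is computed on all trials of a condition; RT statistics on
correct trials with 100 ms ≤ RT ≤ 1500 ms (strict "faster than"/
"exceeding" bounds, boundary values retained).  Whether accuracy
denominators should exclude RT-trimmed trials is a convention choice; here
they do not, and both bases are explicit in the outputs.  Chance level of
the three-alternative task is 1/3 (~33%), the participant-exclusion
criterion.

## Monte-Carlo studies (calibration, power, recovery)

Study sizes are fixed design choices: 160 Hz sampling, epochs −1.2…3.5 s,
n = 20 participants, 200 permutations per test; 200 datasets for null
calibrations, 50 cohort simulations for the power study (2 conditions ×
16 trials) and for the coupling detection rate at ρ = 0.4 (1 condition ×
40 trials; 12 simulations per remaining grid point, enough to order the
recovered mean z across ρ ∈ {0, 0.2, 0.4, 0.6}).

The paired-test null calibration draws participant-level condition maps
directly (trial-averaged Gaussian noise with mild spatial/temporal
smoothing): the family-wise error of the sign-flip scheme is a property
of map-level exchangeability, so waveform synthesis adds cost but no
information there.  The correlation-map calibration uses the generator's
copula layer at ρ = 0 plus envelope measurement noise on the component
topographies.  The power and coupling studies run the full waveform
pipeline: synthesis → filtering → envelopes → (correlation maps →)
cluster test.  The recovered coupling is summarised as the mean Fisher-z
over the posterior channel set, which is defined at every ρ including 0
(within-cluster means would be undefined when no cluster exists).

## Known limitations

* Sensor adjacency, seed channels and component topographies are
  idealised; no forward model or source-space stage exists.
* The evoked tag envelopes inherit the 0.8 s kernels' temporal smoothing
  (~±0.4 s), so pre-target gain steps appear low-passed in time.
* The per-trial correlation path assumes enough trials for rank
  statistics (≥ 5 hard floor; tens in practice).
* Effect sizes in the generator are chosen for detectability at n = 20
  participants and are not calibrated to any empirical dataset; absolute
  amplitudes are in noise-SD units, not microvolts.
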