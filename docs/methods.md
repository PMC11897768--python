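# Methods

`chirpcode` analyses single-unit responses to a full-field "chirp"
stimulus — the probe sequence used to characterise the diversity of
visual responses in retina and dorsal lateral geniculate nucleus (dLGN),
particularly in optogenetic vision-restoration experiments where a
channelrhodopsin is expressed either in ON bipolar cells or directly in
retinal ganglion cells. This note documents the models, conventions and
numerical choices; everything quantitative it mentions is computed by the
test suite or by `scripts/acceptance.py`.

## Stimulus

The chirp is a 30 s normalised-intensity sequence: a 3 s step from dark to
100%, 2 s dark, 2 s at 50%, an 8 s temporal chirp (full-contrast sinusoid
sweeping 1 → 8 Hz), 2 s at 50%, an 8 s contrast chirp (2 Hz carrier whose
Michelson contrast ramps linearly 3% → 97%), 2 s at 50% and 3 s dark.
Conventions: time in seconds, stimulus onset at t = 0, all intervals
half-open `[start, end)`; each sinusoid starts at phase 0 (value 0.5,
rising).

The temporal sweep is linear in instantaneous frequency,
f(t) = 1 + (7/8)·t Hz over the 8 s segment, accumulating exactly 36
cycles. A sweep rate of exactly 1 Hz/s cannot both start at 1 Hz and end
at 8 Hz over 8 s; ending at 8 Hz is the constraint we keep, since the
analysis bands run 1–8 Hz. Cycle boundaries are solved analytically from
the quadratic phase, so downstream per-cycle measures are independent of
the waveform sample rate (minimum 200 samples/s, i.e. ≥ 25 samples per
cycle at 8 Hz).

The contrast-ramp shape is not dictated by anything in the analysis;
linear in Michelson contrast is the convention of the Baden-style chirp
this design follows. Irradiance (log10 photons/cm²/s at 100% intensity)
is carried as metadata; the waveform itself stays in [0, 1].

## Synthetic populations

No recordings ship with the package, so every stage is validated against
a generative twin whose parameters are exactly the quantities the
pipeline estimates.

Expected rate:

    rate(t) = max(0, baseline + gain · Hill(I) · [w_on·D⁺(t) + w_off·D⁻(t)])

* **Step kinetics.** Each discrete luminance transition excites the ON
  (increments) or OFF (decrements) drive by its magnitude, decaying
  exponentially with `transience_tau_s` and terminating at the next
  opposite transition. τ → ∞ gives a sustained response; small τ a
  transient one. Drives are delayed by `latency_s`.
* **Sinusoidal segments.** The rectified positive/negative half-waves of
  the modulation feed the ON/OFF drives, scaled by a Naka-Rushton
  contrast gain (c50, slope) and a half-Gaussian gain in log2 frequency
  (peak TF, spread in octaves). The sinusoidal drive is not passed
  through the τ filter: that would impose an extra, frequency-dependent
  attenuation and conflate step kinetics with temporal tuning.
* **Irradiance.** Hill(I) = 1/(1+10^(slope·(EC50−I))) rescales the evoked
  (not spontaneous) response.

Spiking is an inhomogeneous Poisson process drawn by thinning against the
per-trial rate maximum, with candidate times accepted against a linear
interpolation of the rate series — the draw therefore does not depend on
the stimulus sample rate. Trial-to-trial reliability ρ mixes the
stimulus-locked rate with a flat rate of equal mean:
λ_t(t) = ρ·rate(t) + (1−ρ)·e_t·mean(rate), with e_t lognormal
(mean 1, σ_log = 0.6). ρ = 1 reproduces the same expected rate every
trial; ρ = 0 yields trials with no stimulus information; the quality
index increases monotonically in ρ (property-tested). A multiplicative
gain alone cannot produce the ρ = 0 limit, which is why the mixture form
is used.

Presets are mixtures of **discrete functional-type archetypes** with
small within-type jitter — the retina is organised into discrete cell
types, and that type structure is exactly what the downstream community
detection measures; drawing parameters from broad continuous
distributions would instead produce a clusterless continuum. `grm6_like`
(ON-bipolar-cell-driven) mixes eight types spanning ON, OFF and ON-OFF
polarity, transient to sustained kinetics, low-pass to high-pass temporal
tuning and contrast sensitivity from c50 ≈ 0.25 to 0.7. `brn3c_like`
(RGC-driven) concentrates in three ON types: sustained, 2 Hz bandpass,
low contrast sensitivity (c50 0.65–0.75), shorter latency (30 vs 43 ms
centres — the opsin sits one synapse later in the ON-BC case) and a
somewhat lower trial-to-trial reliability (0.5–0.85 vs 0.6–0.95), with
only residual OFF/ON-OFF units. `wt_like` is at least as diverse as
`grm6_like`. Baseline rates (1–5 spikes/s) and evoked gains
(25–60 spikes/s) sit in the range typical of spontaneously active
degenerate retina. Parameter-recovery studies run
at the high-gain end (gain 70 spikes/s, reliability 0.8, 10 trials;
baseline 5 spikes/s for the latency study) so that estimator error
reflects the method rather than floor effects of near-silent units.

What the generator does **not** emulate: correlated noise across units,
bursting/refractoriness, adaptation across trials, spatial receptive
fields, and any biophysics of the actuator. Passing tests therefore
demonstrate correctness and statistical calibration of the analysis, not
that real recordings satisfy the generative assumptions.

## Preprocessing and light responsiveness

PSTHs use half-open bins from stimulus onset; a spike exactly on the
window end is excluded. Units with < 10% of trial-summed 25 ms bins
containing spikes, or spikes in fewer than 8 trials, are excluded.

The light-responsiveness (LR) statistic is the mean pairwise Pearson
correlation between per-trial 25 ms bin vectors over the whole chirp;
zero-variance trials contribute correlation 0 (conservative against
responsiveness). The null circularly shifts each trial's bin vector by an
independent uniform offset — preserving within-trial rate and
autocorrelation while destroying stimulus locking (plain bin permutation
inflates significance for autocorrelated spike trains). Homogeneous
(stationary) firing is exchangeable under circular shifts, so
p = (1 + #{null ≥ observed})/(n_shuffles + 1) is valid; calibration is
verified empirically. The default 10 000 shuffles is the minimum
resolving the p < 0.0001 LR threshold. The null statistic for any shift
assignment is assembled from FFT-precomputed circular cross-correlations
of the standardised trials, so each shuffle costs one lookup per trial
pair; whether the statistic should instead correlate each trial against
the mean of the others is left as an alternative reading — the pairwise
form is the package default.

## Per-unit metrics

* **Response amplitude**: maximum trial-mean rate over the step and the
  3 s after it, minus the mean rate in the 2 s before onset. With trials
  presented back-to-back there is no pre-onset data at t < 0; the
  trailing dark segment ([28, 30) s) is the adaptation-matched surrogate
  and is the pipeline default. Hill irradiance-response fits take
  placement-averaged amplitudes (amplitudes averaged across a recording's
  units per irradiance) — four free parameters (top, bottom, slope, log
  EC50), multi-start bounded least squares.
* **Quality index** (200 ms bins): Var_time[mean_trials] /
  mean_trials[Var_time], population variances throughout (at these
  bin/trial counts the sample-variance variant is indistinguishable;
  population is fixed for determinism). 0/0 → 0. Between-condition QI
  comparisons can use `match_firing_rate`, a seeded greedy
  nearest-neighbour match on mean rate (caliper 0.25 pooled SD) with a
  Kolmogorov-Smirnov self-check on the matched sets.
* **Latency** (1 ms bins): trial-mean PSTH smoothed with a 10 ms boxcar
  applied forward-backward (zero-phase, so the filter itself does not
  delay the response); threshold = baseline mean + 2 SD of the smoothed
  300 ms baseline; latency = first bin in (0, 300 ms] above threshold,
  undefined if never crossed (OFF units). Zero-phase smoothing smears
  response onsets ~5–10 ms backward, a small negative bias intrinsic to
  the method and visible in the recovery study; the threshold crossing is
  also a noisy statistic when the baseline trace is sparse, which is why
  the recovery study uses units with appreciable spontaneous rate.
* **ON-OFF bias**: (ON − OFF)/(ON + OFF) spike counts in the 500 ms after
  step onset and offset; 0/0 → 0.
* **Transience**: trial-mean 25 ms PSTH normalised to its maximum over
  [0, 6) s (step plus 3 s after — using the step window alone would leave
  OFF units with a near-zero normaliser and an unbounded index); the
  index is the mean normalised rate over 1 s after onset (bias > −1/3) or
  after offset (bias < −1/3). In [0, 1].
* **Classification**: OFF below bias −1/3, ON-OFF within ±1/3, ON above,
  split transient/sustained at transience 0.5. The ±1/3 cut extends the
  OFF rule symmetrically; the transience cut is the scale midpoint. Both
  are config-exposed since the original objective criteria live in prior
  work and may differ in detail.
* Between-condition comparisons default to the sub-saturating irradiance
  whose mean amplitude is nearest 75% of maximum.

## Tuning curves

Per-cycle response amplitude is max − min of the trial-mean 25 ms PSTH
within analytically delimited cycles (latency cannot drift the windows;
each window spans one carrier period, so a phase-shifted response still
presents its full excursion).

* **Contrast**: 16 half-second cycles over the whole contrast chirp,
  normalised to the max − min amplitude in the 0.5 s before chirp onset
  (zero normaliser flags the unit out of fitting); contrast is the
  envelope at cycle midpoint. Naka-Rushton
  R(C) = bottom + (top−bottom)·Cⁿ/(Cⁿ + C50ⁿ), C50 ∈ (0, 1],
  n ∈ (0, 10]. Inclusion: r² > 0.5 and spiking in > 10% of the segment's
  bins.
* **Temporal frequency**: 36 cycles grouped into integer frequency bands
  (1–2 … 7–8 Hz) by each cycle's mean instantaneous frequency; band
  amplitude is the mean of its cycles, band frequency the mean
  instantaneous frequency (band centres are a config-switchable
  alternative). Half-Gaussian in log2 frequency with side-dependent
  baselines (spread is therefore in octaves), peak TF ∈ [1, 8] Hz.
  Inclusion additionally requires spread > 0.51 octaves. The fit
  parameterises the baselines as fractions of the peak amplitude so the
  curve is a genuine peak; otherwise the flexible five-parameter form can
  report an inflection of a monotone profile as "peak TF".

Both fits use bounded least squares from 5 seeded restarts; near-tied
solutions (within 0.1% SSE) resolve toward the lower C50 / peak TF.
Because profiles are normalised and both models carry free scale
parameters, fitted C50 and peak TF are invariant to uniform scaling of
the response — which is also why a multiplicative (Hill) change of
overall gain with background irradiance leaves C50 in place
("sensitivity normalization", verified as an acceptance property).

## Population code

Light-responsive units' trial-mean 50 ms PSTHs are cut into three
segments (step 0.5–4.5 s, temporal chirp 6.5–15.5 s, contrast chirp
17.5–24.5 s: 80/180/140 bins). Conditions are randomly downsampled to
the smallest condition's size (seeded) before clustering.

* **Sparse PCA**: components with exactly 5 non-zero time bins, extracted
  per segment by truncated power iteration on the Gram matrix with
  projection deflation, kept while explaining ≥ 1% of total variance.
  An exact-cardinality constraint is the point (penalised sparse PCA
  gives approximate support sizes), hence the hand-rolled power method.
  Per-segment extraction followed by concatenation matches the
  segment-wise construction; a joint mode over concatenated segments is
  the obvious alternative and intentionally not the default.
* **Consensus clustering**: 50 repeats of Gaussian-mixture fits
  (diagonal covariance, random initialisation, reg_covar 1e-4) for
  k = 1..k_max (default 20; the scan stops early after BIC worsens for 3
  consecutive k — BIC is convex in practice and this bounds runtime). k
  is the lowest-BIC model, accepting added complexity only when the
  approximate Bayes factor exp(ΔBIC/2) ≥ 6. Diagonal covariance is the
  default because full covariances on a few dozen sparse-PC dimensions
  carry more free parameters than there are units at realistic sample
  sizes, and BIC then degenerates to k = 1; the parameterisation is
  config-exposed. The similarity matrix is the exact co-assignment
  fraction across repeats.
* **Communities**: Louvain modularity maximisation on the
  similarity-weighted graph; the best-modularity partition over 20 seeded
  restarts is kept. Communities under 5 members are dissolved and their
  units marked unassigned (excluded from distribution tests).
* **Distribution test**: total variation distance between conditions'
  community proportions, null by permuting condition labels;
  p = (1 + #{null ≥ obs})/(n + 1). A chi-square statistic would serve
  equally; TV is kept for its direct "fraction of misallocated units"
  reading.

## Statistics and reporting

Group comparisons are two-sided Mann-Whitney U or Kolmogorov-Smirnov
tests (scipy, exact/asymptotic switching); within-unit paired designs use
Pearson correlation. No multiple-testing correction is applied; the
report records the number of tests run. Report output is deterministic:
ordered conditions/metrics, floats rounded to six digits.

## Problem sizes

Default studies are sized to run on a single CPU in minutes: recovery
studies use 40–100 units × 10 trials; LR calibration 500–1000 null units
at 2000 shuffles (the FFT construction makes shuffles cheap);
direction-level preset comparisons 150–300 units per condition with
k_max 10–12. These are the package's reference study sizes; all are
parameters.

## Known limitations

* The latency estimator inherits the negative bias and noise sensitivity
  of threshold crossing on a smoothed trace (see above); it is reported
  as the method defines it, not bias-corrected.
* The LR circular-shift null preserves autocorrelation but not slow
  nonstationarities across a trial; strongly drifting units can exceed
  the nominal false-positive rate.
* GMM consensus clustering with full covariances needs unit counts
  comfortably above the sparse-PC dimensionality; with fewer than ~5
  units per expected cluster the covariance regulariser dominates.
* Community identities are not aligned across datasets or conditions;
  only distributions over communities are compared.
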