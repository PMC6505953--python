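# Methods

`alphactf` implements a forward-and-inverted spatial encoding model for
working-memory EEG, together with the selectivity statistics, permutation
inference, behavioral mixture models, and synthetic-cohort studies needed to
interpret it. This note records the model, its assumptions, the parameters
that matter, and the design choices that were genuinely open.

## The encoding model

Band-limited power at each scalp electrode is modeled as a nonnegative
weighted sum of k = 8 spatial channels, one per 45° position bin. Channel
*c*'s response to a stimulus at angular distance *d* from its preferred
position is a half sinusoid raised to a power,

    r(d) = cos(d/2)^p,        p = 25 by default,

which peaks at 1 over the preferred position and falls to 0 at 180°. With
B (m electrodes × n measurements) the observed power, C (k × n) the
channels' predicted responses, and W (m × k) the weights, the generative
assumption is B = W C. Training estimates the weights by ordinary least
squares, Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹; testing inverts the mapping on held-out data,
Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂. These closed forms define the *value*; the public
`train_weights`/`invert_model` compute them through QR-based least-squares
factorizations, and the batched routines solve the (well-conditioned, since
the circulant channel design keeps C₁C₁ᵀ far from singular) normal
equations with stacked Cholesky solves.

Measurements are bin averages. Trials are randomly partitioned into three
sets with equal trial counts per position bin (per condition where
applicable); each set's trials are averaged within bin; two sets train and
one tests, rotating so every set tests once. Estimated channel-response
profiles are circularly shifted so the channel tuned to the probed bin sits
at offset 0 — offsets defined as (channel center − probed center) mod 360,
mapped to (−180°, 180°], with +180° its own fold partner — and averaged
over bins, folds, and partition iterations. Excess trials beyond the
largest common per-cell count are left out of a given iteration;
re-randomized iterations recycle them (50 is a customary single-band
default, 10 for frequency sweeps; both are config knobs).

Three training regimes are provided. *Condition-neutral* training combines
equal trial counts from every condition before averaging, so a single model
serves all conditions' tests — the regime required whenever selectivity is
compared across conditions, because a shared model removes
model-estimation differences from the contrast. *Within-condition* trains
and tests each condition separately (maximally sensitive per condition,
but its cross-condition contrasts are confounded by the training data).
*Cross-training* trains on one-item data and tests on two-item data, which
underlies the inter-item distance profiles.

## CTF slope

The aligned 8-point channel-tuning function (CTF) is folded by averaging
channels equidistant from offset 0 (±45°, ±90°, ±135°), yielding five
values at distances 180, 135, 90, 45, 0. Selectivity is the OLS slope of
those values, ordered by decreasing distance, against the unit-spaced ranks
1…5. The x-axis is rank, **not degrees**: slope values are therefore
scale-free and directly comparable with delay-period values in the
0.06–0.09 range reported for real alpha-band data. A perfectly tuned
noiseless CTF with p = 25 has slope ≈ 0.2138. The slope operator is linear
in the profile.

## Spectral stage

Epoched voltage data are band-pass filtered per trial and electrode with a
zero-phase (two-pass) Hamming-window FIR filter of order ≈ 3 × (sampling
rate / low cutoff) — the behavior of the classic two-way least-squares FIR
routine used throughout the EEG literature — then the analytic signal is
taken with a Hilbert transform and instantaneous power is its squared
magnitude. Downsampling (default 1 sample per 20 ms) keeps every k-th
already-computed power sample, so retained values are an exact subsequence
of full-rate power. Samples within one filter length of an epoch edge are
flagged (`n_edge`) rather than silently trusted. Frequency sweeps cover
1-Hz bands from 4 to 50 Hz. Baselining of raw recordings is an
acquisition-side concern and is a no-op for synthetic input.

## Inference

Selectivity above chance is tested with a cluster-based permutation test:
a one-sample t against 0 at each time (or time × frequency) point;
contiguous suprathreshold points — 1-D adjacency in time, 4-connectivity
in time × frequency (8-connectivity was a defensible alternative; 4 was
chosen as the more conservative and is configurable at the call site by
relabeling) — form clusters scored by summed t. The null distribution of
the maximum cluster mass comes from re-running the IEM with position
labels shuffled within every training and test set (preserving set sizes);
clusters beating the 95th percentile are significant (one-tailed,
family-wise α = 0.05). The threshold is recomputed from the cohort size
(t = 1.703 at 27 df) rather than hard-coded. Zero-variance points are
treated as sub-threshold. Window contrasts (e.g. 250–1,250 ms and
800–1,250 ms after stimulus onset) use two-sided paired t tests on
window-averaged per-subject slopes, reported raw (no multiplicity
correction across the two planned windows).

## The switching-account null

If only one of two stored items is neurally active at a time, each item is
active at most ~50% of trials' time on average. The expected CTF under
that account is simulated from one-item data by redrawing the position
labels of a random 50% of one-item trials before each IEM run (labels
redrawn uniformly over all 8 bins; a redraw may coincide with the truth;
re-randomized each iteration). Two routes are provided:

* `simulate_switching` — the scrambled one-item data alone through the
  standard pipeline;
* `run_switching_analysis` — the comparison design: one shared
  condition-neutral model trained on equal trial counts from the two-item
  and simulated-switching conditions, tested on each separately, so the
  two-item vs switching contrast isolates test-content differences.

A subtlety worth recording: on *noiseless* data the one-item-only route
shows essentially **no** attenuation. The scrambled trials enter the
training averages too, so the fitted weights absorb the attenuation
((1−f) on the tuned component plus a flat lift), and inverting that model
rescales the equally attenuated test pattern back — algebraically,
Ĉ₂ = M⁻¹C̃₂ with M → (1−f)I + (f/8)11ᵀ, whose tuned-direction gain
cancels. One might instead expect the slope to scale by (1−f) (the
test-content attenuation; scrambled trials contribute an exactly flat
expected profile, the 1/8 label-coincidence mass being part of that flat
average) — that holds only if training labels are left intact. In the
noisy regime the picture inverts: noise dominates ŴᵀŴ, the rescaling is
suppressed, and the attenuation compounds, so the simulated-switching
slope falls *below* (1−f) times the one-item slope. This regime dependence
is why the shared-model comparison route exists: with byte-identical
training for both test conditions, a strict-alternation ground truth
yields two-item ≈ switching (paired |t| < 2 in ~90%+ of 28-subject
cohorts) while concurrent storage at 75% amplitude per item yields
two-item > switching essentially always — the contrast the null is for.

## Behavioral mixture models

Continuous-report errors (signed degrees in (−180°, 180]) are fit by
maximum likelihood with a two-component mixture — a von Mises centered on
the target (precision reported as circular SD via the standard
concentration↔circular-variance relation; higher SD = lower precision)
plus a uniform guess component (height `p_guess`) — and, for two-item
trials, a three-component mixture adding a von Mises of the same
concentration centered on the unprobed item's offset (`p_swap`).
Optimization is multi-start (a 5 × 3 (× 2) grid over starting SD and
weight logits) BFGS over an unconstrained parameterization: log κ, and
mixture weights through a softmax, so non-negativity and the simplex
constraint hold by construction. κ is capped at the value for a 0.5°
circular SD so the likelihood stays finite on degenerate samples;
non-convergence is flagged on the result, not raised. At n = 5,000 trials
the three-parameter fit recovers (SD 6°, p_guess 0.1, p_swap 0.2) within a
few percent.

The same-bin analysis compares per-subject mean |error| relative to the
probed vs the unprobed item, restricted to two-item trials whose items
share a bin (optionally < 10° apart), with a paired t — the behavioral
check that observers store both nearby items rather than one merged or
sampled location.

## Synthetic data

The generator emulates the spatial delayed-estimation task: 8 bins of 45°,
exact counterbalancing of the 64 ordered two-item bin pairs, uniform jitter
over the wedge (the maximum-entropy choice consistent with covering all
360°; `jitter_width` = 0 pins trials to bin centers for exactness tests),
and a minimum two-item separation of 4.6° of angular position (0.2° of
visual angle between item centers on a 4°-radius circle; a config knob,
waived when jitter cannot satisfy it). Electrode data follow the forward
model exactly: per subject one weight matrix W (30 × 8, entries uniform on
[0, 1] — a subject has one head, so W is shared across conditions), channel
responses evaluated at each trial's exact position, two-item responses
summed (representations assumed additive; optionally scaled by an
amplitude factor, or replaced by a strict single-item alternation), plus
i.i.d. Gaussian electrode noise with a per-condition SD. The time-resolved
fixture embeds this signal only inside a stated window on an otherwise
pure-noise epoch, giving the cluster test a ground truth.

What the generator does *not* emulate: 1/f background spectra, volume
conduction structure (weights are i.i.d. rather than spatially smooth),
artifacts, eye movements, trial-to-trial amplitude variability, or any
temporal dynamics inside the tuning window. Passing tests therefore
establish the estimator's statistical behavior under its own generative
assumptions, not performance on real recordings.

## The simulation studies

Three canonical cohort studies characterize the estimator (28 subjects,
576 trials per condition, 30 electrodes, p = 25, condition-neutral
training): equal noise (SD 1) and equal amplitude in both load conditions
(a type-I-error calibration of the paired-t load comparison — the second
item's counterbalanced representation acts as noise but must not bias the
probed item's reconstruction); two-item noise SD 2 vs one-item SD 1
(noisier data must widen, not shift, the selectivity sampling
distribution); and a 0.9 amplitude scale on the two-item channel responses
(a true 10% selectivity cut that the estimator must detect). Each sample
runs the full per-subject IEM and a paired t (two-sided, with the
significant tally split by direction); 10,000 samples approximate the
sampling distributions. Expected outcomes: ≈5% significant in the first
two studies, 100% (two < one) in the third, and lower mean slopes in the
second study than the first because its training sets carry more noise.

Two execution routes compute the identical estimator. The literal route
generates per-trial electrode data and runs the general `run_iem`. The
default vectorized route exploits two exact reductions: (i) the IEM
consumes only set-wise bin means, and i.i.d. Gaussian electrode noise
enters those means only through averages, so each group's noise mean is
drawn directly from its exact distribution N(0, SD/√n_group); (ii) trials
within a bin are exchangeable, so a uniformly shuffled within-bin order
followed by contiguous splitting is a uniform random partition. Everything
else — exact jittered positions, separation constraint, counterbalancing,
training solve, inversion, alignment, folding, slope, paired t — is
computed explicitly, vectorized across subjects. A test checks the two
routes agree in distribution (means, dispersion, and a two-sample KS on
the per-sample t). The vectorized route uses a single partition iteration,
which loses nothing here: the fully counterbalanced design leaves zero
excess trials for additional iterations to recycle. Single precision is
used for the trial-level channel-response evaluation (the quantities are
immediately buried in unit-scale noise); all linear algebra is double.

## Numerical and degenerate-input choices

- Training designs are rank-checked; rank deficiency raises an explicit
  error naming the failure (no silent pseudo-inverse fallback).
- Fewer electrodes than channels is rejected at entry.
- Zero-variance points in the cluster test get t = 0 (sub-threshold).
- Paired comparisons with numerically zero within-pair variance report the
  sign-appropriate infinite-t limit (p below floor) rather than NaN.
- The basis evaluates predicted responses at **bin centers** for training
  (measurements are bin averages; the generator alone knows exact angles).
  Using mean within-bin angles instead would be nearly identical by
  symmetry; centers are the simpler convention.
- All randomness flows through one seeded generator per run; cohort
  samples use spawned child seeds, so they are independent,
  order-invariant, and a shorter run is a prefix of a longer one.

## Problem sizes used by the shipped checks

The test suite exercises the three study configurations at 1,000 samples
each (the binomial 95% band around a true 5% rate at n = 1,000 is roughly
3.5–6.6%), route-equivalence at 80 samples of 8-subject cohorts, cluster
calibration with 500 null runs × 400 permutations, switching comparisons
over 12 cohorts of 28 subjects with 192 trials per condition, and mixture
recovery over 20 seeds at n = 5,000. `scripts/acceptance.py` runs the
three studies at the full 10,000 samples. These sizes are the package's
default desk-scale choices; every count is a parameter.

## Known limitations

- The IEM assumes the basis matches the (unknown) true tuning; the studies
  generate data from matched tuning. Broader or mismatched tuning changes
  absolute slopes (though reportedly not the studies' qualitative
  conclusions) and is exposed through `basis_exponent`.
- The switching null's attenuation factor is noise-regime dependent (see
  above); conclusions should rest on the shared-model comparison, not on
  the raw scrambled-pipeline slope.
- Real-data effect sizes require the original recordings; the package
  ships the I/O (HDF5 power + CSV trials) and the full analysis path, but
  no claims about real-data values are tested.
- The behavioral fits are MLEs; no posterior uncertainty is reported.
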