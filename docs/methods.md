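# Methods

`mswtk` re-implements, as a tested pipeline over synthetic data, the
analysis chain used to study reliability-weighted audio-visual integration
in a two-interval rate-discrimination task: psychometric weight
estimation, time-resolved perceptual weights from accumulated evidence,
single-trial EEG discriminant decoding, neural sensory weights, and the
permutation statistics that connect them.  This note documents the models,
the generator that stands in for human data, the numerical choices, and
what the tests do and do not establish.

## Task and stimulus model

A trial presents a 900 ms stream of 12 ms events (clicks and/or flashes)
at a nominal rate of 8–14 Hz, followed by an 11 Hz standard stream; the
observer reports which stream had the higher rate.  Consecutive events are
separated by pauses drawn from {48, 96} ms.  Because 48·n_s + 96·n_l =
900 − 12·R has no exact solution for every rate R, streams are only
required to *fit inside* the window: internal pauses are drawn i.i.d. and
the sequence is accepted iff it fits (making accepted sequences uniform
over the feasible set); with probability 1/2 the stream opens with a drawn
pause, otherwise the first event starts at t = 0; the remaining tail is
silent.  Audio-visual streams are congruent (Δ = 0) or carry a ±2 Hz
visual−auditory conflict; conflict trials are labelled by the *average*
rate, so the auditory/visual streams hold average ∓1 events.  Equal-rate
trials (nominal = 11 Hz) occur at 2% per condition, carry random feedback
and no decoder class label.  The evidence variable used everywhere
downstream is the accumulated rate: counts of event onsets before t, on a
12 ms grid (75 points for a full stream).

## Observer model (behavioural generator)

Internal rate estimates are Gaussian around the true rates, r̂_A ~
N(r_A, σ_A) and r̂_V ~ N(r_V, σ_V(reliability)); audio-visual estimates
combine as w·r̂_A + (1−w)·r̂_V; the response is "first higher" iff the
estimate exceeds an internal criterion (11 Hz by default), flipped with a
small lapse probability.  Noise lives on the rate axis in Hz, so the
cumulative-Gaussian threshold fitted downstream estimates σ directly and
the whole psychometric stage is a closed-loop recovery test.  Default σ
values (2.19, 2.87, 4.55 Hz for auditory, visual-high, visual-low) and
true weights (0.80/0.84, i.e. an auditory bias above the optimal weight)
match typical human performance on this task.  Under this observer the
PSE of conflict conditions is 11 + Δ(w − ½), so the PSE-shift weight
formula returns exactly w — which is what the recovery tests exploit.

## Psychometric stage

Per condition, P("first higher" | rate) is fitted with a fixed-lapse
(λ = 0.01, configurable) cumulative Gaussian by maximum likelihood
(L-BFGS-B on (μ, log σ); perfect separation is flagged when σ pins its
lower bound).  Uncertainty comes from a nonparametric bootstrap over
trials (2000 resamples by default).  Predicted auditory weights use the
unisensory thresholds, w = σ_V²/(σ_A² + σ_V²); observed weights use the
conflict-trial PSE shifts, w = (μ_AV(Δ) − μ_AV(0) + Δ/2)/Δ, averaged over
Δ = ±2; visual weights are 1 − w.  Calibration-block reliability
selection inverts a guessing-floor psychometric curve over SNR, returning
the SNR matching auditory performance (high) and 30 percentage points
below it (low).

## Time-resolved perceptual weights

On conflict trials only, choice is regressed at each time point (12 ms
grid, 24–600 ms; earlier points are all-null, later ones nearly
collinear) on the z-scored accumulated auditory and visual counts with a
logistic model (joint model with both modal regressors; ridge 1e-6 for
stability).  Performance is the ROC area (Az) of pooled held-out
probabilities under stratified 10-fold cross-validation.  Weights are
normalised as w = β/(|β_aud| + |β_vis|): this equals the usual
β/(β_aud + β_vis) whenever both coefficients are positive (those points
are flagged), but stays defined and scale-free when a coefficient dips
below zero, which keeps the across-subject analyses usable; raw β values
are stored alongside.  The reliability influence is
D(t) = [w_aud − w_vis](high) − [w_aud − w_vis](low).  Note the regression
on accumulated counts attenuates weights relative to the generating
combination weights (counts are an error-prone proxy for rate), so
auditory dominance appears compressed relative to the generator's 0.8 —
a property of the method, not a bug.

## EEG generator (artifact-side)

The study this emulates *measures* neural weights; it has no generative
EEG model, so the forward model here is explicitly an artifact-side
construction.  Per trial, each modality's event train is convolved with a
causal gamma-shaped kernel (unit peak at 100 ms, FWHM 50 ms), delayed by
the modality latency (visual 90 ms, auditory 160 ms), scaled by a
reliability-dependent gain, mixed into 64 channels through fixed
unit-norm topographies, and summed with Gaussian noise that is white in
time and exponentially correlated across the channel index.  Defaults:
gain_vis drops to 0.45 and gain_aud rises to 1.5 under low visual
reliability (the phenomenon under study), and noise_sd = 0.4, chosen so
single-subject decoding lands in the Az ≈ 0.55–0.6 range typical of human
EEG on this task.  Epochs span −200…800 ms at 200 Hz (−100…460 ms in the
scaled experiments; everything analysed lies in 24–455 ms).  What this
generator does *not* emulate: volume conduction from realistic head
geometry, 1/f spectra, eye/muscle artifacts, latency jitter, or any
nonlinearity — so passing tests show the *pipeline* recovers what a
linear mixture encodes, not that real EEG behaves this way.

Across-subject heterogeneity draws a latent u_s per subject: the
behavioural weight shift w_low − w_high ~ 0.05 + 0.30·u_s (wide spread,
with a sizeable minority shifting opposite to the optimal direction, as
human data show), and — in the "coupled" regime — the same latent scales
the subject's reliability gain changes (visual drop 0.50 + 0.45·tanh u,
auditory rise by the same amount), so behavioural and neural reliability
influences share a common cause.  The "decoupled" regime uses an
independent latent for the neural side.

## Decoding and neural weights

Rate decoding (above vs below 11 Hz) uses regularised LDA on channel data
averaged in 55 ms windows aligned to the window onset, stepped at 5 ms
over 24–600 ms (12 ms steps in the scaled experiments).  Weights solve
Σ̂ w = m₁ − m₀ with Σ̂ = (1−γ)S + γ(tr S/p)I; γ is the analytic
Ledoit-Wolf intensity by default (floored at 1e-6 so the solve stays
defined on rank-deficient data) with a fixed-γ override, and the offset
centres Y at the class midpoint.  Models are trained on congruent
audio-visual trials only and applied to all trials at the same time
point.  The forward model is the activation-pattern estimate
a = Xᵀy/(yᵀy) per channel and window (a channel equal to Y gets a = 1;
zero-variance channels are flagged NaN); on noiseless data it recovers
the generative mixing vector up to scale, which a plain Pearson
correlation would not (correlation is scale-blind on rank-1 data).

Neural weights regress Y at each time point (24–400 ms window; the
wider 24–600 span is configurable) on the z-scored accumulated counts of
conflict trials, per reliability condition, by OLS with intercept (ridge
only as a fallback above condition number 1e6).  No sum-to-one constraint
is applied.  Because the discriminant scale is arbitrary (it depends on
the shrinkage solve), Y is standardised across the regression trials at
each time point — one scale factor shared by both reliability conditions,
so within-subject contrasts are untouched while weights become comparable
across subjects.

## Statistics

Paired subject × time contrasts use cluster-based permutation: pointwise
paired t, fixed cluster-forming threshold |t| > 1.8 (used verbatim, not a
df-dependent quantile), minimum cluster size 2, cluster statistic =
number of supra-threshold points (size), null = maximum cluster size
under within-subject sign flips (1000 randomisations by default),
p = (1 + #{null ≥ obs})/(1 + n_perm).  Positive and negative runs form
separate clusters against a common null.  NaN time points count as
sub-threshold, so isolated undefined estimates break clusters rather than
abort.  Correlation time series (neural vs behavioural reliability
influence across subjects, Spearman) use the same clustering with the
null permuting the subject pairing once per randomisation, preserving
temporal autocorrelation.  Decoder significance uses the max-statistic
correction: the (1−α) quantile of the null maximum over time under label
shuffles (2000 by default, α = 0.01).  Wilcoxon signed-rank tests report
the normal-approximation Z and the effect size r = Z/√N with N the number
of observations.  One known property: with strongly autocorrelated
series the max-*size* cluster statistic saturates (a lucky permutation
produces a full-width cluster), so p-values bottom out around the
probability of that event; the calibration tests confirm the procedure
stays conservative.

## Scaled experiment sizes

The recovery experiments run at deliberately chosen problem sizes: onset
ordering uses 5 studies × 20 subjects × 360 AV trials; the coupled study
uses 20 subjects × 2000 trials (close to the ~2000 trials/subject a real
session stack yields — per-subject weight estimates are too noisy for
across-subject correlation below roughly half that); decoupled
specificity uses 20 studies × 12 subjects × 600 trials (the false-positive
rate of the cluster test does not depend on per-subject precision);
calibration uses 200–300 null datasets at 200 permutations.  The
neuro-behavioural coupling analysis correlates the *psychometric* scalar
reliability influence 2(w_high − w_low) with the neural D(t) series: the
PSE-based weights are far more precise per subject than per-time-point
logistic weights, and the correlation utility accepts either form.

## Known limitations

- The EEG generator is linear and stationary; latencies are fixed, not
  distributions, so "onset ordering" recovery is easier than in real data.
- Normalised time-resolved weights are ratio estimates and noisy wherever
  both β are near zero (early in the trial); those points are flagged, and
  group analyses should prefer later windows or the raw β series.
- The fixed-lapse psychometric fit mildly biases σ when the true lapse
  differs from λ = 0.01; λ is configurable.
- The max-size cluster statistic discards t-value magnitude; summed-mass
  statistics would have more power for short strong effects but are not
  what this pipeline specifies.
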