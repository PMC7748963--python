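# Methods

This note documents the models implemented in `stopsense`, the design
decisions taken where a convention had to be fixed, the synthetic-data
generator's construction, and the package's known limitations.

## Stop-signal task and SSRT estimation

Sessions follow the standard mobile SST design: 80 trials, 75% go, 1500 ms
trial interval, go stimuli L/R equiprobable, seeded uniformly random trial
order. The one-up-one-down staircase starts at SSD = 250 ms and moves by
25 ms — up after a successful stop, down after a stop failure — clamped to
[0, 1250] ms so the stop signal always fits inside the trial interval.
Under the independent race model this staircase is a stochastic
approximation to the delay where p(respond | signal) = 0.5, which the
package verifies empirically (5,000 tracked stop trials yield a stop-failure
proportion within 0.02 of 0.5).

The simulated responder draws go finishing times from an ex-Gaussian
(Normal(μ, σ) + Exponential(τ); defaults 400/50/100 ms, a typical choice RT
distribution) and stop finishing times from Normal(SSRT, σ_stop). A
response occurs on a stop trial iff `T_go < SSD + T_stop`. Go omissions
(default 2%) and choice errors (default 2%) are injected independently;
go finishes beyond the trial interval count as omissions.

The integration estimator computes, per distinct SSD, the stop-failure rate
`p` and the `100·p`-th percentile of the correct-go RT distribution
(correct responses only; percentiles by linear interpolation between order
statistics). The SSD at `p = 0.5` is found by linear interpolation over the
SSD-sorted `(SSD, p)` pairs; if the curve is non-monotone the first
crossing in ascending SSD order is used, and if no pair brackets 0.5 the
session is flagged not estimable. The headline estimate is
`SSRT = RT_50 − SSD(0.5)`; the per-SSD `n`-th RTs are retained as auxiliary
output. The estimator is translation-equivariant: shifting all go RTs by Δ
shifts the estimate by exactly Δ (up to float round-off in the percentile
arithmetic, < 1e-9 ms; tests assert at that tolerance).

**Exclusion.** A session is dropped if its overall stop-failure rate falls
outside [0.25, 0.75] *or* its SSRT falls outside [50, 1500] ms *or* it is
not estimable. The union reading was chosen deliberately: requiring both
conditions simultaneously would retain sessions with absurd estimates,
contradicting the purpose of the screen. Boundary values are retained.

## Sensor feature extraction

All analysis windows are half-open hours `[t−1h, t)` anchored at the prompt
time `t`; an event stamped exactly at a window end belongs to the next
window, so nothing is double-counted. Conventions the source protocol
leaves open are fixed as follows:

- **Session clipping.** Phone-use sessions spanning a window edge
  contribute only their in-window portion to duration statistics but count
  once toward burstiness if that portion is nonempty (preserves the
  window's time budget).
- **Short sessions** use a strict `< 30 s` threshold.
- **Battery discharge rate** is reported as a positive drain magnitude
  (level units/s), so "faster drain" reads as a larger value; rates are
  means over consecutive same-charging-state sample pairs.
- **Sampled-state streams** (activity labels, network state) persist until
  the next sample, truncated at window edges and capped at 15 minutes;
  longer gaps are unlabeled time excluded from share denominators.
- **Similarity metrics** (Jaccard, Dice, second Kulczynski, Ochiai) operate
  on category/SSID presence sets; both-empty pairs are missing, one-empty
  pairs are 0. The binary-vector formulation is equivalent to the set form.
- **Points of interest** come from an offline venue table; membership uses
  haversine distance with a strict 50 m radius.
- **Sleep** is inferred per noon-to-noon frame as the longest phone-free
  gap of at least 3 h between sessions that overlaps the 9 PM–11 AM span;
  onset is the end of the last use before the gap, offset the start of the
  first use after. The exact published inference procedure is not specified
  at this level of detail, so the longest-gap rule is a documented
  stand-in; the 3 h floor prevents daytime prompts gaps from masquerading
  as sleep. Per participant, durations outside mean ± 2 SD are replaced by
  the nearer boundary.
- **Timezone** is a single configurable zone per participant (default UTC);
  hour-of-day and weekday features need the convention and the data carry
  no zone information.
- **Missing values** are NaN throughout; nothing is imputed at extraction
  time, and models use complete cases.

## HRV features

A window qualifies if it contains at least 5 minutes of continuous beats
(no inter-beat gap above 3 s). Beats outside [300, 2000] ms or differing
more than 20% from the previous accepted interval are flagged and replaced
by a cubic spline over beat index; if more than 20% of beats are flagged
the window is rejected. The bounds and the 20% criterion are configurable
— they are conventional artifact-correction settings, since the cleaning
rule is standard practice rather than a fixed published algorithm.

Time-domain features use sample (n−1) standard deviations throughout. The
triangular index uses the conventional 7.8125 ms (1/128 s) histogram bins.
SDANN partitions the recording into consecutive 300 s segments and needs
at least two. Spectral features report relative LF (0.04–0.15 Hz) and HF
(0.15–0.4 Hz) power, normalized by total 0.04–0.4 Hz power (the LF+HF
alternative differs only through VLF content, which the 0.04 Hz floor
removes). Three estimators are provided: Welch/FFT on a 4 Hz cubic-spline
resampled, mean-detrended tachogram (120 s segments, 50% overlap);
Lomb–Scargle directly on the uneven beats; and a Burg autoregressive
spectrum of order 16 on the resampled tachogram — standard short-term HRV
settings. All three agree on the dominant band for single-tone synthetic
series.

## Questionnaires

The six momentary items (0–6 Likert) are aggregated by inverting the three
negatively worded items (`x → 6 − x`) and summing, giving 0–36 with higher
= better self-reported control. The trait baseline is the plain sum of the
six BIS-11 items loading on the second-order self-control factor; the
default item set {1, 7, 8, 12, 13, 14} follows the published factor
structure and is configurable, since the exact subset used in any given
study is rarely reported. No reverse scoring is applied inside the subset
by default.

## Longitudinal models

- **VIF pruning** iteratively removes the highest-VIF feature until all
  VIFs are ≤ 5 (configurable); ties break alphabetically for determinism.
- **GEE**: Gamma family with log link (guarantees positive predictions and
  gives coefficients a multiplicative reading), exchangeable working
  correlation (the natural default for subject-clustered momentary
  designs), participant clusters. With only ~12 clusters the usual
  sandwich-variance z-tests are anti-conservative, so the package uses the
  Mancl–DeRouen bias-reduced sandwich estimator with a t reference on
  n_clusters − 1 degrees of freedom; simulation at the study's design size
  (12 × 90, five null features, 200 replicates) puts the empirical type-I
  error at ~5% where the uncorrected combination sits near 10%.
- **rmcorr** uses the ANCOVA formulation (outcome on predictor plus subject
  indicators); `r = sign(slope)·√(SS_x/(SS_x+SS_err))`,
  df = N − n_subjects − 1, t-referenced p, Fisher-z confidence interval.
  The implementation is cross-checked against an independent published
  implementation to machine precision.
- **State labels**: per participant, sessions strictly above the median
  SSRT are labeled low-control (positive class); ties go to high-control.
- **Classifiers**: gradient-boosted trees (200 trees, depth 3, learning
  rate 0.1, fixed seed — unremarkable defaults, as no reference settings
  exist), features z-standardized with training-fold statistics only.
  LOSO holds out one participant per fold; the mixed scheme moves the
  chronologically first ⌈fraction·n⌉ of the held-out participant's sessions
  into training (chronological rather than random, respecting deployment
  ordering) and evaluates on the remainder only. Mean accuracy and AUC-ROC
  are averaged over folds; folds whose test set is single-class contribute
  accuracy but no AUC.

## Synthetic cohort generator

The generator emulates the study conditions: 12 participants, 28 days,
hourly prompts 7 AM–11 PM, compliance 0.38 (chosen so the expected number
of answered prompts, 12·28·17·0.38 ≈ 2170, matches the scale of a real
4-week deployment of this design).

Construction is *feature-first*: each hour slot receives target values
drawn around realistic centers (≈6 phone sessions/h, ≈1.5 incoming
calls/h, ≈0.002 battery units/s drain, ≈50 dB ambient noise, ≈1 m/s²
acceleration SD, ≈40% mobile-network share, ≈0.5 Wi-Fi Jaccard overlap),
and raw events are laid out so the extractor recovers the targets exactly
(counts, set overlaps, two-point battery curves) or to within encoding
granularity (time-weighted shares quantized by the 10-minute sampling
grid). Because counts and clipped shares make the *realized* value the
truth, ground truth records the realized standardized value, not the raw
normal draw.

Each participant has a latent control state following a stationary
unit-variance hourly AR(1) (ρ = 0.6) and a trait offset tied to their
generated BIS self-control score. True mean SSRT is log-linear:

```
log SSRT = log 280 + u_i + Σ_k β_k z_k + 0.08·c_t
```

with default planted effects |β_k| = 0.06 on eight features (signs follow
the directions reported for these markers: burstiness, incoming calls,
battery drain positive; short sessions, noise loudness, acceleration SD,
mobile share, Wi-Fi overlap negative), truncated to [60, 1400] ms so the
outlier screen removes only race-model flukes. Every answered prompt then
yields a full 80-trial tracked session from the race responder with its
stop process centered on that true SSRT — so the pipeline's SSRT values
carry realistic estimation noise, not the latent truth.

The momentary self-report generator couples item scores to the latent
state through a configurable coupling that defaults to 0, mirroring the
empirical finding that self-reports and task performance are essentially
uncorrelated; tests verify both the null and the coupled regime.

RR-interval fixtures are single-tone series (0.1 or 0.3 Hz modulation on a
1000 ms base, amplitude set from the target SDNN, optional ectopic beats).
Cohort-level RR generation is available behind `with_hrv` and is off by
default; at ~3,600 beats per window it dominates generation cost while the
HRV operations are fully exercised at window level.

**What the generator does not emulate:** real phone-use rhythms (events
are laid out deterministically within slots), circadian structure in the
features, GPS noise and movement trajectories, missing-sensor dropout,
correlated compliance (prompts are skipped independently), and
demographically structured heterogeneity. Passing tests therefore
demonstrate that the pipeline recovers what was planted under the stated
noise model — not that the features capture real behavior.

## Calibration and simulation sizes

Recovery and calibration claims are checked at these problem sizes, chosen
to match the study design while keeping the suite fast: SSRT recovery over
200 sessions (mean within 25 ms of a 250 ms truth); staircase convergence
over 5,000 stop trials (±0.02); GEE type-I error over 200 replicates of a
12 × 90 null design; sign recovery on the full default cohort
(~2,200 sessions); rmcorr recovery at 12 × 90 (within 0.05 of r = 0.8).
Type-I and classifier calibration use a model-matrix-level generator that
skips stream construction — the distributional structure (AR state,
subject intercepts, Gamma outcome) is identical, and the full end-to-end
path is separately covered by the cohort sign-recovery check.

## Known limitations

- The GEE t-reference with G−1 degrees of freedom is one of several
  reasonable small-sample corrections; with very few clusters (< 8) even
  corrected sandwich inference remains approximate.
- The integration estimator is undefined for sessions whose stop-failure
  curve never crosses 0.5; such sessions are excluded rather than
  extrapolated.
- Sleep inference from screen events is a coarse proxy and inherits the
  3 h gap floor; nap-like patterns and night phone checks bias it.
- The AR spectrum uses a fixed order (16); no order selection is
  performed.
- Location features assume an accurate offline venue table; no GPS
  denoising or stay-point detection is applied.
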