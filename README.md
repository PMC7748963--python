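# stopsense

Inhibitory control — the executive ability to suppress a prepotent response
to a goal-irrelevant stimulus — fluctuates over hours, not just between
people. `stopsense` is a tested Python implementation of the analysis stack
used to study those fluctuations in the wild: it simulates and scores
hourly **stop-signal task (SST)** sessions, turns raw smartphone sensor
streams and chest-strap RR intervals into per-hour behavioral and
heart-rate-variability features, and fits the longitudinal models that link
the two. Because no raw cohort of this kind is publicly deposited, the
package ships a first-class synthetic cohort generator with planted,
recoverable ground truth, so every stage of the pipeline can be validated
end to end.

It is intended for researchers in digital phenotyping and computational
psychiatry who want a reproducible reference implementation of this
pipeline, or a simulation harness for planning similar studies.

## The model at the core

**SSRT by the integration method.** Under the independent horse-race model,
a go process and a stop process race on every stop trial; a response occurs
iff the go process finishes before `SSD + T_stop`, where SSD is the
stop-signal delay. Sessions have 80 trials (75% go). A one-up-one-down
staircase moves the SSD by 25 ms (up after a successful stop, down after a
failure, from a 250 ms start), driving the stop-failure rate
p(respond | signal) to 0.5. For each SSD the session's stop-failure rate
`p` and the `100·p`-th percentile of the correct-go RT distribution are
computed; linear interpolation over the SSD-sorted `(SSD, p)` pairs locates
the delay where `p = 0.5`, and

```
SSRT = RT_50 − SSD(p = 0.5)
```

Sessions with overall stop-failure rate outside [0.25, 0.75] or SSRT
outside [50, 1500] ms are excluded as outliers.

**Feature extraction.** For each task prompt at time *t*, features are
computed over the hour `[t−1h, t)` (and the previous hour for
location/Wi-Fi similarity): phone-use sessions from screen lock/unlock
events (burstiness, short sessions < 30 s, durations, gaps), calls,
battery charge/discharge rates, activity shares and acceleration,
ambient-noise statistics, network-state shares, point-of-interest category
sets with Jaccard/Dice/second-Kulczynski/Ochiai overlap, phone-use-derived
sleep, time-of-day features, and HRV (SDNN, SDANN, RMSSD, SDSD, triangular
index, relative LF 0.04–0.15 Hz and HF 0.15–0.4 Hz power by Welch/FFT,
Lomb–Scargle and AR spectra) from cleaned RR intervals.

**Inference.** After variance-inflation-factor pruning, SSRT is regressed
on features with generalized estimating equations (Gamma family, log link,
exchangeable working correlation, participant clusters, small-sample
sandwich inference); repeated-measures correlation links self-reports to
SSRT; gradient-boosted trees classify high/low control states
(participant-wise median split) under leave-one-subject-out and
mixed-fraction cross-validation.

## Worked example

```python
from stopsense.pipeline import run_pipeline, RunConfig, format_report
from stopsense.synth import CohortConfig

report = run_pipeline(RunConfig(cohort=CohortConfig(n_participants=6, days=10, seed=42)))
print(format_report(report))
```

prints

```
stopsense pipeline report
prompts answered: 396
sessions retained after exclusion: 393 (excluded 3)

GEE (Gamma, log link, exchangeable):
term                                coef                    95% CI         p
const                              5.642            (5.255, 6.028)  2.53e-07
phone.burstiness                 0.02703        (0.01392, 0.04014)   0.00319
phone.n_short                   -0.04885      (-0.07783, -0.01987)   0.00748
call.n_incoming                  0.07523         (0.02987, 0.1206)   0.00799
battery.discharge_rate             73.52             (47.7, 99.35)  0.000746
noise.db_mean                  -0.009139     (-0.01313, -0.005144)   0.00202
activity.accel_sd                 -0.115       (-0.1971, -0.03301)    0.0155
network.pct_mobile             -0.003333    (-0.004963, -0.001703)   0.00331
wifi.jaccard                     -0.2615        (-0.3985, -0.1246)   0.00444
baseline                          0.0319          (0.0147, 0.0491)   0.00503

rmcorr(EMA score, SSRT): r=0.016 (95% CI -0.084 to 0.115), p=0.758, df=386

state classification (gradient-boosted trees):
  loso       ACC 62.6%  AUC-ROC 68.6%
  mixed_10   ACC 63.6%  AUC-ROC 68.6%
  mixed_20   ACC 64.5%  AUC-ROC 68.7%
  mixed_30   ACC 61.1%  AUC-ROC 66.3%
```

The intercept `5.642` is log-SSRT (exp(5.64) ≈ 282 ms). Every planted
generator effect is recovered with the planted sign (e.g. phone-use
burstiness raises SSRT — lower inhibitory control — while ambient-noise
loudness and acceleration variability lower it); the momentary self-report
score shows no association with SSRT because the generator's default
EMA coupling is zero; and the classifiers beat chance on a cohort with
planted effects.

A command-line interface mirrors the stages:

```bash
stopsense simulate --seed 1 --out cohort/
stopsense extract --streams cohort/streams --prompts cohort/prompts.csv \
    --poi cohort/poi.csv --out features.csv
stopsense ssrt --sessions cohort/sessions.jsonl --out ssrt.csv
stopsense run --seed 1 --out run/
```

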