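# contingencylab

Simulation and analysis toolkit for **ecological action–outcome
contingency-judgment experiments** — the paradigm used to measure illusory
control and depressive realism outside the laboratory, with trials embedded
in a participant's everyday phone use.

It is written for experimental psychologists and computational-psychiatry
researchers who need to (a) generate day-long trial schedules with
programmed null contingencies, (b) simulate realistic participant cohorts
when no human data are available, and (c) run the complete validation and
inference chain on session logs — whether simulated or collected by a real
deployment.

## The task and its statistics

Each session presents `n = 40` brief trials (6 s each) separated by
irregular intertrial intervals averaging 12 minutes, generated by the
Fleshler–Hoffman progression (the closed-form series that approximates
constant-probability spacing).  On every trial the participant may press a
button (action A); an auditory outcome O occurs with probability P(O|A) if
they press and P(O|~A) if they do not.  The normative contingency metric is

```
ΔP = P(O|A) − P(O|~A)
```

Both canonical arms program **ΔP = 0** — the participant has no control —
and differ only in outcome density: P(O) = .25 (low) vs .75 (high).  After
every block of 8 trials the participant rates their control on a −100..+100
scale.  Healthy (low-BDI) participants typically rate ΔP = 0 contingencies
well above zero (*illusory control*), mildly depressed (high-BDI)
participants near zero (*depressive realism*), and an instruction
manipulation framing the alternative cause as *discrete* vs *dynamic*
modulates the outcome-density effect.

The analysis layer implements:

* experienced-contingency tabulation (the 2×2 event frequencies a, b, c, d
  over engaged trials, with misses tallied separately and undefined
  conditionals reported explicitly);
* regression-based multiple imputation of missing block ratings (chained
  equations with predictive draws; the fifth completed dataset is analyzed
  by convention);
* a mixed 2×2×2×(5) factorial ANCOVA (BDI × density × instruction × block)
  with experienced ΔP as a between-level covariate, Type-III sums of
  squares and sum-to-zero coding;
* partial η² = SS_effect / (SS_effect + SS_error) with 90% confidence
  limits from noncentral-F inversion (η² = λ / (λ + df1 + df2 + 1));
* single-sample t tests against the accuracy criterion 0, and
  simple-effects follow-ups using the block-averaged pooled error
  MSE_omnibus / 5.

## Worked example

```python
from contingencylab import ExperimentConfig, generate_schedule, scheduled_session_duration

schedule = generate_schedule(ExperimentConfig(), seed=1)
print(schedule.n_trials, len(schedule.judgment_times_s))
print(schedule.iti_s.mean() / 60, scheduled_session_duration(schedule) / 3600)
```

prints `40 5`, mean ITI `12.0` minutes and session length `8.07` hours: a
40-trial, 5-probe session that fills a typical 8-hour day.

Simulating one participant and tabulating their experience
(`python examples/simulate_participant.py`):

```
engaged trials:   30  (missed 10)
2x2 counts:       a=11 b=7 c=10 d=2
P(O|A):           0.611
P(O|~A):          0.833
experienced dP:   -0.222   (programmed: 0)
outcome density:  0.700  (programmed: 0.75)
```

The participant missed 10 of 40 trials and, by pressing on only some
trials, sampled a ΔP of −0.22 even though the programmed contingency is
zero — exactly why experienced ΔP is carried into the ANCOVA as a
covariate.  The `examples/` directory walks through every capability:
schedule generation, single-session simulation, cohort validation,
imputation + ANCOVA, and the one-call `run_study` pipeline.  A thin CLI
(`contingencylab schedule|simulate|analyze|run-study`) wraps the same
functions for shell use.

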