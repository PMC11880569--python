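# habitu

Habituation-based classification of posttraumatic-stress status from
passively collected physiological recordings.

People habituate to repeated stressful stimuli: the autonomic response to
the third explosion is usually smaller than to the first. Blunted or
inverted habituation (sensitization) is a candidate physiological marker
of PTSD. `habitu` turns event-logged recordings — ECG, skin conductance
(EDA/GSR) and pupillometry collected during a stress-inducing session with
typed trigger events — into *habituation features* and evaluates how well
they predict PTSD status defined by the PCL-M questionnaire (17 items,
total 17–85; score > 36 ⇒ positive).

For each event type with two or more occurrences, features are
first-minus-last 5-second window differences:

    x = stat(series[t0 : t0+5 s]) − stat(series[t_last : t_last+5 s])

with stat ∈ {max, min, mean} over heart rate and phasic skin conductance,
plus an eye-blink proxy (missing pupil samples in the window). Positive
x means habituation, negative means sensitization. A Gaussian-process
classifier (among seven families) is evaluated with leave-one-out
cross-validation; every data-dependent step — t-test feature screening at
α = 0.05, imputation, z-scoring, fitting — happens strictly inside each
fold. Per-fold Shapley attributions w_i (computed exactly for ≤ 12
features) explain each prediction, and the *individual habituation
response*

    response = Σ_i x_i · |w_i|

summarizes each participant's overall habituation tendency; it is
regressed against the PCL-M score.

Because comparable clinical data are access-restricted, the package ships
a first-class synthetic cohort generator (raw 2048 Hz ECG/EDA, 300 Hz
pupil with blink dropout, exponential per-stimulus habituation schedules
coupled to simulated PCL-M scores) so the entire pipeline is testable and
its statistical power measurable.

## Worked example

```sh
habitu simulate --n 8 --effect 3.0 --seed 42 --session-duration 240 --out demo
habitu run --input demo --out demo_out --seed 7
```

which prints:

```
8 participants (4 PTSD-positive) -> demo
accuracy 87.5% (majority baseline 50.0%); TPR 75.0%, TNR 100.0%; features/fold 14.62 +/- 5.34
response-vs-PCL-M slope 10.12 (r = 0.78)
artifacts -> demo_out
```

Reading: on an 8-participant cohort whose class-mean habituation gains are
separated by 3 within-class SDs, leave-one-out classification recovers 7
of 8 labels (the baseline of always guessing the majority class would get
4), an average of ~15 features per fold survive the t-test screen, and
participants with larger habituation responses report higher PCL-M scores
(positive regression slope). `demo_out/` contains `summary.json`,
`features.csv`, `attributions.csv`, `responses.csv` and figures: ROC +
confusion matrix, per-participant attribution bars, global importance
rankings, and the response-vs-PCL-M scatter with its regression line.

The same analysis is available as a library:

```python
from habitu import generate_cohort, cohort_matrix, analyze, RunConfig

cohort = generate_cohort(n=21, effect=3.0, seed=1)
result = analyze(cohort_matrix(cohort), RunConfig(seed=1))
print(result.summary.accuracy, result.regression.slope)
```

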