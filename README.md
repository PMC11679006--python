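# fogsentry

Freezing of gait (FOG) is a sudden, involuntary arrest of forward walking
that affects many people with Parkinson's disease and is a major cause of
falls.  A cueing device can interrupt an impending freeze — but only if the
freeze is detected, or better, predicted, in real time.  `fogsentry` is a
tested re-implementation of a FOG prediction/detection pipeline that uses
only plantar-pressure (shoe-insole) data, for researchers in movement
disorders and wearable sensing who want an auditable, reproducible version
of the method and a synthetic test bed for it.

## The method

From two 100 Hz per-foot pressure signals the pipeline computes the foot
center of pressure (COP); a COP sample is valid only while that foot
carries > 5% of the two-foot total ground-reaction force.  Overlapping 1 s
windows (0.2 s shift) are labelled **target** when every sample is FOG or
pre-FOG (the 2 s before an onset), and 8 features are extracted per window
— per foot: the AP COP reversal count, the dominant FFT frequency of the
ML and AP COP velocity, and the mean level-4 db4 wavelet
approximation-coefficient power of the AP COP position.

Windows are classified by a from-scratch **RUSBoost** ensemble (AdaBoost
with per-round 1:1 random undersampling of the majority class) of 100
decision trees with ≤ 5 splits each.  Three consecutive target windows
raise a **model trigger decision (MTD)** at the third window's end, thinned
by a 2.5 s no-cue interval.  An MTD inside an episode's target zone — from
up to 6 s before onset (shortened by preceding FOG/turn/stand events)
through the episode end — is a true positive; the identification delay (ID)
is the first true positive's time minus onset, negative when the freeze is
predicted before it starts.  Evaluation is leave-one-freezer-out
cross-validation with pooled window sensitivity/specificity and
episode-level %identified / %predicted / %detected / mean ID / FP-per-trial.

Because no participant recordings are publicly available, the package
includes a parameterized two-foot gait simulator (walking, turns, standing,
festination-like pre-FOG precursors, trembling and akinetic freezes) that
provides ground truth for every test; see `docs/methods.md` for what the
synthetic results do and do not show.

## Worked example

```python
from fogsentry import simulate_cohort, lofo_crossval

cohort, _ = simulate_cohort(n_freezers=7, n_nonfreezers=4,
                            trials_per_participant=10, seed=1)
folds, report = lofo_crossval(cohort, seed=1)
for key, value in report.to_dict().items():
    print(f"{key:>16}: {value if not isinstance(value, float) else round(value, 2)}")
```

prints

```
     sensitivity: 86.04
     specificity: 99.58
  pct_identified: 100.0
   pct_predicted: 96.47
    pct_detected: 35.29
         mean_id: -0.51
         fp_rate: 0.03
       n_windows: 20720
      n_episodes: 85
```

Read: across the 7 held-out freezers, 86% of target windows and 99.6% of
non-target windows were classified correctly; every one of the 85 synthetic
FOG episodes was identified, 96% of them before onset, on average 0.51 s
early (negative ID = prediction), at 0.03 false alarms per walking trial.
Episodes can be both predicted and detected, which is why the predicted and
detected percentages exceed the identified percentage when summed.

The same flow is available from the shell:

```
fogsentry simulate --seed 1 --out data/
fogsentry features --data data/ --out features.csv
fogsentry crossval --seed 1 --data data/ --out results/
fogsentry report   --seed 1 --data data/ --out results/ --exclude P01
```

`report` additionally re-runs the cross-validation on modified cohorts
(named outliers removed, non-freezers removed, both) for dataset-composition
comparisons.  Every output file embeds the config hash and seed that
produced it.

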