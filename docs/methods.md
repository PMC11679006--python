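# Methods

`fogsentry` implements a freezing-of-gait (FOG) prediction/detection
pipeline driven purely by plantar-pressure data: per-foot
center-of-pressure (COP) kinematics, windowed feature extraction, a
RUSBoosted decision-tree classifier, and an episode-level trigger-decision
evaluation under leave-one-freezer-out cross-validation.  This note records
the model, its assumptions, the numerical choices, and what the synthetic
validation does and does not show.

## Labels and windows

Each 100 Hz sample carries one of three gait states derived from interval
annotations: `FOG` inside an annotated freeze, `PREFOG` in the 2 s
immediately before a freeze onset, `NONFOG` otherwise.  FOG takes
precedence over PREFOG when episodes fall less than 2 s apart, since FOG is
the observed state.  Sample membership in an interval is half-open
`[start, end)`, except that a FOG interval also owns the sample landing
exactly on its end time.  Annotations recorded on a coarser grid (e.g.
30 Hz video) are transferred by nearest-in-time assignment with ties to the
earlier frame — labels are categorical, so "interpolation to the closest
point" means nearest-neighbour here.

Trials are sliced into 1 s windows shifted by 0.2 s (0.8 s overlap),
aligned to the trial start; only complete windows are emitted, giving
exactly `floor((T − 1)/0.2) + 1` windows for a `T`-second trial.  A window
is **target** iff every sample in it is PREFOG or FOG; a single NONFOG
sample makes it non-target.

## COP kinematics

For sensel-grid input the per-foot COP is the pressure-weighted centroid.
A COP sample is **valid** only while that foot carries strictly more than
5% of the two-foot total force; this removes residual-pressure artefacts
during swing.  The rule is scale invariant and leaves both feet invalid
when both read zero.

Invalid spans are bridged by linear interpolation (held flat at trial
edges) *before* differentiation, and the original validity mask is carried
forward.  Interpolating rather than dropping avoids spurious velocity
spikes at validity edges; the choice is configurable in spirit — features
that should not see repaired samples (the reversal count) consume the mask
directly.  COP velocity is the first time derivative via central
differences with one-sided stencils at the ends; it is exact for linear
signals and zero for constants.

## Features (8 per window)

Four per foot, fixed order: AP-reversal count (left, right), dominant ML
COP-velocity frequency (L, R), dominant AP COP-velocity frequency (L, R),
mean wavelet approximation-coefficient power of AP COP position (L, R).

* **Reversals** — alternating-extremum detection with a 1 mm hysteresis
  (configurable) to suppress sensor noise; counted over valid samples only,
  resetting across invalid runs; an all-invalid window counts 0.
* **Dominant frequency** — magnitude FFT of the mean-removed segment, no
  zero padding (1 Hz resolution at 100 samples), DC excluded, bins up to
  Nyquist, ties to the lowest frequency.  A numerically flat spectrum
  degenerates to the 1 Hz bin by the tie rule.
* **Wavelet power** — Daubechies-4 multilevel DWT, level 4, symmetric
  padding, computed on the mean-removed segment; the level-4 approximation
  band of a 100 Hz signal is ≈ 0–3.1 Hz, the locomotor band.  Level 4 on a
  1 s segment incurs boundary effects; that trade-off (band placement over
  edge purity) is deliberate.  Mean removal makes this feature, like the
  others, invariant to a constant COP offset.

A foot with no valid sample in a window contributes zeros for its four
features and flags the window degenerate, so the classifier always sees
fixed-length vectors.

## Classifier

A from-scratch two-class RUSBoost: AdaBoost with a per-round random
undersample of the majority class (all minority examples plus a weighted
draw without replacement of majority examples at a 1:1 ratio), 100 trees of
at most 5 internal splits each, learning rate 0.1 (the rate and ratio are
configurable and recorded in the serialized model).  The weighted error of
each round's tree is computed on the *full* training set;
`α = learn_rate · ln((1−ε)/ε)`; weights of correctly classified examples
shrink by `e^{−α}` and renormalize.  Rounds at ε = 0 keep the learner with
a capped α; rounds at ε ≥ 0.5 discard it and resample, stopping early after
repeated failure.

Trees grow best-first by weighted Gini reduction.  Impure leaves may split
at zero gain — without this, XOR-shaped data can never take its first cut
(every single split has zero immediate gain), which is also standard CART
behaviour.  Determinism is a contract: training rows are canonically
sorted, all tie-breaks are fixed (lowest feature index, lowest threshold,
oldest leaf), and each round's randomness comes from a substream of the
root seed indexed by a round counter, so identical inputs give bit-identical
ensembles regardless of row order.

The ensemble score is the α-weighted fraction of target votes; the class
threshold is a strict 0.5.

## Episode-level evaluation

A **model trigger decision (MTD)** fires at the end of the third — and
every later — window of a consecutive-target run; a 2.5 s no-cue interval
then suppresses MTDs falling less than 2.5 s after the last kept one.
Firing at every ≥3rd window (not once per run) is the only reading under
which the no-cue rule does anything.

Each episode owns an **MTD target zone** from up to 6 s before onset
through the episode end.  Turn-to-walk and stand-to-walk transitions inside
the initial 6 s push the zone start to 1 s after their end; a prior FOG
episode pushes it to its own end with no extra delay (the 1 s delay
attaches to turning/standing only); the start clips to the trial start and
never exceeds the onset.  Kept MTDs inside a zone are true positives
matched to that episode; outside all zones they are ignored during standing
or the first second of walking after standing (gait initiation), otherwise
false positives.

An episode is *predicted* if a matched TP precedes onset, *detected* if one
falls in `[onset, end]`, *identified* if either; the identification delay
is the **first** TP instant minus onset (negative = prediction).  Episodes
can be both predicted and detected, so
`max(pred%, det%) ≤ ident% ≤ pred% + det%` — asserted on every report.

Cross-validation is leave-one-freezer-out: each freezer is held out once,
non-freezers stay in every training set and never contribute test windows.
Window metrics (sensitivity/specificity) are pooled across folds
(per-fold results are also returned); all held-out windows are scored —
standing/turning exclusions apply only to episode-level false positives.
The false-positive rate is FPs per trial, averaged over held-out
participants.

## Synthetic gait generator

The generator emulates the study protocol — a brief stand, walking with two
turns and one mid-trial standing bout, induced freezes — with a simple
kinematic gait model (not biomechanically validated): alternating single
support from a continuous gait phase, stance AP COP progressing heel→toe
(160 mm default excursion), ~2% residual swing force (below the validity
rule), 0.1-cycle-fraction double-support crossfades, Gaussian force and COP
noise.  Defaults: 60 s trials (the study cohorts average ≈ 52 s per trial),
cadence 1.8 steps/s, Poisson(1.5) episodes per trial with log-normal
durations (median 2 s, σ = 0.7, clipped to [0.8, 10] s), phenotype mix 70%
trembling / 30% akinetic.  Trembling freezes oscillate the COP at a
configurable 3–8 Hz tremble frequency (default 6 Hz); akinetic freezes hold
the COP static plus noise.

The pre-FOG precursor is festination-like — cadence ×2.0 and AP excursion
×0.25 over the 2 s horizon, ramping linearly to full effect in 0.5 s and
holding.  Real pre-FOG plantar-pressure signatures are not well
characterized; these effect sizes are free parameters chosen once to make
the target class learnable, not claims about physiology.  Consequently the
end-to-end recovery result (below) demonstrates that the pipeline *can*
recover a planted precursor of this strength — it says nothing about the
detectability of real pre-FOG gait, and the published real-data performance
figures are not reproducible from synthetic data.

Two known ambiguities are modelled honestly rather than removed: akinetic
freezing is statistically identical to quiet standing under these features,
and windows straddling a walk/pre-FOG boundary are non-target by definition
while carrying partial precursor signal.  Both bound the attainable window
metrics below 100%.

Cohorts draw per-participant parameter jitter (cadence ±10%, excursion
±15%, tremble frequency uniform in 4.5–7.5 Hz, ...) from named substreams
of one root seed; non-freezers get episode rate 0; every freezer is
guaranteed at least one episode.

## Problem sizes and reproducibility

The end-to-end acceptance run uses 7 freezers + 4 non-freezers with 10
trials each (≈ 20 700 test windows, ≈ 90 episodes per run), averaged over
3 seeds; at these sizes the whole run completes in about a minute on one
core.  Every entry point takes a single seed; all randomness (simulation,
undersampling, fold seeds) derives from it, and outputs embed the config
hash and seed.

## Limitations

* The simulator's precursor is planted; synthetic performance does not
  transfer to real recordings.
* The wavelet family/level, reversal hysteresis, undersampling ratio and
  learning rate of the original system are unknown; the defaults here are
  reasonable choices, all configurable and logged.
* Window specificity counts all held-out windows, including
  standing/turning; whether the original evaluation excluded them is
  unstated — the episode-level exclusions are applied exactly as defined.
* The published cohort tables ship with the package for aggregate
  recomputation; one printed demographic mean (cohort 1 age) is
  inconsistent with its own per-participant cells, and the package reports
  the recomputed value without special-casing.
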