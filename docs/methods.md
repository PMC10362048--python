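# Methods

This note documents the generative model behind the simulator, the analysis
conventions, the numerical choices, and what the recovery tests do and do
not establish about real recordings.

## Task model

`TaskConfig` fixes the operant structure: three trial types (S-left sound,
S-right light, catch) with equal probabilities; foreperiods drawn iid from
{0.35, 0.5, 0.65, 0.8} s (a `foreperiod_counterbalanced` flag switches to
shuffled blocks of four — the balancing scheme of the original task is not
stated, so iid is the default); an unsignaled uniform 4–6 s inter-trial
interval whose timer resets on ITI licking; a 3 s response window; three
reward drops delivered starting at the 3rd lick (the trial outcome event);
trials with licks end 1 s after the last lick.  The within-bout lick rate is
7 Hz (typical rodent licking; the task description leaves it unstated).

## Agent model

The stepwise-learning agent is the minimal generative model that reproduces
the observed repertoire dynamics: a 3-state predictor set with per-state
lick-probability tables.

* **Step 1 (lick-right)** switches on as a *step* at a planted
  `transition_trial` (a combined-trial index inside the D1 session; default
  40 ± 10 across animals).  A step rather than a sigmoid keeps change-point
  recovery well-posed.  After the transition the agent licks right in light
  trials (p = 0.97), catch trials (p = 0.75 within D1), and initiates
  no-fixation lick bouts during ITIs (hazard 0.5 per interval).
* **Step 2 (fixation-exit)** consolidates 60 combined trials after the
  transition, after which the no-fixation hazard drops (0.15 within D1,
  then 0.05 halving per session).  The per-session no-fixation frequency
  therefore peaks at D1.
* **Step 3 (the light)** is learned in the D2 session.  Catch-lick
  probability rises from 0.65 (between D1 and D2) to its study maximum 0.92
  at D2 and decays geometrically (×0.35 per session) afterwards, so D2 is
  the planted argmax of catch-lick frequency with a wide margin relative to
  binomial noise at ~110 catch trials/session.

Landmarks are planted per animal: D0 = 0 (first session with the new
stimulus), D1 = 2 ± 1, and D2 = D1 + gap with gap ∈ {0, 1, 2, 3}
(probabilities 0.14/0.36/0.36/0.14), reproducing the occasional accelerated
learner whose D1 and D2 coincide (such animals are excluded from D1-dynamics
analyses downstream, exactly as the analysis prescribes).  Left-port trials
run throughout at a stable 94% accuracy as the internal control.  Sessions
hold ~330 initiated trials (≈110 per type), matching the reported per-type
session sizes.  Latency models: light-trial RT is normal with mean 0.55 s
(shrinking by 40 ms/session after D2 toward a 0.30 s floor, so that light
learning shows in faster RTs), S-left RT 0.40 s, catch exits 0.50 s.  An
early-exit hazard of 0.05 per trial produces aborted fixations.

Planted no-fixation bouts satisfy the detection criteria by construction
(first lick > 2 s after the last fixation exit and > 1 s after the last
reward-port exit), so the behavioral round trip is exact at zero noise.

## Neuron model

Each simulated unit is an inhomogeneous Poisson process; a population of
`n_units = 32` with 70% bursting-class yields ~22 bursting units per
session, matching the reported per-session density.  Bursting units have a
< 10 spikes/s baseline (5 ± 1 Hz) plus event-locked gains:

* S-left boxcar, +8 spikes/s on [0.05, 0.2] s after sound onset (stable
  across sessions);
* light-onset gain on [0.05, 0.3] s: zero before D2, ramping 2→6 spikes/s
  across the D2 session, then +1.5 spikes/s per session capped at 9;
* an evaluation-epoch linear ramp from fixation exit (or 0.5 s before port
  entry in no-fixation bouts) to the outcome, peaking at
  `eval_gain_hz × E`, where E is the trial's reward expectation;
* an outcome boxcar on [0.05, 0.35] s after the 3rd lick with gain
  `outcome_gain_hz × max(0, 1 − E)`.

**RPE rule.**  The outcome event (3rd lick) carries a fixed drive of 1 for
*every* completed lick episode, rewarded or not — the animal commits to the
outcome at the 3rd lick, and the response is negatively modulated by the
expectation built up during the approach.  This is what produces the
negative single-trial evaluation-vs-outcome correlation in catch and
no-fixation licks as well as in rewarded light licks; a rule gated on
physical reward delivery would silence the outcome response in non-rewarded
licks and destroy that signature.  Expectation per right-lick trial is
`E = clip(e_sess + 0.5·U, 0, 0.95)` with U uniform; `e_sess` is 0.10 before
D2 and rises by 0.15 per session afterwards (cap 0.55), so outcome responses
also decline across sessions as light responses grow.  Left-lick trials use
a fixed E = 0.8 (old, well-predicted association).

Non-bursting units fire at a flat 8 Hz with no event gains, which leaves
their S-left/catch contrast near zero.

Sampling is exact for a piecewise-constant rate: each constant segment
contributes a Poisson count with uniformly placed times (the ramp is
discretized into 8 segments).  Output spikes receive a 2 ms refractory
prune and 1 ms rounding, mirroring the ISI floor and timestamp resolution
of curated recordings; this deflates rates by ~1–2%, well inside every
tolerance used.

## Analysis conventions

* **Lick response**: ≥3 licks in one reward port with the *3rd lick* within
  3 s of stimulus onset (reward starts at the 3rd lick, so the response is
  consummated then).  A switch (`all_three_in_window`) restricts the count
  to in-window licks instead.
* **Bout segmentation** uses a 1 s inter-lick gap, consistent with the 1 s
  reward-port re-entry threshold of the no-fixation criteria.
* **No-fixation frequency** is reported per 100 initiated trials (the
  normalization of the original per-session curve is unstated; this choice
  is documented rather than inferred).
* **Transition statistic**: D(t) compares the 20 trials after vs before
  each candidate on the combined (light, catch, no-fixation) series; the
  earliest maximizer wins ties, computed in integer arithmetic so ties are
  exact.  The index is adjusted to the closest light-lick trial; shifts
  beyond 5 trials warn and are flagged.  No height threshold is imposed;
  maxima below 0.3 are flagged low-confidence.
* **PSTHs**: 10 ms half-open bins, normalized per bursting neuron.  A trial
  contributes to a bin only when the bin lies fully inside its observed
  (censoring) interval — e.g. stimulus-aligned histograms use only spikes
  before fixation exit — giving per-bin effective-trial normalization, and
  the histogram is truncated at the session's median censoring latency
  (cross-animal averages at the mean of per-animal medians).  Per-bin
  weighting and count renormalization coincide under this per-trial
  deterministic censoring; the choice is the effective-trial scheme.
* **Evaluation response**: maximum pooled rate of any 500 ms window in the
  per-trial evaluation epoch, scanned continuously — a maximizing window
  can always be anchored with its left edge at a spike time or flush
  against the epoch end, so exactly those candidates are examined.  Epoch
  rules per trial type: lick trials [fix-out, outcome]; no-fixation bouts
  use the 95th percentile of the session's lick-trial epoch durations,
  ending at the outcome and starting ≥0.5 s before port entry; no-lick
  trials use the median duration from fixation exit.  Epochs shorter than
  500 ms are used whole and flagged.
* **Sliding comparisons**: paired two-sided t per 100 ms window (10 ms
  step) across animals; significance requires ≥3 consecutive windows below
  alpha (0.01 and 0.05 reported).
* **ROC/AUC**: midrank (Mann–Whitney) convention for ties; two-sided
  permutation p = (1 + #{|AUC* − ½| ≥ |AUC − ½|}) / (1 + n_perm), never
  exactly zero; label shuffles are shared across windows of one sliding
  analysis.  Defaults: 10,000 permutations at α = 0.001 for trial-type
  discrimination, 1,000 at α = 0.05 for lick/no-lick discrimination with
  the 10% class-balance inclusion rule (light trials only before D2).
* **RPE correlations**: Pearson.  Rewarded single-trial analyses use
  pre-D2 sessions (before the light response develops); non-rewarded
  analyses require ≥50 pooled catch + no-fixation licks per session.
* **Exclusions**, logged per animal/session: unresolved landmarks; D1 = D2
  (merged) animals from D1 dynamics; sessions with <2 bursting units from
  population analyses; class-imbalanced ROC cells.

## Problem sizes in the recovery suite

The test suite and `scripts/acceptance.py` run at the defaults above except
where noted: transition recovery uses 200 series of 120 trials with a
planted Bernoulli(0.05→0.95) step; landmark recovery 20 seven-animal
studies (behavior only); bursting classification 100 seeds × 30 units with
600 S-left and 600 catch trials; permutation calibration 500 seeds at 1,000
permutations.  The RPE-signature check runs the simulator's low-noise
condition — a doubled pooled population (`n_units = 64`) — because at the
default density the pooled Poisson noise leaves the single-trial correlation
within sampling error of the −0.5 reference; all other checks use default
noise.

## What the simulator does and does not emulate

It reproduces the *structure* of the data — event-log format, trial
composition, the stepwise repertoire dynamics, censoring geometry, and the
RPE phenomenology — with Poisson spiking and stationary baselines.  It does
not model electrode drift, spike-sorting noise, duplicate units,
between-animal heterogeneity in rate gains, non-Poisson burst structure, or
history effects in behavior beyond the planted learning steps.  Passing
recovery tests therefore validates the analysis code under the stated
assumptions; it does not certify performance on recordings whose noise
violates them (e.g. strongly bursty or nonstationary units near the
2 spikes/s classification margin, where the per-session misclassification
of ~1–2 units at 110 trials seen at default noise would grow).

## Known limitations

* The parser assumes one fixation entry/exit pair per attempt; repeated
  pokes within a single illumination are folded into the first entry.
* Session-level correlation tables pool sessions across animals without a
  within-animal random effect; with many animals a mixed model would be the
  better inferential choice.
* `find_transition` detects exactly one change point by design.
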