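# Methods

## Problem and outcome measures

The pipeline studies one labeling decision: whether successive
freezing-of-gait (FOG) episodes in rapid succession should be treated
as separate events (event-based ground truth) or fused into one period
of gait disruption. Fusion is parameterized by a merging threshold
`mt`: two consecutive episodes are merged when
`next.onset − prev.end < mt` (strict inequality; a gap exactly equal
to the threshold is kept separate, and `mt = 0` is the identity).
Merging is a single left-to-right pass; because fusing a pair never
changes the gap to the *following* episode, one pass reaches the
fixpoint — the test suite checks this against an exhaustive pairwise
fixpoint oracle.

Models are evaluated at two levels.

* **Window level**: sensitivity and specificity of per-window
  classifications. Undefined ratios (a participant with no positive
  windows) are flagged NaN and excluded from cohort means.
* **Episode level**: three consecutive positive windows emit a model
  trigger decision (MTD) timestamped at the end of the third window.
  A run of L ≥ 3 positive windows emits L − 2 triggers (every window
  past the second of a run triggers), which reproduces the grouped
  trigger clusters that 80 %-overlapped windows produce; a
  `per_run=True` switch keeps only the first trigger per run. An MTD
  is a true positive iff it falls inside some episode's target zone
  `[onset − 2 s, end]` (closed endpoints; when zones overlap the
  trigger is attributed to the earliest). An episode is identified
  iff ≥ 1 MTD lies in its zone; the identification delay is the
  earliest in-zone MTD minus onset (negative = prediction).
  Precision is `100·TP/(TP+FP)` over triggers.
* **No-cue protocol**: a greedy left-to-right refractory filter. The
  first trigger survives and opens a half-open interval
  `(t, t + 2.5 s]`; triggers inside an open interval are discarded.
  A boundary trigger exactly 2.5 s after a cue survives (a convention
  the data cannot decide; it is fixed and tested). Episodes whose
  onset falls inside an open interval are credited as identified but
  contribute no identification delay.

Cohort summaries are unweighted means across participants; the SD is
the population SD (divisor N), which is what the published reference
tables' (SD) rows correspond to. Totals (TP, FP) are sums.

## Labeling conventions

Ternary ground truth at 100 Hz: a sample at time `t = i/fs` is FOG iff
`onset ≤ t < end` (half-open, so boundary samples are never
double-labeled), PreFOG iff `onset − 2 ≤ t < onset` and not FOG,
NonFOG otherwise. FOG takes precedence, so the PreFOG zone of an
episode following a short gap is truncated at the previous episode's
end; PreFOG is always derived from the *merged* episode list. Windows
are 1 s with 0.2 s shift; sample spans use `floor(start·fs)` with a
fixed 100-sample width so segmentation is bit-stable. The prediction
target is membership of the window *start* in `[onset − 2, onset)` —
content-based rules would include the pure-FOG window that starts at
the onset, which is deliberately a non-target. Windows that mix FOG
and post-episode NonFOG are detection targets (they contain FOG) and
prediction non-targets. A session whose duration is not a whole
number of shifts leaves a sub-shift tail uncovered by any window; the
no-FOG-discarded guarantee is therefore stated for durations that are
multiples of the shift (all generated sessions are).

## Features

Ten per-window quantities, in fixed column order: dominant FFT
frequencies of COP velocity (ML right, AP right, AP left) and of
thigh AP acceleration (right, left); wavelet approximation mean
energy, approximation mean and minimum detail coefficient of the
right COP AP position; and AP reversal counts (right, left).

* *Dominant frequency*: mean removal, zero-padding to 256 samples
  (bins ≈ 0.39 Hz against the 1 Hz native resolution of a 1 s
  window), argmax over non-DC bins; a constant window maps to 0 Hz.
  The padding length is configurable; the tests compare against a
  dense DTFT scan.
* *Velocity*: first difference × fs (length n − 1).
* *Wavelet summaries*: Daubechies-5, level 4, symmetric boundary
  extension. At 100 Hz the level-4 approximation band is ≈ 0–3.1 Hz —
  the locomotor band — so approximation energy collapses when forward
  progression is arrested. Family and level are configurable; db5/4
  is this package's choice, not an established ground truth.
* *Reversals*: direction changes counted only when the excursion from
  the running extremum exceeds a hysteresis guard (default 0.05 cm).
  Raw sign-counting is degenerate under sensor noise; note that a
  guard of k·σ only suppresses false reversals whose *pairwise* noise
  difference (scale σ√2) stays below it, so reliable equality with
  the noiseless count needs a guard well above 3σ (tests use 6σ).

## Classifier

`RUSBoostClassifier`: AdaBoost.M1 boosting of CART trees limited to 5
internal splits (≤ 6 leaves), 100 rounds, learning rate 1.0. Each
round first undersamples the majority class uniformly at random to
exact class balance, fits the tree on the balanced subset with the
current boosting weights, then computes the weighted error on the
*full* training set and applies the β-update. Rounds whose weighted
error reaches 0.5 are discarded and redrawn (training stops after 25
consecutive failures); an error of 0 stores the tree with a capped
weight and stops early. All randomness flows from `random_state`.
Undersampling ratio (exact balance) and learning rate are not dictated
by the evaluation protocol; both are configurable.

Leave-one-freezer-out cross-validation: one fold per participant with
≥ 1 annotated episode; the training pool is every other participant —
non-freezers contribute to all training pools and are never held out.
Merging and labeling are applied before windowing, identically on both
sides of the split. Fold model seeds derive from the master seed and
the fold index only, so a fold keeps its seed across thresholds and
the threshold comparison is not confounded by reseeding.

## Synthetic cohort generator

The generator's role is to supply data with the statistical structure
the method exploits, not physiological realism. Defaults (the study
conditions used by the acceptance script and the end-to-end tests):

| parameter | default | rationale |
|---|---|---|
| participants / freezers | 11 / 7 | reference cohort shape |
| session duration | 300 s | desk-scale stand-in for ~22 min visits |
| episode rate | 2.0 /min/freezer | ≈ 362 episodes / 7 freezers / 241 min |
| episode duration | U(2, 6) s | short, clinically typical freezes |
| cluster probability / gaps | 0.3, U(0.3, 2.5) s | rapid-succession clusters that thresholds 1–3 s partition nontrivially |
| gait frequency / COP amplitude | 1.0 Hz / 3 cm | locomotor band, stride-scale AP excursion |
| tremble frequency / amplitude | U(3, 8) Hz / 2 cm | trembling-in-place band |
| pre-FOG degradation | 0.4 | 40 % amplitude loss and frequency drift ramping over the 2 s pre-onset zone |
| noise SD | 0.05 cm (0.02 g) | light sensor noise |

Signals are phase-continuous sinusoids with regime-dependent envelopes:
during a freeze the locomotor amplitude collapses to 5 % (arrested
forward progression) and a per-episode tremble tone is superimposed on
COP and thigh channels; in the 2 s pre-onset zone amplitude and
frequency drift linearly by the degradation fraction. In *velocity*
(what three of the five spectral features see) a 2 cm tremble at 6 Hz
dominates a 3 cm stride at 1 Hz by roughly 4:1, so the FOG/NonFOG
spectral separation is strong by construction — pure-FOG windows are
separable from pure-NonFOG windows by a single threshold on one
feature with ≥ 90 % accuracy. Passing end-to-end tests therefore
demonstrates the pipeline's correctness, *not* attainable performance
on real patient data, where boundary windows, akinetic freezes and
inter-subject variability dominate the error budget.

Episode placement draws the per-session count from a Poisson law
matched to the configured rate (forced ≥ 1 for freezers), groups
episodes into geometric clusters with U(0.3, 2.5) s intra-cluster
gaps, and spreads clusters over the session with exponential spacings
normalized to the free time — annotations are disjoint by
construction and the realized rate is unbiased (verified by Monte
Carlo against the configured rate). Inter-participant variation is a
±20 % amplitude scale and a random phase. Onset/end times are
continuous seconds; an optional switch quantizes them to a 30 Hz grid
(off by default). Signals synthesize directly at 100 Hz; insole
pressure-cell grids and higher-rate IMU downsampling are intentionally
not modeled, since the pipeline consumes COP/acceleration series.

## Problem sizes

The acceptance script runs the full 2-task × 4-threshold sweep with
100-tree ensembles on the default cohort (11 × 300 s sessions,
≈ 1 500 windows each); the test suite uses smaller cohorts (60–150 s
sessions, 5–15-tree ensembles) for unit checks and the default cohort
for the end-to-end recovery test. These sizes are the package's
standard desk-scale configuration; all are configurable.

## Known limitations

* Only the trembling-with-arrest FOG subtype is synthesized; akinetic
  and shuffling subtypes are absent.
* The ten features are implemented as specified consumers of COP and
  acceleration series; the upstream feature-selection study that chose
  them from a larger superset is out of scope, as are the wavelet
  family/level and FFT conditioning actually used there.
* Ground-truth ambiguity itself (inter-rater labeling noise) is not
  modeled; annotations are exact.
* The no-cue protocol is a simulation on recorded triggers; it does
  not model gait actually changing in response to a cue.
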