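# fogmerge

Freezing of gait (FOG) is an episodic inability to produce effective
stepping in Parkinson's disease. Wearable cueing systems detect — or,
better, predict — freezes from plantar-pressure and inertial signals
and deliver a cue to shorten or prevent the episode. When ground truth
is labeled with an *event-based* definition (onset = the instant the
stepping foot fails to leave the ground; end = the instant an
effective step resumes), freezes that occur in rapid succession appear
as many short episodes separated by a few ineffective steps. A *period
of gait disruption* view instead fuses such a sequence into one
episode. `fogmerge` is a tested, reusable pipeline for quantifying how
that modeling choice — parameterized as a **merging threshold**
`mt`: successive freezes separated by a gap `< mt` seconds are fused
and the gap relabeled FOG — affects FOG **detection** and
**prediction** models.

The package is aimed at movement-analysis and digital-health
researchers building FOG classifiers and cueing protocols, and at
anyone who needs an end-to-end, seedable benchmark of the methodology
without access to patient data.

## The pipeline

1. **Synthetic cohorts** (`fogmerge.synthio`): multichannel 100 Hz
   sessions — centre-of-pressure (COP) AP/ML positions and thigh AP
   accelerations — with ~1 Hz locomotor oscillation during gait,
   3–8 Hz trembling with arrested forward progression during freezes,
   degraded gait in the 2 s pre-onset zone, clustered rapid-succession
   episodes, and both freezers and non-freezers (defaults: 11
   participants, 7 freezers).
2. **Labeling** (`fogmerge.labeling`): episode merging (gap `< mt`,
   single left-to-right pass) and ternary NonFOG / PreFOG / FOG label
   tracks, with PreFOG = the 2 s before each onset.
3. **Windowing** (`fogmerge.windowing`): 1 s windows, 0.2 s shift
   (80 % overlap), non-homogeneous so no FOG data is discarded.
   Detection target: any FOG sample in the window. Prediction target:
   the window *starts* within the 2 s pre-onset zone.
4. **Features** (`fogmerge.features`): the 10 per-window quantities —
   dominant FFT frequencies of COP velocity (ML right, AP right/left)
   and thigh AP acceleration (right/left), wavelet approximation mean
   energy / mean and minimum detail coefficient of right COP AP
   (Daubechies-5, level 4), and hysteresis-guarded AP reversal counts
   (right/left).
5. **Classification** (`fogmerge.classify`): `RUSBoostClassifier`, a
   scikit-learn estimator boosting 100 trees (≤ 5 splits each) with
   per-iteration random undersampling of the majority class, under
   leave-one-freezer-out cross-validation.
6. **Evaluation** (`fogmerge.evaluate`): window sensitivity /
   specificity; model trigger decisions (MTD = 3 consecutive positive
   windows, stamped at the third window's end); the MTD target zone
   (2 s pre-onset through episode end); identification delay
   (negative = predicted before onset); precision
   `PR = TP/(TP+FP)×100`; and the 2.5 s no-cue refractory protocol.
7. **Experiment** (`fogmerge.experiment` + `fogmerge` CLI): the
   merging-threshold sweep (0, 1, 2, 3 s) for both tasks, emitting
   per-participant and cohort-mean report tables.

## Worked example

```python
from fogmerge import CohortConfig, EnsembleConfig, SweepConfig, run_sweep

cfg = SweepConfig(
    thresholds=(0.0, 2.0),
    tasks=("detection",),
    no_cue_interval_s=2.5,
    cohort=CohortConfig(n_participants=6, n_freezers=4, session_duration_s=120.0),
    ensemble=EnsembleConfig(n_trees=50),
    seed=7,
)
res = run_sweep(cfg)
print(res.episode_counts.to_string(index=False))
for mt in (0.0, 2.0):
    m = res.summary["detection"][f"mt{mt:g}"]["mean"]
    print(f"mt={mt:g}s  sens={m['sensitivity']:.1f}%  spec={m['specificity']:.1f}%  "
          f"identified={m['episodes_identified_pct']:.1f}%  ID={m['mean_id_s']:+.2f}s  "
          f"precision={m['precision']:.1f}%")
```

prints

```
participant_id  n_episodes_mt0  n_episodes_mt2  reduction_at_max_mt
           P01               5               4                    1
           P02               3               3                    0
           P03               6               3                    3
           P04               7               5                    2
           P05               0               0                    0
           P06               0               0                    0
mt=0s  sens=98.5%  spec=97.7%  identified=100.0%  ID=-0.41s  precision=86.2%
mt=2s  sens=97.0%  spec=97.2%  identified=100.0%  ID=+0.13s  precision=86.5%
```

Reading the output: merging with a 2 s threshold fuses the clustered
episodes (21 → 15 across the four freezers); window metrics barely
move; every (merged) episode is still identified; but the mean
identification delay shifts from 0.41 s *before* onset to 0.13 s
*after* it — merging costs lead time, the central trade-off this
pipeline measures. The same sweep is available from the shell:

```sh
fogmerge simulate --seed 7 --out data/
fogmerge run --data data/ --mt 0,1,2,3 --task detection,prediction --no-cue --out results/
fogmerge report --results results/
```

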