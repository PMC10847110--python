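# gaitcontext

Indoor/outdoor walking-context classification and gait characterization
from a single thigh-worn accelerometer (20 Hz, ±4 g).

Real-world walking is context-dependent: people walk longer, faster, and
with fewer stops outdoors than indoors. `gaitcontext` implements the full
analysis chain that turns a raw thigh-acceleration stream into that
conclusion, for researchers in wearable movement analytics and digital
health:

1. **Segmentation** — stepping bouts are detected from the band-passed
   signal energy; bouts separated by standing gaps shorter than one minute
   are grouped into *walking periods* (the unit of analysis); running-like
   periods (median stride frequency > 1.4 Hz) are excluded.
2. **Biomechanics features** — per period: duration (min); continuity
   `(duration − standing time)/duration × 100` (% of the period spent
   stepping, 100 = no standing); and the mean and SD of stride frequency
   normalized by √(g·l₀), where l₀ is the participant's leg length.
3. **Classification** — a Random Forest (40 trees) and a bagged SVM
   (60 RBF estimators) are trained with leave-one-participant-out (LOPO)
   validation; the best case by average validation accuracy/F1/AUROC goes
   to a held-out 5-participant test set, where the single best fold model
   is selected and used to label mixed and unlabeled periods. Feature
   importance is quantified by permutation (accuracy decrease).
4. **Speed** — stride speed from stride frequency via the power law
   `v = exp(ln(a·f)/(1−b))` with per-participant parameters (a, b);
   speeds are made dimensionless by √(g·l₀).
5. **Statistics** — linear mixed-effects models of duration, continuity,
   and normalized stride speed on context (outdoor vs indoor), with
   participant random intercepts (and periods nested in participants for
   the stride-level speed model); random-effect structures are compared by
   ML AIC.

Because the kind of real cohort this targets is not publicly available,
the package ships a **synthetic cohort generator** whose defaults encode
realistic class-conditional structure (indoor: mean 2.2 min, 61.6%
continuity; outdoor: 11.4 min, 81.7%; outdoor +0.28 m/s; ~80:20
indoor:outdoor mix) and which emits raw waveforms phase-locked to its
ground-truth stride schedule — so every stage, from peak-picking to the
mixed models, is testable end to end.

## Worked example

The numbered scripts under `analysis/` run the study pipeline; each is a
thin driver over the library. A reduced cohort (8 participants × 60
periods) runs in under a minute:

```sh
python analysis/01_generate_cohort.py  --seed 1 --participants 8 --periods 60 --outdir results/cohort
python analysis/02_segment_and_extract_features.py --seed 1 --participants 8 --periods 60
python analysis/03_train_and_select_models.py --seed 1
python analysis/04_characterize_contexts.py --seed 1
```

prints, among other things:

```
ensemble_svm: avg accuracy 0.932, F1 0.957, AUROC 0.958
random_forest: avg accuracy 0.938, F1 0.960, AUROC 0.952
selected case: random_forest (biomechanics features)
best model on the test set: fold P01 (accuracy 0.963, F1 0.976, AUROC 0.966)
permutation importance (accuracy decrease):
              feature  importance_mean  importance_sd
         duration_min           0.2505         0.0286
       continuity_pct           0.0482         0.0129
mean_norm_stride_freq           0.0427         0.0167
  sd_norm_stride_freq           0.0083         0.0076
...
indoor: 375 periods, duration 2.15 min, continuity 62.9%, speed 1.084 m/s
outdoor: 101 periods, duration 10.67 min, continuity 81.1%, speed 1.337 m/s
outdoor-indoor speed gap: 0.253 m/s
duration_min: b = 8.555 (se 0.372, t(474) = 23.0, p = 2.83e-79, structure participant)
continuity_pct: b = 18.41 (se 1.74, t(474) = 10.6, p = 1.55e-23, structure participant)
speed_norm: b = 0.08434 (se 0.0154, t(6981) = 5.5, p = 4.69e-08, structure participant_period)
```

Reading this: LOPO validation accuracy is ~0.94 for both learners and the
random forest is selected; period **duration** is by far the most
informative feature (shuffling it costs 0.25 accuracy); and the mixed
models recover the generator's built-in context effects — outdoor walks
are ~8.6 min longer, ~18 percentage points more continuous, and (via the
normalized effect, ≈0.084·√(g·l₀) ≈ 0.25 m/s at these leg lengths)
faster. At the default scale (20 participants, ~3 400 periods) the
estimates land at the configured 9.25 min / 20.14% / 0.28 m/s values
within sampling error.

The same pipeline is available as one command
(`gaitcontext run-all --seed 1 --outdir results/run`) and as a library
(`gaitcontext.pipeline.run_pipeline`).

## Layout

```
src/gaitcontext/     library: config, synthetic, signals, segmentation,
                     features, classification, speed, stats, pipeline, cli
analysis/            numbered narrative drivers (write to results/)
scripts/acceptance.py  from-scratch recomputation of the headline numbers
tests/               pytest suite (unit, property, end-to-end recovery)
docs/methods.md      model and design notes
```
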