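# melaccent

Modeling perceived **immanent accents** in melodies: which notes listeners
hear as emphasized purely because of the notated score — pitch contour,
note values, rests and meter — before any performer adds expression.

The package is written for music-cognition researchers who collect per-note
salience ratings (integer 0–3, raters × notes) on monophonic melodies and
want the full quantitative pipeline:

1. **score_io** — parse melodies (canonical melody-JSON, monophonic
   MusicXML), with exact rational beat arithmetic and deadpan millisecond
   timing (IOI = onset-to-onset, rests included).
2. **features** — 43 per-note features in five groups (pitch contour 22,
   tempo 2, timing 11, simple phrasing 4, meter 4), plus correlation-based
   selection of one version per multi-version feature (43 → 34).
3. **reliability** — per-note mean ratings, Cronbach's alpha (= ICC(C, k)),
   mean pairwise r, and greedy selection of the alpha-maximizing
   "optimized" rater group.
4. **predict** — multiple linear regression (standardized betas,
   semipartial correlations sr with sr² = R²(full) − R²(−i), p-values) and
   RBF-kernel epsilon-SVR with C/gamma grid search, both under repeated
   10-fold cross-validation; R² is the squared Pearson correlation between
   mean ratings and predictions.
5. **contribution** — each feature group's independent contribution
   ΔR² = R²(full) − R²(without group), per-style/genre subsets, and
   per-rater models with a 20% R² inclusion threshold.
6. **synthetic** — seeded generator of melodies and simulated rater panels
   (noisy, quantized linear mixtures of the true features, including
   pure-noise raters) so the whole pipeline is testable with known ground
   truth.

## Worked example

```sh
melaccent demo --out-dir demo_out --seed 7
```

runs the pipeline end to end on a small synthetic study (12 melodies,
12 raters) and logs:

```
INFO stage extract: 865 notes x 43 features
INFO stage reliability: alpha=0.765 -> optimized alpha=0.873 (6 raters)
INFO stage selection: 43 -> 34 columns
INFO stage svr: mean R2=0.8192
INFO stage report: mlr R2=0.8156; wrote demo_out/summary.json
```

Reading the numbers: the 12-rater panel agrees moderately (alpha 0.765);
greedily dropping raters whose omission raises alpha leaves a 6-rater core
at alpha 0.873. Variant selection keeps 34 of the 43 feature columns. On
this panel's mean ratings, cross-validated R² is 0.816 (MLR) and 0.819
(SVR) — high because simulated raters are linear readers of the features;
real panels are harder. `summary.json` also contains the group ablation
(here pitch contour dominates: ΔR² 0.585 vs 0.060 for timing) and the
misplaced-accent example: in a 70-note melody with 15 binary accents,
predicting one accent on the wrong note alone drops R² from 1 to 0.8375 —
a 16% loss — which calibrates expectations for accuracy on near-binary
rating profiles.

The same stages are available as subcommands (`extract`, `reliability`,
`fit`, `ablate`, `simulate`) over CSV/JSON artifacts, and as plain library
calls:

```python
from melaccent import synthetic, features, reliability, predict

study = synthetic.demo_study(master_seed=0)          # ~4200 notes, 30 raters
sel   = reliability.optimize_group(study.ratings)
y     = reliability.mean_ratings(study.ratings, sel.members)
X34, report = features.select_variants(study.features, y.reindex(study.features.index))
cv    = predict.cross_validate(X34, y, method="mlr", k=10, reps=10, seed=0)
print(cv.mean_r2)
```

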