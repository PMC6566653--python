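# Methods

`melaccent` models *immanent* melodic accents: the perceived emphasis a note
carries purely because of its position in the notated score — its pitch
relative to the recent contour, its duration relative to its neighbors, its
place in the metrical grid, its proximity to rests and unit boundaries —
independent of anything a performer adds. The modeling target is the
per-note mean of a panel of listeners' 0–3 salience ratings; the predictors
are 43 deterministic per-note features computed from the score alone.

## Score representation

A melody is an ordered list of sounded note events with exact rational beat
positions and durations (quarter-note units), a notated meter (possibly
changing at measure boundaries), and a nominal tempo. Milliseconds are
derived assuming "deadpan" rendering: onset_ms = onset_beats · 60000 /
tempo_qpm.

* **IOI** (inter-onset interval) is onset-to-onset, so a notated rest
  lengthens the preceding note's IOI; the final note's IOI is its nominal
  duration. This keeps the IOI feature defined for every note and matches a
  rendering in which nothing sounds during rests.
* Pitch is integer MIDI semitones; the repertoire modeled is notated Western
  art music, so no microtonality.
* Anacrusis (pickup) measures are measure 0, with `beat_in_measure` offset
  so the first full downbeat lands at its notated position.
* Indices (notes, measures) are 0-based throughout; beats are
  `fractions.Fraction`, so grid membership tests are exact.

The MusicXML reader covers the monophonic partwise subset (ties merged, dots
via duration encoding, chords rejected); tempo defaults to 100 qpm with a
warning when the file carries no tempo marking.

## Features

43 features in five groups; full definitions sit in the feature registry
(`melaccent.features.REGISTRY`, dumpable as JSON). Conventions that apply
everywhere:

* a **leap** is an interval of more than 2 semitones;
* contexts that would cross melody boundaries yield 0 (binary features must
  stay in {0,1}, and there is no principled partial evaluation);
* "longest", "peak", "shorter" are strict comparisons; "equally short" means
  identical notated duration (durations are exact rationals, so ties are
  well defined, and tied peaks are simply not peaks);
* gradual weights are stored as magnitudes (≥ 0); the regression
  coefficient carries any direction;
* adjacency ignores rests: pitch and timing contexts run over consecutive
  *sounded* notes, while rest effects are carried explicitly by the phrasing
  features 36–37.

Choices worth flagging:

* **Running pitch mean** (features 1–2): preceding notes whose onsets fall
  within the previous two notated measures, extended backwards until at
  least 10 preceding notes are included; the first note uses its own pitch.
* **Leap weights**: log2(|ΔST| − 1) for leap features (3–12), log2(|ΔST| + 1)
  on the first interval for peak features (13–16). Since the minimum leap is
  3 semitones, nonzero leap-log weights are always ≥ 1.
* **Feature 27** (log version of long-after-short): the natural-log ratio
  ln(IOI_short/IOI_long) is negative by construction; it is stored as its
  magnitude to keep the gradual-column convention. Only one of 25/26/27
  survives variant selection anyway.
* **Feature 33** (gradual longest-of-five): defined here as
  1 − mean(4 neighbor IOIs)/IOI_target, clipped at 0 — a simple relative
  weight consistent with the group's other gradual features.
* **Meter** (40–43): each supported meter maps to four grid periods
  (sub-beat, tactus, half-bar-or-bar, bar-or-2-bars); e.g. 4/4 → (½, 1, 2, 4)
  quarter-beats, 6/8 → (½, 1½, 3, 6), 3/4 → (½, 1, 3, 6). Labeling is
  *exclusive*: a note gets only its highest applicable level. Cumulative
  labeling would make the four columns perfectly nested and collinear.
  Two-bar grids are anchored at measure 0. The mapping table covers the
  common simple and compound meters and is user-extensible; unsupported
  meters raise an error listing the supported set.
* **Punctuation** (38–39): a deliberately small boundary detector — after a
  note followed by a rest, after the last note, and after a note at least
  twice as long as both neighbors when followed by a leap. It is pluggable
  (`extract_phrasing(boundary_fn=...)`) so a fuller melodic-segmentation
  model can be substituted without touching the feature surface.

**Variant selection.** Eight features exist in binary and gradual versions
(variant groups {3,4}, {5,6}, {7,8}, {9,10}, {13,14}, {15,16}, {25,26,27},
{32,33}). Given the mean ratings, the version with the largest absolute
correlation is retained per group (point-biserial for binary columns —
numerically Pearson on 0/1 coding — Pearson for gradual); exact ties go to
the lower feature id, and a zero-variance column counts as correlation 0
with a warning. 43 − 9 = 34 columns survive.

## Rater aggregation and reliability

Ratings form a raters × notes integer matrix on 0–3; unmarked notes are 0 by
the rating interface's coding, so there is no missing-data path. The overall
measure is the per-note mean across raters. Panel consistency is Cronbach's
alpha with raters as items and notes as cases (equivalently ICC(C, k)), plus
the mean pairwise Pearson correlation. The *optimized group* is found
greedily: repeatedly recompute alpha with each remaining rater omitted,
remove the rater whose omission raises alpha most, stop when no omission
helps or only two raters remain (alpha is undefined below that); ties break
to the smallest rater id for determinism.

## Models and evaluation

**MLR** is ordinary least squares on z-scored predictors and response;
coefficients are standardized betas. Each feature's semipartial correlation
is computed from its t statistic, sr_i = t_i · √((1 − R²)/df_res), and
satisfies sr_i² = R²(full) − R²(without i) to numerical precision. p-values
are two-sided t-tests with df = n − p − 1, reported descriptively with no
multiple-testing correction. Exact collinearity raises an error naming the
offending columns.

**SVR** is epsilon-SVR with an RBF kernel (scikit-learn), predictors
z-scored, epsilon = 0.1, C and gamma chosen by grid search minimizing inner
3-fold squared error over coarse powers of 4 (C ∈ 2⁻⁵…2¹⁵, gamma ∈
2⁻¹⁵…2³); all of this is overridable via `SvrConfig`.

**Cross-validation** is k-fold (default k = 10) with fresh random note
partitions per repetition (default 10 repetitions), out-of-fold predictions
pooled over all notes per repetition, and R² — the squared Pearson
correlation of observed and predicted ratings — averaged over repetitions.
Folds are random over notes; a melody-grouped split is deliberately not the
default, since notes are modeled as exchangeable rows. For
`cross_validate(method="svr")`, the grid search is run once on the full data
and the chosen (C, gamma) reused across folds; a fully nested per-fold
search is available through `fit_svr` but is an order of magnitude slower
and changes results little on these feature sets.

**Two R² conventions.** Squared correlation cannot be negative, so the
per-rater reports use 1 − SSE/SStot on out-of-fold predictions instead,
which goes negative when the model predicts a rater worse than their mean —
an informative outcome for inconsistent raters. Every report labels which
convention it used; aggregate analyses always use squared correlation.

**Group ablation.** ΔR²(g) = cross-validated R²(full) − R²(all features
except group g), with identical fold partitions for the full and every
reduced model (same seed) so each difference is a paired comparison. Because
groups share variance (a long note is often also on a strong beat), the five
ΔR² values generally sum to less than the full R².

**Misplaced-accent example.** `accent_misplacement_r2(n, a, m)` builds a
binary truth vector (a accents among n notes) and a prediction with m
accents moved to unaccented positions, and returns their squared
correlation. For (70, 15, 1) the closed form gives r = 755/825, R² ≈ 0.8375
— a 16% accuracy loss from a single wrong note, which is why high R² against
near-binary rating profiles is hard.

## Synthetic studies

The generator exists to give every pipeline stage a ground truth; it targets
statistical structure, not musicological authenticity.

* **Melodies**: random walks over a note-value alphabet (sixteenth to half,
  with dotted eighth and dotted quarter), meters drawn from {4/4, 3/4, 2/4,
  6/8}, tempi uniform in 60–160 qpm, rest probability 0.08, leap probability
  0.25 with sizes 3–12 (smaller more likely), occasional 3–4-leap arpeggio
  runs, pitches reflected into a 55–84 MIDI range. Melodies that happen to
  contain no leap or no long-after-short pattern are resampled (bounded at
  100 retries) so the structural features are always exercised.
* **Raters**: each rater's latent judgment is a group-weighted sum of the
  standardized true feature signal plus Gaussian noise (noise SD in units of
  the latent's SD), quantized to 0–3 through thresholds set at that rater's
  latent quantiles (0.55, 0.80, 0.93 by default) so most notes get 0 —
  mirroring a task where raters mark only the most important notes. A lapse
  probability replaces responses with uniform draws; lapse = 1 is a
  pure-noise rater.
* **Default study**: 60 melodies of 60–80 notes (≈ 4200 notes) and 30
  raters — 15 consistent (noise 0.8, lapse 0.02), 10 weakly consistent
  (noise 2.0, lapse 0.1, each over-weighting a different feature group), 5
  pure noise. Generative weights live at the feature level (a few features
  per group) and are scaled by group multipliers in a fixed known order —
  pitch contour 1.0 > timing 0.75 > tempo 0.55 > phrasing 0.40 > meter
  0.25 — giving ground truth for both feature-sign recovery and group-rank
  recovery. Everything derives from one master seed; regeneration is
  byte-identical.
* **Calibrated continuous response**: `linear_response` returns y = Zβ* + ε
  with the noise variance set so the explainable variance fraction equals a
  target (default 0.6). Recovery tests use this for exact calibration, since
  the quantized 0–3 panel attenuates variance in ways that cannot be pinned
  to a target R². Recovery is evaluated on the post-selection (34-column)
  matrix, matching the pipeline's actual order of operations.

**What passing recovery tests does and does not show.** The simulated raters
are noisy linear readers of the very features the model uses, so recovery
tests validate the machinery — extraction correctness, reliability
screening, estimation, ablation accounting — not the psychological claim
that human accent perception is feature-linear. Real rating data bring
non-linear feature interactions, serial position effects, and
fragment-repetition cues the generator does not emulate.

## Problem sizes and numerical choices

Tests and the acceptance script run the default study shape (≈ 4200 notes,
30 raters) where the check is about study-scale behavior, and 6–12-melody
studies where the check is structural; cross-validation repetitions are
reduced (2–3) inside ablation loops, where the paired-fold design already
suppresses partition variance. Feature-oracle equivalence is asserted
exactly for binary columns and at 1e-9 for gradual ones; alpha identities at
1e-9; semipartial identities at 1e-9. Degenerate inputs (constant response,
constant rater, zero-variance feature, empty rater subset, unsupported
meter) raise typed errors or warn-and-continue as documented per function.

## Known limitations

* The punctuation detector is a three-rule simplification; features 38–39
  inherit its coarseness (the hook exists to replace it).
* The metrical-level table covers common meters only; odd meters must be
  supplied by the caller.
* MusicXML support is the monophonic partwise subset; there is no MIDI
  reader.
* Per-rater SVR at full panel scale is slow with wide grids; the per-rater
  default is MLR, with SVR opt-in.
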