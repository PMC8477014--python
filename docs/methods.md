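# Methods

## The classification problem

A home-cage recording is a stream of mutually exclusive behavior labels,
one per video frame at a nominal 33.3 Hz (the 30-fps camera rate is
accepted via configuration; the default frame rate is 100/3 Hz so that a
100-frame sample spans exactly 3 s).  The task is to predict, from a 5-min
window of behavior alone, whether the window falls in the day or the night
phase of a 10-h/14-h light cycle.  Phase ground truth is a deterministic
function of time: `phase(t) = day iff (t - day_start) mod 86400 < 36000`.

## Encoding

* **Samples.** Frames are grouped into consecutive blocks of 100
  (trailing partial block discarded).  Frame *i* is attributed to the bout
  containing its midpoint time `(i + 0.5)/fps`, which is unambiguous even
  for bouts shorter than a frame.  Each sample is encoded as the
  *composition vector* of per-behavior time fractions (non-negative,
  summing to 1) plus the dominant (longest-duration) label; dominant-label
  ties break to the behavior whose bout starts earliest in the sample.
  A one-hot-of-dominant encoding is available as an option; composition is
  the default because it subsumes one-hot and loses no duration
  information.
* **Windows.** Overlapping windows of 100 samples start at every
  `stride`-th sample.  A window is kept only if the phase is constant at
  all 100 sample starts; straddlers (< 0.6 % of candidates under the
  default schedule) are dropped rather than given a mixed label.  The
  flattened form is step-major: column `t * 37 + b` holds behavior *b* at
  step *t*, 3,700 columns in all.
* **Behavior dropping** (for feature elimination) removes whole behaviors
  *before* windowing and does not renormalize the remaining composition —
  time spent in a dropped behavior reads as absence of activity, not as
  activity redistributed over the remaining behaviors.  A sample fully
  occupied by dropped behaviors receives a reserved "none" dominant label.

## The synthetic generator

Real round-the-clock recordings are not redistributable, so the package
generates its own. The generator is a **circadian semi-Markov process**:
bout durations are first-class (clamped log-normal by default; gamma and
fixed available), transitions between *distinct* behaviors are Markov
(zero transition-matrix diagonal — a behavior change is what delimits a
bout), and all parameters switch between a day set and a night set.  The
governing phase is the phase at the *bout start*: a sleep bout begun in the
day keeps day parameters even if it crosses into night, matching the
observation that the long sleep episodes belong to the resting (day) phase.
Streams are exactly reproducible from a single integer seed.

### Default calibration (37 behaviors)

Bout-frequency weights give the day phase frequent Sleep, Twitch, Groom and
quiescent postures, and the night phase an elevated exploratory repertoire
(Dig, Forage, Walk.Left/Right, Turn, Eat, ...).  Durations:

| quantity | day | night |
|---|---|---|
| Sleep duration | log-normal, median 12 s, σ=1.25, clamp [0.03, 460] s | median 8 s, σ=0.9, clamp [0.03, 300] s |
| Sleep bout share | 2.0 % | 0.8 % |
| non-sleep durations | per-behavior medians 0.2–2.5 s, σ≈0.5–0.9 | same, times per-behavior factors 0.7–1.45 |
| target bouts / 5-min window | 225 | 263 |

The day Sleep tail yields bouts above 300 s only in the daytime, about 2–3
times per simulated day, occasionally hitting the 460-s cap.  The non-sleep
duration medians are multiplied by a single per-phase factor solved
numerically (Brent's method on the closed-form clamped-log-normal means,
weighted by the exact stationary distribution of the transition kernel) so
that the expected bout rate gives 225 day / 263 night bouts per 300-s
window.  This solve is analytic and deterministic; nothing is fitted to
simulation output.  Minimum bout duration is clamped at 0.03 s everywhere;
clamping (not resample-until-inside) keeps bound satisfaction
deterministic.

### Controls

* **Null** (`make_null_config`): night parameters replaced by a copy of the
  day parameters.  Window content is then independent of the label, so any
  classifier's true accuracy on class-balanced data is exactly ½.
* **Order-only** (`make_order_only_config`): both phases cycle
  deterministically through k behaviors — day forward, night backward —
  with *identically distributed* bout durations.  Durations are jittered
  (i.i.d. log-normal, mean = `bout_s`, σ = 0.75 on the log scale) rather
  than fixed: with exactly fixed durations every window is a rotation of
  one periodic pattern, and a linear classifier can exploit the positional
  phase of those rotations (equal class-mean scores forbid only *perfect*
  separation, not above-chance accuracy).  Jitter makes the positional
  phase diffuse within a window, leaving the order reversal — an
  adjacent-pair property no single-position feature can see — as the only
  signal.  `jitter_sigma=0` recovers the fixed-duration variant for
  illustration.

### What the generator does not model

Posture and kinematics, spatial position, sub-second grooming
microstructure, inter-individual variability, scorer noise and label
ambiguity, and day-to-day drift.  Passing tests on this generator show that
the pipeline recovers the *kinds* of structure it encodes (composition
contrasts, duration tails, behavior order); they do not certify accuracy
levels on real recordings.

## Models

* **Tabular** (on the 3,700-column flattened windows): logistic regression
  (C = 0.1, newton-cg, L2 — the columns are heavily collinear), random
  forest (80 trees, √p features per split, min leaf 40), RBF SVM
  (γ = 1, C = 10).  These defaults are the tuned values for the original
  recordings; on other data they should be re-tuned with `grid_search`
  (5-fold, grouped, ties to the first spec in grid order).  The shipped
  grids span C ∈ {0.01…10} for LG, trees {80,160,320} × min-leaf {2,10,40}
  for RF, and C {1,10,100} × γ {1e-3…1} for the SVM — the γ grid reaches
  1e-3 because typical squared distances between composition windows are
  of order 10², and the forest grid reaches min-leaf 2 because individual
  position-tagged composition columns are weak and shallow leaves cost the
  forest several points.  SVM ROC scores are the decision values through a
  logistic link (any monotone map preserves the ROC).
* **Ensemble**: equal-weight majority vote of the three tabular models.
  Three voters and two classes cannot tie.  Its ROC score is the mean of
  the member scores, since votes are label-valued.
* **Sequence model**: 1D convolution over the step axis (kernel ≥ 2 steps —
  a kernel of 1 cannot see order) → ReLU → non-overlapping max-pool →
  bidirectional LSTM (concatenated final hidden states) → dropout → single
  sigmoid unit, trained with Adam on binary cross-entropy, early-stopped on
  validation loss with best-weights restore.  The implementation is
  self-contained numpy with manual backpropagation through time,
  finite-difference-checked in the test suite, and fully deterministic
  given the seed on a fixed platform (across BLAS builds, repeat runs agree
  in accuracy to within about one percentage point).  Library defaults are
  64 filters / kernel 5 / pool 2 / 64 LSTM units / dropout 0.3; the test
  suite's experiments use a smaller instance (32 filters, pool 4, 24
  units, ≤ 10–12 epochs) — the reported experiments are sized for a single
  CPU, and on the synthetic task the small instance already saturates.

## Feature selection

Backward elimination operates on whole behaviors, not columns: each
candidate removal rebuilds samples → windows → flattened matrix without
that behavior (elimination must precede windowing because every behavior
owns one column per step).  Per iteration, the behavior whose omission
yields the highest test accuracy is removed; the run stops when the best
candidate falls more than `tolerance` (default 0.5 accuracy points) below
the best accuracy seen, for `patience` (default 1) consecutive iterations,
and returns the set at the accuracy peak.  Accuracy is measured on a
grouped shuffled-block 20/50/30 tune/train/test split.  Permutation
importance permutes all of a behavior's columns jointly with one row
permutation, so the behavior's whole temporal pattern moves between
windows.

## Evaluation protocol

* **Grouped blocks.** Overlapping windows share samples, so the unit of CV
  assignment is a contiguous block of `ceil(window_len / stride)` windows —
  no test window then shares any sample with a train window.
* **Stratification.** Blocks are stratified by label before fold
  assignment.  Without this, a no-signal dataset shows the classic
  pessimistic CV bias: the training fold's majority class anti-correlates
  with the test fold's, and majority-leaning learners land measurably
  *below* ½ at chance.
* **Class balance for chance-level checks.** The 10/14 schedule makes night
  58 % of windows, so a majority-class predictor scores 0.58.  Chance-level
  control experiments therefore subsample the majority class (seeded) to
  parity before splitting; accuracy of any classifier on balanced,
  label-independent data is then binomial around ½, and the checks use the
  95 % binomial interval at the evaluated window count.
* **Metrics.** Accuracy is reported as mean ± SD *across CV folds*;
  ROC/AUC via the empirical curve (trapezoidal area = pairwise rank
  statistic, ties counted half, verified against brute force); confusion
  counts, and sensitivity/specificity for both classes (undefined ratios
  are NaN, never silently 0).  Train AUC is reported alongside test AUC as
  an overfitting guard.  Behavior summaries compare per-window behavior
  durations between phases with Welch's unequal-variance t-test,
  uncorrected for multiple comparisons and flagged as such.

## Numerical choices and degenerate inputs

Composition rows sum to 1 ± 1e-9 (≤ 1 after behavior dropping); transition
rows sum to 1 ± 1e-9 with an exactly zero diagonal; stream contiguity is
validated to 1e-9 per bout with errors naming the offending bout index.
Empty ethogram files and zero-length streams are rejected rather than
returning empty containers.  Single-class training labels are an error —
a silent constant predictor would corrupt ensemble votes.  Grid-search and
elimination ties break deterministically (first in grid order; first
candidate at the maximum).

## Experiment sizing

The shipped experiments are sized for a single desktop CPU: chance-level
and effect-recovery checks use roughly 2,000 windows (9 simulated null
days at stride 100; 2 calibrated days at stride 25), the order-only
experiment 3 days at stride 50, and the elimination noise-injection study
20 replicates of a 5-behavior reduced config at stride 5.  Larger runs
change none of the qualitative results.

## Known limitations

* The 37-name catalog beyond the behaviors with documented day/night roles
  is a plausible stand-in vocabulary, not an exact scoring-software export.
* The semi-Markov generator has no within-phase nonstationarity (no
  anticipatory activity before light transitions) and no long-range
  dependence beyond bout order.
* Day/night separability under the default calibration is stronger than in
  real recordings (classifiers saturate near 1.0); accuracy *levels* on
  synthetic data are not comparable to real-data accuracy, only the
  contrasts between models and controls are meaningful.
* The sequence model's bitwise reproducibility is platform-dependent
  (BLAS); seeds fix everything else.
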