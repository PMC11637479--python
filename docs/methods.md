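# Methods

## Scope and data model

`capiscore` starts where image analysis ends: its input is a delimited-text
table with one row per NVC image, carrying the counts the measurement
software produced (capillaries, giants, abnormal shapes, tortuosities,
haemorrhages) and the width in mm of nailfold the image covers, plus a
per-exam calibration flag. Counts — never percentages — are the canonical
image-level representation; percentages are only defined at exam level, after
pooling, so denominators are never ambiguous. A missing haemorrhage count is
a validation error rather than an implicit zero: the normal/non-specific
split depends on haemorrhage presence, and silent missingness would change
classifications. One CSV dialect is used throughout (comma, `.` decimal,
UTF-8, header required), and floats are serialized with the shortest
round-tripping representation so write → read → write is byte-identical.

## Quality control and aggregation

Exams are excluded, in this order, when they have fewer than 8 images, when
they are uncalibrated, or when no capillaries were counted at all; the first
failing check is reported. The 8-image floor is configurable
(`--min-images`) for sensitivity analyses.

Exam features are **pooled**: density = Σ capillaries / Σ width, and each
percentage uses the exam-wide capillary count as denominator. Pooling weights
every image by the nailfold width it actually covers and avoids the
small-denominator instability of averaging per-image ratios. The unweighted
per-image mean density is exposed as a separate diagnostic
(`per_image_mean_density`) but never feeds the rules: the feature-vector type
guarantees the identity `density = total_capillaries / total_width_mm` (to
1e-9 relative), which an image-averaged density would violate. Pooling makes
aggregation exactly order-invariant (widths are summed with an
exactly-rounded `fsum`) and invariant under splitting an image's counts into
two images with the same totals.

## The decision tree

The eleven thresholds sit in a single frozen `Thresholds` object whose
defaults are the published cut-offs; every comparison in the engine is a
(feature, operator, threshold-field) triple, so a sensitivity analysis only
touches configuration, never code. Three choices deserve note:

* **"Giant capillaries are detected"** is read minimally as `pct_giant > 0`
  — one giant capillary anywhere in the exam suffices.
* **Low-density staging precedence.** Below 5 capillaries/mm the pattern
  starts at SSc-late, may be re-staged to SSc-active (`G ≥ 33%` or
  `A ≤ 7%`), and is then subject to an unconditional final clause
  (`G ≤ 7%` or `A ≥ 15%` → SSc-late) that is evaluated last and wins
  whenever it fires. Both override clauses can fire simultaneously (e.g.
  `G = 5%, A = 5%`); the "applied last, regardless" ordering resolves every
  such case deterministically in favour of SSc-late.
* **The non-SSc branch needs no density guard.** Rule 4 nominally applies
  "when density is > 6", but any exam reaching it already failed Rule 1's
  `D ≤ 6` disjunct, so the condition is an invariant of the route, not a
  third branch.

Feature values are compared exactly as computed; no rounding precedes a
threshold test. Each exam's output records which disjuncts fired, in
evaluation order, from a fixed 13-label vocabulary — the trace is never
empty.

## Gold standard

Three blinded raters grade each exam; the gold standard is the verdict shared
by ≥ 2 of 3 ("majority"), with unanimity tracked separately ("full
consensus"). Ungradable is an ordinary label in the vote: a 2-vote ungradable
majority is a valid consensus outcome, and such exams — like exams with three
distinct verdicts — are excluded from pattern analysis downstream. A triple
with two agreeing patterns and one ungradable abstention resolves 2–1 to the
pattern. Exactly three raters are required; n-rater generalizations are out
of scope.

## Evaluation protocol

Accuracy is assessed per algorithm step: the SSc/non-SSc binary (both sides
mapped through the group), SSc staging restricted to exams whose **gold**
label is SSc, the normal/non-specific split restricted to gold non-SSc exams,
and the overall five-class comparison. Restriction by the gold label means a
prediction on the wrong side of Rule 1 is excluded from staging metrics
rather than counted as a staging error; when such a cross-side prediction
occurs inside a restricted step it receives its own matrix column rather than
crashing or being silently dropped. Matrices are rows = true /
columns = predicted. A precision over an empty predicted column or a recall
over an empty true row is reported as NaN and excluded from any averaging —
never substituted with 0. The matrix/metric computation is cross-checked in
the test suite against naive counting loops and against scikit-learn, which
is used only as an oracle.

## Synthetic cohorts

The simulator emulates the structure of a consensus-graded referral cohort:
pattern mix 231 : 326 : 162 : 122 : 40 (normal, non-specific, early, active,
late), image counts per exam from a normal(24.8, 9.9) truncated at the
8-image QC floor, and per-image widths from a normal(1.76 mm, 0.3) truncated
at 0.2 mm, so an average exam covers ≈ 44 mm and ≈ 300 capillaries.
(Truncation shifts the realized means slightly above the nominal ones —
about +1 image per exam.) For each exam a true density is drawn from its
pattern's truncated normal; per-image capillary counts are Poisson with mean
density × width; giant/abnormal/tortuous counts are binomial per capillary;
haemorrhage counts are Poisson per image. A Poisson count law is a modelling
choice — only per-exam means and dispersions were available to match.

Two presets ship:

* **separable** — each pattern's distributions are concentrated well inside
  that pattern's rule region (verified at 10,000 exams: ≈ 99.8% of exams are
  classified as generated). It answers "does the pipeline recover known
  truth?", not "how accurate is the rule set on real data".
* **overlapping** — means pulled toward the thresholds; accuracy drops to
  ≈ 0.5 with confusion concentrated between neighbouring stages, exercising
  non-trivial confusion matrices and per-class metrics.

Both are synthetic constructions, labelled as such; they do not estimate any
clinical cohort's feature distributions, and simulated accuracies are
properties of the presets only. Simulated raters report the truth or, with a
configurable error probability, a uniformly chosen *adjacent* stage on the
severity chain normal ↔ non-specific ↔ early ↔ active ↔ late — the simplest
error structure consistent with expert disagreement concentrating between
neighbouring patterns. Ungradable verdicts are off by default
(`--ungradable-rate`), and QC violations (< 8 images or uncalibrated) can be
planted with `--qc-violations` for testing the filter. Everything is driven
by one `numpy` generator seeded from the config: identical config + seed
gives byte-identical tables.

## Numerical and degenerate-input choices

* Threshold comparisons use IEEE doubles directly; the boundary test suite
  exercises every cut-off at ±1e-9.
* An exam with zero total capillaries is a QC exclusion (and a precondition
  error if aggregation is forced), not a zero-density classification.
* Evaluation steps whose restricted set is empty report n = 0 with NaN
  metrics.
* Problem sizes in the test suite and acceptance script (10,000-exam
  closed-loop cohorts, ~600,000-point rule grids, 1,000 random metric
  cohorts) were chosen so the full check-suite completes in well under a
  minute each while keeping Monte-Carlo error far from the asserted margins.

## Limitations

* Upstream image processing (capillary detection, sizing, shape
  classification) is out of scope; garbage measurements in, garbage patterns
  out.
* The simulator draws marker counts independently per capillary, images
  independently within an exam, and raters independently of exam difficulty;
  real data violate all three. Passing closed-loop tests therefore
  demonstrates pipeline correctness, not clinical performance.
* The published clinical accuracies of the rule set cannot be reproduced
  here because the underlying cohort is not publicly deposited; no attempt
  is made to imitate them with tuned synthetic data.
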