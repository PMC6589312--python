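# Methods

## The problem

JOAS-style severity grading of conjunctival hyperaemia is ordinal (0
none, 1 mild, 2 moderate, 3 advanced) and subjective: certified graders
disagree, mostly by one step.  Evaluating an automated grader therefore
cannot reduce to accuracy against a single "truth"; the natural yardstick
is *agreement relative to expert-expert agreement*.  This package
implements that yardstick — the kappa distance score — together with the
surrounding workflow: reference-label construction, grader
qualification, ensemble rules, augmentation planning, vessel-area
measurement and the nonparametric comparison statistics.

## Agreement model

All agreement is quadratic-weighted Cohen's κ on the **fixed**
4-category scale: disagreement between grades i and j costs
(i−j)²/9 regardless of which grades happen to occur in a particular
panel.  Using observed categories only would make κ values
incomparable across panels, so the fixed scale is deliberate.  Images a
rater marked ungradable, or did not rate, are excluded pairwise and
counted; the grader-qualification screen instead excludes listwise
(an image unusable for any rater in the qualification set is dropped
for all), because qualification compares all graders on one shared
image set.  Degenerate input — both raters constant and identical,
which zeroes the expected disagreement — is an error, not a value.

Thresholds follow the asymmetric wording of the workflow they encode:
graders qualify when κ is **strictly above** 0.7; models are screened
out while their mean inter-model κ is **0.7 or less**.

## KDS

With expert pairs (A, B) and (C, D) each grading one half of a
validation set, a responder n scores

    KDS = (κ_na + κ_nb − 2 κ_ab) + (κ_nc + κ_nd − 2 κ_cd),

with κ_na, κ_nb, κ_ab computed on the A/B half only and κ_nc, κ_nd,
κ_cd on the C/D half.  KDS is linear in its inputs (adding δ to both
grader-grader kappas shifts the score by −4δ) and 0 for a responder at
exactly expert-level consistency.

Ensembles are referenced to the experts' *adopted* validation grade
(agreement → that grade; disagreement → specialist's grade when one is
available, otherwise the image is dropped).  The half rule demands
strictly more than half of the members match the expert grade — 3 of 6
is not enough, which is why even-sized ensembles outperform their
odd-plus-one counterparts on the half score — and otherwise falls back
to the plurality member grade.  The least rule demands a single match.
Plurality ties default to the lowest tied grade (deterministic and
conservative: never overstates severity); `highest` and `nearest_mean`
policies are selectable.  The mean-round combiner averages the member
grades and rounds half-up.

The multimodel table evaluates the top-n ranked members for
n = 2..N (N = 7 when seven models survive screening; smaller panels
shrink the range accordingly), and standardises each series with its
**population** standard deviation (divide by the number of n values):

    KDS_(n,multi) = z(KDS_(n,half)) + z(KDS_(n,least)).

Each z-series sums to zero by construction; a series constant across n
has no defined standardisation and is reported as a degenerate-input
error.  Ranking ties are broken lexicographically by responder id.

## Vessel-area occupancy

The vessel-area measurement reproduces the *interface* of per-pixel
threshold tools: pixel redness r = (R − G)/(R + G + 1) ∈ [−1, 1),
mask = r > threshold (default 0.15) inside an optional ROI (default:
full frame), percentage = 100 · masked / evaluated pixels.  The
normalised red-green contrast is illumination-robust and monotone in
vessel paint; raising the threshold can only shrink the percentage, and
the measure is mirror-invariant.  Inputs with a tiny ROI (< 100 px) or
a degenerate redness distribution are flagged unmeasurable (the percent
is still reported for inspection).  No automatic conjunctiva
segmentation is attempted — the ROI parameter leaves the denominator
choice to the caller.

## Augmentation

Grade-stratified amplification rebalances a 688/1734/1176/102 training
distribution by factors 4/2/2/18.  Per grade, 2/1/1/9 processing types
are sampled once (not per image) without replacement from nine kinds —
no correction, contrast ±25% about mid-grey, γ = 0.75, γ = 1.5,
per-channel histogram equalisation, Gaussian noise (σ = 10 grey
levels), salt-and-pepper (1% of pixels), and mirroring — and every
chosen type is emitted both plain and mirrored, so multiplier = 2 ×
types.  "Inversion" is horizontal mirroring: intensity inversion would
destroy the redness signal this domain lives on.  Contrast/noise
parameters are unpublished for the original workflow; the defaults here
are visually mild, order-of-magnitude-typical choices and are
configurable.  Per-grade class weights (1.5, 1, 1, 5) are carried as
classifier-stage metadata.

## Grade classifiers

The classifier contract is fixed (8-bit RGB → 256×192 bilinear resample
→ [0, 1]; output a probability simplex over four grades, argmax with
lowest-grade tie-break), the backend is pluggable.  Deep networks are
intentionally out of scope; the shipped baseline extracts three redness
features (mean redness, vessel-area %, redness SD) and fits a
class-weighted multinomial logistic regression.  Optional bootstrap
subsampling and seeded feature jitter (applied at fit and, as a pure
function of seed and feature vector, at predict time) decorrelate
ensemble members trained on one corpus, emulating how independently
trained networks disagree on borderline images.  Non-matching aspect
ratios are stretched, not cropped.

## Statistics

Spearman ρ (midranks, large-sample p) and tie-corrected Kruskal–Wallis
come from scipy.  Steel–Dwass all-pairs comparisons are computed
directly: per pair, midrank the combined sample, standardise the rank
sum with the tie-corrected variance, and refer √2·|t| to the
studentized-range distribution with k groups and infinite degrees of
freedom (the classical formulation).  A Monte-Carlo permutation mode
relabels the full dataset and compares each observed |t| to the null
distribution of the **maximum** pairwise |t|, preserving the familywise
adjustment; it serves as the distribution-free cross-check in the test
suite.  No confidence intervals are attached to KDS — there is no
established interval method for composites of dependent kappas, and the
package does not invent one.

## Synthetic data

The generators define the study conditions for every test:

* **Panels.**  Latent grades are drawn from the 688:1734:1176:102
  distribution; a rater with adjacency-error rate ε reports the truth
  with probability 1−ε and otherwise a uniformly chosen adjacent grade
  clamped to the scale (end grades are slightly stickier, as ordinal
  scales behave); with probability u the rater answers ungradable.
  Because quadratic weights barely penalise one-step errors, ε = 0.22
  is the default that puts a rater pair at the closed-form pairwise
  κ of 0.729 — the certified-grader regime.  `expected_kappa` evaluates
  that closed form exactly by enumerating the 4×4 joint distribution,
  and the simulator is required (in tests) to converge to it.
* **Images.**  A pale scleral field (RGB ≈ 232/224/216) with Gaussian
  texture noise (σ = 4), crossed by red random-walk polyline vessels;
  vessel count ranges (1–4, 4–10, 9–17, 16–30) and thickness ranges
  grow with grade and deliberately **overlap** between adjacent grades —
  severity is a continuum, and the overlap is what makes trained
  models and simulated raters disagree on borderline images rather than
  being trivially separable.  The generator records its painted-pixel
  count per image as ground truth for the vessel-area module.

What the generators do *not* emulate: photographic appearance (specular
highlights, lids, fluorescein staining), conjunctiva segmentation
failures, inter-image illumination drift, or any spatial correlation
between rater errors and image content.  Passing tests therefore
demonstrate the correctness and internal consistency of the evaluation
machinery under controlled conditions, not clinical performance on real
photographs.

## Replay: sizes and determinism

The end-to-end replay defaults to 400 training + 400 validation images
and 6 stand-in classifiers — small enough to run in well under a minute
on one CPU while leaving every stage statistically meaningful (tests
use 250 + 250).  Every random draw descends from one root seed through
named substreams (crc32 of the stage name), so stages are independently
reproducible and two runs at the same seed produce byte-identical JSON
reports.  Per-image render streams are keyed by (seed, image id), so
regenerating any subset of images reproduces them exactly.

## Known limitations

* The vessel-area redness score and its 0.15 threshold are this
  package's own operational definition of the per-pixel-threshold
  interface; published percentages from proprietary tools are not
  comparable.
* The Steel–Dwass analytic reference uses the infinite-df studentized
  range; for very small groups the permutation mode is the better
  authority.
* The baseline classifier sees three global features; it cannot express
  spatial structure and is not a stand-in for CNN accuracy claims.
* Adjudication policy when two experts disagree and the image is kept
  follows the specialist's grade; other conventions can be supplied via
  the specialist callback.
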