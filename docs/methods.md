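# Methods

This note documents the models, conventions and design choices behind
`spheromet`, in the order data flows through the pipeline.

## Segmentation and shape features

One spheroid per brightfield frame is assumed (the assay seeds one
aggregate per round-bottom well).  Segmentation is a global Otsu threshold
with configurable polarity, retention of the largest connected component
(ties broken deterministically by the topmost-leftmost pixel, with a
warning), and hole filling.  No object-merging or splitting heuristics are
applied: at 4× magnification the spheroid dominates the frame and such
heuristics mainly create artifacts.

Feature conventions are fixed so that results are bit-reproducible and
testable against independent re-implementations:

* **area** — foreground pixel count (px²).
* **perimeter** — length of the 0.5-level marching-squares contour after a
  5-vertex circular moving average.  The raw staircase contour of a digital
  disc overestimates the true circumference by ≈ 4.8 % (a perfect disc
  would score a form factor of 0.91); the short vertex average removes that
  bias (disc ≈ 0.995) while leaving straight edges essentially untouched
  (a 200-px square scores 0.793 against the analytic π/4 ≈ 0.785).
  CellProfiler's own estimator differs by a comparable margin in the other
  direction; any fixed convention is fine downstream because features are
  normalised per cell line before use.
* **form factor** — 4π·area/perimeter²; 1 for a circle.
* **compactness** — mean squared pixel distance from the centroid,
  normalised by area/2π so a filled circle scores 1 (a square scores
  π/3 ≈ 1.047).
* **solidity** — area over the area of the convex hull of all pixel
  *corner* points.  The corner convention guarantees solidity ≤ 1 (a hull
  over pixel centres can be smaller than the pixelated object).
* **median radius** — median of the Euclidean distance transform over the
  object (px).
* **granularity** — classic granulometry: the image (zeroed outside the
  mask) is opened with discs of radius 1…n (default 16); the spectrum value
  at scale k is the percent of the initial masked signal removed between
  scales k−1 and k.  Digital discs sieve imperfectly, so marginally
  negative differences are clipped to zero.  Scales contributing < 5 % of
  the spectrum maximum are discarded as background/noise; the arg-max scale
  is always kept.  The 5 % rule is relative to the maximum amplitude and is
  configurable.

All coordinates are 0-based row/column.

## Triplicate QC

Two policies, applied to disjoint data and never combined:

**Fluorescence (viability) readouts** use a 20 % CV gate (sample, n−1,
standard deviation over the mean).  A failing triplicate first tries a
single-value removal; if no pair passes the gate the point is excluded.
The curve is invalidated when an excluded or rescued point lies in the
IC50/inflection region — operationalised as the two doses bracketing the
dose whose cleaned response is closest to the halfway point between the
extreme responses — when more than one point is excluded, or when the
negative-control triplicate fails the gate and cannot be rescued by one
removal.

**Morphometric features** use Dixon's Q test at n = 3:
Q = |suspect − nearest| / range, with the suspect being the value most
distant from the other two, against Q_crit = 0.970 (r₁₀ table, n = 3,
two-sided, 95 %).  At most one value per triplicate is replaced, by the
mean of the remaining two.  Replacement is additionally guarded by the
expected monotone dose response: the direction is probed from the
triplicate *medians* of the first and last doses (medians, because a
single gross outlier at an extreme dose would flip a mean-based sign), and
a candidate replacement is accepted only if the total wrong-direction
excess of consecutive dose means beyond a 5 % relative band does not
increase.  A stricter variant — requiring the whole mean sequence to be
monotone within the band — was rejected: with realistic replicate noise,
adjacent plateau means violate a fixed 5 % band often enough that many
legitimate replacements would be refused for reasons unrelated to the
triplicate under test.  The not-worsening form keeps the guard's purpose
(never let a replacement fabricate or deepen a trend violation) while
staying decisive.  One pass is made per series; the procedure is
idempotent.  Note that at n = 3 the test's 95 % critical value implies
≈ 5 % spurious flags on clean triplicates by construction; the guard
absorbs a fraction of these.

## Normalisation, direction alignment, PCA weighting

All steps run per cell line.  Features are divided by the mean of that
line's zero-dose wells, so the control level is 1 (percent-of-control is a
display scale only; the inversion rule needs the fraction scale to compare
against 1).  A feature whose treated-well mean exceeds 1, and whose
reciprocal has a smaller treated-well mean, is replaced by its reciprocal —
this aligns direction only (e.g. form factor rises under treatment while
area falls) and is logged with the triggering means.  Control wells are
excluded from the trigger means (they sit at 1 by construction and would
dilute the trend) but the whole column, controls included, is transformed.
A re-check undoes any inversion whose treated-well mean ended up above the
recorded pre-inversion mean, which can happen when the matrix changes
between the two steps or when edge noise on an essentially flat feature
triggered the transform.

PCA runs on the treated wells (replicates as rows — keeping replicate
variance in the decomposition), with columns centred and standardised to
unit variance; raw morphometric features span five orders of magnitude, so
unstandardised PCA would simply rank features by scale.  Standardisation
is configurable off.  The smallest k whose cumulative explained-variance
ratio reaches the threshold (default 0.90) is kept; feature j scores
raw(j) = Σ_{i≤k} aᵢ·|cᵢⱼ| and weights are normalised to sum to 1.  Weights
are invariant to loading-vector sign flips by construction.  The per-well
composite metric is σ = Σⱼ ωⱼ·xⱼ; clean controls score exactly 1.  σ is
fitted directly (no per-concentration rescaling); an optional 0–1
rescaling is available for display.

## Dose–response fitting and censoring

The 4PL `r(c) = bottom + (top − bottom)/(1 + (c/IC50)^hill)` is fitted by
bounded least squares on log₁₀ concentration, with the midpoint
parameterised as log₁₀ IC50.  Initialisation takes top/bottom from the
extreme-dose responses, the midpoint at the dose nearest half-maximal
response and hill = 1, plus five deterministic jittered restarts (the best
residual wins; restarts stop early once a fit is essentially exact).  The
optimiser budget is 1000 evaluations per start — real curves converge in
under a hundred; uninformative flat series would otherwise crawl.  Under
this parameterisation `top` is always the low-dose asymptote, so rising
and falling curves need no sign constraint on the hill slope.  A fit is
`converged` unless the optimiser failed or the midpoint/slope landed on a
search bound (log-midpoint bounds sit 3 decades outside the tested range).

An IC50 is **definite** only if the fit converged, the midpoint lies
inside the tested range, the observed swing from the low-dose asymptote
reaches half the fitted span, *and* the fitted span is at least a third of
the low-dose asymptote level.  The last, absolute condition encodes the
convention behind printed ">max-dose" entries — a readout that cannot move
by an appreciable fraction of its control level in the tested range does
not support a definite midpoint — and is what stops a 4PL that merely
absorbed noise on a flat series (fitted spans up to ≈ 0.32 of the
asymptote in simulation, against ≥ 0.42 for genuine composite-metric
curves) from reporting one.  Otherwise the IC50 is censored as
`greater_than` the top tested dose, or `not_determinable` on fit failure,
fewer than four distinct doses, or upstream QC invalidation.  Ratios
between censored IC50s follow interval arithmetic: definite/definite to
two decimals, a one-sided bound when exactly one operand is a lower bound
(">" when it is in the numerator, "<" in the denominator, two significant
digits), n/a otherwise.

## Validation layer

Concordance between readouts uses only rows where both IC50s are definite;
the pair list is returned for audit.  Pearson and Spearman are computed on
the linear scale by default (log₁₀ available); on the shipped reference
comparison table the linear scale reproduces the published correlation
levels.  The robustness scan reruns weighting → fitting at several
cumulative-variance thresholds and correlates the resulting definite IC50
vectors pairwise on matching (cell line, compound) keys.

## Synthetic data: what it emulates, and what it does not

`synthgen` produces (a) frames containing one star-convex object with a
radial-Fourier rough boundary, optional disc speckle of a chosen grain and
Gaussian pixel noise, whose continuous area/perimeter are integrated from
the generating profile and returned for oracle tests; and (b) screen
tables in which every feature follows a 4PL in its own direction around
control = 1, scaled to realistic raw magnitudes (area ≈ 1.5·10⁵ px² down
to solidity ≈ 0.97), with lognormal multiplicative noise (unit mean,
CV-parameterised — multiplicative noise keeps features positive, matching
the reciprocal transform's domain), exact triplicate structure, and
outliers injected per triplicate with a ×3–5 uniform factor recorded in a
truth record.  The default ladder is ten half-log doses up to 10 µM plus a
zero-dose control; default replicate noise is 10 % CV (a choice — the
source assay reports only that fluorescence CVs stayed under 20 %);
default hill slope 1.2; default true IC50 500 nM.

Deliberately not emulated: photorealistic texture, fluorescence channels,
necrotic-core physiology, plate-position effects, and correlated
feature noise (features from one image share segmentation error in
reality; here per-feature noise is independent, which makes the composite
metric's noise averaging slightly optimistic).  Passing tests therefore
demonstrate the correctness and statistical behaviour of the *pipeline*,
not the biological fidelity of any simulated screen.

## Problem sizes and statistical ceilings

Simulation-backed checks use 20 seeds for end-to-end recovery (median
|log₂ IC50 error| and the median per-compound Spearman ρ between
per-concentration mean σ and dose), 200 seeds for QC decisiveness (at 2 %
replicate CV, within the ≤ 5 % regime where a ×3 outlier's Q statistic
clears the critical value), and 12 seeds × 2 cell lines × 4 compounds for
the threshold robustness scan.  Two ceilings are worth knowing.  First,
ρ(σ, dose): with half-log dosing up to 20× the IC50, the four or five
lowest doses sit below response onset, and their rank order under any
noise is arbitrary — the expected ρ is ≈ −0.88 to −0.94 regardless of how
good the metric is, so per-compound values hover at the −0.9 line and the
median over seeds is the meaningful summary.  Second, Dixon false flags:
the 95 % critical value guarantees ≈ 5 % spurious flags on clean
triplicates; observed false-modification rates just under 5 % reflect the
test operating as designed, not a tunable defect.

## Known limitations

* Segmentation is single-object, global-threshold; debris larger than the
  spheroid or strong illumination gradients will defeat it.
* Perimeter/solidity values follow this package's stated conventions and
  differ from CellProfiler's by up to a few percent on the same mask;
  mixing native and CellProfiler feature tables *within one normalisation
  group* is therefore discouraged, though either source works alone.
* The Dixon guard evaluates one feature series at a time; with two or more
  gross outliers in the same series the guard can refuse legitimate
  replacements (observed as the dominant miss mode in simulation).
* 4PL fits use per-concentration means (SD weighting optional), matching
  the mean ± SD summaries the assay produces, at the cost of ignoring
  within-dose replicate structure.
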