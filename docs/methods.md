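# Methods

This note documents the models, conventions and design choices behind
`mammoeval`: what each quantity means, which parameters matter, what the
synthetic cohort generator does and does not emulate, and the numerical
decisions a user reproducing or extending the analysis should know about.

## The evaluation problem

In double-read screening mammography two radiologists independently
interpret each four-view examination (left/right × CC/MLO). A lesion-
localising AI model emits, per view, a non-negative saliency map and a
malignancy probability. The toolkit quantifies three relationships:

1. how well the two readers' lesion annotations agree with each other
   (per-case concordance);
2. how well a model's saliency agrees with the readers' annotations, and
   with another model's saliency (SIM/KLD);
3. how detection accuracy varies across cancer categories (missed,
   prior-vis, prior-invis), concordance bands and tumour size groups.

## Reader concordance

Annotations are axis-aligned boxes in a 0-based half-open convention
`[row_min, row_max) × [col_min, col_max)`, which makes areas and IoU
integer-exact on rasters. Two boxes overlap when their intersection area
is strictly positive. Matching is greedy one-to-one by descending IoU
among overlapping same-view pairs; greedy was chosen over optimal
assignment for determinism and transparency, and the test suite verifies
it is maximal (no overlapping pair is left with both boxes unmatched).

Per case, the eight corner coordinates of each matched pair (reader A as
x, reader B as y; pairs pooled over views) feed Lin's concordance
correlation coefficient with population (divide-by-n) moments:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2).

CCC equals Pearson's r shrunk by a location/scale penalty, so
|CCC| ≤ |r| always. The "four corner points as 8 paired numbers" pairing
is one of two readings of the corner-based definition; the alternative (4
paired 2-D points with a multivariate concordance variant) is not
implemented. McBride bands are assigned as: almost perfect > 0.99,
substantial (0.95, 0.99], moderate (0.90, 0.95], poor ≤ 0.90 — the quoted
band phrasing fixes only the outer bounds, so boundary values go to the
lower category; the edges are arguments, not constants. A case with no
overlapping pair at all has undefined CCC and is assigned *poor* and
*challenging* (worst possible agreement). "Challenging to localise" means
no matched pair attains IoU > 0.95; the source phrasing for this
definition is self-contradictory ("did not significantly overlap
(IoU > 0.95)") and is resolved as significant overlap ⇔ IoU > 0.95.

## Saliency agreement

Two representations are supported. *Value histograms*: pixel values
binned into 256 equal-width bins over [0, 1] (values clipped into range
so mass is exactly 1); bin count is a parameter — SIM is mildly sensitive
to it, and 256 matches 8-bit intensity resolution. *Spatial
distributions*: a map is resampled to a common grid (the saliency grid
shape by default) with corner-aligned bilinear interpolation and divided
by its total mass; an annotation-box set is rasterised to a binary union
mask and normalised the same way, i.e. uniform density inside the
annotated region. All-zero sources raise rather than silently producing
a degenerate distribution.

SIM is the histogram intersection Σ min — symmetric, 1 iff identical, 0
iff disjoint support, and identically 1 − ½·L1 for normalised inputs.
KLD is evaluated exactly in the regularised printed form
Σ D¹ log(ε + D¹/(ε + D²)) with ε = 1e−10 and natural log (no base is
stated in the field's usage; nats are the default of every numerical
library). Because of ε the self-divergence is not exactly zero: it is of
order n·ε (≤ 1e−6 on grids up to 10⁴ cells) and vanishes as ε → 0. The
form is asymmetric and, unlike true KL, can be slightly negative in
degenerate corners; none of the analyses depend on nonnegativity.

## Saliency operators

The deterministic mechanics of the two emulated detector styles:

* **top-t% pooling** — mean of the ⌈t/100 · n⌉ largest grid values
  (ceiling, so the pool is never empty); t = 6 by default.
* **greedy patch selection** — repeatedly take the patch position with
  the largest mean intensity, then zero out its footprint (suppression by
  erasure) before the next pick; K = 3 for the compact style, 6 for the
  diffuse one. Ties break at the lexicographically smallest (row, col),
  and an already-selected top-left cannot repeat, which keeps constant
  grids from returning K copies of one patch. Window means are computed
  by direct per-window summation rather than an integral image: the
  integral-image subtraction introduces ~1e-16 noise that breaks exact
  tie-breaking. Default patch shape is the square covering the same area
  fraction of the grid as a 256×256 patch covers of a 2944×1920 image.
* **aggregation** — weighted sum of patch maps on a zero canvas (weights
  ≥ 0 summing to 1, uniform by default); conserves weighted mass exactly.
* **multi-scale fusion** — the coarser grids of a strict 2× pyramid
  (184×120, 92×60, 46×30 by default) are upsampled corner-aligned and
  averaged with the finest; fusing identical constants is exact. Whether
  the diffuse model's learned aggregation weights its scales unequally is
  not recoverable without trained weights; uniform averaging is the
  default and a weights hook is exposed.

## Preprocessing

Pipeline order: segment → crop → flip → resize. Segmentation thresholds
the image (Otsu over all pixels by default — restricting Otsu to nonzero
pixels would split breast from any brighter artifact instead of
foreground from background), closes with a 5-px disc, fills holes and
keeps the largest connected component. The crop is the tight bounding box
of the mask (no foreground pixel lost). RCC/RMLO views are flipped
horizontally so all breasts face left; the flip is an involution on
pixels and boxes. Resize is bilinear with corner-aligned sampling
(output pixel i samples input at i·(H−1)/(h−1)): constants are preserved
exactly and output values never leave the input range. The working
resolution is portrait 2944×1920 (rows × cols). Box transforms mirror
each pixel operation; box scaling uses the plain size ratio, which
preserves containment.

## The synthetic cohort generator

The study design this toolkit serves uses private screening data and
trained networks, so the generator manufactures cohorts with the same
observable structure. Per cancer case: a laterality, a size group
(T1 ≤ 2 cm, T2 2–5 cm, T3 ≥ 5 cm; default mix 0.68/0.24/0.08 echoing a
screening case mix), a cancer category (default mix 0.25/0.35/0.40), six
elliptical "signs" per affected view (multifocal presentation), truth
boxes, two readers' boxes obtained by independent Gaussian corner jitter
of each truth box, and per-model saliency grids. Cancer-free cases (one
per cancer case by default) carry only false-positive saliency blobs.
Pixel spacing defaults to 0.08 cm/px on 368×240 frames, so T-group
thresholds map to 25 and 62.5 px and a T3 lesion still fits a desk-scale
breast; spacing, frame and grid shapes are all configurable.

**The concordance dial.** The key requirement is that `jitter_sigma` map
cleanly onto McBride bands: cohorts generated at a band-calibrated sigma
should actually land in that band case by case. Raw corner jitter fails
this — the per-case CCC depends on the corner-coordinate variance V of
the truth boxes, which varies with laterality, lesion size and placement.
Three design elements fix it:

* lesion clusters centre their rows on `cols/2`, making the row–column
  separation term of V identical for left and right breasts;
* the cluster fan-out scales with lesion size (clamped to the breast), so
  V grows with box size and small-box cases get proportionally small
  jitter;
* reader noise is scaled per case by √(V_case / V_ref) with
  V_ref = 3000 px². CCC is scale-free, so every case then has expected
  CCC = 1/(1 + σ²/V_ref) regardless of its geometry.

With 6 signs per view (12 matched pairs per case) the CCC estimator's
sampling noise is small enough that band recovery reaches ≈ 1.00 /
0.97–0.99 / 0.83–0.88 / 0.98–1.00 across the four bands at n = 300.
`calibrate_band_sigmas` finds the four sigmas by pilot simulation,
interpolating the monotone mean-CCC-versus-sigma curve at per-band
targets (0.997, 0.970, 0.9275, 0.80) — the mean is a far less noisy pilot
statistic than an in-band fraction.

**Detection and localisation dials.** Each affected view draws one
conspicuity amplitude A ~ U(0.6, 0.9) shared by its blobs; the view's
malignancy score is min(1, A·q), with q the category's `detect_quality`
(defaults 0.80 missed / 0.95 prior-vis / 0.88 prior-invis — free
simulation parameters: the category-difficulty mapping is not derivable
from published tables) times a model-style multiplier (compact 1.0,
diffuse 0.95). False-positive blobs follow a Poisson count with
amplitudes U(0.05, 0.52), giving cancer-free cases a realistic
false-positive rate; the diffuse style triples the rate and broadens its
blobs, mirroring the qualitative contrast between the two detector
families. `quality_uplift` scales every score up and emulates the
direction of transfer learning; because it is applied after all random
draws, regenerating a cohort with an uplift changes no draw and every
stratum's sensitivity can only rise. In `tie_to_concordance` mode each
case's q is additionally multiplied by a piecewise-linear increasing
function of its realised reader CCC (knots at the McBride edges, range
0.6–1.0), and saliency blob offsets grow from ~0.1 to ~0.9 mean lesion
radii as agreement falls — the coupling that reproduces the study-style
orderings: sensitivity non-increasing from almost-perfect to poor in
every category, SIM decreasing and KLD increasing across the same bands.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: photorealistic parenchyma and density patterns,
vendor/detector characteristics, reader-specific biases (noise is iid
Gaussian and unbiased), correlated reader errors, benign-lesion
confounders, and real CNN saliency topology (blobs are isotropic
Gaussians). Results on synthetic cohorts validate the *machinery* —
metrics, matching, stratification, statistics — not any clinical claim.

## Evaluation and statistics

A case is called positive when the maximum per-view malignancy score
reaches the decision threshold (0.5 by default; no operating point is
canonical, so a threshold sweep is trivial to run and monotone by
construction). Localisation is scored by default as
argmax-of-the-saliency-map inside the union of reference boxes (grid
coordinates mapped to image coordinates by the size ratio at pixel
centres); a mass-fraction criterion (≥ τ of saliency mass inside the
union) is selectable. Cases without reference boxes return
not-applicable, never a silent miss. Sensitivity and specificity are
reported with exact numerators/denominators and 95% Wilson intervals;
empty strata render as "—", never as 0.

Group comparisons: chi-square on the detected/missed contingency across
groups for proportion differences; for multi-stratum comparisons, each
group's cases are split into seeded subsample folds, per-fold
sensitivities feed a one-way ANOVA, and pairwise Welch t-tests are
Holm-corrected. Degenerate inputs (zero variance everywhere) report
p = 1 rather than NaN. Type-I error of both paths is verified ≤ 7% at
nominal 5% by simulation in the test suite.

## Problem sizes and tolerances

Default analysis cohorts are 400 cancer + 200 cancer-free cases with
184×120 saliency grids; the geometry oracle enumerates every integer box
pair on a 10×10 grid directly (plus exhaustive 1-D interval counting on
[0, 20], whose outer products are exactly the 2-D rasterisations); CCC
and SIM identities are checked against exact rational arithmetic at
1e−12; KLD against a symbolic oracle at 1e−12; pooling and patch
selection against sort/exhaustive-search oracles. Equality tolerances
follow from the arithmetic (1e−12 for closed forms, 1e−9 where resampling
intervenes), not from fitting.
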