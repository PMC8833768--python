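# Methods

This note documents the models, numerical choices and limitations
behind `raresight`, in the order data flows through the package.

## Channel-type taxonomy

An event's four marker positivities (DAPI, CK, Vim, CD45/CD31) index a
total, deterministic 16-row lookup. DAPI-positive patterns map to the
8 cellular categories (epi.CTC, mes.CTC, CK|CD45/CD31,
CK|Vim|CD45/CD31, Vim|CD45/CD31, Vim only, CD45/CD31 only, DAPI only);
DAPI-negative CK-positive patterns map to the 4 LEV categories; the
four DAPI-negative CK-negative patterns are `excluded` — they are not
analytes of this assay. CD45/CD31-only events are only *rare* if they
survive the rarity screen (below); otherwise they are the `common
cell` leukocyte/endothelial background. Derived totals: total rare
cells (8 cellular), total LEVs (4 LEV), total rare events (their sum),
and total CK+ cells, defined as the four DAPI+ CK+ categories — the
assay literature uses the term without a formula, and this is the only
marker-consistent reading.

## Synthetic frames

`generate_frame` renders objects as radially symmetric flat-top disks
with a soft logistic edge (width 0.5 px): the median intensity over the
object approximates the peak amplitude and a thresholded mask recovers
≈ πr², so area and eccentricity ground truth are analytic. Nuclei
render only on DAPI; cytoplasmic markers on the cell radius; halo and
bubble artifacts are Gaussian annuli on the CK channel only. Defaults:
1024×1024 frames (tests use 512×512), background 100, noise σ 5, peak
amplitude 150 with an enforced floor of 8× the noise σ on positive
channels and exactly 0 on negative channels, WBC cell/nucleus radii
6/4 px, rare-cell radii 11/7 px, LEV radius 3 px. Per-object radius
and amplitude jitter (log-normal, σ 0.08 / 0.15) supplies the
biological variability a rarity screen needs — without it the common
population's feature spread collapses to rasterization noise.
Placement is rejection-sampled with a minimum boundary separation of
4 px and fails loudly (`PackingError`) past a 25% area packing limit;
attached LEVs are placed just outside a host cell's boundary (gap ≤
2 px), inside the close-proximity band.

What the generator does **not** emulate: point-spread functions,
spectral bleed-through, autofluorescence, illumination gradients,
slide-to-slide batch effects, or cell debris continua. Passing tests
therefore demonstrate the pipeline's logic (segmentation, typing,
filtering, enumeration, statistics) on well-posed images, not
robustness to real acquisition artifacts beyond the planted
halo/bubble rings.

## Detection

Nuclei: the DAPI channel is thresholded at background + 5 robust σ
(background = image median, σ = 1.4826·MAD; global Otsu available),
touching components split by watershed on the Euclidean distance
transform (peak separation 4 px), components under 12 px² discarded.
Cell bodies: marker-based watershed over the pixel-wise maximum of the
background-subtracted CK and Vim channels, restricted to signal
components that touch a nucleus — anucleate signal blobs (LEVs,
debris) are never absorbed into a neighboring cell — with a 2 px
fallback dilation for cells with no cytoplasmic signal. One watershed
means no pixel ever belongs to two cells. LEV candidates: CK
components that overlap no nucleus, have DAPI median below threshold
and area within [6, 400] px²; each is flagged cell-attached when its
5 px dilation touches any cell mask (the assay describes "close
proximity" without quantifying it; 5 px ≈ one cell radius at this
scale).

Features per event: median background-subtracted intensity per channel
(DAPI over the nucleus mask when present — the nuclear stain would
otherwise be diluted by large cytoplasms), cell/nucleus area and
eccentricity from second-order mask moments, plus solidity and an
annularity score (interior-hole fraction of the filled component) for
LEV candidates.

## Classification

Positivity is background + 5 robust σ per channel; DAPI positivity
additionally requires a nonempty nucleus mask. The **rarity screen**
decides which CD45/CD31-only events are worth reporting: intensities
are arcsinh-transformed (cofactor 5, the cytometry-standard variance
stabilisation that stays linear through zero), areas log-transformed,
and the squared robust Mahalanobis distance (minimum-covariance-
determinant location/scatter, fixed seed) is compared to the χ²₈
quantile 0.999. The robust Mahalanobis form was chosen over a simpler
per-feature median/MAD z-score norm because areas and intensities are
strongly correlated and right-skewed; ignoring that inflates the χ²
tail several-fold and misclassifies ~2–3% of ordinary leukocytes as
rare, where the calibrated form stays under 1%. Features with zero
spread are dropped (they carry no outlier information), so a constant
population has no outliers. With fewer than 100 events the screen is
uncalibratable: non-leukocyte patterns stay rare and a warning is
raised.

LEV filters: candidates failing solidity ≥ 0.8 or annularity ≤ 0.3 are
removed as halo/bubble/debris; then any frame still holding more than
3 candidates contributes **no** LEVs (junk-frame rule — more than
three CK+ particles on one frame indicates processing contamination).
The alternative reading, keep the 3 brightest, is available as
`junk_frame_mode="keep_top"`. The filter can only remove events, and
relaxing the junk rule can only add them.

## Enumeration

`mL analyzed = WBCs detected / (CBC WBC × 10⁶)`, with the CBC value in
million cells/mL; events/mL = count / mL per category, totals
recomputed and conserved; a test's value is the mean of its slides'
rates. WBCs detected are the classifier-confirmed common cells (all
DAPI+ events failing the rarity screen), the closest operational
reading of "WBCs detected by the assay".

## Synthetic cohorts

Each category's events/mL is zero-inflated log-normal: a patient
presents the category with probability `detect_p`; presenting
patients draw a rate whose log-location is solved so the *overall*
population median equals the reported group median (closed form via
the normal quantile; a positive median requires detect_p > 0.5).
Categories reported with median 0 (epi.CTC, mes.CTC, CD45/CD31-only,
three LEV types) instead give the presenting-subpopulation median,
set from the reported means and detection fractions. The marginal log
σ is 1.1 (the reported ranges span 2–3 decades). Two per-patient
burden factors (log σ 0.7, one shared by the cellular categories, one
by the LEV categories) induce the inter-category rank correlations the
real cohort shows (~0.3–0.6) while leaving marginal medians untouched
— their variance is subtracted from each category's residual σ. ND
per-category medians are not published; they are the BCa medians
scaled so the ND group totals land on their published medians, with a
one-off calibration factor for the gap between the median of a sum and
the sum of medians. The emergent group totals then sit within ~8% of
the published values (BCa ≈ 72.5 cells/mL, 33.3 LEVs/mL against
74.61/30.91) while per-category medians match exactly.

Per-slide values are the patient rate times small log-normal
measurement noise (σ 0.2); per-test values average the slides. Slide
counts are not Poisson-discretised: at ~0.37 mL per slide the printed
sub-1/mL category medians would be unrecoverable from integer counts,
and the generator's contract is to reproduce the published rate
distributions. WBC concentrations are log-normal (median 6.75, range
clipped to 3.3–25 million/mL); LEV attachment splits follow the
published 55.4%/54.1% attached fractions.

Convergence: per-category sample medians converge to their targets
(verified at n = 500 within 10%, taking the median over seeds because
a single n = 500 sample median of a σ = 1.1 log-normal still has ~7%
standard error).

## Statistics

Spearman rho on mid-ranks; p exact by full enumeration of pairings for
n ≤ 9 (vectorised over the rank cross-product), t-approximation above.
Wilcoxon rank-sum via the Mann-Whitney U with mid-rank ties; p exact
by enumeration for tie-free data with n₁+n₂ ≤ 12, otherwise normal
approximation with tie and continuity correction (continuity is a
flag). The normal approximation's agreement with the exact tail is
within 0.01 for p ≤ 0.1 at the crossover size; its mid-distribution
error is ~0.015 there, which is irreducible at that n. Categorical
variables with multiple levels are compared over all unordered level
pairs; singleton levels are skipped with a warning. Cohort comparisons
report raw p (significance at 0.05, as the assay literature does) with
an optional Benjamini-Hochberg column. Stage encodings: clinical T
stage (T0, Tis, Ta, T1, T2a, T3b, T4a) → 0..6; the pathological list
adds T2b and T3a in anatomical position.

## Morphospace

The morphometric matrix holds the 8 measures (median DAPI, CK, Vim,
CD45/CD31 intensity; cell/nucleus area and eccentricity) for rare
nucleated events; Vim is included as the fourth intensity measure — the
four stained channels all carry signal and the density panels of the
source workflow display it. Columns are z-scored before any distance
computation, making results invariant to affine feature rescaling.
tSNE (perplexity 30 by default, PCA initialisation, single worker) is
deterministic under a fixed seed; Ward/Euclidean agglomerative
clustering, k = 5 by default, has no random component. Density
summaries are Gaussian KDEs per category for cell area, cell
eccentricity and the three marker intensities; constant features are
flagged degenerate rather than smoothed.

## Patient-level classification

Design matrix: the 12 category events/mL per individual (totals are
linear combinations and excluded); BCa is the positive class.
Stratified 5-fold cross-validation (with a 50/50 cohort this yields
the five equal folds of 20 the study design describes), shared fold
assignment across families, reproducible under seed. RF and SVM tune
hyperparameters by 3-fold grid search inside each training split
(defaults: RF trees {100, 250} × depth {None, 5, 10}; SVM RBF C
{0.1, 1, 10, 100} × gamma {scale, 0.01, 0.1}); larger forests were
indistinguishable on a 100×12 matrix and only slow the search. Naive
Bayes has no grid. Features are standardised inside the SVM pipeline
only (fitted on each training fold); trees and NB are scale-free.
Metrics: per-fold and mean ± SD accuracy, sensitivity, specificity and
ROC AUC (probability scores), plus pooled misclassification counts by
true group. RF feature importances (impurity-based) are averaged over
the five fold-models and normalised to sum to 1.

## Problem sizes used in the shipped tests

Frames are 512×512 with ~110 leukocytes each (20-frame slide runs);
cohorts are 50+50; the detection suite checks recall/precision ≥ 0.95,
leukocyte specificity ≥ 99%, rank-sum separation across 20 seeds and
RF sensitivity/specificity ≥ 70% over 10 seeds. These sizes are the
package's chosen test conditions; the generators scale to full-frame,
full-slide sizes through `FrameSpec` and `CohortSpec`.

## Known limitations

* The rarity screen is a defined, deterministic stand-in for the
  assay's proprietary outlier report; it reproduces the *role* of that
  component, not its exact selections.
* Optical realism is out of scope (no PSF, spectral overlap or
  illumination models), so detection metrics on synthetic frames upper-
  bound real-image performance.
* The classifier's synthetic performance reflects the calibrated
  generator's separability, not the published cohort's images; only
  the published count identities are exact reproductions.
* Spearman's exact-p path enumerates n! pairings and is capped at
  n ≤ 9 by design.
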