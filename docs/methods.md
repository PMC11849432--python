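# Methods

## The procedure

`contrast-gate` treats dataset curation as a measurement problem: how much
lesion-to-tissue contrast does a slice need before a segmentation model can
learn anything from it?

1. **Preprocessing** (for volume input). Already brain-extracted, registered
   volumes are cut into axial slices along the last array axis; slices whose
   lesion area is strictly greater than 1 cm² (pixel count × in-plane pixel
   area, at native resolution) are retained; slices are mirrored horizontally
   so the lesion centroid falls in the left hemisphere (centroid column vs.
   the vertical midline decides laterality); everything is resampled to
   192×192 (bilinear for intensities, nearest-neighbour for masks, spacing
   rescaled).
2. **Contrast scoring.** Within the brain mask, HU values outside `[15, 80]`
   are discarded (inclusive bounds: 15 and 80 survive); survivors are min-max
   normalized to `[0, 1]` per slice. Fisher's ratio
   `F = (μ_obj − μ_bg)²/(σ²_obj + σ²_bg)` is computed between the retained
   lesion pixels and the retained healthy pixels of the hemisphere containing
   the lesion centroid. Population variances (divisor N) are used in both
   regions. F assumes roughly Gaussian intensities with similar variances in
   the two regions — a good description of windowed brain CT. Because F is
   invariant under any shared affine map, the windowing order (window →
   normalize → score) does not affect it; this invariance is asserted to
   1e−9 in the tests.
3. **Evaluation.** Detection (1 iff prediction ∩ reference ≥ 1 pixel — a
   disjoint blob has not segmented the lesion), DSC, exact set-to-set
   Hausdorff distance over all foreground pixels (no boundary extraction;
   an empty prediction is assigned the 60 px acceptability cap and flagged),
   and signed RAAD. Acceptability: DSC ≥ 0.1, HD ≤ 60 px, |RAAD| ≤ 0.5.
   Two models are compared per contrast bin with one-tailed Wilcoxon
   signed-rank tests (zeros dropped, exact null for n ≤ 25); orientation is
   per metric (higher DSC/detection better; lower HD and |RAAD| better).
4. **Threshold estimation.** See below.
5. **Validation.** A trainable segmenter is fitted twice — on the full
   training set and on its F ≥ t subset — and both are evaluated on one
   fixed test set (and on its F ≥ t subset). If performance is unchanged,
   the removed slices carried no learnable information.

## Threshold estimators

**ROC elbow.** For each threshold t on a grid (default 0.005–0.30, step
0.005 — resolving two significant figures around 0.05), pixel-level
TP/FP/FN/TN are summed over the slices with F ≥ t and turned into one
TPR/FPR point; thresholds retaining no slices are dropped. Both axes are
min-max normalized over the sweep before measuring distance to the ideal
corner (FPR is two orders of magnitude more compressed than TPR — raw
distance would ignore it entirely); a constant axis contributes zero, and
ties resolve to the smaller threshold. Pixel-level aggregation is chosen
because slice-level rates cannot produce sub-percent FPR values.

**Clustering sweep.** Features per slice: detection, DSC, HD, RAAD
(signed), F — each min-max normalized. Eight combinations are scored:
k-means under all five distances and average-linkage agglomerative
clustering under Euclidean, squared Euclidean and Canberra. k-means keeps
component-wise mean centroids, assigns by the chosen distance, and returns
the best of 10 seeded restarts by within-cluster distance sum; restart
seeds derive deterministically from the base seed. Purity of a partition at
cutoff t is the accuracy of the better cluster↔label assignment against the
reference split F < t vs F ≥ t. The selected threshold is the argmax over
the grid of R²(t), the squared Pearson correlation between the eight
purities and the eight silhouettes (each silhouette computed under its own
clustering distance). Thresholds where either vector has zero variance, or
where purity is undefined (one-sided reference), are excluded.

### A caution on the R² sweep

The R²-argmax estimator is implemented as designed but is statistically
degenerate, and the package's own experiments show it: on data with a clean
two-group structure most of the eight combinations return *identical*
partitions, so the purity vector takes only two or three distinct values.
Pearson correlation is invariant to the scale of the purity spread, so with
two distinct groups R²(t) is ±1 wherever the groups differ at all —
regardless of whether the difference is structure or noise — and the argmax
is decided by noise. With per-distance silhouettes the correlation is
instead dominated by metric-induced silhouette offsets (squared-Euclidean
silhouettes run systematically higher) that carry no information about
partition fidelity. In repeated planted-cliff simulations the R² selection
recovers the true threshold at roughly chance level, while the purity
*level* peaks sharply and reliably at the true cliff in every run, and the
ROC elbow recovers it within one grid step. Users should rely on the elbow
and on the purity peak; the R² curve is emitted for transparency. The
acceptance test asserting R²-sweep recovery is expected to fail and is left
failing deliberately.

## Synthetic data

The phantom emulates the statistical structure of windowed brain CT, not
its anatomy: an elliptical brain (semi-axes 0.42/0.36 of a 192 px grid,
1 mm pixels) of Gaussian tissue at 35 ± 4 HU, with a connected hypodense
lesion blob (union of 2–4 disks, radius 7–14 px) confined to one
hemisphere. The lesion mean deficit δ solves the Fisher formula in
expectation, `δ = √(F_target · (σ²_les + σ²_bg))`, and the sampled noise is
standardized region-wise (exact mean and population SD over the lesion and
over the ipsilateral healthy region), so the ratio *measured through the
real contrast module* equals the target almost exactly — closing the loop
between generator and scorer. Targets above F = 4 are rejected (the lesion
would leave the HU window). Default F targets are exponential with scale
0.06, truncated at 0.4: a right-skewed distribution with ~57% of slices
below 0.05, the regime where low-contrast slices dominate. A uniform option
(`f_distribution="uniform"`) models a contrast-balanced test design and is
what the threshold-recovery experiments use, since estimating a threshold
from a sweep requires slices on both sides of every candidate.

The surrogate segmenter imposes a known performance-vs-contrast law on the
true masks — it never reads the image, because the law itself is the object
under test. On detection success (probability 1 at F ≥ c\*, falling
linearly to `detection_floor` at F = 0; failure yields an empty mask) the
prediction is built constructively so each planted quantity is exact up to
pixel rounding: the lesion is shrunk from its rim to exactly
`round(s·area)` true positives, where the sensitivity s follows a sigmoid
with midpoint c\* and steepness 400 (10–90% transition over ≈ 0.011 F
units, i.e. the cliff is localized within the recovery resolution) plus
N(0, 0.10) noise; `round(fp·area)` false positives are added outside the
lesion, with fp ramping 0.02 → 0.12 as F grows (underestimation below the
cliff, growing overestimation above it — the trend that makes the
aggregate FPR increase monotonically with the contrast cutoff); the false
positives are the healthy pixels nearest a point whose offset from the
lesion shrinks from 40 px at zero contrast to 0 above the cliff, so poor
slices are also mislocalized (large HD). Consequences of the construction:
measured DSC ≈ 2s/(1+s+fp) tracks the sensitivity law within ~0.05 at the
defaults; DSC declines very gently above the cliff as false positives grow,
so DSC is cliff-shaped but not globally monotone in F — the monotone
planted quantity is sensitivity.

What passing tests on this generator do **not** show: robustness to real CT
artifacts (beam hardening, motion), to registration error, to non-Gaussian
tissue mixtures, or to annotation noise; nor that 0.05 is the right
threshold for any particular clinical dataset — the threshold is a property
of the data and model, and must be re-estimated per task.

## The bundled baseline segmenter

`IntensityThresholdSegmenter` makes the retraining validation runnable in
seconds: its prediction is the largest 8-connected component of the
retained pixels at or below a global cutoff on windowed, normalized
intensity, and `fit` maximizes the mean training DSC of that same rule over
a 64-point cutoff grid (ties to the smaller cutoff). Scoring the deployed
rule — component step included — matters: under a plain-threshold
objective, slices whose lesion is indistinguishable from background exert a
monotone pull on the cutoff, whereas under the deployed rule their largest
sub-cutoff component is a noise cluster wherever the cutoff sits and they
contribute essentially no preference. That is exactly the behavior the
validation experiment needs from "uninformative" slices. The segmenter is
deterministic; the seed parameter exists to satisfy the trainable-segmenter
interface.

## Numerical choices and degenerate inputs

- Mask binarization threshold 0.5 everywhere (masks may arrive as floats
  after resampling).
- Window bounds inclusive; a slice whose retained set is empty or constant
  is a named degenerate error; `contrast_profile` reports degenerates
  instead of raising.
- Fisher's ratio requires ≥ 2 pixels and positive variance sum in each
  region; both violations are named errors.
- Darkening defines the preserved border as the one-pixel inner ring under
  8-adjacency; a lesion that is all border yields no candidates (reported).
  Homogenization ties at the median are left unchanged; its gate compares
  lesion HU SD against healthy brain (brain ∖ lesion) on raw HU.
- Augmentation candidates are the darkening rounds, the homogenized
  original, and darkening∘homogenization compositions (darkening first);
  the acceptance band defaults to [median, max] of the observed F
  distribution, and every kept candidate is re-scored through the contrast
  module.
- k-means ties in assignment go to the lower cluster index; an emptied
  cluster is reseeded with the farthest point; identical feature vectors
  across all slices is a degenerate-clustering error. A constant feature
  column normalizes to zeros.
- The elbow on a sweep with a constant axis degrades gracefully (that axis
  contributes zero). An optional ROC crop (`crop_fpr_max`, `crop_tpr_min`)
  restricts the elbow search; the full curve is the default.
- `report.json` is a pure function of the config: per-stage timings go to
  the log only, floats are rounded to six decimals, keys are sorted.

## Problem sizes

The shipped experiments use 400-slice studies (40 synthetic patients) for
threshold recovery, 96 px phantoms and 100–200 slices for augmentation and
validation checks, and three planted cliffs (0.03, 0.05, 0.08) × three
seeds for the recovery acceptance test. The full test suite runs in well
under a minute; the acceptance script in ~10 s.

## Known limitations

- The R²-sweep threshold selector is degenerate (see above).
- The hemisphere convention (left) and the centroid-vs-midline laterality
  rule are simple conventions; heavily midline-crossing lesions would make
  the ipsilateral background ill-defined.
- The area filter uses in-plane spacing only; anisotropic in-plane voxels
  are supported but oblique acquisitions are not corrected.
- Whether resizing should preserve aspect ratio is an open choice;
  stretching is used.
- The Wilcoxon exact method treats ties in |differences| approximately;
  detection differences (many ties) should be read with that in mind.
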