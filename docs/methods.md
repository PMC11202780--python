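# Methods

`lungsurv` implements a 2-year survival classification pipeline for non-small
cell lung cancer from radiotherapy CT archives: structure-set parsing and
GTV-1 localization, contour rasterization, segmentation QC, fixed-depth input
stacks, the GTV1-SliceNum clinical feature, the PEN-BCE loss family, and a
3-D CNN training harness. This note records the models, the parameters that
matter, the numerical choices, and what the synthetic-data experiments do and
do not establish.

## Data model and GTV-1 localization

A patient is an axial CT series (one DICOM per slice) plus one RTSTRUCT.
ROIs hold closed planar contours in patient-coordinate millimetres; each
contour references its CT slice through the `ReferencedSOPInstanceUID` of the
first `ContourImageSequence` item. The set of tumour-bearing slices is the
intersection of the series' SOP UIDs with the UIDs referenced by the "GTV-1"
contours, ordered by slice z position.

Choices where the DICOM standard leaves room:

- Slices are ordered by the z component of `ImagePositionPatient`, not by
  filename or `InstanceNumber`; ties break on SOP UID. Geometric order is
  what both the coordinate transform and slice stacking require.
- ROI-name matching is exact after whitespace stripping; a regex option
  (`resolve_roi(..., regex=...)`) absorbs naming drift ("GTV 1", "GTV-1 ")
  found in real archives without loosening the default.
- Contours lacking a `ContourImageSequence` (geometry-only) are matched to
  the nearest slice by z, accepted only within half a slice thickness, and
  flagged with a warning.
- Patients without a usable GTV-1 ROI are excluded from the cohort; the
  exclusion surfaces as a structured `MissingROIError`.
- Raw stored pixel values are preserved; the rescale slope/intercept are
  applied only when Hounsfield units are requested.

## Geometry

Millimetre coordinates map to pixels affinely: `x_px = (x_mm - x0) / xs`
(likewise y), with x along columns — the standard axial-series convention.
Rounding is deferred to rasterization.

Rasterization fills a polygon at pixel centers with the even-odd (ray
crossing) rule; a pixel whose center lies within 1e-9 of an edge counts as
inside. Even-odd keeps self-intersecting hand-drawn contours deterministic;
boundary inclusion makes thin contours visible. The unit test suite holds
this implementation to exact agreement with an independent geometric oracle
(shapely point-in-closure tests) on random convex polygons up to 64×64.

Byte normalization maps an image to 0–255 via
`round((v - min) / (max - min) * 255)`. The variant that divides by `max`
alone is available as `strict_as_printed=True`; it exceeds 255 whenever the
array holds negative values (CT values after rescale routinely do), so the
range-preserving form is the default.

## Segmentation QC

Three error classes are handled:

- **Area jumps** (interpolation artifacts): interior slice `i` is flagged
  when `area_i < τ · min(area_{i-1}, area_{i+1})`. τ defaults to 0.5 —
  ellipsoid-like tumours have concave area profiles along z, for which an
  interior slice is never below the smaller neighbour, so genuine taper is
  never flagged, while a collapsed slice falls far below both neighbours.
  First/last slices have one neighbour and are exempt. Repair replaces the
  slice with the zero level set of the averaged signed distance transforms
  of its neighbours — shape-based interpolation, which reduces to the
  mid-radius disk for concentric disks and degrades gracefully for
  non-overlapping shapes.
- **Multiple tumour regions**: slices with >1 connected component are
  reduced to the patient's dominant side (larger summed GTV-1 area relative
  to the image vertical midline; ties go to the side holding the largest
  single component). The midline approximates the anatomical midline for
  centred axial scans.
- **Mislabels**: flagged only (GTV-1 centroid outside both lung ROIs, when
  lung masks are supplied); no automatic repair is defensible without a
  clinician.

`run_qc` applies laterality selection first (so the area profile reflects a
single tumour), then area-jump repair, and is idempotent on its own output.
Repair by neighbour interpolation has an intrinsic accuracy limit: when the
damaged slice is a local area maximum (short tumours, coarse slices), the
interpolated area lies between the neighbours' and cannot reach the truth.
The repair-accuracy experiments therefore use smooth stacks — z semi-axis of
at least four slice thicknesses — where the observed repair Dice is ≥ 0.92.

## Input stacks

The classifier consumes `H×W×D` stacks (default 240×240×5) in [0, 1]. The
window of D tumour slices always contains the largest-area slice, centred on
it where possible and shifted inward at the ends of the tumour range so
every selected slice still contains tumour. Patients with fewer than D
tumour slices keep all of them and duplicate edge slices alternately,
end-first: `[7,8,9] → [7,7,8,9,9]`. The even-depth variant (4-slice
ablation) takes the 5-window minus its last slice (minus the first when the
largest slice sits at the end, preserving the always-contains-argmax
invariant). Area ties break toward lower z. Resizing is bilinear with
anti-aliasing on the byte image; the ROI-crop variant instead cuts a 128×128
window centred on the tumour bounding-box midpoint, clamped at image borders
and zero-padded only when the image is smaller than the crop.

## Clinical features and labels

`Survival.time` is days from treatment start; `deadstatus.event` is 1 for an
observed death. The 2-year label is `survival_time > 730` strictly — a
patient dying on day 730 did not survive *beyond* two years. Two censoring
policies exist: `discard_censored` (default; censored classes are unknown)
and `include_censored`, where censored follow-up beyond 730 days proves
survival (label 1) and censored follow-up below 730 days is labeled 0 even
though the true class is unknowable — the loader keeps that subset, and the
choice is documented here precisely because it injects label noise.

GTV1-SliceNum is the count of distinct CT slices carrying ≥ 1 GTV-1 contour
(two contours on one slice count once). It is invariant under QC repair and
stack building, both of which preserve the slice set. The schema declares
age in days; the loader normalizes to years with a 200-threshold heuristic
(no human age in years exceeds 200, none in days falls below it).

Feature importances are impurity-based (decision tree or 100-tree random
forest), computed on a design matrix with median-imputed ordinals and
mode-imputed, sorted-category-coded categoricals; importances are normalized
to sum to 1. Imputation lives only inside the importance harness — the CNN
path uses no clinical covariates.

## The loss family

All losses act on clipped probabilities (ε = 1e-7) with natural logarithms
and average over the batch, penalties included — this makes the batch-mean
property exact (the loss of a concatenation is the size-weighted mean of the
parts). PEN-BCE per sample:

    -[y ln p + (1-y) ln(1-p)] + α·y·max(0, p_FN - p)² + β·(1-y)·max(0, p - p_FP)²

The hinge penalties charge positives predicted below `p_FN` (confident false
negatives) and negatives predicted above `p_FP` (confident false positives);
they are quadratic, so the extra gradient grows linearly with the violation
and vanishes smoothly at the threshold. The penalty terms add positively
outside the negation — the y=1 single-sample reduction is
`-ln p + α·max(0, p_FN - p)²`. Defaults (α=1, β=5, p_FN=0.5, p_FP=0.2) are
the best row of the published nine-row grid, exposed as `PEN_BCE_GRID`.

The focal loss uses the `p_t` convention (`p_t = p` for positives, `1-p`
otherwise); the flat rendering with an extra `y` factor would silence
negative samples entirely and is available as `strict_as_printed=True` for
comparison only. The asymmetric loss shifts negatives by
`p_m = max(p - margin, 0)`, hard-zeroing easy negatives.

Every loss ships an analytic gradient with respect to `p`; subgradient 0 is
taken exactly at hinge points. Training criteria wrap the same pure
functions, so values seen in training are identical to the array API by
construction, and the α=β=0 configuration of PEN-BCE reproduces a BCE
training run bit-for-bit at equal seeds.

## Training harness

The recipe: stratified 85/15 train/test split; 5-fold stratified CV over the
training portion (each fold starts from the same initial weights); SGD with
Nesterov momentum 0.9, initial learning rate 2e-5, weight decay 1e-6, batch
size 16, up to 200 epochs. "Validation loss constant" is read as no
improvement beyond 1e-4 for 25 epochs, upon which the learning rate is
multiplied by 0.9; early stopping uses a 50-epoch patience with best-weights
restore. Reported test metrics are the mean of the fold-models applied to
the held-out test set; accuracy thresholds at 0.5 and AUC is the
Mann–Whitney midrank statistic (undefined, reported as missing, on
single-class test sets). Augmentation, when enabled, applies per-sample
in-plane rotation (≤ 15°) and horizontal/vertical shifts (≤ 10% of
width/height) with bilinear resampling.

The networks are built on an in-package numpy layer library with explicit
backward passes (float64 throughout), which is what makes seeded CPU
training exactly reproducible. The 3-D ResNet-34 uses basic-block stages
(3, 4, 6, 3) with a (3, 7, 7) stem; at a 5-slice depth there is no room for
depth striding, so all downsampling (stem stride, a non-overlapping
(1, 2, 2) max pool, and stage-entry strides) is in-plane and the depth axis
collapses only at the global average pool. `tiny3d` — two strided conv/BN
stages and a linear sigmoid head — exercises the identical harness at desk
scale. Full-scale runs are organized the same way but are outside the scope
of the test suite: the desk experiments use `tiny3d` on 32×32×5 stacks with
n = 80, 20 epochs, and a learning rate of 0.05 suited to that model size.

## Synthetic cohorts

The fixture generator emulates the structure of a public radiotherapy
archive: per-patient folders of CT DICOMs plus an RTSTRUCT, a clinical CSV
with the archive's column names, and a ground-truth manifest. Tumours are
ellipsoids polygonized to 32-vertex contours per slice (area error of the
polygon vs the true ellipse < 0.7%, so rasterization at ≥ 100 px dominates
the < 5% recovered-area tolerance); lungs are two tall ellipses, the cord a
small posterior circle. Defaults: 128×128 pixels at the archive's 0.977 mm
spacing and 3.0 mm slice thickness, 18–30 slices per patient (a desk-scale
stand-in for the archive's 75–297), tumour in-plane semi-axes 8–22 mm and z
semi-axis 4–28 mm (GTV-1 extents of roughly 2–18 slices, echoing the
archive's 2–97 at its larger series lengths). Cohorts are byte-identical at
fixed seed (fixed UID roots, fixed dates, formatted decimal strings).

Survival is Weibull (shape 1.3) with log-scale
`ln(1400) - 0.09 · GTV1-SliceNum` days: the scale was set so the uncensored
2-year survivor fraction lands near the ~1/4–1/3 seen in real cohorts and
the top/bottom slice-count quartiles differ by well over 20 points — a
strong, known association for the feature-importance harness. A null
configuration (`slice_count_coef=0`) removes it. Censoring is a Bernoulli
11.4% flag (the archive's censored fraction) with the follow-up drawn
uniformly from 10–100% of the true survival time.

What the fixtures do *not* emulate: CT texture (intensities are flat tissue
classes plus Gaussian noise), scanner private tags, non-ellipsoidal tumour
shapes, inter-observer contouring variability, and any real correlation
structure among clinical covariates. Passing tests therefore establish the
pipeline's mechanics — parsing, geometry, QC logic, feature counting, loss
algebra, optimization plumbing — not clinical performance on real CT, which
requires the real archive and full-scale training.

## Known limitations

- Neighbour interpolation cannot repair a slice whose true area exceeds both
  neighbours (local maxima of the area profile); such repairs bias the area
  downward.
- The `include_censored` policy mislabels censored patients with short
  follow-up by construction.
- The numpy training engine is CPU-bound and float64; it is built for exact
  reproducibility at desk scale, not for training the full 3-D ResNet-34 on
  240×240×5 inputs, which demands GPU-class throughput.
- The area-jump detector assumes a roughly concave area profile; genuinely
  multi-lobed tumours along z could be flagged and "repaired" incorrectly —
  τ is configurable per cohort.
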