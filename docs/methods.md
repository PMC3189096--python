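# Methods

## Model and assumptions

The pipeline assumes a co-registered pair of 2D 8-bit axial slices (T1-
and T2-weighted) of the same matrix, acquired without intensity
inhomogeneity, with the head well centered so that the anatomical midline
coincides with the image's central pixel column. Registration itself is
out of scope: inputs are taken as aligned.

The core statistical object is the joint intensity histogram: pixel k is
the point x_k = (x_{k,T1}, x_{k,T2}) and the histogram h(a,b) counts
pixels with T1 = a, T2 = b. Fuzzy c-means is run **over occupied bins
weighted by their counts** rather than over pixels. Because all pixels in
a bin share coordinates — hence distances, hence memberships — the
weighted objective

J = Σ_bins h_k Σ_i u_ik^m ‖x_k − v_i‖²

equals the per-pixel objective exactly, at a fraction of the cost (the
number of occupied bins is at most 65 536 and typically a few thousand).
The test suite verifies trajectory-level equivalence against an
independent per-pixel implementation started from the same fuzzy state.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `clusters` (c) | 32 | deliberate over-segmentation so the tumor separates into its own group(s); configurable to sweep 10–40 |
| `fuzzifier` (m) | 2.0 | standard FCM softness; m→1 approaches k-means |
| `eps` | 1e-5 | stop when the objective changes by ≤ eps (absolute); with image-scale objectives the loop typically runs to `max_iter` |
| `max_iter` | 300 | FCM iteration cap |
| `k_sd` | 2.0 | region-growing acceptance half-width in seed SDs, both channels (conjunction) |
| `connectivity` | 8 | component labeling and growth neighborhood |
| `brain_threshold` | 0 | brain mask = pixels with T1 or T2 strictly above this; raise for noisy backgrounds in real data |
| `noise_floor` | 50 | T2 bins below this are discarded as noise before the laterality correlation |
| `laterality_threshold` | 0.95 | Pearson r above which the halves are called symmetric (possible midline tumor) |
| `morph_radius`, `morph_element` | 1, square | structuring element of the refinement opening; the 3×3 square leaves solid convex masks intact, while the radius-1 disk (a cross) shaves rectangle corners |

Seed statistics for region growing are computed once from the initial
seed region and **frozen** during growth; the reference is always the
seed mean, never an updated region mean. A single-pixel seed has SD 0,
making the acceptance interval the exact seed value — degenerate but well
defined. Growth candidates are by default any image pixel (a config
switch restricts growth to the cluster's own defuzzified pixels), because
growth is meant to re-aggregate fragments into whole tissue regions.

Because the acceptance predicate is fixed, the grown region equals the
connected component of (eligible ∪ seed) pixels containing the seed; the
implementation computes it in one labeling pass, and tests check equality
with an explicit breadth-first oracle.

## Knowledge-based rules: numerical choices

- Bounding-box exclusion is **conjunctive** (taller than half the brain
  box AND wider than half); a config switch offers the disjunctive
  variant for sensitivity analysis.
- The laterality correlation is Pearson's r between the left- and
  right-half T2 histogram count vectors over bins ≥ `noise_floor`. Two
  exactly equal vectors give r = 1 regardless of variance; a flat
  (zero-variance) but unequal vector gives r = 0 by convention. With an
  even width the halves are columns [0, w/2) and [w/2, w); an odd central
  column belongs to neither half.
- The tumor side is the half with the higher count at the reference bin
  argmax |left − right|. This single-bin rule is reliable when the tumor
  produces a concentrated surplus of bright-T2 counts; it is the part of
  the cascade most sensitive to histogram lumpiness.
- A straddling candidate is attributed by majority pixel count (> 0.5
  strictly on the far side eliminates it).
- Solidity = pixel area / pixel area of the convex hull, computed by
  rasterizing the scipy ConvexHull facet inequalities at pixel centers
  (tolerance 1e-9); collinear masks fall back to counting lattice points
  on the extremal segment, so a 1-px line has solidity 1. This geometric
  definition matches the brute-force point-in-hull oracle exactly, which
  is why it is used instead of `skimage.regionprops`.
- The 2-way feature split is agglomerative clustering of the 1-D feature
  values under average linkage with |·| distance, merged until two
  clusters remain (verified against `scipy.cluster.hierarchy`). Ties in
  the final higher/lower choice go to the cluster containing the lowest
  index. When all values are equal, or only one candidate remains, the
  filter keeps everything: a relative rule has no basis to discard, and
  failing open preserves recall.
- Rule order is fixed: bounding box → laterality → solidity → area.
  Defuzzification argmax ties break to the lowest cluster index; empty
  clusters are dropped before seeding.

Morphological refinement retains the largest connected component
**between** erosion and dilation: the erosion's purpose is to detach
residual neighboring tissue, and a bare opening would simply reattach it.
Hole filling is an explicit border flood fill, since dilation alone
cannot guarantee a hole-free result. If erosion annihilates the mask the
pipeline retries with radius 0 (hole filling only).

## Evaluation

PM = 100·TP/GT and CR = (TP − 0.5·FP)/GT are computed at full precision
and rounded to two decimals only for display. Case summaries use the
arithmetic mean and the sample (n−1) SD; paired comparisons use the
two-sided paired t-test and refuse zero-variance differences. The
packaged 29-case clinical counts table is used to validate the formulas:
recomputed PM/CR match the printed columns to two decimals, the overall
means reproduce 72.80 ± 36.20 % (PM) and 0.43 ± 0.86 (CR), and excluding
the five automatic-pathway failures reproduces 87.41 % / 0.78.

## What the phantom emulates — and what it does not

The generator renders an axis-aligned elliptical "brain" (gray-matter
band, white-matter core, two mirror-symmetric CSF ventricles, skull ring)
and an elliptical tumor that is bright on T2, placed in either hemisphere
or straddling the midline, with an optional edema ring whose T2 intensity
lies between tumor and normal tissue — the documented failure mode of the
selection rules. Defaults: 256×256 matrix; tumor semi-axes (22, 28) px,
i.e. ≈1900 px area, matching the ground-truth areas of clinical
meningioma slices at that matrix size; tumor T2 mean 200 vs gray matter
115 and CSF 230.

Intensities are tissue means plus two noise terms: a **spatially smooth**
intra-tissue heterogeneity field (Gaussian-filtered white noise,
correlation length 2 px, scaled to each tissue's SD — brain tissues 25,
tumor 5, since meningiomas are characteristically homogeneous on T2) and
iid per-pixel acquisition noise (`noise_sd`, default 5). Both are drawn
independently per channel. The smooth component is what makes the
phantom's half-histograms realistically broad — narrow synthetic peaks
would make the laterality correlation of any lateral-tumor image exceed
0.95 — while keeping defuzzified clusters spatially coherent enough to
seed region growing, as in real tissue.

The phantom does **not** model MR physics (partial volume at boundaries
is abrupt, no bias field, no Rician noise floor, no gyral anatomy), and
its left-right symmetry is exact up to noise, whereas real brains are
only approximately symmetric. Passing the phantom study therefore shows
that the pipeline's stages compose correctly under the intensity
assumptions the method states — not that those assumptions hold on any
particular scanner's output.

## Problem sizes in the standard study

The bundled acceptance study runs 20 lateral-tumor and 20 midline-tumor
phantoms at 256×256 with noise SD 5, plus a 6-phantom ablation with
region growing disabled; FCM equivalence is checked on 20 random images
up to 32×32, region growing against its oracle on 50 random 16×16
instances, and the feature split against enumeration on 100 random lists.

## Known limitations

- The laterality side call reads a single histogram bin; tissue-scale
  sampling lumps can occasionally out-vote the tumor surplus, which is
  the dominant residual failure on lateral phantoms (~1 in 20).
- Edematous cases confound the selection rules by design (edema is
  T2-bright); the semi-supervised pathway is the documented recourse.
- All processing is 2D and single-slice; volumes must be handled slice
  by slice.
- With c = 32 the absolute-eps stopping rule effectively runs FCM to the
  iteration cap (~seconds per slice); lower `max_iter` for interactive
  use.
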