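# Methods

This note documents the models, conventions and numerical choices behind
mammoscope, in the spirit of a statistical-software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Physical calibration

All geometry is referred to a pixel pitch of 0.75 µm/px (a 1000 × 1000 px
raster per 750 × 750 µm² field). The pitch is not an independent
measurement: it is the unique value that makes the three standard unit
conversions used throughout mutually consistent — a 35 px region has a
5.0 µm equivalent circular diameter, 500 px has 18.9 µm (printed as
19 µm), and 500 px corresponds to 281.25 ≈ 280 µm². The pitch is
configurable everywhere (`PixelCalibration`); the raster dimension is an
inference, not an assertion about any particular instrument.

## MSER nuclear segmentation

The detector works on upper level sets (bright nuclei on a dark
background; proflavine is a nuclear stain) with 8-connected components.
The component tree is built by a union-find max-tree pass over pixels
sorted from bright to dark, with canonicalization in the reverse order;
the kernels are numba-compiled because a 10⁶-pixel field yields trees with
10⁵–10⁶ nodes.

Stability is the relative area variation q(t) = [A(t−Δ/2) − A(t+Δ/2)]/A(t)
evaluated at every threshold t of every component's lifetime interval.
Conventions that the definition leaves open are fixed as follows:

* **Chain continuation.** Below a component's interval the area function
  follows the enclosing (ancestor) components; above it, the iteratively
  largest nested component (at each successive threshold, the largest
  component contained in the current one; ties broken by smallest pixel
  index). Fractional query thresholds use the step continuation
  A(τ) = A(⌈τ⌉); queries clamp to [0, 255].
* **Selection.** A threshold is selected when q(t) is a local minimum
  along the chain — strictly below the previous value and not above the
  next — so a tied run keeps only its lowest threshold. The full-image
  component is never reported.
* **Gates.** Selections must satisfy MinArea ≤ A ≤ MaxArea and
  q ≤ MaxVariation. MaxVariation = 2.5 exceeds the usual fractional
  range of variation scores; it is applied exactly as configured, with no
  renormalization, since all intensity parameters are stated on the
  relative 0–255 scale.
* **Diversity.** Surviving selections are scanned deepest-first; a
  selection whose nearest surviving enclosing selection differs in area by
  less than MinDiversity (relatively) is removed — the nested (inner)
  region is the one discarded.

Defaults: MinArea 35 px, MaxArea 500 px, MaxVariation 2.5, MinDiversity
0.5, Δ 6.

The brute-force oracle (`mser_brute_force_oracle`) implements the same
contract by explicitly labeling all 256 level sets with per-threshold
containment maps, sharing no code with the max-tree path beyond the
labeling primitive; the test suite asserts pixel-set-and-threshold
equality of the two on batches of random images. Surviving regions are
unioned and relabeled by 8-connectivity into the nucleus mask, so nested
stable selections of the same nucleus collapse to one label.

## Nuclear morphometry

* **Moment ellipse.** Axis lengths are 4√λ of the eigenvalues of the
  per-pixel central second-moment matrix with a +1/12 unit-square term on
  the diagonal. This makes a 1 × k pixel run behave like a continuous
  segment of length k (major axis 4√(k²/12)) and gives a single pixel the
  degenerate axis 4√(1/12) ≈ 1.155 px, matching the convention of the
  classic image-processing toolboxes this field uses.
* **IND.** Euclidean distance from each nucleus centroid to the nearest
  other centroid (kd-tree); undefined (error / missing feature) with
  fewer than two nuclei.
* **Summary statistics.** Mean; median; mode as the centre of the most
  occupied 1.0 µm bin centred on integers, ties to the smallest bin
  (a convention for continuous data, the sources being silent); IQR from
  linear-interpolation quartiles; sample SD (n−1); range = max − min.
  Six statistics over three measurement vectors (IND, diameter, wall
  width) plus density and area fraction give the 14 + 19 = 33 parameters;
  "range" is included among the summaries because the dispersion measures
  of IND are first-class parameters in this scheme.
* **Density** is reported per mm².

## Ductal segmentation

Order of operations: adaptive Wiener denoise → CLAHE → binarize →
remove small objects → clip to ROI → extract geometry.

* **Wiener.** Local mean µ and variance σ² on a 5 × 5 window (reflective
  borders), noise floor ν = mean of all σ², output
  µ + max(σ²−ν,0)/max(σ²,ν)·(x−µ), clipped to [0, 255]. Implemented
  directly on `uniform_filter` moments: the stock scipy routine zero-pads
  borders, which visibly darkens edges and alters even a constant image.
* **CLAHE.** `skimage.exposure.equalize_adapthist`, 8 × 8 tiles, clip
  limit 0.01, 256 bins, output rescaled to 0–255. A constant image is
  passed through unchanged.
* **Binarize.** Foreground at intensity ≥ threshold. The threshold is a
  per-site input (the original workflow was interactive); 107 — the
  cohort mean — is the default.
* **Small objects.** 8-connected components with area strictly below
  500 px (the nuclear size ceiling) are removed, so isolated nuclei
  outside duct walls drop out.
* **ROI.** Polygons are supplied as files; a pixel belongs to the ROI if
  its centre is inside or on the polygon (exact point-in-polygon test).
* **Geometry.** Holes are 4-connected background components within the
  ROI that touch neither the ROI border nor the raster edge; all holes
  are filled into `filled_mask`, and holes of at least 35 px (the nuclear
  size floor, suppressing speckle) become lumens. Foreground uses
  8-connectivity and background 4-connectivity, the standard dual pair.
  Boundaries are the thin 8-connected contour curves obtained by
  4-adjacency to the exterior; the 8-neighborhood variant would double
  contours on diagonals and bias wall widths by up to half a pixel.

## Ductal morphometry

Wall width is measured at every outer-boundary pixel as the Euclidean
distance to the nearest inner (lumen) boundary pixel of any lumen, via a
distance transform of the inner boundary; tests verify it against
exhaustive pairwise distances. With several lumens, `lumen_area` sums all
of them while lumen shape descriptors (axes, eccentricity, ellipse area,
solidity) are measured on the largest lumen — a fixed convention for
cribriform ducts. Wall area is the area of the annulus (the wall proper,
not the filled region). Ellipse axes are reported as full lengths
(diameters). Solidity is region area divided by the exact convex-hull
polygon area of the pixel squares' corners, so any rectangular raster
scores exactly 1 and a plus-sign of five unit squares scores exactly 5/7;
for rasterized disks the corner hull exceeds the region by an O(1/r)
perimeter band (≈ 4% at r = 20 px, under 2% beyond r ≈ 70 px).

## Classification

* **Single-parameter screening.** One-dimensional two-class LDA reduces
  to a monotone threshold rule on the parameter, so each parameter's ROC
  is computed exactly by a threshold sweep (both directions; the
  direction with AUC ≥ 0.5 is kept; trapezoidal AUC; Youden-J optimal
  cutpoint). Welch's unequal-variance t test accompanies the ranking.
  Rankings are reported for four site groups: nuclear parameters on all /
  non-duct / duct sites, ductal parameters on duct sites.
* **CART.** Recursive binary splitting by Gini impurity over midpoints of
  sorted distinct values, grown to purity (min leaf 1). Ties in impurity
  resolve to the lexicographically smaller feature name, then the lower
  cutoff, making growth deterministic. Missing values at a split go to
  the child holding the majority of the node's non-missing rows (ties to
  the condition side); each node records that side for later routing. A
  missing lumen count means "no segmented duct" and is imputed as zero
  before training and during routing.
* **Pruning.** Two structural rules: a parameter may appear at no more
  than one node, and at most three malignant leaves may remain (one per
  malignant histology — IDC, ILC, DCIS). Violations are resolved deepest
  first: from the violating node, the nearest ancestor (the node itself
  qualifies unless it must disappear under the repeated-parameter rule)
  whose split separates a majority-malignant side from a majority-benign
  side of its routed training sites has its children collapsed into
  majority-class leaves; if no ancestor qualifies, the violating node
  itself is folded into a leaf. Pruning never adds nodes and terminates
  because every step removes internal nodes.
* **LOOCV.** The tree structure and all non-root cutoffs are held fixed
  ("more than one lumen" is the only biologically sensible lumen rule);
  each fold refits only the root cutoff by Gini on the remaining sites
  and classifies the held-out site; the confusion matrix aggregates over
  folds.
* **Tree ROC.** Sites sorted by ascending StdIND; at every candidate
  cutoff c a site is called malignant when StdIND < c or when it has more
  than one lumen, giving a curve with a sensitivity floor from the lumen
  rule; trapezoidal AUC with (0,0) and (1,1) anchors.

## Synthetic phantoms

The generator renders single optical sections at the study conditions: a
750 × 750 µm² field at 0.75 µm/px, background 30 with additive Gaussian
noise (SD 6) and a smooth multiplicative illumination field (±10%),
emulating illumination and staining variability. Nuclei are flat-top
bright disks (peak 185, ±8% per-nucleus jitter, ~1 px soft edge) —
stained nuclei are filled bodies, and a flat-top profile is also what
makes them well-defined extremal regions; diameters are drawn from
7–10 µm (6.5–9 µm for single-file lobular cells), inside the biologically
expected range and the 5–19 µm MSER gates. A global 12 µm minimum centre
separation keeps rendered nuclei from fusing, chosen so that the
worst-case diameter pair plus the soft edge still leaves a gap.

Phenotype morphologies: adipose — nuclei scattered on adipocyte
boundaries (circles of 35–65 µm radius) plus sparse stroma; fibrous —
uniform sparse nuclei; lobules — acinar rings (18–26 µm radius) with
irregular exponential-gap spacing plus stroma; IDC — dense hard-core
sheets (1800–3000 mm⁻²); ILC — single-file strands with 12 ± 0.4 µm step,
terminated rather than allowed to cross another strand; ducts — a bright
wall band (intensity 130) with an enclosed lumen (normal: thin wall;
hyperplastic: thick wall) or, for DCIS, a filled expanded duct perforated
by 2–6 lumens of 10–18 µm radius (cribriform). Duct sites carry an
octagonal ROI and a per-site binarization threshold (N(107, 8) clipped to
[90, 125]).

Cohort generation mirrors the 259-site reference composition
(42 adipose / 31 fibrous / 82 lobules / 20 normal ducts /
4 hyperplastic / 26 DCIS / 37 IDC / 17 ILC = 179 benign + 80 malignant).
Per-site parameters are drawn from the phenotype ranges above using a
generator keyed on (master seed, site index), and the rendering seed is
master seed + site index, so cohorts are exactly reproducible.

**What the phantoms do and do not emulate.** By construction the benign
phenotypes have dispersed, irregular nuclear spacing and the malignant
ones tight, regular spacing, with DCIS carrying benign-like surroundings
but multiple lumens — the "easy" regime in which the two-rule decision
model (IND dispersion, then lumen count) is the right answer and its
machinery can be verified end to end. Density and area fraction are given
overlapping per-site ranges across classes (dense lobules vs. sparse ILC)
so they do not short-circuit the tree. The phantoms do not reproduce
chromatin texture, stromal collagen, out-of-focus light, unresolvable
nuclear clumping inside duct walls, or partial-field lesions — the
failure modes that limit sensitivity on tissue (single-file ILC embedded
in benign stroma being the canonical one). Passing the synthetic-cohort
criteria therefore demonstrates correctness of the pipeline under its own
assumptions, not clinical performance; metrics from the phantom cohort
are expected to be near-ceiling and systematically higher than anything
achievable on patient images.

## Problem sizes and determinism

Unit tests use 64 × 64 rasters for detector/oracle equivalence (the
oracle is O(256·n) per image) and full 1000 × 1000 fields for phantom
recovery checks. The acceptance script regenerates everything from its
seed: 40 random images for oracle agreement, 50 duct phantoms for lumen
recovery, and one full 259-site cohort for the classification metrics;
the whole run is a few minutes on one CPU. All randomness flows from
explicit `numpy.random.Generator` seeds; there is no global random state.

## Known limitations

* MSER on smooth (non-flat-top) blobs selects compact cores; nuclei with
  strong internal intensity gradients may be under-segmented. Touching
  nuclei merge into one label (8-connected union), biasing counts down in
  dense tissue.
* The duct pipeline assumes one duct per ROI; multiple ducts in a single
  polygon are measured as one object.
* CLAHE on structureless noise amplifies it; the per-site threshold is
  the operator's control for this, and a threshold that leaves nothing
  above the 500 px ceiling raises a segmentation error rather than
  returning an empty geometry.
* The LOOCV refit searches only the root cutoff; it does not re-select
  the root feature per fold.
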