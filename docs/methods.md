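# Methods

`rectodose` reimplements, end to end, the dose-mapping analysis used to
quantify how a protective rectal gel spacer changes the dose the rectal
wall receives during high-dose-rate (HDR) intracavitary brachytherapy.
Because clinical CT/plan data of this kind are not publicly deposited,
the package ships a first-class synthetic cohort generator that emulates
the paired study design (each patient imaged and planned before and
after gel insertion, five fractions each); every downstream stage is the
real analysis, exercised on those synthetic cases or on imported data.

## Dose model and accumulation

Physical per-fraction doses are converted voxel-/vertex-wise to the
equivalent dose in 2 Gy fractions under the linear-quadratic model,

    EQD2 = d (d + α/β) / (2 + α/β),   α/β = 3 Gy (late rectal toxicity),

*before* summation, so fractions of different size are accumulated on a
common radiobiological scale.  The conversion is exact at d = 2 Gy and
strictly increasing, so dose orderings are preserved.

The rectal wall is represented as a surface lattice: each delineated
slice polygon is resampled by arc length to a fixed number of angular
samples (`n_theta`), starting at the **left-lateral anchor** — the
boundary point hit by the +x ray from the slice centroid (LPS axes:
x = patient left, y = posterior, z = superior).  Traversal is oriented
through the anterior half first, giving each vertex parameters
u ∈ [0, 1] (normalized inferior→superior position) and v ∈ [0, 1)
(normalized circumference), with v < 0.5 anterior and v ≥ 0.5 posterior.

Inter-fraction correspondence is **parameterization-based**: vertices on
different fractions correspond when they share (u, v).  A full
point-matching deformable surface registration is intentionally not
reimplemented; for a roughly tubular organ the shared parameterization
is deterministic, testable and anatomically reasonable, and
`accumulate_fractions` accepts a `correspondence` callable so a true DIR
can be plugged in.  Fractions with different slice counts are resampled
to the reference fraction's rings by linear interpolation in u.  Note
one consequence of the fixed +x anchor: correspondence is invariant
under translations of the anatomy but not under rotations about the
body axis, which are negligible between fractions in practice.

## Unfolding (2D rectal surface dose map)

The accumulated surface dose is unrolled at fixed 1 mm × 1 mm
resolution: rows are longitudinal positions at ~1 mm pitch (linear
interpolation between rings), each row holds `round(circumference)`
pixels sampled at 1 mm arc steps from the anchor, horizontally centered
(hence the lens-shaped foreground).  Background is NaN plus an explicit
mask, so zero-dose foreground stays distinguishable.  The
anterior/posterior split takes, per row, the first half of the
foreground run (50% of that slice's circumference); an odd width gives
the extra pixel to the anterior half.  Mean dose on the map agrees with
the area-weighted mean vertex dose to within ~2% on smooth fields.

## Feature families (363 per region)

* **DVPs (50)** — D_x-cc for x = 0.1 … 5.0 cm³: vertices carry volume
  (area weight × wall thickness), are sorted by dose descending, and
  D_x-cc is the dose at which the running volume reaches x cm³.  Wall
  thickness defaults to 3 mm; `"auto"` derives it as delineated volume /
  surface area.  If a region holds less than x cm³ the minimum dose is
  reported (logged).
* **Textures (43)** — 3 global moments (variance, skewness, kurtosis of
  the raw foreground dose) plus GLCM (9), GLRLM (13), GLSZM (13) and
  NGTDM (5) statistics of the dose map quantized to 32 equal-width bins
  over the region's range.  GLCM and GLRLM matrices are merged (summed)
  over the four distance-1 directions before feature computation; GLSZM
  zones are 8-connected equal-level components; NGTDM neighbourhoods are
  8-neighbours restricted to foreground.  A constant map collapses to a
  single gray level with the degenerate closed-form values (energy 1,
  contrast 0, correlation 1 by convention).  Formulas follow the
  standard definitions of each family; exact IBSI compliance is not
  claimed.
* **DGPs (270)** — nine descriptors × 30 dose levels (1–30 Gy, 1 Gy
  step).  The threshold mask is dose ≥ L for the whole and anterior maps
  and dose < L for the posterior map, where *sparing* is the quantity of
  interest.  All mask pixels are pooled into one region even when
  disconnected (one value per level).  Eccentricity and axis lengths
  come from the second-moment-equivalent ellipse (0 for a single pixel);
  the perimeter rule is the total marching-squares iso-contour length at
  0.5 on the zero-padded mask (axis-aligned edges count 1, staircase
  corners are cut diagonally); centroid distances are measured to the
  bottom-most row and left/right-most columns of the rectum foreground.

## Discrimination grid

24 feature-selection strategies × 8 classifiers = 192 models per region,
evaluated with stratified fivefold cross-validation grouped at the
patient level (both conditions of a patient share a fold, so no identity
leakage).  Within each fold: z-score by training statistics, refit the
selector on the training portion only (k = 20 features), train the
classifier, score AUC on the held-out fold.  The model AUC is the mean
of fold AUCs (pooled-prediction AUC is recorded alongside).  Features
are then ranked by how often they appear in the top-20 lists of folds
belonging to models with mean AUC > 0.80.

Implementation notes, fixed for reproducibility rather than tuned:

* Information-theoretic selectors run greedy forward selection on
  equal-frequency 5-bin discretized features; MIFS uses β = 1, LCSI uses
  β = γ = 0.5, DISR normalizes joint relevance by joint entropy.  FCBF's
  predominant set is padded with the next-best symmetric-uncertainty
  features when it is smaller than k.
* Sparse-learning selectors (ls_l21, ll_l21, RFS, MCFS, NDFS, UDFS)
  solve their ℓ2,1-regularized objectives with fixed-iteration IRLS
  (50 iterations, tolerance 1e-6; Woodbury identities for n ≪ d) or
  proximal gradient for the logistic loss; NDFS is simplified to an
  ℓ2,1 regression of a spectral bipartition indicator and UDFS to the
  eigenvector iteration on M = XᵀLX; both are documented simplifications
  that preserve the family's behaviour and pass the same sanity
  contracts as every other selector.
* Unsupervised graph methods use a heat-kernel 5-NN affinity built on
  the features as given (the grid feeds them z-scored data).
* Classifier defaults: logistic (L2, C = 1), RBF SVM (C = 1), Gaussian
  naive Bayes, 5-NN, CART, bagging (50 trees), random forest (100
  trees), AdaBoost (50 stumps).

Isomap (k-NN graph, geodesic distances, classical MDS) projects the
top-10 features to 2D for visualization; k grows automatically until
the neighbour graph is connected.

## Paired statistics

Each variable is compared pre vs post with a Shapiro–Wilk-gated paired
test: Student's paired t (summary mean ± SD) when both samples pass
normality at α = 0.05, Wilcoxon signed-rank (median, IQR) otherwise;
two-tailed, significant at p < 0.05.  The gate is applied to each
condition's sample by default (a differences-based gate is a toggle).
No multiple-testing correction is applied by default, with an optional
Benjamini–Hochberg toggle.  All-zero differences are reported as p = 1
with a degeneracy flag.

## Synthetic cohort: what it emulates, and what it does not

The rectum is a stack of elliptical cross-sections (defaults: lateral
semi-axis 11.35 mm, AP 11.65 mm — pre-gel wall separations near
23 mm — 21 slices at 2.5 mm spacing) with smooth low-order Fourier
perturbations in angle and along z, a per-patient log-normal calibre
factor (SD 0.18) and an independent smooth inter-fraction radial field
(SD 1 mm).  The gel effect rescales each slice about its centroid by the
population post/pre separation ratios (lateral 28.1/22.7 ≈ 1.238, AP
26.5/23.3 ≈ 1.137) and shifts the centroid posteriorly by the net
1.7 − 1.3 = 0.4 mm push; it is deterministic per patient.  The CTV
centroid sits 24.7 mm anterior to the anterior wall, and each fraction
places 7 dwells (5 mm apart, 0.5 mm jitter) along z at the CTV.  Dose is
a bare inverse-square point-kernel sum (r capped at 1 mm), with the
source strength (500 Gy·mm² per dwell) calibrated once so the anterior
wall's per-fraction physical D_0.1cc falls in 3–6 Gy — no TG-43
anisotropy or radial dose function, no scatter, no applicator geometry,
no CT intensities.  Wall thickness is a configuration (default 3 mm)
because whether clinical delineations are wall-only or full-organ is
ambiguous; both conventions are reachable.

Consequences for interpretation: passing tests show that the *pipeline*
recovers a configured geometric/dosimetric effect and stays at chance on
null cohorts; they do not certify clinical effect sizes.  In particular,
which feature family dominates the top-10 frequency ranking depends on
the synthetic dose structure — on these cohorts texture and geometric
features of the posterior map often outrank the posterior DVPs, whereas
clinical data may weight families differently.

## Problem sizes and numerics

Analysis resolution defaults to `n_theta` = 256 angular samples; the
test-suite and the acceptance script use 128 (sub-millimetre arc spacing
for the ~70–90 mm synthetic circumferences) and 30-patient cohorts, with
coarser 9-slice geometry for the 20-seed null-control replication —
sizes chosen so the complete analysis remains a desk-scale computation
on one CPU.  Cross-validation folds derive from shuffling patients with
a seeded generator; every stage's seed is derived from one master seed
by a fixed offset scheme, and identical configuration + seed reproduces
every output bit for bit.  Degenerate inputs have defined behaviour
throughout: empty threshold masks give nine zero DGPs, constant maps
give closed-form textures, out-of-grid samples give zero dose with a
logged warning, rings with circumference < 4 mm abort unfolding.

## Known limitations

* Parameterization-based correspondence ignores true tissue tracking;
  large torsion or longitudinal sliding between fractions would
  mis-assign dose (the hook exists for a real DIR).
* The dose engine's inverse-square kernel overestimates dose far from
  the applicator relative to TG-43.
* GLRLM/GLSZM/NGTDM definitions vary across radiomics toolboxes; values
  here follow the documented conventions above and are oracle-tested
  against brute-force reimplementations, not against any toolbox.
* The 50%-circumference anterior/posterior split is an arc-length rule,
  not a geometric hemisphere; for strongly asymmetric slices the two can
  differ.
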