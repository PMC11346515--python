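# Methods

`mitovol` measures mitotic chromosome geometry from voxelized volume-EM
stacks and propagates those measurements into chromatin packing
densities and nucleosome concentrations.  Because raw serial block-face
SEM data are far too large to ship with a package, every stage is
validated against synthetic phantoms with closed-form ground truth; this
note records the models, the parameters that matter, and the limits of
what phantom-based validation can show.

## The measurement model

A stack is a 3D grayscale grid with anisotropic voxel spacing — by
default 25 × 25 × 60 nm, the analysis grid obtained when 4-nm-pixel
block-face images are average-binned 5 × 5 × 1 and sections are cut at
60 nm.  All arrays are indexed `(x, y, z)` with voxel centres at
`(i + 0.5) · spacing`; all physical quantities are nm/µm internally, and
every distance computation (EDT, skeleton weights, marching cubes) uses
the physical spacing rather than voxel counts, because a 60-nm z-step
would otherwise distort widths and separations by more than a factor of
two.

Segmentation follows the classic density-threshold workflow:

1. **Average binning** (`bin_average`), block means with trailing
   partial blocks truncated so block statistics stay uniform.
2. **Global threshold** (`select_threshold`).  `auto` is Otsu's
   between-class-variance criterion on the full histogram, with the cut
   snapped to the midpoint of the empty gray-level gap it falls in (so a
   noise-free two-valued image thresholds exactly between its modes).
   Otsu is a reproducible stand-in for a visually chosen threshold; a
   manual value passes through untouched.
3. **Mask cleanup** (`mask_and_clean`): polarity-aware thresholding,
   filling of enclosed noise holes (a voxel of chromosome interior drops
   below threshold with probability ~3·10⁻⁴ at the default contrast and
   noise, enough to pepper a complement with dozens of holes that would
   break the distance transform), and removal of connected components
   below `min_object_voxels` (default 50).
4. **Object separation** (`separate_objects`): marker-controlled
   watershed on the negated anisotropic Euclidean distance transform.
   Markers are the regional maxima of the h-reconstruction of a lightly
   smoothed EDT, computed per connected component with
   `h = max(min_depth_fraction · max thickness, one voxel diagonal)`,
   then dilated `marker_extension` (default 4) steps and merged.  The
   reconstruct-then-regional-maxima construction is essential: plain
   h-maxima keeps equal-height peaks separate no matter how shallow the
   saddle between them, which fragments every tube.  With the default
   `min_depth_fraction = 0.5`, a centromeric constriction that narrows
   the chromatid to ≥ ~0.7 of its radius does not split it, while the
   thin seam between tangent sister chromatids (relative depth ≳ 0.55)
   does.  Constrictions much deeper than that are geometrically
   indistinguishable from a sister seam at this resolution and will
   split — a genuine ambiguity of the data, not a tunable.

## Morphometry

**Volume** is voxel count × voxel volume — exact for the voxel model.

**Surface area** triangulates the binary label's 0.5-isosurface with
marching cubes at physical spacing, after Gaussian pre-smoothing with
σ = 1 voxel.  Binary isosurfaces carry a systematic staircase inflation
(+9% on a 500-nm sphere at 12.5-nm voxels); one voxel of smoothing
reduces that to ~0.1% without moving the surface.  A `voxel_faces`
method (exposed-face counting) is kept as the staircase upper bound.
`binning_sensitivity` defaults to *unsmoothed* marching cubes, since its
purpose is to expose resolution-dependent surface roughness, not to
estimate the true area.

**Centreline.**  The centreline is the geodesic between the two ends of
the object on a 26-connected voxel graph whose edge weights are
`physical step × (1 + α·(1 − EDT/EDTmax))` with α = 8, i.e. paths are
pulled onto the ridge of the distance transform (a medial-axis path).
End voxels are found by a double Dijkstra sweep in the plain metric
(they sit at the cap apices), the connecting path is routed in the
weighted metric, trimmed at each end up to the first point whose local
radius reaches 97% of that end's maximum (the medial axis of a capped
tube stops one radius short of the apex), and smoothed by a 5-point
moving average that removes lattice zigzag.  An object whose trimmed
path is shorter than its own maximum radius is flagged ball-like and
reported with zero length.  We chose this construction over 3D thinning
because topology-preserving thinning of thick tubes can legally collapse
them to a point, and in practice does so unpredictably under one-voxel
shifts of the object; the ridge geodesic is deterministic, rotation
stable (< 0.3% length variation for a rod rotated arbitrarily in-plane
at isotropic spacing) and accurate to ~1% on 7–13 µm rods and bent
tubes, degrading to ~2% for stubby chromosomes a few radii long.

**Width** at a sample point is twice the anisotropic EDT value there.
Ten samples (the measurement protocol's count) are spaced equally along
arc length, excluding 10% at each end (telomeres) and a 10% window
around the detected constriction (centromere), both of which have
specialized geometry.  On tube phantoms with radii 200–500 nm the
estimate agrees with the analytic diameter to within one voxel diagonal
(69.6 nm at the default grid) — the quantization floor of the method.

**Centromere and arm ratio.**  The constriction is the global minimum
of the 5-point-smoothed radius profile along the centreline, excluding
10% at each end, with ties broken toward mid-arc.  A minimum that does
not dip below 0.9 × the median radius is called absent (the early
prometaphase case, where the primary constriction has not yet formed).
Arm ratio is the longer over the shorter arc segment; class cut-offs
follow the standard cytogenetic convention (metacentric ≤ 1.7,
submetacentric ≤ 3.0, acrocentric above), which the source analysis did
not specify numerically.

**Identity assignment.**  Only the extremes of the size ranking are
identifiable from relative size and centromere class, so the five
largest and four smallest karyotype entries form two candidate bands.
Within a band, objects are matched to entries by a rank-distance
assignment (Hungarian algorithm) that requires class agreement and is
injective per expected copy number; a strict rank zip fails whenever
measurement noise swaps the order of near-equal chromosomes (chromosomes
3 and 4 differ by ~4% in length).  Mid-sized chromosomes are never
assigned.

## Densitometry

With per-chromosome DNA content known, the chain is pure arithmetic and
is implemented exactly as reported:

- linear packing ratio: least-squares slope **through the origin** of
  content vs length, `Σ(c·l)/Σ(l²)` (a zero-length chromosome carries
  zero DNA; an intercept fit is available behind a flag); per-chromatid
  ratio is half the cohesed-chromosome slope;
- volumetric density: total Mb / total µm³;
- nucleosome metrics, assuming a 195-bp repeat (146 bp core + 49 bp
  linker):
  `nucleosomes/µm³ = density · 10⁶ · (1 − NFR) / 195`,
  `volume/nucleosome = 10⁹ / (nucleosomes/µm³)` nm³ (cube side is its
  cube root), and
  `µM = (nucleosomes/µm³) · 10¹⁵ / (6.02·10²³) · 10⁶`.
  The nucleosome-free fraction defaults to 0: ATAC-seq puts it near
  0.3%, which is below every other error in the chain; the parameter
  exists for sensitivity analysis.  89.2 Mb/µm³ gives 4.57 × 10⁵
  nucleosomes/µm³, 2,186 nm³ (a 13-nm cube) and 760 µM.
- chromatin volume concentration: occupied per-nucleosome volume over
  available per-nucleosome volume, in percent.  The occupied volume is
  an *input* (≈700 nm³ gives the ~32% figure); the geometric occupancy
  model behind it is not reimplemented here.
- helper identities: isotropic linear shrinkage s reduces volume by
  `1 − (1 − s)³` (7% linear ≈ 20% volume), and percent reductions are
  `100·(before − after)/before`.

The bundled karyotype is a female diploid human complement with a third
copy of chromosome 12 (47 chromosomes), using reference per-chromatid
contents at telomere-to-telomere assembly scale; contents × copies ×
a replication factor of 2 gives the mitotic genome (~12.48 Gb), which
over a 140 µm³ metaphase complement reproduces the ~89 Mb/µm³ density.
The nucleosome-free fraction computation merges overlapping or touching
half-open intervals per chromosome and divides merged coverage by the
genome length.

## Spindle geometry and statistics

Distances follow the standard definitions: P2P between the two
centrosomes; sK2K between sister kinetochores paired by chromosome;
sT2T between sister telomeres of the *same arm* (p with p, q with q —
sister chromatids are copies, so cross-arm pairing is meaningless);
K2P from a kinetochore to its *nearer* pole, because sister
kinetochores face opposite poles.  All are invariant under rigid
motions of the landmark set.

Fixed cells are ordered along mitosis by centrosome separation (ATU,
arbitrary time units — ordinal, not clock time).  Nuclear-envelope
deposition defines telophase; a mean sister-kinetochore separation
above 2 µm defines anaphase; remaining cells are split at P2P 10 and
13 µm into early/late prometaphase and metaphase-like.  The "chromosome
scattering" metric is the standard deviation of per-chromosome landmark
centroids projected on the pole axis — this package's own
formalization, labelled as such in output.

Group comparisons run Shapiro–Wilk per group and a two-tailed pooled-
variance Student's t (Welch behind a flag, since the named test is the
pooled one); regressions are OLS with intercept plus the ANOVA F test
for the slope, with a perfect fit reporting the smallest positive float
rather than p = 0.

## The phantom generator

A phantom is a set of tubular chromatids: C¹ spline centrelines through
control points, radius profile
`r(s) = R·(1 − (1 − c)·exp(−(s − s₀)²/2σ²))` with σ = 5% of arc length
(a Gaussian constriction at the centromere; the real constriction's
profile is not published), hemispherical caps, voxel-centre membership
(no partial volumes — matching the hard-threshold measurement model),
8-bit grayscale with cytoplasm mean 90, chromosome mean 170, additive
Gaussian noise of sd 12 clipped to range, and a fixed seed.  The
intensity/noise values emulate the visible chromosome/cytoplasm
contrast of stained block-face images without claiming their actual
values, which are not published; they are configurable, not calibrated.
Ground truth (volume, lateral area, length, width per chromatid) comes
from quadrature of the radius profile plus cap terms, and the default
chromatid diameter is 0.68 µm, the mean single-chromatid width.

`complement_spec` lays out a complement of straight (optionally bowed)
tubes with lengths `2·Mb / (Mb/µm)` — replicated cohesed content over
the linear packing ratio.  For full-scale worked examples the cohesed
chromosomes are modelled as single tubes with *effective* radii of
498 nm (large, Chr1–5) and 320 nm (small, Chr19–22), solved analytically
so that a 66 Mb/µm complement carries exactly 89.2 Mb/µm³; these are
effective cylindrical radii, smaller than half the 1.23 µm outer cohesed
width because two overlapping chromatid cylinders do not fill a disk of
their outer diameter.

What the phantoms do **not** emulate: electron-optics blur, charging,
curtaining, section loss or misalignment, the chromosome periphery
compartment, intra-chromosome density variation, or realistic surface
granularity (tubes are smooth; the binning/surface-area contrast test
uses elevated voxel noise, sd 25, as a stand-in for fine-scale surface
texture).  Passing phantom tests therefore demonstrates that the
*measurement chain* is correct and stable at the stated resolutions; it
does not certify segmentation accuracy on real stained chromatin.

## Problem sizes and numerical choices

Test and acceptance runs are sized for a single CPU: single-tube grids
are a few hundred kvoxels; the nine-chromosome full-scale complement is
~2 Mvoxels; the 47-chromatid karyotype-count scenario runs at reduced
tube scale (250-nm radius, 85 Mb/µm lengths, ~4 Mvoxels).  Determinism:
one `numpy` generator seeded from the spec; identical specs give
bit-identical stacks.  Degenerate inputs: constant volumes refuse
auto-thresholding; empty masks return empty label maps with a warning;
border-touching labels are zero-padded before surface extraction;
overlapping phantom chromatids raise rather than produce ambiguous
ground truth.  Tolerances used in validation — volume 2%, length 5%,
width one voxel diagonal — reflect the voxel-model quantization floor at
the 25 × 25 × 60 nm grid, not fitted slack.

## Known limitations

- Lengths of stubby objects (a few radii long) carry ~2% bias from cap
  trimming; chromosomes shorter than ~4 radii cannot be modelled at all
  (the tube invariant rejects them), which is why scaled complements
  keep small chromosomes thinner.
- Very deep constrictions (radius multiplier ≤ ~0.6) can be split by the
  watershed as if they were sister seams; at 60-nm sections this is an
  information limit, not a parameter choice.
- The threshold is global per stack; staining gradients would need
  local thresholding, which is out of scope.
- Real image parity is not claimable from phantoms alone: the per-cell
  thresholds behind the published masks are not recorded, so only
  phantom-truth parity is tested.
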