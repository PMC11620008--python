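# Methods

This note records the measurement definitions, coordinate conventions,
numerical choices and limitations of `onhmetry`. It is the package's own
account of what is computed; every number quoted here is produced by the
test suite or `scripts/acceptance.py`.

## Input model

The universal input is a 3D integer label volume indexed
`(bscan, ascan, axial)` with physical voxel spacings in micrometres; the
axial index increases with depth. The label scheme names background,
RNFL, vessels, the RPE–BM complex, and prelaminar tissue, with optional
lamina cribrosa and alpha/beta/gamma peripapillary atrophy (PPA) codes.
The RPE and Bruch's membrane are treated as one complex because the
membrane alone (≈2 µm) is thinner than the axial pixel of commercial
spectral-domain devices (≈2.6–3.9 µm). Radial+circular acquisitions are
represented as sets of 2D label slices with angle/diameter metadata
instead of a cube.

En-face geometry is done in micrometres (`x = ascan · Δx`,
`y = bscan · Δy`, origin at voxel (0,0)) because spacings are
anisotropic; a 6 × 6 mm, 200 × 200 A-scan cube has 30 µm en-face pixels
but ~3 µm axial pixels.

### TSNIT convention and tilt

Angular profiles use 0° = temporal, 90° = superior, 180° = nasal,
270° = inferior for both eyes (counterclockwise in the en-face view for
OD, clockwise for OS), which makes fellow-eye profiles directly
comparable. When a fovea position is available, the temporal axis is
rotated onto the disc-centre→fovea direction (disc-tilt correction);
otherwise the laterality-implied horizontal is used and a warning is
recorded in provenance. TSNIT sector bins are centred on the anatomical
axes: T [−45°, 45°), TS [45°, 85°), NS [85°, 125°), N [125°, 235°),
NI [235°, 275°), TI [275°, 315°). Clock-hour 12 is centred at superior;
numbering proceeds nasally and each hour spans 30°.

## Biomarkers

**BMO ellipse.** Membrane presence is projected en face over
{RPE–BM, alpha-PPA, beta-PPA}; gamma-PPA (membrane absent) counts as
opening. Spurious membrane specks smaller than 64 en-face pixels are
removed, then a morphological closing with a disk of radius 3 pixels
(≈90 µm on the default grid — below clinically relevant BMO-size
changes) repairs small gaps. Both steps correct minor segmentation
errors; without the speck removal, 5% salt noise inside the opening
gets merged into the margin by the closing and bites several percent
out of the hole. The boundary of the largest interior hole (multiple
holes keep the largest, with a warning) is fitted with a direct
least-squares conic constrained to an ellipse; inputs are centred and
scaled first, which keeps the fit numerically exact on clean points and
exactly scale-equivariant. At least 6 points are required, so the
conic can never silently degenerate.

**cpRNFL.** Vessel voxels are re-assigned per voxel to RNFL or
background by comparing anisotropic Euclidean distances (two distance
transforms per B-scan plane); exact ties go to RNFL so continuous
tissue is not perforated. Thickness is then RNFL-voxel count × axial
spacing per A-scan — counting, rather than surface fitting, is the
natural measure on a label mask and tolerates non-contiguous labels.
Profiles are sampled bilinearly at 720 points (0.5°, well below both
the 9° smoothing window and vessel width) on circles of 3.4/3.5 mm
around the BMO centre; bilinear sampling is exact on affine maps.
Sector and clock-hour means are unweighted means over the samples in
each angular bin (identical to arc-length weighting on a circle).
For radial+circular acquisitions the circular B-scans are used
directly, with columns mapped to TSNIT angles via start-angle and
direction metadata.

**MRW.** For cube scans, 24 radial slices at 7.5° steps are synthesized
through the BMO centre (nearest-neighbour in the en-face plane — labels
are categorical; lateral step = min en-face spacing). Per half-meridian,
the membrane edge is the innermost column bearing the complex, at the
complex's mean axial position in that column (the measurement is from
the complex, not a sub-layer), and the width is the minimum Euclidean
distance in the radial plane to the inner limiting membrane — the
shallowest voxel labelled RNFL, vessel or prelaminar tissue per column.
48 half-meridian widths are averaged globally and per sector;
meridians with an obscured edge are excluded and counted, and more
than 50% missing raises a quality error rather than a misleading mean.
The 2D-in-plane (not 3D point-cloud) minimum matches how per-meridian
rim widths are reported clinically.

**Cup volume.** Per B-scan crossing the opening, a chord joins that
B-scan's own BM endpoints (innermost columns flanking the widest
membrane gap); every column strictly between them contributes
`max(0, tissue_top − chord) × Δx`. Negative contributions clamp to zero
— the cup is a volume, not a signed integral. Areas are summed across
B-scans weighted by Δy. B-scans without determinable endpoints
contribute zero and are flagged. This per-B-scan chord definition
deliberately differs from some manufacturers' cup constructions.

## Agreement statistics

Dice is `2|A∩B|/(|A|+|B|)` with the empty-vs-empty case defined as 1
(perfect agreement on absence). ICC(A,1) is the two-way mixed-model,
absolute-agreement, single-measure intraclass correlation,
`(MSR − MSE)/(MSR + (k−1)MSE + (k/n)(MSC − MSE))`, with the F-based
absolute-agreement 95% interval using Satterthwaite degrees of freedom;
negative lower bounds are legitimate and never clipped. Reliability
categories: poor < 0.5 ≤ moderate < 0.75 ≤ good ≤ 0.90 < excellent (the
0.90 boundary is assigned to "good" since only values *greater than*
0.90 are excellent). Absolute-difference summaries use the sample SD
(n−1). Profile smoothing is a circular box average whose window covers
all samples within 4.5° of the centre (9 taps on a 1° grid); it
preserves the circular mean exactly and commutes with rotation.

## The phantom

The phantom is defined continuously in micrometres and only then
rasterised (a voxel takes the label of the region containing its
centre), so ground truth is raster-independent and algorithm error is
separable from discretisation error. Geometry: a flat peripheral ILM
with an RNFL slab of thickness `t(θ) = t₀ + A·sin 2θ` beneath it; the
RPE–BM complex as a slab outside a rotated BMO ellipse; inside the
opening a prelaminar surface
`z_top(ρ) = z_chord + h − (h + m₀)ρ²` forming a rim rising `m₀` above
the BM-endpoint chord at the margin and a cup of depth `h` at the
centre; straight vessel tubes strictly inside the RNFL slab (they must
resolve back to RNFL, exercising the nearest-neighbour rule without
changing the thickness truth). Closed forms: BMO area `πab`; cpRNFL
sector means by exact integration of `t(θ)`; cup volume
`πab·h²/(2(h+m₀))` (for `m₀ = 0`, the elliptic-paraboloid value
`πabh/2`); MRW per meridian as the certified minimum distance from the
edge point to the piecewise rim/ILM curve (dense sampling plus bounded
refinement).

Defaults emulate a 6 × 6 mm, 200 × 200 A-scan cube with 640 axial
pixels of 3.125 µm (within the 2.6–3.9 µm range of commercial devices):
t₀ = 100 µm, A = 30 µm, semi-axes 900 × 700 µm at 25°, rim height
250 µm, cup depth 500 µm — all in the physiologic range for a healthy
adult disc. The peripheral ILM depth (501.6 µm) is deliberately not
axially grid-aligned so that voxel-quantisation errors dither rather
than accumulate. `derive_radial_set` evaluates the same continuous eye
on radial/circular grids, emulating a radial-protocol device imaging
the same subject; the radial lateral step matches the cube route so the
two protocols are directly comparable.

Noise models: voxelwise label flips (uniformly random *different*
label), en-face membrane flips (a fraction of columns has its BM
toggled — salt-and-pepper in the membrane projection), and boundary
jitter as a spatially *correlated* Gaussian displacement field
(σ given in pixels, correlation length 3 px) applied to the membrane
margin — grader-style boundary placement errors are smooth along the
margin, not per-pixel speckle. All noise is seeded and reproducible.

What the phantom does not emulate: OCT speckle and intensity, real
retinal curvature, vessel shadowing, motion artifacts, and pathology
beyond geometric cup/rim variation. Passing the recovery tests
therefore demonstrates correctness of the measurement geometry on
clean and moderately noisy label masks, not robustness to real
segmentation-model failure modes.

## Problem sizes and numerical choices

The recovery experiment runs on the full 200 × 200 × 640 device grid
(~25.6 M voxels, a few seconds end to end); tolerances are the
discretisation budgets — BMO area 2%, cpRNFL means 2 µm, MRW one
lateral + one axial step (33 µm at device resolution; measured error
≈8 µm), cup volume 3%. Grid-convergence checks use 50/100/200 pixels
per axis (ending at the device grid): in this range discretisation
error dominates and every biomarker's error falls strictly with each
2× refinement; beyond the device grid the cpRNFL and BMO errors reach
a sub-micrometre quantisation-alignment floor where monotonicity is no
longer meaningful. Cross-protocol experiments use eight phantom eyes
with parameters varied across their physiologic ranges; the
cube-vs-radial global cpRNFL difference is <0.1 µm and the MRW
difference ≈4.5 µm (edge localisation on a 30 µm lateral step is the
limiting factor, as obscured or quantised BMO edges are clinically the
dominant MRW error source too).

Other numerical choices: bilinear interpolation for scalar en-face
maps, nearest neighbour for labels; morphological closing uses a disk;
degenerate inputs raise typed errors (no BMO hole, <6 boundary points,
zero-variance ICC tables, >50% missing meridians) rather than silently
returning values.

## Known limitations

* MRW accuracy is bounded by BM-edge localisation at the en-face pixel
  scale; no sub-voxel edge refinement is attempted.
* Sector means weight profile samples uniformly in angle; for circular
  scans with non-uniform A-scan spacing this differs slightly from
  arc-length weighting.
* The scheme-validation layer accepts any consistent integer coding but
  the extraction semantics assume the anatomical meaning of the five
  required labels.
* Radial-set inputs must be centred on the BMO (as the acquisition
  protocol intends); off-centre radial sets bias the derived ellipse.
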