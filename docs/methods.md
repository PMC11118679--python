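# Methods

This note documents the models, defaults and numerical choices behind
`octscreen`, and what the synthetic phantoms do and do not establish about
performance on acquired data.

## Phantom model

The phantom generator emulates the three data products of an automated OCT
screening instrument.

**Well images.** A well is a uniform background (gray level 0.25 of full
scale) that, with probability `occupancy`, carries one elliptical explant
(level 0.65) of semi-axes `tissue_radii_mm` (default 4 × 3 mm) in a
30 × 30 mm field, plus additive Gaussian noise (SD 0.02), quantized to
uint8. Ground truth stores the exact rasterized bounding box and the
centroid in mm.

**OCT volumes.** The default acquisition grid is 500 A-lines × 500 B-scans
over a 6 × 6 mm field with 2 repeated A-scans per position averaged at
generation time, i.e. the 500×2×500 scan pattern of the target instrument.
Axial sampling is a configurable default of 512 px at 2 μm/px (the
instrument's axial spacing and bit depth are not public; >1 mm of depth
comfortably contains a ≤250 μm explant). Within the elliptical footprint a
tissue slab of per-column thickness `t(x,y)` (profiles: `uniform`, `dome` —
quadratic in the normalized elliptical radius — or `bimodal` half/half)
rests 20 μm above a 10 μm bright membrane layer spanning the full field at
70 % of the axial range. Intensity model per voxel:

    tissue = 0.5 · (1 + drift(x, y)) · speckle,   background = 0.05,
    membrane = 0.9,

with `drift` a smooth field scaled to ±`reflectance_drift` (default 0.2),
`speckle` mean-one lognormal with σ = `speckle_sd` (default 0.3), a small
additive noise floor proportional to the speckle level, and a seeded
fraction `specular_column_rate` (default 0.02) of whole (B-scan, A-line)
columns saturated after repeat averaging. These three knobs reproduce the
three artifact classes the segmenter must survive — speckle, reflectance
inhomogeneity, and specular saturation over a bright membrane — without any
physical-optics simulation (no interferometry, dispersion or roll-off).
Thickness is quantized to `round(t/dz)` voxels; ground truth carries the
voxel mask (tissue only, never membrane), the discrete thickness map, and
closed-form area/volume/central-thickness where they exist (uniform and
dome profiles with the footprint inside the field; the dome's thickness is
uniformly distributed over [edge, peak] w.r.t. footprint area, giving
median (edge+peak)/2 and central mean (edge+3·peak)/4).

**Depth stacks.** One rendered B-scan is rescaled by a triangular
brightness profile peaking at the requested index, making the mean-frame
intensity strictly unimodal by construction — the sweep search is therefore
testable without modeling coherence-gate physics.

**Screen tables.** `make_screen_dataset` draws sample-level true readouts
from Normal(group mean, group SD) per timepoint and adds Normal(0,
repeat SD) per repeated acquisition. Defaults encode the validation
conditions of the thinning assay: baseline thickness 191.8 ± 11.5 μm,
negative day-10 change −30.3 % (→ 133.7 μm), positive +30 %, repetition SD
0.4 μm (0.039 mm² area, 0.005 mm³ volume), five repeats, area 17.0 ±
0.755 mm² with −20 % negative / 0 % positive change; volume is the product
of the thickness and area draws.

All generators route randomness through one `numpy.random.default_rng(seed)`
per call; identical (spec, seed) is bit-identical.

## Detection

The classical detector smooths with a Gaussian of 0.25 mm, estimates the
background as the median of the smoothed image, and keeps pixels whose
absolute deviation exceeds 6 robust (MAD-based) noise SDs. Components below
`min_area_mm2` (default 1 mm²) are dropped; the largest remaining component
(ties: earlier first pixel in row-major order) gives the tight half-open
box and the deviation-weighted centroid. The absolute-deviation rule makes
the detector agnostic to whether tissue is darker or brighter than the
well. The centroid is intensity-weighted rather than box-center — on
near-symmetric explants the two coincide, and weighting is robust to a
ragged rasterized boundary.

mAP protocol: single class, greedy confidence-ordered matching with each
ground-truth box matched at most once, all-point-interpolated
precision–recall area, averaged over IoU thresholds 0.50 to 0.95 in steps
of 0.05. Boxes are half-open, 0-based, x = column; mm coordinates originate
at the image's top-left corner with pixel centers at (i + 0.5) · scale.

No learned detector or segmenter ships in this package: the deterministic
classical paths carry all guarantees, which keeps every result reproducible
from a seed with no training images or weights involved.

## Depth sweep

`find_optimal_depth` is an argmax of mean frame intensity, ties to the
lowest index, with an optional closed restriction window on stage
positions; the once-per-plate sweep cache lives in the pipeline. No
sub-position interpolation is attempted — the stage lands exactly where
commanded in simulation, and real stages are swept at step sizes below the
depth of field.

## Segmentation

`segment_classical` runs: (1) saturated-column flagging — a column is
flagged when ≥ 60 % of its pixels lie within 5 % of the frame's intensity
range from its maximum (range-relative, hence invariant to affine intensity
rescaling); frames with more than `max_specular_column_fraction` (0.5)
flagged are rejected as unsegmentable; (2) anisotropic Gaussian smoothing,
σ = (0.8 axial, 2.5 lateral) px — gentle axially so the ~20 μm gap above
the membrane is never bridged, strong laterally where tissue is
homogeneous; smoothing is skipped when a median-filter residual estimates
zero noise, so exact two-level frames segment exactly; (3) Otsu threshold
estimated on unflagged pixels; (4) in-painting of flagged columns by
per-row linear interpolation between their unflagged neighbours — done
*before* component analysis so a saturated column cannot split the tissue
band (in-painting after component selection, the naive order, loses every
fragment but the largest); (5) membrane suppression: any component whose
per-column axial extent never exceeds `membrane_max_thickness_um` (40 μm)
is removed — an extent rule rather than a position prior, so it tolerates
tissue sag; (6) the largest remaining component is kept and holes filled.

Metric conventions: with both masks empty, recall = precision = Dice = 1;
with exactly one empty, all are 0.

On reduced-resolution noisy phantoms the smoothing dilates the tissue
boundary by roughly one voxel per surface, a systematic +2–4 % on thickness
and area. Both control groups are biased identically, so assay statistics
(Z′, SSMD, p-values) are essentially unaffected; absolute readouts from
noisy data carry this bias.

## Morphometry

Thickness is voxel count × dz rather than top-to-bottom span: it is what a
binary mask directly measures, it is additive, and it is robust to interior
holes; the span variant is available via `method="span"`. Area counts
nonzero columns × lateral pixel area; volume integrates the thickness map.
The central-thickness median is taken over tissue columns only (a
whole-field median would be 0 for any explant smaller than half the field)
and the comparison is inclusive (≥ median) so uniform maps are
well-defined; a strict variant is behind a flag.

## Assay statistics

Z′ uses |μ_p − μ_n| in the denominator so group labeling cannot flip the
sign; SSMD keeps its sign by construction. Sample SDs use n−1 throughout.
Repeatability pools within-(sample, timepoint) repetition SDs by their
degrees of freedom; reproducibility first averages repetitions per sample
and takes the SD across per-sample means within one condition — the
variance-component alternative (subtracting the repetition term) differs
negligibly whenever repeat SD ≪ between-sample SD, which holds by two
orders of magnitude at the default noise levels. The group comparison is a
two-sided Welch t-test; no multiple-testing correction is applied (one
comparison per readout).

## Pipeline

Wells are visited row-major from A1; empty wells are logged as void and
skipped; five volumes per occupied well by default. The simulated stage is
idealized (no backlash or settling) but keeps a complete motion log so a
hardware driver can implement the same interface. Screen outputs
(readouts.csv with fixed float formatting, qc.json, screen_log.jsonl) rerun
byte-identically from the master seed.

## Problem sizes in the test suite

The suite exercises segmentation and the end-to-end screen on reduced
acquisition grids (e.g. 160 A-lines × 24 B-scans × 256 axial px for
segmentation batches; 96 × 32 × 128 px at 4 μm for the six-well screen)
with artifact levels at their full defaults: the segmenter's behaviour is
governed by artifact statistics and layer geometry in pixels, not by the
lateral extent of the grid, so smaller grids probe the same failure modes.
Morphometry oracles run at the full 500 × 500 lateral grid, where
rasterization error on a 2 mm-radius footprint is well under 1 %.

## Limitations

Phantoms are geometric/statistical, not physical: no depth-dependent
signal roll-off, shadowing under opaque structures, refraction, or motion;
specular artifacts are idealized as whole saturated columns; the membrane
is flat and the tissue slab's curvature comes only from its thickness
profile. Passing phantom suites demonstrates correctness of the algorithms
under the modeled artifact classes, not performance on any particular
instrument's images. Published performance figures obtained on real
acquisitions (detector mAP, learned-segmenter Dice) are instrument- and
dataset-specific and are deliberately not targets of this package.
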