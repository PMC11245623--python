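# Methods

## The scientific procedure

`carposort` reconstructs a two-stage methodology for deciding which charred
archaeological grape pips are worth classifying to variety, and for
classifying them:

1. calibrate how charring deforms pip shape (the length/width ratio falls
   with temperature), fit a quadratic ratio-vs-temperature curve, and invert
   it to estimate the charring temperature of a pip of unknown history;
   reject pips estimated above a temperature where classification is known
   to fail;
2. classify the accepted pips by registering their 3D point clouds against a
   reference library with ICP, using the pairwise registration errors as
   features for a linear discriminant analysis, evaluated by repeated
   train/test resampling.

The original raw scans are not deposited, so every quantitative claim the
package tests is made on synthetic pips generated from a model calibrated to
the published per-condition means of the two reference cultivars
(`src/carposort/data/charring_reference_means.csv`: mean ± SD of length,
width, DVI and length/width ratio for fresh material and the
{200, 250, 300, 350} °C × {2, 8} h charring grid).

## Synthetic pip model

A pip is a tapered ellipsoid with a superelliptic transverse cross-section
(exponent 2.5, slightly fuller than elliptic), narrowed toward the beak
(stalk) end by a quadratic taper of strength `beak_fraction`, with the
ventral half inflated by `asymmetry`, and two longitudinal grooves — the
ventral infolds — carved into the ventral face as Gaussian profiles
(σ = 0.15 mm) at ±`infold_separation`/2 about the midline. Four exact
landmark points (both poles, both widest equator points) are appended so the
nominal length and width are realized exactly; the remaining points sample
the surface area-uniformly in the polar angle. Coordinates are mm; x is
length (beak at −x), y breadth, z dorsoventral with ventral at +z.

Variety geometry: the two calibration cultivars use the published fresh
means (Cabernet Sauvignon 5.81 × 3.81 mm, DVI 0.96 mm; Tzuriman S.
5.83 × 4.27 mm, DVI 1.14 mm). Heights, beak strengths and groove depths are
not published; they were chosen once to give the five-variety reference
library distinct multi-channel geometry, emulating the high matched-
condition classification accuracy reported for real cultivars. Three
accession-style varieties (9043, 98, 138) have plausible invented geometry.

Per-seed variability is multiplicative with two channels: a common size
factor applied to all dimensions and a ratio factor moving length against
width (and height/DVI with width). Their CVs are implied by the published
fresh SDs (size CV ≈ 0.022, ratio CV ≈ 0.053 for Cabernet): the ratio CV is
the printed fresh L/W CV, and the size CV is what remains of the length CV
after the ratio channel's share. This reproduces the published fresh scatter
of lengths and of per-seed ratios; it does not model independent height or
DVI variation.

## Charring deformation model

Charring is anisotropic affine shrinkage: x shrinks by
`mean_length(variety, T, t) / fresh_length`, y and z by the width analogue —
both read from the reference table, linearly interpolated in temperature
(and duration) between grid values and clamped outside. Per-seed charring
noise adds the *incremental* size/ratio CVs implied by each condition's SDs
beyond the fresh scatter, so a generated batch matches the published
per-condition spread. Cracks: 0 below 300 °C, then 2–4 transverse bands
(half-width 0.05 mm) lose points with probability 3·intensity, where the
intensity ramps linearly to 0.3 at 350 °C, plus coordinate jitter
(SD = 0.05 mm · intensity) — mirroring the reported onset of "noticeable"
cracking at 300 °C and heavy cracking at 350 °C. The published DVI column is
non-monotonic in temperature and is not modeled beyond the width-channel
scaling.

## Scanning and preprocessing

`simulate_scan` rests the pip on a virtual stage (lowest point
`stage_offset` = 0.05 mm above the background plane) and records, per pixel,
the maximum height among the points in its footprint — a top-view
stereoscopic height map; pixels with no points are exactly 0 (background).
`scan_to_cloud` inverts this with the scanner intrinsics: one point per
foreground pixel at ((col − cx)·sx, (row − cy)·sy, height). Pixel indices
are 0-based with pixel centers at integer coordinates. Only the upper
surface survives scanning; the classification experiments therefore run on
these ventral-face shells, as a real top-view scanner would produce.

`canonicalize_pose` centers the cloud and aligns the principal scatter axes
to (x, y, z) in decreasing-variance order. Sign conventions: the x-end
quartile with the smaller mean transverse cross-section (the beak) points to
−x; the face with detectable infold grooves points to +z (falling back to
the larger-z-extent side when no grooves are found either way, e.g. heavily
cracked pips); y completes a right-handed frame. Rank-deficient scatter
(collinear clouds) raises a degenerate-input error. `normalize_length`
rescales uniformly to a common length (default 1.0; the equal-length target
is not published), preserving all shape ratios exactly.

## Morphometry

Length is the x-extent. Breadth is the maximal y-extent over transverse
slabs (slab thickness 2 % of length, ≈ 0.1 mm on a real pip); the slab
position of maximal breadth fixes the DVI transect. The ventral profile
z(y) is the per-bin maximum over points with z > 0 in a band of half-width
7 % of length around the transect, linearly interpolated across empty bins
and smoothed with a 3-sample moving average; groove minima are interior
local minima (prominence ≥ 0.4 % of length) refined by parabolic
interpolation, one required on each side of the midline. DVI is the
distance between them; fewer than two detectable minima yields a *missing*
value (reported as such), not an error — grooveless or crack-shattered
surfaces legitimately have no DVI. All internal tolerances are
length-relative, so measurements are exactly scale-equivariant and the
ratios scale-invariant. The batch summarizer reports both the mean of
per-seed ratios (the statistic printed in the reference table) and the
ratio of mean length to mean width, which differ on strongly deformed
material.

## Registration and classification

Point-to-point ICP: nearest-neighbor correspondences via a k-d tree,
least-squares rigid update via SVD (Kabsch) with reflection correction,
defaults 50 iterations and relative MSE tolerance 1e-6. Clouds arrive
canonicalized and length-normalized, so ICP starts at identity and needs no
restarts; no scale is estimated and no correspondence trimming is applied by
default (an optional trim fraction exists for crack-damaged clouds). The
recorded MSE sequence is non-increasing — the classic guarantee — and is
asserted on every run in the tests. The similarity matrix entry [i, j] is
ICP(i → j).mse with a zero diagonal; it is directional and not symmetrized.

Features are z-scored per train column (zero-variance columns map to zero);
test matrices reuse the train parameters. The LDA solves the generalized
eigenproblem S_b v = λ (S_w + γ·mean(diag S_w)·I) v and keeps the top C−1
directions; prediction is the nearest class centroid in discriminant space,
ties broken by label order. γ defaults to 1e-3 because the feature dimension
equals the training-set size, making S_w singular; accuracy is insensitive
to γ over 1e-4…1 on the synthetic benchmark. Tournament sessions draw a
stratified 80 % subsample of the training pool, classify the full test pool,
and accumulate accuracy and confusion counts; the all-pairs ICP table is
computed once and indexed per session, which is asserted equivalent to
recomputation.

## Calibration curve and sorting

The curve r = a·x² + b, x = (T − 200)/150, is fitted by OLS to per-condition
mean ratios (the 16 packaged 2 h/8 h condition means by default; duration
enters only through which observations are supplied). Fresh rows are
excluded. This x-scaling reproduces the published coefficients
(a = −0.283, b = 1.446 vs printed −0.28/1.44), which is why it was chosen —
the original axis units are not stated. Inversion: x̂ = √((b − r)/−a) for
r ≤ b, with extrapolation past 350 °C permitted; r > b clamps to x̂ = 0
(200 °C) and is *accepted* — such seeds indicate milder-than-calibration
charring. A seed is accepted when its estimated temperature is ≤ the
threshold (default 275 °C, the upper edge of the reliable-classification
range; the boundary counts as accepted). Joint temperature-and-duration
estimation is out of scope: the projection yields a single x̂.

## Group statistics

The two-way ANOVA is the balanced fixed-effects Type-I decomposition
(condition × duration); unbalanced designs are rejected with a clear error,
and single-replicate designs fall back to the additive model. Tukey–Kramer
comparisons use the studentized range distribution directly
(`scipy.stats.studentized_range`, no printed tables) with the unequal-n
correction. The compact letter display uses insert-and-absorb, which makes
letter sharing exactly equivalent to pairwise non-significance; this
equivalence is tested exhaustively on random patterns. With all values
identical, F is reported as 0 with p = 1.

## Problem sizes and numerical choices

The shipped experiment layout uses 5 varieties × 10 seeds, 300-point
clouds, 25 tournament sessions and a 100-seed unknown-provenance set
(54 mild : 46 drastic) — a scaled-down version of the published layout
(5 × 20, 100 sessions) that preserves every qualitative property; one full
run takes ~20 s on one core. Seeds for every stage derive from one root
seed via `numpy.random.SeedSequence` spawn keys, so reports are
byte-identical across runs and changing the session count does not perturb
seed generation. Degenerate inputs (empty scans, < 3 points, collinear
geometry, single-class training, zero-length clouds) raise typed errors
rather than producing numbers.

## What the synthetic benchmark does and does not show

Passing tests demonstrate that the pipeline is internally correct and that
its qualitative behavior matches the published findings under a generator
faithful to the published per-condition moments: classification accuracy is
high at the matched mild condition and degrades with test-charring severity,
and ratio-based triage recovers a mild/drastic split close to the generating
proportions. They do not certify the published accuracy percentages (real
between-variety shape structure is richer than the generator's), real
scanner noise, post-depositional degradation of archaeological material, or
DVI dynamics under charring. The acceptance computation
(`scripts/acceptance.py`) depends only on the packaged published means, not
on the generator.
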