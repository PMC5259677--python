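# Methods

## Problem setting

A β-barrel is a closed β-sheet: the first strand hydrogen-bonds to the last,
so the sheet wraps into a tube. In cryo-EM maps at medium resolution
(5–10 Å) the ~4.8 Å spacing between adjacent strands is below the resolving
power of the map, and the barrel appears as a featureless shell of density.
The number of strands and their stagger nevertheless determine barrel
geometry almost completely, and the strand tilt angle α against the barrel
axis is conserved across known structures (roughly 30°–60°). This package
exploits that prior: instead of trying to see strands in the density, it
lays geometrically consistent strand center-lines (β-traces) on a surface
model of the barrel and lets a small candidate sweep cover the unknown tilt
and phase.

## Barrel surface model

**Axis search.** Occupied voxels (above threshold; default 0.3 × map
maximum for simulated maps, absolute value required for experimental ones)
are translated so their density-weighted centroid is at the origin.
Candidate axis directions are drawn from a quasi-uniform hemisphere grid at
5° spacing; for each candidate the voxel centers are rotated so the
candidate points along +z and projected to the xy-plane, a general-conic
least-squares ellipse (Halir–Flusser's numerically stable variant of the
direct ellipse fit) is fit, and the candidate is scored by the sum of
squared radial residuals |r − r_ellipse(θ)|. The minimiser is refined on a
±5° tangent grid at 1° steps. Fits whose minor semi-axis collapses below
1 Å are treated as failures: they arise when a flat or elongated density
blob is viewed edge-on and would otherwise score spuriously well. For
speed the fit uses at most 4000 occupied voxels (deterministic stride
subsampling); the axis is insensitive to this because the score is a mean
property of the whole shell.

**Surface construction.** The aligned map is cut into z-slices one voxel
thick. Within each slice with at least 5 occupied voxels an ellipse is fit,
then refined: the slice is divided into 72 azimuthal bins (5°) and the
ellipse is re-fit to the density-maximum voxel of each bin, twice. This
refinement matters: the least-squares ellipse of a *thick* occupied annulus
(and small barrels at 10 Å are nearly filled tubes) sits at the annulus
area centroid, about half an ångström outside the barrel wall, whereas the
per-bin density peaks trace the wall itself. The final surface points are
then the occupied voxels closest to the refined ellipse, one per nonempty
azimuthal bin — so where the density deviates from an ideal elliptical
cylinder (morphed regions, ragged ends) the surface follows the density,
and where density is absent no surface point is invented. Fewer than three
usable slices is an error (the map is not a barrel-shaped volume).

**Continuous lookup.** Trace generation interrogates the discrete surface
through bilinear interpolation: radius (about the slice ellipse center) is
interpolated linearly in azimuth between selected surface points within a
slice and linearly in z between slices. Azimuthal gaps wider than three
bins fall back to the fitted-ellipse radius and are flagged; a trace with
more than half of its samples on fallback is marked low-confidence.

## Trace generation

The local direction of a β-trace keeps the tilt angle α with the axis:
stepping ds along the path advances dz = ds·cos α axially and ds·sin α
azimuthally, i.e. dθ/dz = tan α / r(z, θ) with r the local surface radius.
Each trace is anchored at mid-height and integrated down to z_min and up to
z_max in 1 Å steps, every sample snapped to the surface. Consecutive traces
advance by the horizontal spacing h = d / cos α (d = 4.8 Å) in arc length
along the mid-height cross-section of the refined mid-slice ellipse, and
generation stops before the cumulative advance comes within h/2 of closing
the loop — on an ideal barrel of perimeter P this yields round(P/h) traces,
which is how the strand count is effectively estimated from the barrel
diameter. Tilts are sampled at {35°, 40°, 45°, 50°, 55°} with three evenly
spaced translation offsets {0, h/3, 2h/3} per tilt: fifteen candidate sets,
generated fully deterministically, finally mapped back to the original map
frame. Even spacing of the offsets bounds the worst-case phase error by
h/6 ≈ 1 Å. A single tilt sign is used (right-tilted viewed from outside,
the prevailing handedness of transmembrane barrels); the CLI exposes a flag
to flip it.

## Evaluation protocol

The observed β-trace of a strand with Cα atoms c₁…c_n is the polyline
[c₁, m₁, …, m_{n−2}, c_n] with mᵢ the mean of three consecutive Cαs — a
smoothed center-line that suppresses the β-pleat zigzag about threefold.
Distances between curves use the symmetric two-way distance: both curves
are resampled at 1 Å arc-length steps, each sample of one curve is
projected onto the other *original* polyline (distance to the nearer end
when the foot falls outside — resampling only defines the summation points,
never the target curve, so corner-cutting cannot bias the metric), the two
directed means are averaged. Detected and observed sets are matched
one-to-one (T = min of the two counts) by exact optimal assignment on the
pairwise distance matrix; the overall distance D is the mean over matched
pairs, so surplus detected traces are not penalised in D — they surface in
the detected/observed strand-count comparison instead. Cα coverage counts a
residue as detected when its Cα lies strictly within 2.5 Å (about half the
interstrand spacing; configurable) of the *matched* detected trace;
unmatched strands contribute to the denominator only. The best of the
fifteen sets minimises D, with ties broken toward lower tilt, then lower
offset.

## Synthetic data

The generator places Cα atoms at a 3.3 Å rise (the canonical β-strand
translation per residue) along constant-tilt helical paths on an elliptical
cylinder, with strand k anchored at azimuthal arc position k·h at
mid-height. For a circular barrel the closure constraint fixes the radius,
a = n·d/(2π cos α); elliptical barrels keep the same perimeter at a chosen
axis ratio (perimeter via the complete elliptic integral). A user-fixed
radius violating closure by more than 1% is rejected. Strand direction
alternates (antiparallel), irrelevant to 10 Å density but realistic for
ground truth. Ragged ends are modelled as one uniform random axial offset
per strand, seeded and reproducible.

Density is a sum of unit-weight isotropic Gaussians at the Cα positions,
real-space σ = resolution/(π√2) (Fourier amplitude 1/e at spatial frequency
1/resolution), deposited with trilinear weights and blurred in one
convolution, normalised to maximum 1. This emulates how simulation tools
render structures to maps, with two simplifications: Cα-only scatterers
(sidechains and backbone atoms would thicken the shell slightly, which at
10 Å is immaterial) and no B-factors or noise. Consequently the test
fixtures probe the *geometry* of the method — axis recovery, counting,
tilt/phase selection, the distance protocol — but not robustness to
experimental noise, uneven scale, or segmentation errors; real maps also
require a user-chosen absolute density threshold, which the synthetic
fixtures cannot exercise.

The fixture grid spans n ∈ {6, 8, 12, 16, 22} strands × tilt ∈
{35°, 45°, 55°} × {circular, elliptical b/a = 0.8}, 10 residues per strand,
rendered at 10 Å and 1 Å/voxel. Elliptical fixtures carry 1 Å ragged ends
so the non-ideal branch of the grid perturbs both shape and axial extent;
circular fixtures are noiseless. These 30 cases are what the test suite and
`scripts/acceptance.py` run end-to-end (about a minute on one CPU); the
same generator scales to longer strands or finer maps if needed.

## Numerical choices and degenerate inputs

- All geometry is in physical Å; voxel (i, j, k) is centered at
  origin + (i+½, j+½, k+½)·voxel_size. Centers match how density is
  sampled and avoid half-voxel bias in fitting.
- Ellipse fitting requires ≥ 5 non-collinear points; hyperbola-type conics,
  collinear clouds and collapsed axes raise errors rather than returning
  garbage. The fit residual is the RMS radial misfit along rays from the
  ellipse center.
- Slices with fewer than 5 voxels fall back to the global ellipse of the
  axis search; an all-zero or over-thresholded map is rejected up front.
- Barrels too small for a tilt (h ≥ mid-height perimeter) and maps whose
  axis search fails on more than half the candidates raise dedicated
  errors.
- Detection contains no randomness whatsoever; the only RNG in the package
  is the seeded ragged-end perturbation of the generator.

## Known limitations

Strand stagger (shear) and per-strand tilt variation are not modelled;
every trace spans the full axial extent of the surface, so per-strand
length errors concentrate at barrel ends. Error in trace placement
accumulates azimuthally on very large barrels because each trace is placed
relative to the previous one. Automatic segmentation of barrel regions from
whole maps is out of scope, as are mmCIF input and map symmetry handling.
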