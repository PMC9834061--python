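# Methods

This note documents the models, conventions, numerical choices and known
limitations of `helicta`.  Everything stated here is computed by the test
suite or the acceptance script; nothing is quoted from external results.

## Conventions

* Volumes are indexed `[z, y, x]`; physical coordinates are `(x, y, z)` in
  Ångström with the center of voxel `(0, 0, 0)` at the volume origin.
  Tables always store Ångström, never voxels, so binning changes cannot
  corrupt coordinates.
* Euler angles are intrinsic ZYZ in degrees, rotating the reference into
  the particle (`R = Rz(rot) · Ry(tilt) · Rz(psi)`).
* Rotation centers sit at voxel `n // 2` per axis (the usual even-box
  convention).  Interpolation is trilinear throughout, except where noted.
* Maps are MRC2014 mode-2 files (written via gemmi); metadata tables are
  STAR files with a documented column dictionary, TSV accepted.

## The synthetic-tomogram generator

The generator is the stand-in for the microscope and defines the study
conditions; its defaults are fixed once and not tuned per experiment.

**Filaments.**  Subunits are placed every `rise` of arc length along a
(possibly curved, parallel-transported) centerline, offset 15 Å radially,
with azimuth advancing by `twist` per subunit; `two_strands` adds a second
strand at +180° azimuth (2-start geometry — the simplest arrangement
consistent with a twisted double-stranded appearance).  Defaults are the
F-actin-like values rise = 27.9 Å, twist = −167.7°/subunit.  The default
subunit is a chiral two-lobe model (50 Å nominal diameter: a large axial
lobe and a smaller one displaced both axially and tangentially).  The
tangential offset is essential, not cosmetic: a 2-start lattice built from
azimuthally symmetric subunits is *exactly* symmetric under an in-plane
180° flip, which would make filament polarity undetectable in principle.
A polarity −1 filament is constructed to be exactly the in-plane 180° flip
of the +1 filament (verified by a correlation ≥ 0.98 test); getting this
right requires mirroring the subunit pose azimuth together with the local
frame, not merely pointing the subunit axis down.

**Particles.**  Ribosome-like particles are lumpy soft spheres (250 Å) with
internal asymmetric mass so orientations are well defined; the optional
expansion-segment mimic is a prominent surface Gaussian (70 Å FWHM,
amplitude 1.8× the body scale) at the +z pole, strong enough to survive
averaging and clear a 3σ difference threshold — deliberately "supersized".

**Missing wedge.**  A Fourier coefficient is sampled iff some tilt in the
acquisition range places it on a central section: for tilt axis y this is
`|k_z| ≤ tan(tilt_max)·|k_x|`.  For ±60° the lost fraction is exactly 1/3
by solid angle; the package reports this fraction over the Nyquist-resolved
disc, because the square corners of the discrete grid are artifacts of the
lattice, not of the acquisition.  ±90° reduces to the identity.

**Noise.**  Additive white Gaussian noise.  SNR is defined as signal
variance over noise variance *within the signal support mask* (voxels above
10% of the peak density) — conventions differ between packages and this one
is stated explicitly because the whole-box variance ratio would look much
smaller for the same noise level.

**CTF.**  Off by default.  A single analytic weak-phase 2D CTF
(`ctf_2d`/`apply_ctf`: defocus in Å, 300 kV, Cs 2.7 mm, 7% amplitude
contrast) can be multiplied onto synthetic projection images; per-tilt CTF
handling of real tilt series is out of scope.

**Not modelled:** electron-optical image formation beyond that optional
CTF (dose weighting, detector MTF), tomographic alignment errors, crowding
by other macromolecules, and structural heterogeneity beyond the discrete
species list.  Passing tests therefore demonstrate the
correctness and statistical behaviour of the algorithms under the stated
noise/wedge model, not performance on real tilt series.

## Filament segmentation

Centerlines are interpolated with arc-length-parametrized splines, cut
every 32.13 Å (the default intersegment distance), and each segment's
tangent comes from the spline derivative.  Subvolumes are extracted with
trilinear interpolation, oriented so the tangent maps onto +z by the
*minimal* rotation (in-plane azimuth set to 0 by convention — azimuth is a
search parameter downstream, so nothing is lost), and centered in x/y
against a featureless soft-edged cylinder (radius 40 Å, 2-voxel cosine
edge).  Because the cylinder is z-invariant the 3D centering collapses to a
2D correlation with parabolic sub-voxel peak refinement.

## 2D-projected helical reconstruction

**Projection.**  Oriented segments are viewed side-on and the central slab
(1/3 of the box) is summed through, producing images with the filament
horizontal.  Image azimuth (`rot`), in-plane angle (`psi`), and shifts
(axial limited to ±rise/2) are the alignment parameters.

**Filament-coherent alignment.**  A side view of a low-resolution helix is
nearly degenerate along a ridge of (azimuth, axial shift) combinations, and
once the reference is filtered to 60 Å a single image carries *no*
information about its axial lattice phase (1/27.9 Å⁻¹ lies beyond the
cutoff).  Independent per-segment alignment therefore scatters and the
reconstruction loses its subunit lattice.  The package instead exploits
that segments of one filament share three unknowns — lattice phase ψ,
azimuth offset δ, and polarity: with arc positions s_j known from
segmentation, the nearest lattice index is k_j = round((s_j − ψ)/rise) and
helical symmetry dictates `rot_j = δ + k_j·twist` and
`shift_j = −(s_j − ψ − k_j·rise)`.  Every (ψ, δ, polarity) hypothesis is
scored against projection-matching score tensors in two bands: a 60 Å
envelope band pins δ, and a wider 18 Å lattice band (which still contains
the rise spacing) pins ψ.  The winning hypothesis dictates each segment's
*continuous* pose — snapping to the search grids would imprint a
correlated staircase artifact on the reconstruction.  This is the
counterpart of helical priors in conventional helical-processing packages.
Polarity classes are defined absolutely (psi folded to [−90, 90)), so their
meaning cannot silently swap between iterations.  When acquisition
geometry is supplied, scores are computed over each image's sampled Fourier
region only (the 2D central-section footprint of the rotated 3D wedge).

**Reconstruction.**  All projection directions share the filament axis, so
weighted back-projection separates into independent 2D filtered
back-projections per z-slice (ramp filter — the sampling-density weighting
of single-axis geometry), implemented with `skimage.transform.iradon`.

**Symmetrization** averages the map over screw operations k·(rise, twist)
for every k that keeps the central 60% of the box inside the volume, with
per-voxel validity weights so border voxels are not diluted toward zero,
and cubic-spline interpolation because the operation may be applied
repeatedly.  Real-space symmetrization with resampling is idempotent only
to interpolation error: applying it twice changes the map by up to ~1%
(max, central region), not the ~0.1% an exact projector would give.

**Rise/twist refinement** maximizes the mean correlation between the map's
azimuthal-residual (ring average subtracted, half-voxel radial bins) and
each of its non-trivial symmetry mates, over a hierarchical grid: a full
coarse grid (0.5 Å / 0.5° over rise ±15%, twist ±10° around the prior —
also the grid the brute-force oracle test checks), then a 0.1-step local
grid, then parabolic sub-step interpolation.  Two technical points, both
load-bearing.  First, correlating against the *mean* of the mates instead
of averaging per-mate correlations is biased: disagreeing mates shrink the
mean's norm and inflate the normalized correlation at wrong parameters.
Second, z-invariant residuals — most prominently the angular-sampling
streaks of back-projection — are self-similar under a twist of 0 mod 180°
at any rise and attract the search toward that alias; the coarse stage
therefore also removes the per-column z-mean.  That removal clips part of
the genuine slow crossover signal (which lives near k_z = 0) and would bias
the final estimate by ~0.2–0.6°, so the fine stage scores the full
ring-subtracted residual inside a window too narrow for the streak alias to
reach.  A featureless map raises an "unresolved" error, detected by the
azimuthal residual falling below 2% of the masked density or by a flat
coarse surface.  The twist axis is treated as circular (search windows may
cross ±180°; results are wrapped).

**Iteration.**  Three rounds by default: align → reconstruct → refine →
symmetrize, the symmetrized map becoming the next reference (always
low-pass filtered to 60 Å for alignment).  The first reference is an
F-actin-like helical model rendered from the prior (27.5 Å, −166.7°) — a
featureless cylinder cannot seed the loop because it carries no azimuthal
information; the 60 Å filter keeps its fine detail from biasing the result.
The rise/twist search prior stays anchored on the initial values rather
than re-centering on each iteration's estimate: re-centering lets small
systematic errors compound through the coherent azimuth assignment (drift
of several degrees over three iterations in development experiments), while
the anchored ±15%/±10° window comfortably contains both prior and truth.
The last round adds 2D classification with frozen alignments (k = 8, 10
iterations — unspecified in the original workflow, recorded here as the
package's choice) and keeps the highest-contrast classes covering 70% of
the images, an automated stand-in for visual class selection.

**Polarity** is determined per segment and voted per filament.  The 2D
in-plane flip test is weakly discriminative (projection discards most of
the asymmetry), so the dedicated scorer maps segments back to their 3D
subvolumes and correlates against the polar reference and its flip —
mirroring the workflow step that validated polarity on subvolumes.  Votes
are diagnostic only by default; `apply=True` flips minority segments.

**FSC** uses integer-radius shells and half-sets split by filament — never
by segment, whose overlap would inflate the correlation — with threshold
0.143 (configurable; no criterion is canonical at these resolutions).

## Sub-tomogram averaging

3D alignment scores wedge-masked normalized cross-correlations on a
hierarchical ZYZ grid (30° coarse, pole-thinned, halved per refinement
level) with FFT shift search.  Averaging rotates per-particle wedge masks
along with the particles and divides the summed Fourier transform by the
accumulated coverage, floored at 0.5 (half a particle) so never-sampled
voxels do not explode.  (One subtlety: mapping between centered and
unshifted Fourier frames must use `ifftshift`, which differs from
`fftshift` for odd boxes.)  Classification is EM-style alternation of
assignment and averaging at 60 Å; with geometry supplied the metric is
computed per particle over its own sampled Fourier region with
coverage-weighted class means — without this the dominant between-particle
variance is the wedge orientation itself and classes split on it instead of
structure (purity drops from ≥0.9 to ~0.6 in the two-species benchmark).
Difference densities are detected on z-scored maps (inside the dilated
reference support) thresholded at 3σ, 26-connected components of at least
five voxel volumes, reported with centroid/volume/peak; two blobs closer
than one voxel merge by the connectivity definition.

## Problem sizes

Test and acceptance experiments are sized for a single CPU: the filament
recovery experiment uses 20 filaments (~180 segments, 64³ boxes, three
iterations); polarity voting uses 30 filaments at SNR 0.2; classification
uses 40 particles at SNR 0.3; FSC behaviour is checked on 48³/64³ phantoms
with up to 800 synthetic projections.  These sizes are the package's
standard desk-scale study conditions; the algorithms contain nothing that
ties them to these sizes.

## Known limitations

* The 2-start two-strand geometry makes azimuth recoverable only modulo
  180° (exact C2), and an ideal 2-start filament is also exactly symmetric
  under (rise, twist + 180°); the ±10° twist search window around the
  actin-like prior excludes that alias.
* Box truncation of the slow crossover pattern biases the refined twist by
  ~0.2° at 64³ (vanishes by 96³); the acceptance tolerances absorb this.
* Helical-parameter refinement assumes the filament axis is on z, which the
  pipeline guarantees by construction; maps from other sources must be
  axis-aligned first.
* No CTF, no dose weighting, no tomogram alignment errors (see generator
  limitations above); polarity discrimination rests on the generator's
  chiral subunit and would be weaker for more symmetric real subunits — as
  it was in the in-situ study this workflow generalizes, where votes were
  likewise treated as diagnostic only.
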