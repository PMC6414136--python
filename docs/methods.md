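# Methods

## Coordinate and grid conventions

All geometry lives in the DICOM LPS patient frame in millimetres; meshes and
STL files are exported in it without any flip, so downstream print software
sees the same frame the CT headers define. Voxel arrays are indexed
(slice, row, column); voxel indices address voxel centers, and every mask is
defined on the same lattice as the CT it came from — there are no half-voxel
shifts between a volume and its masks, which keeps distance-transform
geometry unambiguous. DICOM series are read-only input (slices sorted by
position along the slice normal, HU from each slice's rescale slope and
intercept, hard errors on mixed series UIDs, duplicate positions, or
non-uniform slice steps); a small self-describing NPZ container carries
volumes and masks between stages and in tests, avoiding any need to write
DICOM.

## Working resolution

All morphology runs at 1 mm isotropic by default. Head-and-neck CT
simulation protocols are anisotropic (typically 3 mm slices), and a shell
defined in millimetres needs near-isotropic voxels to be represented
faithfully; 1 mm keeps thickness quantization well below elastomer print
tolerance while a full head fits in a ~200×220×190 grid that processes in
seconds. Resampling uses linear interpolation for HU and nearest-neighbour
for masks, with edge-replication boundaries, and preserves the edge-to-edge
physical extent to within one voxel (the voxel-(0,0,0) center shifts by
(target − spacing)/2 per axis so grid edges stay fixed).

## Body segmentation

External contour = largest 6-connected component of {HU ≥ −400}, internal
cavities filled, then morphological closing with a 2 mm ball and a second
hole fill. −400 HU is standard external-contour practice: it falls inside
the steep air–tissue transition and is insensitive to realistic noise
levels. Guard rails: an empty threshold set raises "no body found", and a
largest component touching all six grid faces raises an error because the
threshold is then almost certainly wrong for the data.

## Uniform-thickness shell

The normative definition of the cap is

    shell = { voxels outside body : EDT(body)(x) ≤ t } ∩ extent

with EDT the exact Euclidean distance transform in millimetres
(`scipy.ndimage.distance_transform_edt` with the voxel spacing as sampling)
and the boundary case `distance == t` included, for determinism.
Equivalently: the body dilated by a Euclidean ball of radius *t*, minus the
body, clipped to the extent. This was chosen over iterated
structuring-element dilation because it yields uniform *physical* thickness
independent of voxel anisotropy, and it admits an exhaustive oracle: on
small grids the implementation is tested voxel-for-voxel against a
brute-force nearest-neighbour query over all voxel-center pairs.

Quantization behaviour worth knowing: distances are measured between voxel
*centers*, and the nearest body center lies slightly inside the continuous
skin surface, by ~0.15 mm averaged over surface orientations at 1 mm
spacing. The built shell's outer boundary therefore sits ~0.15 mm low, which
is negligible for thickness (3% of t = 5 mm) but is amplified in the
*relative volume* of a thin shell: on an 80 mm sphere the built 5 mm shell
measures ~3% below the analytic 80→85 mm shell volume. The two candidate
cures were evaluated and rejected: measuring distance to the union of voxel
cubes inflates the body by the cube corners (~+0.5 mm, a +13% shell volume
error), and sub-voxel iso-surface distances would destroy the exact
voxel-pair oracle property. The center-distance definition is kept as the
single normative one.

The cap extent is a half-space at/above a user-chosen axial plane (a
free-form outline can be substituted as a user-supplied mask); an optional
rim feather tapers the admitted thickness linearly from zero at the plane to
*t* over `edge_feather_mm`, so printed caps end in a thin edge rather than a
5 mm cliff.

## Meshing and STL

Marching cubes at level 0.5 of the shell mask, presmoothed by a 0.5-voxel
Gaussian (clipped back to [0, 1] so the level stays inside the data range)
for sub-voxel surface placement. The mask is padded by one voxel first, so
the extracted surface is always closed; meshes are validated watertight,
non-degenerate, and positive-volume before any export. Optional Taubin
smoothing (λ = 0.5, ν = 0.53, 10 iterations) is volume-preserving to well
under 1%; a hard per-vertex displacement cap (0.5 mm default) is enforced by
clamping, so the smoothed surface cannot drift from the voxel surface by
more than the stated bound. STL is written as binary little-endian (80-byte
header, uint32 facet count, 50 bytes per facet) with per-facet normals
recomputed from the winding; the reader checks the facet count against the
file length and rebuilds an indexed mesh by merging exactly coincident
vertices, so write→read reproduces coordinates at 32-bit float precision.

## QA metrics

*Air gap*: for every body-surface voxel (6-connectivity surface) inside the
cap extent, the Euclidean distance to the nearest bolus voxel minus half a
voxel diagonal (the center-to-center offset of two touching voxels), floored
at zero. The metric is fully volumetric — 3D distances, independent of slice
orientation — and is evaluated only inside the extent because the rim
necessarily diverges from the scalp. A cap built directly on its body mask
reports ≤ 0.14 mm at 1 mm spacing (zero within quantization); a cap
translated 3 mm reports 3.1 mm.

*Wall thickness*: at every inner-surface bolus voxel (bolus voxel
6-adjacent to the body) inside the extent, the distance through the solid
(body ∪ bolus) to the outside air, via a second distance transform. On a
uniform shell this recovers *t* to within half a voxel (median 4.58 mm for
t = 5 at 1 mm).

An STL from a scanner or vendor can be voxelized back onto the CT grid
(voxel center-in-surface test) and pushed through the same two metrics, so
the fit of a *printed and fitted* cap imaged on a verification CT is
measured with the same definitions as the designed one.

## HU→density calibration

The calibration curve is a piecewise-linear map through ordered
(HU, density) knots — the representation planning systems use — with linear
extrapolation beyond the end knots floored at zero, and density interpreted
as physical density (g/cm³). Percent error is scored against the measured
density (mass and caliper dimensions), which is the reference quantity.
Published clinical curves are scanner-specific figures rather than tables,
so the package ships a *representative generic* 120 kVp curve as its
fixture and reads user curves from two-column delimited text; conclusions
about a specific scanner require that scanner's curve.

## TLD dose statistics

Agreement at each TLD location is the absolute percent difference
100·|measured − planned|/planned, with the planned (TPS) dose as the
denominator — the comparison is "how far did delivery land from the plan".
Summaries use the sample (n−1) standard deviation; a single-record summary
reports SD 0 with an explicit flag. The packaged 20-location phantom
reference table reproduces mean 2.4%, SD 1.5%, max 6.3%, and 95% of
locations within the 5% action level. Multi-fraction in-vivo measurements
are summarized per fraction and then averaged; interfraction
reproducibility is each location's across-fraction sample SD averaged over
locations measured in every fraction.

## Synthetic phantom

The phantom is an analytic star-convex "head": an ellipsoid (default
semi-axes 75×90×80 mm, about an adult head) of soft tissue (40 HU) with a
skull shell (700 HU, 7 mm thick) starting 5 mm below the surface, in air
(−1000 HU), sampled on a 3×1×1 mm grid like a CT-simulation protocol, with
seeded Gaussian noise (default SD 10 HU, a typical head-protocol level).
Generation is a pure function of the spec including its seed. Optional
low-amplitude sinusoidal bumps make the scalp non-convex for conformality
stress tests. Surface distance queries are closed-form for spheres, solved
per point by foot-point root finding for ellipsoids (~1e-9 mm), and
evaluated against a dense surface sampling for bumpy surfaces (~0.01 mm at
the test sampling density).

What the phantom does *not* emulate: partial-volume blur at the skin (HU
histograms are exactly tri-valued when noise is off — this is what makes the
three-material invariant and the volume oracles exact), anatomy (ears,
sinuses, neck), couch/immobilization hardware, and beam or dose physics.
Passing tests therefore demonstrate the geometry pipeline — segmentation,
shell construction, meshing, gap/thickness metrics — to sub-voxel accuracy,
not the dosimetric performance of any printed material; the TLD statistics
module operates on measured tables, not simulated doses.

## Problem sizes and runtime

The validation pipeline uses an r = 80 mm sphere at 1 mm isotropic
(≈ 7.8 M voxels): generation through STL completes in well under a minute on
one core, and the full test suite in about a minute. Unit tests use
r = 25–60 mm spheres for speed; the oracle-equivalence checks run on ≤ 40³
grids where the all-pairs query is exact and cheap.

## Known limitations

- The cap extent is a single axial plane (plus feather); genuinely freeform
  extents must be supplied as masks.
- Shell volume carries the −3% center-distance quantization bias at 1 mm
  described above; halve the working spacing if shell *volume* (not
  thickness) is the quantity of interest.
- The deformable fit of a soft printed cap (swim-cap compression, strap
  tension) is not modelled; measured air gaps on verification CTs are the
  ground truth the volumetric metric is designed to score.
- Non-axial acquisitions and DICOM-RT structure sets are out of scope.
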