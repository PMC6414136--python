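# boluscap

Automated design of patient-specific, uniform-thickness bolus caps for total
scalp irradiation (TSI), from a head CT to a ready-to-print STL, with the
quantitative QA used to trust the result.

TSI delivers a uniform dose to the entire scalp, which requires a bolus — a
tissue-equivalent layer on the skin that pulls the dose build-up region up to
the skin surface. Hand-made bolus caps (taped sheets under a swim cap) are
laborious and leave random air gaps that degrade surface dose. `boluscap`
automates the alternative: segment the patient's body surface from CT, grow a
shell of uniform physical thickness *t* on the scalp, and export it as a
watertight binary STL that a 3D-printing vendor can produce in a soft,
skin-conformal elastomer.

## Method

Given a CT volume resampled to 1 mm isotropic:

1. **External contour** — largest 6-connected component of {HU ≥ −400},
   cavities filled, surface regularized by 2 mm morphological closing.
2. **Cap extent** — an axial plane *z*₀ in patient coordinates; no bolus is
   generated inferior to it (an optional feather tapers the rim).
3. **Uniform shell** — with *D*(x) the exact Euclidean distance transform of
   the body mask (in mm), the cap is

   shell = { x ∉ body : 0 < *D*(x) ≤ *t* } ∩ extent,  *t* = 5 mm by default,

   i.e. the body dilated by a Euclidean ball of radius *t*, minus the body.
   Thickness is therefore uniform in millimetres regardless of voxel
   anisotropy.
4. **Meshing** — marching cubes at level 0.5 of the (0.5-voxel Gaussian
   presmoothed) shell mask, volume-preserving Taubin smoothing with a hard
   0.5 mm displacement cap, binary STL export in LPS mm.

QA metrics accompany every build: the **air gap** (distance from each
body-surface voxel inside the extent to the nearest bolus voxel, less half a
voxel diagonal, floored at 0 — zero by construction for a freshly built cap,
and the physical gap for a displaced or scanned one) and the **wall
thickness** (distance from the bolus inner surface through the solid to the
outside air). Two further analysis tools mirror the physics workflow around
the cap: a piecewise-linear HU→density calibration to sanity-check candidate
printing materials against their measured density, and planned-vs-measured
TLD dose statistics (absolute percent difference with the planned dose as
denominator; mean, sample SD, max, fraction within tolerance).

A synthetic head phantom (analytic ellipsoid with a skull shell, optional
surface bumps, seeded noise) provides closed-form ground truth for every
stage; no scan data are needed to validate an installation.

## Worked example

```
$ boluscap simulate --out head.npz --head-radii 75 90 80 --noise-sd-hu 10 --seed 7
wrote phantom volume (67, 220, 190) to head.npz

$ boluscap bolus head.npz --inferior-plane-mm 120 --stl-out cap.stl --qa-report-out qa.tsv
INFO boluscap: read: (67, 220, 190) voxels, spacing [3. 1. 1.] mm
INFO boluscap: resample: working grid (201, 220, 190) at 1 mm
INFO boluscap: segment: body 2279.8 cm^3 (threshold -400 HU)
INFO boluscap: extent: inferior plane z = 120 mm
INFO boluscap: shell: 168.0 cm^3 at t = 5 mm
INFO boluscap: qa: max gap 0.13 mm, median thickness 4.69 mm
INFO boluscap: mesh: 211964 facets, 167.8 cm^3 enclosed
INFO boluscap: write: STL -> cap.stl
bolus shell: 168.0 cm^3, median thickness 4.69 mm, max air gap 0.13 mm, 211964 facets
```

The cap hugs the synthetic scalp (max air gap 0.13 mm — sub-voxel, i.e. zero
within quantization) with a median wall of 4.69 mm against the requested
5 mm; the 0.3 mm shortfall is the expected half-voxel quantization of a
voxelized shell at 1 mm. `cap.stl` is a watertight binary STL in patient
millimetres, printable as-is.

Dose-verification statistics for the packaged 20-location phantom TLD table:

```
$ boluscap tldstats
n=20  mean |%diff|=2.4%  SD=1.5%  max=6.3%  within 5%: 95%
```

Material check of a soft printable elastomer (mean 84 HU, measured density
1.14 g/cm³) against the packaged generic calibration curve:

```
$ boluscap calib --hu 84 --measured-density 1.14
predicted density at 84 HU: 1.074 g/cm^3 (5.76% error vs measured 1.14)
```

(Scanner-specific curves, supplied with `--curve`, will predict elastomer
densities considerably better than the generic fixture curve.)

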