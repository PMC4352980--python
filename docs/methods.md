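# Methods

This note documents the models, algorithms and numerical choices behind
`spiraltomo`, and what the synthetic-data tests do and do not demonstrate.

## Coordinate and angle conventions

Volumes are `(ny, nx, nz)` arrays: `y` is the camera vertical axis and the
rotation axis, `x` the camera horizontal axis, `z` the detection optical axis.
Transverse sections are `(x, z)` planes at fixed `y`; volume TIFFs store one
transverse section per page. Voxel and pixel centres sit at integer 0-based
indices (position = index × voxel size). The rotation axis crosses a
transverse plane at `x = (nx − 1)/2 + axis_offset_x`, `z = (nz − 1)/2`.
Angles increase counter-clockwise viewed from above; a point at transverse
radius `r` and phase `φ` projects to detector coordinate `r·cos(θ − φ)`
relative to the axis, which fixes the sinogram handedness. Resampling
throughout is linear interpolation with zero outside the grid.

## Forward model (the simulator)

**Phantoms.** Ground truth is a list of spheres/ellipsoids with attenuation
(1/µm) and fluorescence (a.u.) values; a voxel takes the sum of all primitives
covering its centre. Rasterisation is binary, so projections of a sphere of
radius `r` agree with the analytic chord length to ~2 % only once `r ≳ 30`
voxels; oracle tests use that regime.

**Transmission.** Illumination is ideal parallel-beam; refraction and
scattering are ignored. This matches the reconstruction model (a
parallel-beam inverse Radon transform) rather than the physical LED
illumination — the simulator exists to exercise the pipeline, not to emulate
aberrations the pipeline does not model. Image formation is Beer–Lambert:
`I = dark + (background − dark)·V·exp(−OD) + ε`, with `V` an optional radial
vignetting field, `ε` additive Gaussian read noise (an sCMOS proxy; Poisson
shot noise is out of scope) seeded per frame from the acquisition seed, and
counts rounded to 16 bits (disable with `quantize=False`).

**Defocus.** No PSF model is published for this configuration, so a standard
geometric-optics approximation is used: the rotated volume is cut into slabs
of thickness δz/2 (Nyquist with respect to the blur scale) perpendicular to
the detection axis, each slab's partial line integral is blurred with an
isotropic Gaussian of width `σ(d) = σ₀·max(1, |d|/δz)` (σ₀ = 1 px in focus,
`d` = slab distance from the focal plane), and the blurred optical depths are
summed before exponentiation. Blurring optical depth rather than intensity is
itself an approximation, adequate for optically thin specimens.
`depth_of_field_um = inf` bypasses the slab model and produces exact line
integrals — the configuration under which the Beer–Lambert round trip holds to
1e-6 and against which the correction/log chain is validated.

**Spiral trajectory.** Frame `i` has angle `(i·Δθ) mod 360` and a focal
position linear in `i` between `z_start` and `z_end`; with
`frames_per_rotation·Δθ = 360` every angle recurs once per rotation at a new
depth. Defaults follow the acquisition protocol the package targets: 20
rotations, 1° steps (7200 frames), ~500 µm focal travel, 60 Hz frame rate,
δz = 15 µm at NA 0.3, 2 µm pixels.

**Numerical shortcuts** (all invisible at the contract level): the per-angle
rotation is resampled only inside the phantom's bounding cylinder and
occupied rows; each slab is sampled at 2 points across its thickness
(`z_samples_per_slab`); defocus blur is applied in the Fourier domain with
analytic Gaussian transfer functions cached on a 0.05 px σ grid; slab spectra
are shared by the ~20 frames of one angle. Frames are yielded in true
acquisition order, which interleaves all angles, so the generator materialises
the whole acquisition first (~0.9 GB at 7200 × 256² uint16).

**Fluorescence stacks.** A SPIM stack at view θ is the rotated fluorescence
volume blurred laterally with σ₀, boxcar-integrated over the slice thickness,
and sampled every `z_spacing` (2 µm default) along the detection axis; the
stack centre is displaced from the rotation axis by `axis_z_offset` — the
unknown the registration recovers.

## EDoF fusion

Focus measure: squared response of a difference-of-Gaussian high-pass
(`hp_sigma` = 2 px), smoothed with a Gaussian (`smooth_sigma` = 4 px). Weights
are the focus measure plus `eps` = 1e-3 × the group's mean squared high-pass
response (guards texture-free pixels; an all-flat group degenerates to the
plain mean). The exact filter of the original real-time implementation is not
published; this is a standard variance-of-high-pass focus measure consistent
with its description. Consequences verified by tests: fusion is a convex
combination per pixel, commutes with global intensity scaling, and an
identical-frame group fuses to that frame (to float32 rounding).

`stream_fuse` consumes frames in acquisition order keeping only per-angle
accumulation buffers (Σwf, Σw, Σf and the running mean squared response);
because batch fusion uses the same accumulator in the same order, streaming
and batch outputs are bit-identical. Fusion operates on raw counts by
default; flat-field correction happens at reconstruction time (the original
processing order is unstated; the choice is recorded here and the corrected
alternative is available by fusing corrected frames).

## Reconstruction

Projections are corrected (`(raw − dark)/(background − dark)`, floored at
1e-6), log-converted to optical depth, reorganised into one sinogram per image
row, and inverted by FBP. The log-conversion is a deliberate choice: FBP
requires line integrals, and corrected transmittance only approximates them
after the log; `log=False` back-projects corrected intensity for comparison.

Filtering uses the band-limited real-space ramp kernel (Ram-Lak) evaluated in
the Fourier domain on zero-padded rows (next power of two ≥ 2× width, min 64),
with optional Shepp-Logan/cosine/Hamming/Hann apodisation. Back-projection
interpolates linearly with zero outside the detector and scales by `π/(2N)`,
correct for uniform coverage of either 180° or 360°; all 360° are used without
folding because opposite views differ under defocus. The output slice is
`width × width` with the axis at the centre, divided by the pixel size to give
1/µm. Verified against the closed-form uniform-disk sinogram (interior mean
within 0.1 %, masked RMSE < 0.1 %) and against an independent inverse-Radon
implementation.

**Axis search.** Default protocol (the original's is unstated): 5 sinogram
rows, chosen evenly across the band of rows whose summed optical depth exceeds
10 % of the best row (an empty row carries no axis information), offsets
scanned over ±20 px in 1 px steps, image variance averaged over rows,
parabolic refinement around the discrete maximum; a boundary maximum raises
rather than returning a clamped value. Median |error| ≈ 0.05 px over
randomised phantoms with offsets in ±8 px.

## Registration

**Two-view z-alignment.** The tomogram and the SPIM stacks share the detector,
so x/y are inherently aligned; only the stack position along the detection
axis is unknown. With stacks from θ and θ+90°, the second stack axis-permuted
onto the reference's x axis, the shared offset displaces the reference along
its z axis and the permuted stack along the reference's x axis by the same
amount. The residual misregistration is therefore a one-parameter translation
along the transverse diagonal; normalised cross-correlation over that shift
(integer scan, parabolic sub-voxel peak) recovers the offset. A pure 1D shift
along z alone was tested and cannot overlay the stacks for offsets beyond a
few voxels (peak correlation collapses); the diagonal coupling is the
package's resolution of that geometry. The returned value is the registration
shift for the reference view, so swapping the arguments negates it. Peak
correlation below 0.2 raises ("insufficient mutual structure").

**Sphere landmarks.** Bright spheres (eye lenses) are found by a
gradient-direction Hough vote: voxels with gradient magnitude above 20 % of
the maximum vote, weighted by magnitude, at `p + r·∇/|∇|` for every radius in
the search range; accumulators are smoothed (σ = 1 vx), normalised by `r²`,
and scanned with non-maximum suppression at separation `r_min`. Centres are
refined by a local 3³ centroid, radii by a parabola across the radius axis.
Radii bias ~5 % low on blurred phantoms (the gradient peak sits just inside
the edge) — within the 1-voxel contract of the detector.

**Landmark transform.** Two eye centres fix four of six rigid degrees of
freedom; the remaining rotation about the inter-eye axis is fixed by a dorsal
hint, by default the volume intensity centroid's offset from the eye midpoint
(any anatomical asymmetry keeps it stable). Orthonormal frames are built by
Gram-Schmidt for both landmark sets and composed; the transform stays rigid
under growth, with residual equal to half the eye-separation mismatch. Eye
correspondence across time points is the pairing yielding the smaller
rotation, assuming inter-frame motion below 90°. Time points where detection
fails are flagged and passed through untransformed.

**Segmentation.** Seeded region growing accepts 26-connected voxels whose
local gradient is below threshold. The gradient is measured as the intensity
range over the 26-neighbourhood (morphological gradient): a derivative-stencil
gradient paired with 26-connected growth leaks diagonally across intensity
edges. The grown core is dilated once so the mask boundary sits mid-way
through the gradient shell; a uniform test sphere's volume is then recovered
within 1 %. `threshold = 0` returns the seed voxel alone; a seed on a
high-gradient voxel raises with a re-seeding hint.

## Pipeline, formats, determinism

Stacks are multi-page TIFFs (frames uint16, projections/volumes float32,
masks uint8) with JSON text sidecars carrying all acquisition and processing
metadata; configurations are YAML validated into the parameter types before
any computation. `run_pipeline` executes simulate → fuse → reconstruct
(→ SPIM overlay), logs stage-tagged lines to stderr, and writes a manifest
(version, config hash, per-stage timings and files, reduction factor, axis
estimate) atomically. All randomness derives from the single configured seed
via per-frame seed sequences, so reruns are byte-identical regardless of
generation order.

## Problem sizes and limitations

The test suite and the acceptance script run the full-scale acquisition
arithmetic (7200 × 256² frames) but reconstruct at 128³ and register at 96³,
sizes chosen so the full chain exercises every code path in minutes on one
CPU; the algorithms are size-agnostic.

What passing tests show: the pipeline's geometry, bookkeeping, inversion
accuracy and parameter recovery are correct under the stated forward model.
What they do not show: robustness to refraction, scattering, shot noise,
rolling-shutter skew, stage wobble, or non-rigid specimen motion — none of
which the simulator emulates. Iterative reconstruction, cone-beam geometry,
ring-artifact removal, deformable registration and multiview deconvolution
are out of scope.
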