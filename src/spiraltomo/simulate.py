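"""Synthetic spiral bright-field acquisition for SPIM-based optical tomography.

This module stands in for the microscope.  It builds parametric attenuation /
fluorescence phantoms, computes parallel-beam line integrals of the attenuation
through the rotated sample, and emulates the spiral acquisition protocol in
which the specimen rotates continuously while being translated through the
detection objective's plane of focus, so that each projection angle is
revisited once per rotation at a different focal depth.

Geometry conventions
--------------------
* Volumes are stored as ``(ny, nx, nz)`` arrays: ``y`` is the camera vertical
  axis and the rotation axis, ``x`` the camera horizontal axis, ``z`` the
  detection optical axis.  Transverse sections are ``(x, z)`` planes at fixed
  ``y``.
* Voxel/pixel centers sit at integer 0-based indices; the physical position of
  voxel ``i`` along an axis is ``i * voxel_size`` micrometres.
* The rotation axis crosses the transverse plane at
  ``x = (nx - 1) / 2 + axis_offset_x`` (pixels), ``z = (nz - 1) / 2``.
* Angles are in degrees and increase counter-clockwise when viewed from above
  (looking down the -y axis); a point at transverse radius ``r`` and phase
  ``phi`` projects to detector coordinate ``r * cos(theta - phi)`` relative to
  the axis.

Image formation follows the Beer-Lambert law: a transmission frame is
``I = dark + (background - dark) * V * exp(-optical_depth) + noise`` where
``V`` is an optional radial vignetting field and the optical depth is the line
integral of the attenuation coefficient along ``z``.  Defocus is modelled
geometrically: the rotated volume is divided into slabs perpendicular to the
detection axis and each slab's partial line integral is blurred with an
isotropic Gaussian whose width grows linearly with the slab's distance from
the focal plane.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "OpticsParams",
    "Primitive",
    "PhantomSpec",
    "SpiralParams",
    "Frame",
    "Volume",
    "SpimStack",
    "make_phantom",
    "project_attenuation",
    "simulate_spiral",
    "simulate_spim_stack",
    "correction_frames",
    "vignetting_field",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OpticsParams:
    """Detection-side optical and camera parameters.

    Parameters
    ----------
    numerical_aperture : float
        Detection NA, in (0, 1].  A typical SPIM detection lens has NA 0.3.
    wavelength_um : float
        Detection wavelength in micrometres (metadata; the geometric defocus
        model does not use it directly).
    refractive_index : float
        Immersion medium refractive index.
    depth_of_field_um : float
        Depth of field ``dz`` in micrometres; the axial range rendered
        acceptably sharp.  ~15 um for NA 0.3 in water.  ``inf`` selects an
        ideal all-in-focus system (no defocus blur), useful for validating
        the Beer-Lambert arithmetic.
    pixel_size_um : float
        Camera pixel size divided by magnification (um per pixel in sample
        space).
    background_level, dark_level : float
        Mean counts with full illumination and no sample, and with no
        illumination (camera offset + dark current).
    noise_sd : float
        Standard deviation of additive Gaussian read noise, in counts.
    psf_sigma_px : float
        In-focus PSF width sigma_0 in pixels; also the floor of the defocus
        blur.
    vignetting_strength : float
        Relative drop of the illumination at the image corner, in [0, 1).
        0 disables vignetting.
    """

    numerical_aperture: float = 0.3
    wavelength_um: float = 0.52
    refractive_index: float = 1.333
    depth_of_field_um: float = 15.0
    pixel_size_um: float = 2.0
    background_level: float = 3000.0
    dark_level: float = 100.0
    noise_sd: float = 0.0
    psf_sigma_px: float = 1.0
    vignetting_strength: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.numerical_aperture <= 1.0:
            raise ValueError("numerical_aperture must be in (0, 1]")
        if not self.depth_of_field_um > 0:
            raise ValueError("depth_of_field_um must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if not self.background_level > self.dark_level >= 0:
            raise ValueError("require background_level > dark_level >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if not 0.0 <= self.vignetting_strength < 1.0:
            raise ValueError("vignetting_strength must be in [0, 1)")


@dataclass(frozen=True)
class Primitive:
    """One ellipsoid or sphere of the ground-truth phantom.

    ``center_um`` and ``semi_axes_um`` are in micrometres in the volume's
    ``(x, y, z)`` coordinates (origin at voxel (0, 0, 0)).  For a sphere the
    three semi-axes are equal.  ``attenuation`` is the attenuation coefficient
    mu in 1/um; ``fluorescence`` is in arbitrary units.  Overlapping
    primitives add.
    """

    shape: str
    center_um: tuple[float, float, float]
    semi_axes_um: tuple[float, float, float]
    attenuation: float = 0.0
    fluorescence: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid"):
            raise ValueError(f"unknown primitive shape {self.shape!r}")
        if len(self.center_um) != 3 or len(self.semi_axes_um) != 3:
            raise ValueError("center_um and semi_axes_um must be 3-tuples")
        if any(a <= 0 for a in self.semi_axes_um):
            raise ValueError("semi-axes must be positive")
        if self.shape == "sphere" and len(set(self.semi_axes_um)) != 1:
            raise ValueError("a sphere needs three equal semi-axes")
        if self.attenuation < 0 or self.fluorescence < 0:
            raise ValueError("attenuation and fluorescence must be >= 0")

    @classmethod
    def sphere(
        cls,
        center_um: Sequence[float],
        radius_um: float,
        attenuation: float = 0.0,
        fluorescence: float = 0.0,
        label: str = "",
    ) -> "Primitive":
        return cls(
            "sphere",
            tuple(float(c) for c in center_um),
            (float(radius_um),) * 3,
            attenuation,
            fluorescence,
            label,
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric ground truth: a list of primitives inside a bounding box.

    ``extent_um`` is the ``(x, y, z)`` size of the simulated volume in
    micrometres.  Every primitive must fit inside the extent.
    """

    primitives: tuple[Primitive, ...]
    extent_um: tuple[float, float, float]

    def __init__(self, primitives: Sequence[Primitive], extent_um: Sequence[float]):
        object.__setattr__(self, "primitives", tuple(primitives))
        object.__setattr__(self, "extent_um", tuple(float(e) for e in extent_um))
        if len(self.extent_um) != 3 or any(e <= 0 for e in self.extent_um):
            raise ValueError("extent_um must be three positive lengths")
        for p in self.primitives:
            for c, a, e in zip(p.center_um, p.semi_axes_um, self.extent_um):
                if c - a < 0 or c + a > e:
                    raise ValueError(
                        f"primitive {p.label or p.shape!r} extends outside the "
                        f"phantom extent {self.extent_um}"
                    )


@dataclass(frozen=True)
class SpiralParams:
    """Spiral acquisition trajectory.

    The sample rotates continuously (one frame per ``angular_step_deg``) while
    the focal plane travels monotonically from ``z_start_um`` to ``z_end_um``.
    ``frames_per_rotation * angular_step_deg`` must equal 360, so each angle
    is revisited exactly once per rotation at a new focal depth.
    ``axis_offset_x_px`` displaces the rotation axis from the detector centre
    column (a miscentering for the reconstruction to recover).
    """

    n_rotations: int = 20
    angular_step_deg: float = 1.0
    frames_per_rotation: int = 360
    z_start_um: float = 0.0
    z_end_um: float = 500.0
    axis_offset_x_px: float = 0.0
    frame_rate_hz: float = 60.0

    def __post_init__(self) -> None:
        if self.n_rotations < 1 or self.frames_per_rotation < 1:
            raise ValueError("n_rotations and frames_per_rotation must be >= 1")
        if abs(self.frames_per_rotation * self.angular_step_deg - 360.0) > 1e-9:
            raise ValueError("frames_per_rotation * angular_step_deg must be 360")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")

    @property
    def total_frames(self) -> int:
        return self.n_rotations * self.frames_per_rotation

    def angle_of(self, index: int) -> float:
        return (index * self.angular_step_deg) % 360.0

    def focal_z_of(self, index: int) -> float:
        n = self.total_frames
        if n == 1:
            return self.z_start_um
        t = index / (n - 1)
        return self.z_start_um + t * (self.z_end_um - self.z_start_um)


@dataclass
class Frame:
    """One transmission image with its trajectory metadata."""

    pixels: np.ndarray  # (ny, nx), counts
    angle_deg: float
    focal_z_um: float
    index: int


@dataclass
class Volume:
    """3D scalar grid with isotropic voxels.

    ``voxels`` has shape ``(ny, nx, nz)``; ``voxels[y]`` is the transverse
    ``(x, z)`` section at row ``y``.
    """

    voxels: np.ndarray
    voxel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def transverse_slice(self, y: int) -> np.ndarray:
        return self.voxels[y]


@dataclass
class SpimStack:
    """A fluorescence light-sheet stack from one view angle.

    ``data`` has shape ``(ny, nx, n_slices)``; slice ``k`` is the optical
    section at stage position ``k * z_spacing_um`` along the detection axis of
    the rotated sample.  ``pixel_size_um`` is the lateral sampling.
    """

    data: np.ndarray
    z_spacing_um: float
    angle_deg: float
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("SPIM stack must be a 3D array")
        if not self.z_spacing_um > 0:
            raise ValueError("z_spacing_um must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


# ---------------------------------------------------------------------------
# phantom rasterization
# ---------------------------------------------------------------------------


def make_phantom(spec: PhantomSpec, voxel_size_um: float) -> tuple[Volume, Volume]:
    """Rasterize a phantom onto a voxel grid.

    Each voxel takes the summed attenuation (resp. fluorescence) of all
    primitives whose interior covers the voxel centre.  Returns the
    attenuation volume (1/um) and the fluorescence volume (a.u.) on the same
    grid.
    """
    if voxel_size_um <= 0:
        raise ValueError("voxel_size_um must be positive")
    ex, ey, ez = spec.extent_um
    nx = max(1, int(round(ex / voxel_size_um)))
    ny = max(1, int(round(ey / voxel_size_um)))
    nz = max(1, int(round(ez / voxel_size_um)))
    att = np.zeros((ny, nx, nz), dtype=np.float32)
    flu = np.zeros((ny, nx, nz), dtype=np.float32)
    for p in spec.primitives:
        cx, cy, cz = (c / voxel_size_um for c in p.center_um)
        ax, ay, az = (a / voxel_size_um for a in p.semi_axes_um)
        y0, y1 = max(0, int(math.floor(cy - ay))), min(ny, int(math.ceil(cy + ay)) + 1)
        x0, x1 = max(0, int(math.floor(cx - ax))), min(nx, int(math.ceil(cx + ax)) + 1)
        z0, z1 = max(0, int(math.floor(cz - az))), min(nz, int(math.ceil(cz + az)) + 1)
        yy = (np.arange(y0, y1, dtype=np.float64) - cy) / ay
        xx = (np.arange(x0, x1, dtype=np.float64) - cx) / ax
        zz = (np.arange(z0, z1, dtype=np.float64) - cz) / az
        inside = (
            yy[:, None, None] ** 2 + xx[None, :, None] ** 2 + zz[None, None, :] ** 2
        ) <= 1.0
        if p.attenuation:
            att[y0:y1, x0:x1, z0:z1] += np.where(inside, np.float32(p.attenuation), 0.0).astype(
                np.float32
            )
        if p.fluorescence:
            flu[y0:y1, x0:x1, z0:z1] += np.where(inside, np.float32(p.fluorescence), 0.0).astype(
                np.float32
            )
    return (
        Volume(att, voxel_size_um, meta={"content": "attenuation_per_um"}),
        Volume(flu, voxel_size_um, meta={"content": "fluorescence_au"}),
    )


# ---------------------------------------------------------------------------
# rotation and projection
# ---------------------------------------------------------------------------


def _rotation_matrix_xz(theta_deg: float) -> np.ndarray:
    """3x3 matrix rotating (y, x, z) index vectors in the (x, z) plane.

    Maps output-grid coordinates to input-grid coordinates; positive angles
    rotate the sample counter-clockwise viewed from above.
    """
    t = math.radians(theta_deg)
    c, s = math.cos(t), math.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotate_volume(
    voxels: np.ndarray, theta_deg: float, axis_offset_x_px: float = 0.0
) -> np.ndarray:
    """Resample a volume rotated by ``theta_deg`` about the rotation axis.

    Linear interpolation; values outside the original grid are zero.
    """
    ny, nx, nz = voxels.shape
    center = np.array([0.0, (nx - 1) / 2.0 + axis_offset_x_px, (nz - 1) / 2.0])
    mat = _rotation_matrix_xz(theta_deg)
    offset = center - mat @ center
    return ndi.affine_transform(
        voxels, mat, offset=offset, order=1, prefilter=False, mode="constant", cval=0.0,
        output=np.float32,
    )


def project_attenuation(
    attenuation: Volume, theta_deg: float, axis_offset_x_px: float = 0.0
) -> np.ndarray:
    """Parallel-beam line integrals of the attenuation along ``z``.

    The volume is rotated by ``theta_deg`` about the (possibly offset)
    rotation axis and summed along the detection axis; the result is the
    dimensionless optical depth per detector pixel, shape ``(ny, nx)``.
    """
    rot = rotate_volume(attenuation.voxels, theta_deg, axis_offset_x_px)
    return rot.sum(axis=2, dtype=np.float32) * np.float32(attenuation.voxel_size_um)


def vignetting_field(shape: tuple[int, int], strength: float) -> np.ndarray:
    """Radial illumination falloff: 1 at the centre, ``1 - strength`` at the
    image corner."""
    ny, nx = shape
    if strength == 0.0:
        return np.ones((ny, nx), dtype=np.float32)
    yy = np.arange(ny, dtype=np.float32) - (ny - 1) / 2.0
    xx = np.arange(nx, dtype=np.float32) - (nx - 1) / 2.0
    r2 = yy[:, None] ** 2 + xx[None, :] ** 2
    r2max = ((ny - 1) / 2.0) ** 2 + ((nx - 1) / 2.0) ** 2
    return (1.0 - strength * r2 / r2max).astype(np.float32)


def correction_frames(optics: OpticsParams, shape: tuple[int, int]):
    """Ideal (noise-free) background and dark reference frames matching the
    simulator's image formation, for flat-field correction downstream."""
    from .recon import CorrectionFrames  # local import: recon depends on this module

    v = vignetting_field(shape, optics.vignetting_strength)
    background = optics.dark_level + (optics.background_level - optics.dark_level) * v
    dark = np.full(shape, optics.dark_level, dtype=np.float32)
    return CorrectionFrames(background=background.astype(np.float32), dark=dark)


# ---------------------------------------------------------------------------
# spiral acquisition
# ---------------------------------------------------------------------------


def _to_counts(
    optical_depth: np.ndarray,
    optics: OpticsParams,
    vignette: np.ndarray,
    rng: np.random.Generator | None,
    quantize: bool,
) -> np.ndarray:
    span = optics.background_level - optics.dark_level
    img = optics.dark_level + span * vignette * np.exp(-optical_depth, dtype=np.float32)
    if optics.noise_sd > 0 and rng is not None:
        img = img + rng.standard_normal(img.shape, dtype=np.float32) * np.float32(
            optics.noise_sd
        )
    np.clip(img, 0.0, None, out=img)
    if quantize:
        return np.clip(np.rint(img), 0, 65535).astype(np.uint16)
    return img.astype(np.float32)


def _support_radius_px(voxels: np.ndarray, cx: float, cz: float) -> float:
    """Largest transverse distance of any non-zero voxel from the rotation
    axis, or 0 for an empty volume."""
    mask = (voxels != 0).any(axis=0)
    if not mask.any():
        return 0.0
    ix, iz = np.nonzero(mask)
    return float(np.sqrt((ix - cx) ** 2 + (iz - cz) ** 2).max())


def simulate_spiral(
    attenuation: Volume,
    optics: OpticsParams,
    spiral: SpiralParams,
    seed: int = 0,
    quantize: bool = True,
    z_samples_per_slab: int = 2,
) -> Iterator[Frame]:
    """Simulate the spiral bright-field acquisition.

    Emits ``n_rotations * frames_per_rotation`` frames in acquisition order:
    frame ``i`` has angle ``(i * angular_step) % 360`` and a focal-plane
    position interpolated linearly between ``z_start_um`` and ``z_end_um``.

    The image at each frame is formed by slicing the rotated volume into slabs
    of thickness ``dz/2`` perpendicular to the detection axis, blurring each
    slab's partial line integral with a Gaussian of width
    ``sigma(d) = psf_sigma_px * max(1, |d| / dz)`` (``d`` = slab distance from
    the focal plane), summing the blurred optical depths and converting to
    camera counts via Beer-Lambert plus seeded Gaussian read noise.  With
    ``depth_of_field_um = inf`` the defocus model is bypassed and frames
    contain the exact line integrals.

    ``quantize=True`` rounds to 16-bit camera counts (the on-disk format);
    ``quantize=False`` keeps float32 counts, preserving the Beer-Lambert
    round trip to machine precision.

    Frames are yielded lazily but the synthesis is organised per angle (all
    rotations of one angle share the rotated volume), so the full acquisition
    is materialised in memory before the first frame is yielded.
    """
    n_frames = spiral.total_frames
    voxels = attenuation.voxels
    ny, nx, nz = voxels.shape
    vs = attenuation.voxel_size_um

    zmin, zmax = sorted((spiral.z_start_um, spiral.z_end_um))
    if zmax < 0 or zmin > (nz - 1) * vs:
        warnings.warn(
            "focal-plane travel does not overlap the volume's z extent; "
            "frames will be generated anyway",
            stacklevel=2,
        )

    children = np.random.SeedSequence(seed).spawn(n_frames) if optics.noise_sd > 0 else None
    vignette = vignetting_field((ny, nx), optics.vignetting_strength)
    buf_dtype = np.uint16 if quantize else np.float32
    counts = np.empty((n_frames, ny, nx), dtype=buf_dtype)
    focal = np.array([spiral.focal_z_of(i) for i in range(n_frames)])

    ideal = not np.isfinite(optics.depth_of_field_um)
    cx = (nx - 1) / 2.0 + spiral.axis_offset_x_px
    cz = (nz - 1) / 2.0

    def frame_rng(i: int) -> np.random.Generator | None:
        return np.random.default_rng(children[i]) if children is not None else None

    if ideal:
        for k in range(spiral.frames_per_rotation):
            od = project_attenuation(attenuation, k * spiral.angular_step_deg,
                                     spiral.axis_offset_x_px)
            for r in range(spiral.n_rotations):
                i = r * spiral.frames_per_rotation + k
                counts[i] = _to_counts(od, optics, vignette, frame_rng(i), quantize)
    else:
        _simulate_defocused(
            counts, voxels, vs, optics, spiral, focal, vignette, frame_rng,
            quantize, z_samples_per_slab, cx, cz,
        )

    for i in range(n_frames):
        yield Frame(
            pixels=counts[i],
            angle_deg=spiral.angle_of(i),
            focal_z_um=focal[i],
            index=i,
        )


def _simulate_defocused(
    counts: np.ndarray,
    voxels: np.ndarray,
    vs: float,
    optics: OpticsParams,
    spiral: SpiralParams,
    focal: np.ndarray,
    vignette: np.ndarray,
    frame_rng,
    quantize: bool,
    z_samples_per_slab: int,
    cx: float,
    cz: float,
) -> None:
    """Defocused image synthesis, one rotation of the volume per distinct
    angle, with FFT-domain Gaussian defocus shared across the focal stack."""
    from scipy import fft as sfft

    ny, nx, nz = voxels.shape
    dz_um = optics.depth_of_field_um
    sigma0 = optics.psf_sigma_px
    t_slab_um = dz_um / 2.0

    r_sup = _support_radius_px(voxels, cx, cz)
    if r_sup == 0.0:
        od = np.zeros((ny, nx), dtype=np.float32)
        for i in range(counts.shape[0]):
            counts[i] = _to_counts(od, optics, vignette, frame_rng(i), quantize)
        return

    r_sup += 2.0  # interpolation margin
    x_lo = max(0, int(math.floor(cx - r_sup)))
    x_hi = min(nx - 1, int(math.ceil(cx + r_sup)))
    wx = x_hi - x_lo + 1
    z_lo = max(0, int(math.floor(cz - r_sup)))
    z_hi = min(nz - 1, int(math.ceil(cz + r_sup)))
    y_any = (voxels != 0).any(axis=(1, 2))
    y_idx = np.flatnonzero(y_any)
    y_lo = max(0, int(y_idx[0]) - 2)
    y_hi = min(ny - 1, int(y_idx[-1]) + 2)
    wy = y_hi - y_lo + 1
    # a contiguous crop around the support region (rotation-invariant: a
    # cylinder about the axis, limited to the occupied rows) keeps the
    # per-angle resampling cache-friendly; coordinates below are in the
    # cropped frame
    src = np.ascontiguousarray(
        voxels[y_lo : y_hi + 1, x_lo : x_hi + 1, z_lo : z_hi + 1]
    )
    cxs = cx - x_lo
    czs = cz - z_lo
    z_lo_um = z_lo * vs
    z_hi_um = z_hi * vs
    n_slabs = max(1, int(math.ceil((z_hi_um - z_lo_um) / t_slab_um)))
    m = max(1, int(z_samples_per_slab))
    n_samples = n_slabs * m
    # uniform sample positions covering the slabs, in cropped voxel units
    dq_vox = (t_slab_um / m) / vs
    z0_vox = 0.5 * dq_vox
    slab_centers_um = z_lo_um + (np.arange(n_slabs) + 0.5) * t_slab_um

    # worst-case blur fixes the padded FFT grid for the whole acquisition
    d_max = max(
        abs(slab_centers_um.max() - focal.min()),
        abs(slab_centers_um.min() - focal.max()),
    )
    sigma_max = sigma0 * max(1.0, d_max / dz_um)
    pad = int(math.ceil(3.0 * sigma_max)) + 1
    H = sfft.next_fast_len(wy + 2 * pad)
    Wp = sfft.next_fast_len(wx + 2 * pad)
    fy = np.fft.fftfreq(H).astype(np.float32)
    fx = np.fft.rfftfreq(Wp).astype(np.float32)
    rho2 = fy[:, None] ** 2 + fx[None, :] ** 2

    gauss_cache: dict[float, np.ndarray] = {}

    def transfer(sigma: float) -> np.ndarray:
        key = round(sigma / 0.05) * 0.05  # quantize blur widths for caching
        g = gauss_cache.get(key)
        if g is None:
            g = np.exp(np.float32(-2.0 * math.pi**2 * key**2) * rho2)
            gauss_cache[key] = g
        return g

    mat_scale = np.diag([1.0, 1.0, dq_vox])
    center = np.array([0.0, cxs, czs])
    fpr = spiral.frames_per_rotation

    span = np.float32(optics.background_level - optics.dark_level)
    base = (optics.dark_level + span * vignette).astype(np.float32)
    noise_sd = np.float32(optics.noise_sd)
    # frame region receiving the blurred optical depth (content plus the
    # defocus halo of up to `pad` pixels), clipped to the frame
    r0, c0 = y_lo - pad, x_lo - pad
    fr = (max(0, r0), min(ny, r0 + H), max(0, c0), min(nx, c0 + Wp))
    od_rows = slice(fr[0] - r0, fr[1] - r0)
    od_cols = slice(fr[2] - c0, fr[3] - c0)
    v_block = span * vignette[fr[0] : fr[1], fr[2] : fr[3]]

    for k in range(fpr):
        theta = k * spiral.angular_step_deg
        rot = _rotation_matrix_xz(theta)
        matrix = rot @ mat_scale
        offset = rot @ (np.array([0.0, 0.0, z0_vox]) - center) + center
        samples = ndi.affine_transform(
            src, matrix, offset=offset, order=1, prefilter=False,
            output_shape=(wy, wx, n_samples), mode="constant", cval=0.0,
            output=np.float32,
        )
        slab_od = samples.reshape(wy, wx, n_slabs, m).mean(axis=3) * np.float32(t_slab_um)
        live = [s for s in range(n_slabs) if slab_od[:, :, s].max() > 0]
        spectra = np.empty((len(live), H, Wp // 2 + 1), dtype=np.complex64)
        padded = np.zeros((H, Wp), dtype=np.float32)
        for j, s in enumerate(live):
            padded[:] = 0.0
            padded[pad : pad + wy, pad : pad + wx] = slab_od[:, :, s]
            spectra[j] = sfft.rfft2(padded)
        tmp = np.empty(spectra.shape[1:], dtype=np.complex64)
        acc = np.empty_like(tmp)
        for r in range(spiral.n_rotations):
            i = r * fpr + k
            rng = frame_rng(i)
            img = base.copy() if rng is None else (
                rng.standard_normal((ny, nx), dtype=np.float32) * noise_sd + base
            )
            if live:
                for j, s in enumerate(live):
                    sig = sigma0 * max(1.0, abs(slab_centers_um[s] - focal[i]) / dz_um)
                    if j == 0:
                        np.multiply(spectra[j], transfer(sig), out=acc)
                    else:
                        np.multiply(spectra[j], transfer(sig), out=tmp)
                        acc += tmp
                od = sfft.irfft2(acc, s=(H, Wp))[od_rows, od_cols]
                np.clip(od, 0.0, None, out=od)
                # I = dark + span*V*exp(-od) = base + span*V*expm1(-od)
                img[fr[0] : fr[1], fr[2] : fr[3]] += v_block * np.expm1(-od)
            if quantize:
                np.clip(img, 0.0, 65535.0, out=img)
                counts[i] = np.rint(img).astype(np.uint16)
            else:
                np.clip(img, 0.0, None, out=img)
                counts[i] = img


# ---------------------------------------------------------------------------
# fluorescence SPIM stacks
# ---------------------------------------------------------------------------


def simulate_spim_stack(
    fluorescence: Volume,
    theta_deg: float,
    z_spacing_um: float,
    axis_z_offset_um: float = 0.0,
    n_slices: int | None = None,
    psf_sigma_px: float = 1.0,
) -> SpimStack:
    """Optical sections of the rotated fluorescence volume.

    The sample is rotated by ``theta_deg`` about the rotation axis and sliced
    perpendicular to the detection axis at ``z_spacing_um`` intervals.  Each
    section is blurred laterally with ``psf_sigma_px`` and integrated axially
    over the slice thickness (boxcar).  The stack centre is displaced from the
    rotation axis by ``axis_z_offset_um`` along the detection axis -- the
    unknown that multimodal registration must recover.
    """
    if z_spacing_um <= 0:
        raise ValueError("z_spacing_um must be positive")
    voxels = fluorescence.voxels
    ny, nx, nz = voxels.shape
    vs = fluorescence.voxel_size_um
    if n_slices is None:
        n_slices = max(1, int(math.floor((nz - 1) * vs / z_spacing_um)) + 1)

    rot = rotate_volume(voxels, theta_deg)
    if psf_sigma_px > 0:
        rot = ndi.gaussian_filter(rot, sigma=(psf_sigma_px, psf_sigma_px, 0.0))
    box = max(1, int(round(z_spacing_um / vs)))
    if box > 1:
        rot = ndi.uniform_filter1d(rot, size=box, axis=2)

    cz_um = (nz - 1) / 2.0 * vs
    cs = (n_slices - 1) / 2.0
    # slice k sits at z = cz + (k - cs) * spacing + offset (micrometres)
    step_vox = z_spacing_um / vs
    z0_vox = (cz_um + (0 - cs) * z_spacing_um + axis_z_offset_um) / vs
    data = ndi.affine_transform(
        rot,
        np.diag([1.0, 1.0, step_vox]),
        offset=np.array([0.0, 0.0, z0_vox]),
        order=1,
        prefilter=False,
        output_shape=(ny, nx, n_slices),
        mode="constant",
        cval=0.0,
        output=np.float32,
    )
    return SpimStack(
        data=data,
        z_spacing_um=z_spacing_um,
        angle_deg=theta_deg % 360.0,
        pixel_size_um=vs,
        meta={"axis_z_offset_um": axis_z_offset_um},
    )
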