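"""Multimodal and time-lapse registration onto the tomographic frame.

The tomographic volume is centred on the rotation axis, while a fluorescence
SPIM stack shares the tomogram's x/y axes (same detector) but has an unknown
offset along the detection axis.  Acquiring the fluorescent sample from two
views 90 degrees apart makes that offset observable: the second stack, axis
permuted so its stack axis maps onto the reference's x axis, matches the
reference up to a 1D translation along z whose optimum (by normalised cross
correlation) locates the rotation axis.

Spherical landmarks (zebrafish eye lenses are near-perfect spheres of high
contrast) are detected with a gradient-direction Hough vote and used to build
rigid transforms that map every time point of a time-lapse onto a common
anatomical reference, so a fixed section index addresses homologous anatomy
across time.  A seeded region-growing segmenter bounded by local gradient
magnitude supports organ volume measurements.

Point coordinates follow ``(x, y, z)`` order in voxel units (array index
``[y, x, z]``) unless stated otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage as ndi

from .simulate import SpimStack, Volume

__all__ = [
    "SpimStack",
    "SphereDetection",
    "RigidTransform",
    "MultichannelVolume",
    "SegmentationResult",
    "TimelapseRegistration",
    "align_spim_z",
    "fuse_multimodal",
    "detect_spheres",
    "eye_landmark_transform",
    "intensity_dorsal_hint",
    "register_timelapse",
    "segment_region",
]

# array index (y, x, z)  <->  coordinate vector (x, y, z)
_P_IDX_TO_XYZ = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class SphereDetection:
    """One detected sphere: sub-voxel ``center`` in (x, y, z) voxels,
    ``radius`` in voxels and a positive detection ``score``."""

    center: np.ndarray
    radius: float
    score: float

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        if self.center.shape != (3,):
            raise ValueError("center must be a 3-vector")
        if self.score <= 0:
            raise ValueError("score must be positive")


@dataclass
class RigidTransform:
    """Proper rigid motion ``p -> rotation @ p + translation`` on (x, y, z)
    points.  ``residual`` optionally records the landmark misfit."""

    rotation: np.ndarray
    translation: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=np.float64)
        self.translation = np.asarray(self.translation, dtype=np.float64)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal")
        if not math.isclose(float(np.linalg.det(self.rotation)), 1.0, abs_tol=1e-9):
            raise ValueError("rotation determinant must be +1 (no reflections)")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
        out = pts @ self.rotation.T + self.translation
        return out[0] if np.asarray(points).ndim == 1 else out

    def inverse(self) -> "RigidTransform":
        rt = self.rotation.T
        return RigidTransform(rt, -rt @ self.translation)

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )


@dataclass
class MultichannelVolume:
    """Geometrically congruent channels on one isotropic grid."""

    channels: dict[str, np.ndarray]
    voxel_size_um: float
    meta: dict = field(default_factory=dict)


@dataclass
class SegmentationResult:
    """Region-growing output: boolean ``mask``, voxel count and metric
    volume."""

    mask: np.ndarray
    n_voxels: int
    volume_um3: float


@dataclass
class TimelapseRegistration:
    """Registered series: per-time-point volumes in the reference frame,
    transforms (``None`` where landmark detection failed) and failure flags."""

    volumes: list[Volume]
    transforms: list[RigidTransform | None]
    failed: list[bool]


# ---------------------------------------------------------------------------
# SPIM <-> tomography alignment
# ---------------------------------------------------------------------------


def resample_isotropic(stack: SpimStack) -> np.ndarray:
    """Resample the stack axis to the lateral pixel size (linear
    interpolation), keeping the stack centre fixed."""
    data = np.asarray(stack.data, dtype=np.float32)
    ratio = stack.z_spacing_um / stack.pixel_size_um
    if abs(ratio - 1.0) < 1e-9:
        return data
    ns = data.shape[2]
    n_out = max(1, int(round((ns - 1) * ratio)) + 1)
    c_in = (ns - 1) / 2.0
    c_out = (n_out - 1) / 2.0
    return ndi.affine_transform(
        data,
        np.diag([1.0, 1.0, 1.0 / ratio]),
        offset=np.array([0.0, 0.0, c_in - c_out / ratio]),
        order=1,
        prefilter=False,
        output_shape=(data.shape[0], data.shape[1], n_out),
        mode="constant",
        cval=0.0,
        output=np.float32,
    )


def _center_crop(a: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    slices = []
    for n, m in zip(a.shape, shape):
        lo = (n - m) // 2
        slices.append(slice(lo, lo + m))
    return a[tuple(slices)]


def align_spim_z(
    ref: SpimStack,
    rot: SpimStack,
    max_shift_um: float | None = None,
    min_corr: float = 0.2,
) -> float:
    """Recover the stack-centre offset from the rotation axis along the
    detection axis, in micrometres.

    ``ref`` and ``rot`` are stacks of the same fluorescent sample acquired 90
    degrees apart (``rot`` at ``ref.angle_deg + 90`` or ``- 90``).  Both are
    resampled to isotropic voxels and ``rot`` is axis-permuted so its stack
    axis maps onto the reference's x axis.  Because the two stacks share the
    stage protocol, the unknown offset displaces the reference along its stack
    (z) axis and the permuted stack along the reference's x axis by the same
    amount, so the residual misregistration is a one-parameter translation
    along the transverse diagonal.  Normalised cross-correlation over that
    single shift, refined parabolically, gives the stack-centre offset from
    the rotation axis (for the reference view; swapping the arguments negates
    the result).  Raises if the peak correlation falls below ``min_corr``
    (insufficient mutual structure).
    """
    dtheta = (rot.angle_deg - ref.angle_deg) % 360.0
    if abs(dtheta - 90.0) < 1e-6:
        forward = True
    elif abs(dtheta - 270.0) < 1e-6:
        forward = False
    else:
        raise ValueError(
            f"rot stack must be +-90 degrees from ref (got {dtheta:.2f})"
        )
    g0 = resample_isotropic(ref)
    g90 = resample_isotropic(rot)
    if forward:
        # stack axis -> -x, camera x -> z (rotation by +90 about y)
        h = np.flip(np.transpose(g90, (0, 2, 1)), axis=1)
        sx, sz = 1, 1
    else:
        # stack axis -> +x, camera x -> -z
        h = np.flip(np.transpose(g90, (0, 2, 1)), axis=2)
        sx, sz = -1, 1
    common = tuple(min(a, b) for a, b in zip(g0.shape, h.shape))
    g0c = _center_crop(g0, common)
    hc = _center_crop(h, common)

    _, nx, nz = common
    if max_shift_um is None:
        max_u = max(1, min(nx, nz) // 2 - 1)
    else:
        max_u = max(
            1,
            min(min(nx, nz) - 2, int(round(max_shift_um / ref.pixel_size_um)) + 2),
        )
    shifts = np.arange(-max_u, max_u + 1)
    corr = np.full(len(shifts), -2.0)
    for j, u in enumerate(shifts):
        ux, uz = sx * int(u), sz * int(u)
        a = g0c[:, max(ux, 0) : nx + min(ux, 0), max(uz, 0) : nz + min(uz, 0)]
        b = hc[:, max(-ux, 0) : nx - max(ux, 0), max(-uz, 0) : nz - max(uz, 0)]
        if a.size == 0:
            continue
        av = a - a.mean()
        bv = b - b.mean()
        denom = float(np.sqrt((av * av).sum() * (bv * bv).sum()))
        if denom == 0:
            continue
        corr[j] = float((av * bv).sum()) / denom
    i = int(np.argmax(corr))
    if corr[i] < min_corr:
        raise ValueError(
            f"insufficient mutual structure: peak correlation {corr[i]:.3f} "
            f"below {min_corr}"
        )
    # parabolic sub-voxel peak
    if 0 < i < len(shifts) - 1 and corr[i - 1] > -2 and corr[i + 1] > -2:
        denom = corr[i - 1] - 2 * corr[i] + corr[i + 1]
        delta = 0.5 * (corr[i - 1] - corr[i + 1]) / denom if denom < 0 else 0.0
    else:
        delta = 0.0
    u_star = float(shifts[i]) + delta
    # for the forward geometry the matching shift is u* = -offset / voxel
    sign = -1.0 if forward else 1.0
    return float(sign * u_star * ref.pixel_size_um)


def fuse_multimodal(
    tomo: Volume, spim: SpimStack, z_offset_um: float
) -> MultichannelVolume:
    """Resample a SPIM stack onto the tomographic grid.

    x and y are inherently aligned (same detector); slice ``k`` of the stack
    sits at ``(k - (n-1)/2) * z_spacing + z_offset`` micrometres from the
    rotation axis along z.  Returns one channel per modality on the tomogram's
    isotropic grid.  Raises when the transformed stack does not overlap the
    tomographic volume.
    """
    ny, nx, nz = tomo.voxels.shape
    vs = tomo.voxel_size_um
    sdata = np.asarray(spim.data, dtype=np.float32)
    sy, sx, ns = sdata.shape

    sy_c, sx_c = (sy - 1) / 2.0, (sx - 1) / 2.0
    ty_c, tx_c = (ny - 1) / 2.0, (nx - 1) / 2.0
    cs = (ns - 1) / 2.0
    czv = (nz - 1) / 2.0
    lat = vs / spim.pixel_size_um
    # tomo index (y, x, z) -> stack index (y', x', k), with
    # k(z) = ((z - czv) * vs - z_offset) / z_spacing + cs
    matrix = np.diag([lat, lat, vs / spim.z_spacing_um])
    offset = np.array(
        [
            sy_c - ty_c * lat,
            sx_c - tx_c * lat,
            cs - (czv * vs + z_offset_um) / spim.z_spacing_um,
        ]
    )

    k_lo = ((0 - czv) * vs - z_offset_um) / spim.z_spacing_um + cs
    k_hi = ((nz - 1 - czv) * vs - z_offset_um) / spim.z_spacing_um + cs
    if max(k_lo, k_hi) < 0 or min(k_lo, k_hi) > ns - 1:
        raise ValueError("SPIM stack does not overlap the tomographic volume")

    fluo = ndi.affine_transform(
        sdata,
        matrix,
        offset=offset,
        order=1,
        prefilter=False,
        output_shape=(ny, nx, nz),
        mode="constant",
        cval=0.0,
        output=np.float32,
    )
    return MultichannelVolume(
        channels={"tomography": tomo.voxels, "fluorescence": fluo},
        voxel_size_um=vs,
        meta={"z_offset_um": z_offset_um, "spim_angle_deg": spim.angle_deg},
    )


# ---------------------------------------------------------------------------
# sphere detection (gradient-direction Hough vote)
# ---------------------------------------------------------------------------


def detect_spheres(
    vol: "Volume | np.ndarray",
    r_min: float,
    r_max: float,
    n_best: int = 2,
    edge_threshold: float = 0.2,
    radius_step: float = 1.0,
) -> list[SphereDetection]:
    """Detect bright spheres by gradient-direction Hough voting.

    Voxels whose gradient magnitude exceeds ``edge_threshold`` times the
    maximum vote (weighted by the magnitude) at positions displaced along the
    gradient direction -- towards increasing intensity, i.e. towards the
    centre of a bright sphere -- for every radius in ``[r_min, r_max]``.
    Accumulators are smoothed, normalised by ``r^2`` (the expected number of
    edge voxels grows with the surface area) and scanned for peaks with
    non-maximum suppression at minimum separation ``r_min``.  At most
    ``n_best`` detections are returned in descending score order; centres are
    refined to sub-voxel precision by a local centroid and radii by parabolic
    interpolation.  A featureless volume yields an empty list.
    """
    if not 0 < r_min < r_max:
        raise ValueError("need 0 < r_min < r_max")
    v = vol.voxels if isinstance(vol, Volume) else np.asarray(vol)
    v = v.astype(np.float32, copy=False)
    gy, gx, gz = np.gradient(v)
    mag = np.sqrt(gy**2 + gx**2 + gz**2)
    mmax = float(mag.max())
    if mmax == 0.0:
        return []
    sel = mag > edge_threshold * mmax
    pts = np.argwhere(sel).astype(np.float64)  # (N, 3) index order (y, x, z)
    if len(pts) == 0:
        return []
    w = mag[sel].astype(np.float64)
    dirs = np.stack([g[sel] for g in (gy, gx, gz)], axis=1) / w[:, None]

    radii = np.arange(r_min, r_max + radius_step / 2, radius_step, dtype=np.float64)
    shape = v.shape
    score = np.zeros((len(radii),) + shape, dtype=np.float32)
    for ri, r in enumerate(radii):
        centers = np.rint(pts + r * dirs).astype(np.int64)
        ok = np.all((centers >= 0) & (centers < np.array(shape)), axis=1)
        c = centers[ok]
        np.add.at(score[ri], (c[:, 0], c[:, 1], c[:, 2]), w[ok].astype(np.float32))
        score[ri] = ndi.gaussian_filter(score[ri], 1.0) / np.float32(r * r)

    raw_score = score.copy()
    detections: list[SphereDetection] = []
    min_sep = max(2.0, float(r_min))
    for _ in range(n_best):
        flat = int(np.argmax(score))
        peak = np.unravel_index(flat, score.shape)
        val = float(score[peak])
        if val <= 0:
            break
        ri, py, px, pz = peak
        # sub-voxel centre: weighted centroid over a 3^3 neighbourhood
        lo = np.maximum(np.array([py, px, pz]) - 1, 0)
        hi = np.minimum(np.array([py, px, pz]) + 2, np.array(shape))
        win = raw_score[ri][lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        wpos = np.clip(win, 0.0, None)
        grid = np.mgrid[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]].astype(np.float64)
        tot = float(wpos.sum())
        if tot > 0:
            cyxz = np.array([float((g * wpos).sum()) / tot for g in grid])
        else:
            cyxz = np.array([py, px, pz], dtype=np.float64)
        # radius refinement across the radius dimension at the peak voxel
        if 0 < ri < len(radii) - 1:
            y0, y1, y2 = (float(raw_score[j, py, px, pz]) for j in (ri - 1, ri, ri + 1))
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
            radius = float(radii[ri] + np.clip(delta, -1, 1) * radius_step)
        else:
            radius = float(radii[ri])
        detections.append(
            SphereDetection(center=cyxz[[1, 0, 2]], radius=radius, score=val)
        )
        # suppress a ball of radius min_sep around the peak, at all radii
        sl = tuple(
            slice(max(0, int(p - min_sep)), min(n, int(p + min_sep) + 1))
            for p, n in zip((py, px, pz), shape)
        )
        score[(slice(None),) + sl] = 0.0
    return detections


# ---------------------------------------------------------------------------
# landmark-based rigid registration
# ---------------------------------------------------------------------------


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = float(np.linalg.norm(v))
    if n < 1e-12:
        raise ValueError(f"degenerate {what} (zero length)")
    return v / n


def _landmark_frame(eyes: np.ndarray, dorsal_hint: np.ndarray) -> np.ndarray:
    """Right-handed orthonormal frame from the eye pair and a dorsal hint."""
    e1 = _unit(eyes[1] - eyes[0], "eye axis (coincident eyes?)")
    d = np.asarray(dorsal_hint, dtype=np.float64)
    d_perp = d - np.dot(d, e1) * e1
    e2 = _unit(d_perp, "dorsal hint (parallel to the eye axis?)")
    e3 = np.cross(e1, e2)
    return np.column_stack([e1, e2, e3])


def eye_landmark_transform(
    eyes_t: np.ndarray,
    eyes_ref: np.ndarray,
    dorsal_hint_t: np.ndarray,
    dorsal_hint_ref: np.ndarray,
) -> RigidTransform:
    """Rigid transform mapping a time point's eye landmarks onto a reference.

    The transform sends the eye midpoint to the reference midpoint, the
    eye-to-eye axis onto the reference eye axis, and the dorsal hint (which
    fixes the remaining rotation about the inter-eye axis) onto the reference
    dorsal direction.  Eye ordering matters: ``eyes_t[i]`` corresponds to
    ``eyes_ref[i]``.  The transform is rigid even if the eye separation has
    changed (growth); the residual then equals half the separation mismatch.
    """
    eyes_t = np.asarray(eyes_t, dtype=np.float64).reshape(2, 3)
    eyes_ref = np.asarray(eyes_ref, dtype=np.float64).reshape(2, 3)
    f_t = _landmark_frame(eyes_t, dorsal_hint_t)
    f_ref = _landmark_frame(eyes_ref, dorsal_hint_ref)
    rotation = f_ref @ f_t.T
    mid_t = eyes_t.mean(axis=0)
    mid_ref = eyes_ref.mean(axis=0)
    translation = mid_ref - rotation @ mid_t
    mapped = eyes_t @ rotation.T + translation
    residual = float(np.mean(np.linalg.norm(mapped - eyes_ref, axis=1)))
    return RigidTransform(rotation, translation, residual=residual)


def intensity_dorsal_hint(vol: "Volume | np.ndarray", eyes: np.ndarray) -> np.ndarray:
    """Default third registration constraint: the offset of the volume's
    intensity centroid from the eye midpoint, in (x, y, z) voxels.

    Any anatomical asymmetry (the body relative to the eye pair) keeps this
    direction stable across time points.
    """
    v = vol.voxels if isinstance(vol, Volume) else np.asarray(vol)
    v = np.clip(v.astype(np.float64), 0.0, None)
    tot = float(v.sum())
    if tot <= 0:
        raise ValueError("volume has no positive intensity for a dorsal hint")
    cy, cx, cz = ndi.center_of_mass(v)
    centroid = np.array([cx, cy, cz])
    mid = np.asarray(eyes, dtype=np.float64).reshape(2, 3).mean(axis=0)
    return centroid - mid


def _resample_rigid(vol: Volume, transform: RigidTransform) -> Volume:
    """Resample ``vol`` into the reference frame of ``transform`` (which maps
    this volume's coordinates onto the reference's, in voxel units)."""
    inv = transform.inverse()
    # index-space affine: idx_in = P @ (R_inv @ (P @ idx_out) + t_inv)
    a = _P_IDX_TO_XYZ @ inv.rotation @ _P_IDX_TO_XYZ
    b = _P_IDX_TO_XYZ @ inv.translation
    out = ndi.affine_transform(
        vol.voxels.astype(np.float32, copy=False),
        a,
        offset=b,
        order=1,
        prefilter=False,
        mode="constant",
        cval=0.0,
        output=np.float32,
    )
    return Volume(out, vol.voxel_size_um, meta=dict(vol.meta))


def _pair_eyes(
    dets: Sequence[SphereDetection],
    vol: Volume,
    ref_eyes: np.ndarray | None,
    ref_hint: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, RigidTransform | None]:
    eyes = np.array([d.center for d in dets[:2]])
    hint = intensity_dorsal_hint(vol, eyes)
    if ref_eyes is None:
        # canonical ordering for the reference: ascending x, then y
        order = np.lexsort((eyes[:, 1], eyes[:, 0]))
        return eyes[order], hint, None
    best = None
    for order in ((0, 1), (1, 0)):
        cand = eyes[list(order)]
        t = eye_landmark_transform(cand, ref_eyes, hint, ref_hint)
        angle = math.acos(min(1.0, max(-1.0, (np.trace(t.rotation) - 1.0) / 2.0)))
        if best is None or angle < best[0]:
            best = (angle, cand, t)
    return best[1], hint, best[2]


def register_timelapse(
    volumes: Sequence[Volume],
    detections: Sequence[Sequence[SphereDetection]] | None = None,
    r_min: float = 5.0,
    r_max: float = 20.0,
) -> TimelapseRegistration:
    """Register a time series of volumes onto the first time point.

    Eye landmarks are taken from ``detections`` (two per time point) or found
    with :func:`detect_spheres`; the dorsal hint is the intensity-centroid
    offset from the eye midpoint.  Each volume is rigidly resampled into the
    reference frame, so a fixed section index addresses the same anatomy at
    every time point.  Eye correspondence is chosen as the pairing giving the
    smaller rotation (assumes inter-frame motion below 90 degrees).  Time
    points where detection fails are flagged and passed through untouched.
    """
    if len(volumes) == 0:
        raise ValueError("need at least one time point")
    if detections is None:
        detections = [
            detect_spheres(v, r_min=r_min, r_max=r_max, n_best=2) for v in volumes
        ]
    ref_dets = detections[0]
    if len(ref_dets) < 2:
        raise ValueError("could not detect two eye landmarks in the reference volume")
    ref_eyes, ref_hint, _ = _pair_eyes(ref_dets, volumes[0], None, None)

    out_volumes: list[Volume] = [volumes[0]]
    transforms: list[RigidTransform | None] = [RigidTransform.identity()]
    failed = [False]
    for t in range(1, len(volumes)):
        dets = detections[t]
        if len(dets) < 2:
            out_volumes.append(volumes[t])
            transforms.append(None)
            failed.append(True)
            continue
        _, _, transform = _pair_eyes(dets, volumes[t], ref_eyes, ref_hint)
        out_volumes.append(_resample_rigid(volumes[t], transform))
        transforms.append(transform)
        failed.append(False)
    return TimelapseRegistration(out_volumes, transforms, failed)


# ---------------------------------------------------------------------------
# gradient-bounded region growing
# ---------------------------------------------------------------------------


def segment_region(
    vol: Volume,
    seed: Sequence[float],
    gradient_threshold: float,
) -> SegmentationResult:
    """Semi-automatic segmentation by gradient-bounded region growing.

    Starting from ``seed`` (x, y, z voxels), 26-connected voxels whose local
    gradient stays below ``gradient_threshold`` are accepted.  The local
    gradient is the intensity range over the voxel's 26-neighbourhood
    (morphological gradient), which matches the growth connectivity so the
    region cannot leak diagonally across an intensity edge.  The grown region
    is then dilated by one voxel so the mask boundary sits at the middle of
    the gradient shell rather than inside it.  Returns the mask, voxel count
    and metric volume (count times the voxel volume).

    ``gradient_threshold = 0`` returns the seed voxel alone.  A seed on a
    high-gradient voxel raises (re-seed inside a homogeneous region).
    """
    v = vol.voxels.astype(np.float32, copy=False)
    sx, sy, sz = (int(round(c)) for c in seed)
    idx = (sy, sx, sz)
    ny, nx, nz = v.shape
    if not (0 <= sy < ny and 0 <= sx < nx and 0 <= sz < nz):
        raise ValueError(f"seed {tuple(seed)} outside the volume")
    vox3 = vol.voxel_size_um**3
    if gradient_threshold < 0:
        raise ValueError("gradient_threshold must be >= 0")
    if gradient_threshold == 0:
        mask = np.zeros(v.shape, dtype=bool)
        mask[idx] = True
        return SegmentationResult(mask, 1, vox3)
    mag = ndi.maximum_filter(v, size=3) - ndi.minimum_filter(v, size=3)
    if mag[idx] >= gradient_threshold:
        raise ValueError(
            "seed lies on a high-gradient voxel; choose a seed inside a "
            "homogeneous region or raise the threshold"
        )
    allowed = mag < gradient_threshold
    labels, _ = ndi.label(allowed, structure=np.ones((3, 3, 3), dtype=bool))
    mask = labels == labels[idx]
    # the gradient stencil flags voxels one step inside the true edge; one
    # dilation puts the mask boundary at the middle of the gradient shell
    mask = ndi.binary_dilation(mask, structure=np.ones((3, 3, 3), dtype=bool))
    n = int(mask.sum())
    return SegmentationResult(mask, n, n * vox3)
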