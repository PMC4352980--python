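"""Extended-depth-of-field fusion of through-focus transmission stacks.

During a spiral acquisition every projection angle is visited once per
rotation, each time at a different focal depth.  The frames of one angle form
a through-focus stack; fusing them with focus-dependent weights yields a
single projection with extended depth of field, cutting the stored data by a
factor equal to the number of rotations.

The focus measure is a difference-of-Gaussian high-pass: the squared response
of ``image - gaussian(image, hp_sigma)``, smoothed with a Gaussian of
``smooth_sigma``.  Per-pixel weights are the focus measure plus a small
``eps`` (a fraction of the stack's mean squared high-pass response) so that
texture-free pixels degrade gracefully to the plain mean.  The fusion is a
convex combination: every fused pixel lies within the range spanned by the
stack at that pixel, and scaling all frames by ``c > 0`` scales the fusion by
``c``.

``stream_fuse`` consumes the frame stream in acquisition order while keeping
only per-angle accumulation buffers, mirroring the real-time processing on
the microscope; it is bit-identical to grouping first and fusing per group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
from scipy import ndimage as ndi

from .simulate import Frame, OpticsParams, SpiralParams

__all__ = [
    "AngleGroup",
    "ProjectionSet",
    "group_by_angle",
    "focus_weight",
    "fuse_group",
    "stream_fuse",
]

DEFAULT_HP_SIGMA = 2.0
DEFAULT_SMOOTH_SIGMA = 4.0
#: auto-eps: this fraction of the stack's mean squared high-pass response
EPS_FRACTION = 1e-3


@dataclass
class AngleGroup:
    """All frames sharing one projection angle, ordered by focal position."""

    angle_deg: float
    frames: list[Frame]

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("an angle group needs at least one frame")
        fz = [f.focal_z_um for f in self.frames]
        diffs = np.diff(fz)
        if len(fz) > 1 and not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise ValueError("focal_z must be strictly monotone within a group")


@dataclass
class ProjectionSet:
    """Per-angle extended-depth-of-field projections.

    ``data`` has shape ``(n_angles, ny, nx)`` with ``angles_deg`` ascending;
    there are exactly ``360 / angular_step_deg`` entries.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    angular_step_deg: float
    pixel_size_um: float = 1.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.angles_deg = np.asarray(self.angles_deg, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.angles_deg):
            raise ValueError("data must be (n_angles, ny, nx) matching angles_deg")
        n_expected = int(round(360.0 / self.angular_step_deg))
        if self.data.shape[0] != n_expected:
            raise ValueError(
                f"expected {n_expected} projections for a {self.angular_step_deg} deg "
                f"step, got {self.data.shape[0]}"
            )

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    def projection(self, angle_deg: float) -> np.ndarray:
        idx = int(round((angle_deg % 360.0) / self.angular_step_deg)) % self.n_angles
        return self.data[idx]


def group_by_angle(
    frames: Iterable[Frame], spiral: SpiralParams
) -> list[AngleGroup]:
    """Partition a spiral frame stream into per-angle through-focus groups.

    The grouping key is ``round(angle / angular_step) mod frames_per_rotation``,
    so the result does not depend on the order in which frames arrive.  The
    stream must contain each frame index ``0 .. total_frames - 1`` exactly
    once; a missing or duplicated index raises with the offending index named.
    """
    fpr = spiral.frames_per_rotation
    n_expected = spiral.total_frames
    buckets: dict[int, list[Frame]] = {k: [] for k in range(fpr)}
    seen = np.zeros(n_expected, dtype=bool)
    for frame in frames:
        if not 0 <= frame.index < n_expected:
            raise ValueError(f"frame index {frame.index} outside 0..{n_expected - 1}")
        if seen[frame.index]:
            raise ValueError(f"duplicate frame index {frame.index}")
        seen[frame.index] = True
        key = int(round(frame.angle_deg / spiral.angular_step_deg)) % fpr
        buckets[key].append(frame)
    if not seen.all():
        missing = int(np.flatnonzero(~seen)[0])
        raise ValueError(f"missing frame index {missing}")
    groups = []
    for k in range(fpr):
        ordered = sorted(buckets[k], key=lambda f: f.focal_z_um)
        groups.append(AngleGroup(angle_deg=k * spiral.angular_step_deg, frames=ordered))
    return groups


def _highpass(image: np.ndarray, hp_sigma: float) -> np.ndarray:
    img = np.asarray(image, dtype=np.float32)
    return img - ndi.gaussian_filter(img, hp_sigma)


def focus_weight(
    image: np.ndarray,
    hp_sigma: float = DEFAULT_HP_SIGMA,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
) -> np.ndarray:
    """Non-negative per-pixel focus measure.

    Squared response of a difference-of-Gaussian high-pass filter, smoothed
    with a Gaussian.  Zero for constant images and invariant to adding a
    constant offset.
    """
    if hp_sigma <= 0 or smooth_sigma <= 0:
        raise ValueError("hp_sigma and smooth_sigma must be positive")
    hp = _highpass(image, hp_sigma)
    w = ndi.gaussian_filter(hp * hp, smooth_sigma)
    np.clip(w, 0.0, None, out=w)  # guard tiny negatives from the separable kernel
    return w


class _FusionAccumulator:
    """Streaming weighted-average state for one angle.

    Accumulates ``sum(w_i * f_i)``, ``sum(w_i)``, ``sum(f_i)`` and the running
    mean squared high-pass response so that the group-level ``eps`` can be
    applied at finalisation:

        fused = (sum(w f) + eps * sum(f)) / (sum(w) + n * eps)

    Identical arithmetic is used by the batch and streaming paths, which makes
    them bit-identical.
    """

    __slots__ = ("hp_sigma", "smooth_sigma", "eps", "sum_wf", "sum_w", "sum_f",
                 "sum_msr", "n")

    def __init__(self, hp_sigma: float, smooth_sigma: float, eps) -> None:
        self.hp_sigma = hp_sigma
        self.smooth_sigma = smooth_sigma
        self.eps = eps
        self.sum_wf = None
        self.sum_w = None
        self.sum_f = None
        self.sum_msr = 0.0
        self.n = 0

    def add(self, pixels: np.ndarray) -> None:
        img = np.asarray(pixels, dtype=np.float32)
        hp = _highpass(img, self.hp_sigma)
        w = ndi.gaussian_filter(hp * hp, self.smooth_sigma)
        np.clip(w, 0.0, None, out=w)
        if self.sum_wf is None:
            self.sum_wf = w * img
            self.sum_w = w.copy()
            self.sum_f = img.copy()
        else:
            self.sum_wf += w * img
            self.sum_w += w
            self.sum_f += img
        self.sum_msr += float(np.mean(hp * hp, dtype=np.float64))
        self.n += 1

    def result(self) -> np.ndarray:
        if self.n == 0:
            raise ValueError("cannot fuse an empty group")
        if self.eps == "auto":
            eps = np.float32(EPS_FRACTION * self.sum_msr / self.n)
        else:
            eps = np.float32(self.eps)
        denom = self.sum_w + self.n * eps
        if eps > 0 and np.all(denom > 0):
            return (self.sum_wf + eps * self.sum_f) / denom
        # fully texture-free stack (or eps == 0): fall back to the plain mean
        # wherever the weights vanish
        mean = self.sum_f / np.float32(self.n)
        with np.errstate(invalid="ignore", divide="ignore"):
            fused = (self.sum_wf + eps * self.sum_f) / denom
        return np.where(denom > 0, fused, mean).astype(np.float32)


def fuse_group(
    group: AngleGroup,
    hp_sigma: float = DEFAULT_HP_SIGMA,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    eps="auto",
) -> np.ndarray:
    """Fuse one through-focus group into a single projection.

    Per-pixel weighted average with weights ``focus_weight + eps``; ``eps``
    defaults to ``1e-3`` times the group's mean squared high-pass response.
    A group of identical frames fuses to that frame exactly.
    """
    acc = _FusionAccumulator(hp_sigma, smooth_sigma, eps)
    for frame in group.frames:
        acc.add(frame.pixels)
    return acc.result()


def stream_fuse(
    frames: Iterable[Frame],
    spiral: SpiralParams,
    optics: OpticsParams | None = None,
    hp_sigma: float = DEFAULT_HP_SIGMA,
    smooth_sigma: float = DEFAULT_SMOOTH_SIGMA,
    eps="auto",
) -> ProjectionSet:
    """Fuse a spiral frame stream into per-angle projections on the fly.

    Holds one accumulator (three image-sized buffers) per angle and never the
    raw frames, mirroring the real-time routine on the acquisition machine.
    The achieved data reduction factor (input frames / output projections) is
    reported in ``ProjectionSet.meta['reduction_factor']``.
    """
    fpr = spiral.frames_per_rotation
    n_expected = spiral.total_frames
    accs: dict[int, _FusionAccumulator] = {}
    seen = np.zeros(n_expected, dtype=bool)
    n_in = 0
    for frame in frames:
        if not 0 <= frame.index < n_expected:
            raise ValueError(f"frame index {frame.index} outside 0..{n_expected - 1}")
        if seen[frame.index]:
            raise ValueError(f"duplicate frame index {frame.index}")
        seen[frame.index] = True
        key = int(round(frame.angle_deg / spiral.angular_step_deg)) % fpr
        acc = accs.get(key)
        if acc is None:
            acc = accs[key] = _FusionAccumulator(hp_sigma, smooth_sigma, eps)
        acc.add(frame.pixels)
        n_in += 1
    if not seen.all():
        missing = int(np.flatnonzero(~seen)[0])
        raise ValueError(f"missing frame index {missing}")
    data = np.stack([accs[k].result() for k in range(fpr)])
    angles = np.arange(fpr) * spiral.angular_step_deg
    meta = {
        "n_input_frames": n_in,
        "reduction_factor": n_in / fpr,
        "hp_sigma": hp_sigma,
        "smooth_sigma": smooth_sigma,
        "eps": eps,
    }
    if optics is not None:
        meta["optics"] = optics
    return ProjectionSet(
        data=data,
        angles_deg=angles,
        angular_step_deg=spiral.angular_step_deg,
        pixel_size_um=optics.pixel_size_um if optics is not None else 1.0,
        meta=meta,
    )
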