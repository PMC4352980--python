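"""On-disk formats: multi-page TIFF stacks with plain-JSON sidecars.

Every stack (raw frames, fused projections, reconstructed volumes, SPIM
stacks, masks) is a multi-page TIFF; its acquisition/processing metadata lives
in a JSON text file next to it (same stem, ``.json`` suffix) rather than in
TIFF tags, for toolchain portability.  Raw frames are 16-bit unsigned,
projections and volumes 32-bit float, masks 8-bit.

Round trips are lossless for the stored dtype; float frame buffers are
rounded to 16-bit counts on write, matching the camera format.
"""

from __future__ import annotations

import dataclasses
import json
import os
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import tifffile

from .edof import ProjectionSet
from .recon import AxisEstimate
from .simulate import Frame, OpticsParams, SpimStack, SpiralParams, Volume

__all__ = [
    "write_frames",
    "read_frames",
    "read_sidecar",
    "write_projections",
    "read_projections",
    "write_volume",
    "read_volume",
    "write_spim_stack",
    "read_spim_stack",
    "write_mask",
    "write_json_atomic",
]

FRAME_SIDECAR_KEYS = ("kind", "n_frames", "angles_deg", "focal_z_um", "spiral", "optics")


def _sidecar_path(path: os.PathLike) -> Path:
    return Path(path).with_suffix(".json")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    return obj


def write_json_atomic(path: os.PathLike, payload: dict) -> None:
    """Write JSON via a temporary file and rename, so readers never see a
    partial file."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(json.dumps(_jsonable(payload), indent=1, sort_keys=True))
    os.replace(tmp, path)


def _read_sidecar(path: Path, required: tuple[str, ...]) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing metadata sidecar {sidecar}; expected a JSON file with "
            f"keys: {', '.join(required)}"
        )
    meta = json.loads(sidecar.read_text())
    missing = [k for k in required if k not in meta]
    if missing:
        raise ValueError(f"sidecar {sidecar} lacks required keys: {', '.join(missing)}")
    return meta


def read_sidecar(path: os.PathLike) -> dict:
    """Load the JSON sidecar of any stack file."""
    return _read_sidecar(Path(path), ("kind",))


# ---------------------------------------------------------------------------
# frame streams
# ---------------------------------------------------------------------------


def write_frames(
    path: os.PathLike,
    frames: Iterable[Frame],
    spiral: SpiralParams,
    optics: OpticsParams,
    seed: int | None = None,
) -> Path:
    """Stream a spiral acquisition to a 16-bit multi-page TIFF plus sidecar.

    Float frame buffers are rounded and clipped to the camera's 16-bit range.
    Returns the sidecar path.
    """
    path = Path(path)
    angles: list[float] = []
    focal: list[float] = []
    n = 0
    with tifffile.TiffWriter(path) as tif:
        for frame in frames:
            pix = frame.pixels
            if pix.dtype != np.uint16:
                pix = np.clip(np.rint(pix), 0, 65535).astype(np.uint16)
            tif.write(pix, contiguous=True)
            angles.append(float(frame.angle_deg))
            focal.append(float(frame.focal_z_um))
            n += 1
    meta = {
        "kind": "frames",
        "n_frames": n,
        "angles_deg": angles,
        "focal_z_um": focal,
        "spiral": spiral,
        "optics": optics,
        "seed": seed,
    }
    sidecar = _sidecar_path(path)
    write_json_atomic(sidecar, meta)
    return sidecar


def read_frames(path: os.PathLike) -> Iterator[Frame]:
    """Lazily read a frame stream written by :func:`write_frames`.

    Raises if the sidecar is missing or the TIFF page count does not match the
    sidecar (truncated file).
    """
    path = Path(path)
    meta = _read_sidecar(path, FRAME_SIDECAR_KEYS)
    n = int(meta["n_frames"])
    with tifffile.TiffFile(path) as tif:
        n_pages = len(tif.pages)
        if n_pages != n:
            raise ValueError(
                f"{path} is truncated or inconsistent: expected {n} pages, "
                f"found {n_pages}"
            )
        for i in range(n):
            yield Frame(
                pixels=tif.pages[i].asarray(),
                angle_deg=float(meta["angles_deg"][i]),
                focal_z_um=float(meta["focal_z_um"][i]),
                index=i,
            )


def read_frames_params(path: os.PathLike) -> tuple[SpiralParams, OpticsParams]:
    """Recover the spiral and optics parameters from a frame sidecar."""
    meta = _read_sidecar(Path(path), FRAME_SIDECAR_KEYS)
    return (
        SpiralParams(**meta["spiral"]),
        OpticsParams(**meta["optics"]),
    )


# ---------------------------------------------------------------------------
# projections
# ---------------------------------------------------------------------------


def write_projections(path: os.PathLike, pset: ProjectionSet) -> Path:
    path = Path(path)
    tifffile.imwrite(path, pset.data.astype(np.float32))
    meta = {
        "kind": "projections",
        "n_projections": pset.n_angles,
        "angles_deg": pset.angles_deg,
        "angular_step_deg": pset.angular_step_deg,
        "pixel_size_um": pset.pixel_size_um,
        "meta": {k: v for k, v in pset.meta.items()},
    }
    sidecar = _sidecar_path(path)
    write_json_atomic(sidecar, meta)
    return sidecar


def read_projections(path: os.PathLike) -> ProjectionSet:
    path = Path(path)
    meta = _read_sidecar(
        path, ("kind", "n_projections", "angles_deg", "angular_step_deg")
    )
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != int(meta["n_projections"]):
        raise ValueError(
            f"{path}: expected {meta['n_projections']} pages, found {data.shape[0]}"
        )
    return ProjectionSet(
        data=data,
        angles_deg=np.asarray(meta["angles_deg"], dtype=np.float64),
        angular_step_deg=float(meta["angular_step_deg"]),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        meta=meta.get("meta", {}),
    )


# ---------------------------------------------------------------------------
# volumes and SPIM stacks
# ---------------------------------------------------------------------------


def write_volume(path: os.PathLike, vol: Volume) -> Path:
    """Write a volume as 32-bit float pages: page ``y`` is the transverse
    (x, z) section at that row."""
    path = Path(path)
    tifffile.imwrite(path, vol.voxels.astype(np.float32))
    meta = {
        "kind": "volume",
        "n_slices": vol.voxels.shape[0],
        "voxel_size_um": vol.voxel_size_um,
        "axes": "pages = transverse (x, z) sections indexed by y",
        "meta": {k: v for k, v in vol.meta.items()},
    }
    sidecar = _sidecar_path(path)
    write_json_atomic(sidecar, meta)
    return sidecar


def read_volume(path: os.PathLike) -> Volume:
    path = Path(path)
    meta = _read_sidecar(path, ("kind", "n_slices", "voxel_size_um"))
    voxels = tifffile.imread(path)
    if voxels.ndim == 2:
        voxels = voxels[None]
    if voxels.shape[0] != int(meta["n_slices"]):
        raise ValueError(
            f"{path}: expected {meta['n_slices']} pages, found {voxels.shape[0]}"
        )
    loaded = dict(meta.get("meta", {}))
    if isinstance(loaded.get("axis_estimate"), dict):
        d = loaded["axis_estimate"]
        loaded["axis_estimate"] = AxisEstimate(
            offset_x=float(d.get("offset_x", 0.0)),
            offsets_scanned=np.asarray(d.get("offsets_scanned", [])),
            metric=np.asarray(d.get("metric", [])),
            rows_used=tuple(d.get("rows_used", ())),
        )
    return Volume(voxels, float(meta["voxel_size_um"]), meta=loaded)


def write_spim_stack(path: os.PathLike, stack: SpimStack) -> Path:
    path = Path(path)
    # pages indexed by stack slice for viewer friendliness
    tifffile.imwrite(path, np.moveaxis(stack.data, 2, 0).astype(np.float32))
    meta = {
        "kind": "spim_stack",
        "n_slices": stack.n_slices,
        "z_spacing_um": stack.z_spacing_um,
        "angle_deg": stack.angle_deg,
        "pixel_size_um": stack.pixel_size_um,
        "meta": {k: v for k, v in stack.meta.items()},
    }
    sidecar = _sidecar_path(path)
    write_json_atomic(sidecar, meta)
    return sidecar


def read_spim_stack(path: os.PathLike) -> SpimStack:
    path = Path(path)
    meta = _read_sidecar(path, ("kind", "n_slices", "z_spacing_um", "angle_deg"))
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if data.shape[0] != int(meta["n_slices"]):
        raise ValueError(
            f"{path}: expected {meta['n_slices']} pages, found {data.shape[0]}"
        )
    return SpimStack(
        data=np.moveaxis(data, 0, 2),
        z_spacing_um=float(meta["z_spacing_um"]),
        angle_deg=float(meta["angle_deg"]),
        pixel_size_um=float(meta.get("pixel_size_um", 1.0)),
        meta=meta.get("meta", {}),
    )


def write_mask(path: os.PathLike, mask: np.ndarray, voxel_size_um: float) -> Path:
    path = Path(path)
    tifffile.imwrite(path, (np.asarray(mask) != 0).astype(np.uint8) * np.uint8(255))
    sidecar = _sidecar_path(path)
    write_json_atomic(
        sidecar,
        {
            "kind": "mask",
            "n_slices": int(np.asarray(mask).shape[0]),
            "voxel_size_um": voxel_size_um,
            "n_voxels": int(np.count_nonzero(mask)),
        },
    )
    return sidecar
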