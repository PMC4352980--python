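"""Pipeline configuration: a human-editable YAML file validated into the
domain parameter types before any computation starts.

Example
-------
::

    seed: 7
    voxel_size_um: 2.0
    phantom:
      extent_um: [256, 256, 256]
      primitives:
        - {shape: sphere, center_um: [100, 128, 128], semi_axes_um: [30, 30, 30],
           attenuation: 0.008, fluorescence: 1.0, label: left_eye}
    optics: {depth_of_field_um: 15.0, pixel_size_um: 2.0}
    spiral: {n_rotations: 20, angular_step_deg: 1.0, frames_per_rotation: 360,
             z_start_um: 0.0, z_end_um: 256.0}
    fusion: {hp_sigma: 2.0, smooth_sigma: 4.0}
    recon:  {filter_name: ramp, axis: auto, log: true}

Unset blocks fall back to the domain defaults.  ``to_dict``/``from_dict``
round-trip exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .simulate import OpticsParams, PhantomSpec, Primitive, SpiralParams

__all__ = [
    "FusionConfig",
    "ReconConfig",
    "SpimConfig",
    "PipelineConfig",
    "config_hash",
]


@dataclass(frozen=True)
class FusionConfig:
    hp_sigma: float = 2.0
    smooth_sigma: float = 4.0
    eps: "float | str" = "auto"

    def __post_init__(self) -> None:
        if self.hp_sigma <= 0 or self.smooth_sigma <= 0:
            raise ValueError("fusion sigmas must be positive")
        if self.eps != "auto" and float(self.eps) < 0:
            raise ValueError("eps must be 'auto' or >= 0")


@dataclass(frozen=True)
class ReconConfig:
    filter_name: str = "ramp"
    axis: "float | str" = "auto"
    log: bool = True
    axis_rows: int = 5
    search_range: float = 20.0
    search_step: float = 1.0

    def __post_init__(self) -> None:
        from .recon import FILTERS

        if self.filter_name not in FILTERS:
            raise ValueError(f"unknown filter {self.filter_name!r}")
        if self.axis != "auto":
            float(self.axis)
        if self.axis_rows < 1:
            raise ValueError("axis_rows must be >= 1")


@dataclass(frozen=True)
class SpimConfig:
    """Optional fluorescence stage: SPIM stacks at two views 90 degrees apart,
    aligned to the tomogram and overlaid."""

    z_spacing_um: float = 2.0
    axis_z_offset_um: float = 0.0
    angles_deg: tuple[float, float] = (0.0, 90.0)
    psf_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.z_spacing_um <= 0:
            raise ValueError("z_spacing_um must be positive")
        if len(self.angles_deg) != 2:
            raise ValueError("angles_deg must name exactly two views")
        if abs((self.angles_deg[1] - self.angles_deg[0]) % 360.0 - 90.0) > 1e-6:
            raise ValueError("the two SPIM views must be 90 degrees apart")


@dataclass(frozen=True)
class PipelineConfig:
    phantom: PhantomSpec
    optics: OpticsParams = OpticsParams()
    spiral: SpiralParams = SpiralParams()
    fusion: FusionConfig = FusionConfig()
    recon: ReconConfig = ReconConfig()
    spim: SpimConfig | None = None
    voxel_size_um: float = 2.0
    seed: int = 0
    output_dir: str = "spiraltomo_out"

    def __post_init__(self) -> None:
        if self.voxel_size_um <= 0:
            raise ValueError("voxel_size_um must be positive")

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        def plain(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: plain(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            return obj

        d = plain(self)
        d["phantom"] = {
            "extent_um": list(self.phantom.extent_um),
            "primitives": [plain(p) for p in self.phantom.primitives],
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        ph = d["phantom"]
        phantom = PhantomSpec(
            primitives=[
                Primitive(
                    shape=p["shape"],
                    center_um=tuple(p["center_um"]),
                    semi_axes_um=tuple(p["semi_axes_um"]),
                    attenuation=float(p.get("attenuation", 0.0)),
                    fluorescence=float(p.get("fluorescence", 0.0)),
                    label=p.get("label", ""),
                )
                for p in ph["primitives"]
            ],
            extent_um=tuple(ph["extent_um"]),
        )
        spim = d.get("spim")
        if spim is not None:
            spim = SpimConfig(
                z_spacing_um=float(spim.get("z_spacing_um", 2.0)),
                axis_z_offset_um=float(spim.get("axis_z_offset_um", 0.0)),
                angles_deg=tuple(spim.get("angles_deg", (0.0, 90.0))),
                psf_sigma_px=float(spim.get("psf_sigma_px", 1.0)),
            )
        return cls(
            phantom=phantom,
            optics=OpticsParams(**d.get("optics", {})),
            spiral=SpiralParams(**d.get("spiral", {})),
            fusion=FusionConfig(**d.get("fusion", {})),
            recon=ReconConfig(**d.get("recon", {})),
            spim=spim,
            voxel_size_um=float(d.get("voxel_size_um", 2.0)),
            seed=int(d.get("seed", 0)),
            output_dir=str(d.get("output_dir", "spiraltomo_out")),
        )

    def to_yaml(self, path: os.PathLike) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: os.PathLike) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def config_hash(config: PipelineConfig) -> str:
    """Deterministic hash of the full configuration; changes iff any
    parameter changes."""
    blob = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
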