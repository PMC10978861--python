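"""End-to-end orchestration: body ROI -> boneness map -> graph-cut.

:class:`PipelineConfig` holds every tunable of the three phases (defaults
are the reference operating point: body threshold -400 HU, sigma 0.25,
lambda 100), serializes to/from YAML with unknown-key rejection, and every
run emits a provenance record (parameters, package version, input
checksums) so a segmentation can be reproduced bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import __version__
from .boneness import BonenessParams, bje_map
from .graphcut import GraphCutParams, mincut_segment
from .roi import segment_body
from .seeds import load_seeds
from .volume import BinaryMask, ImageVolume, SeedVolume, read_volume, write_volume

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "segment_volume"]


@dataclass
class PipelineConfig:
    """All parameters of the three-phase segmentation."""

    # paths (optional so the config can also drive in-memory runs)
    input_path: str | None = None
    seeds_path: str | None = None
    output_path: str | None = None
    save_boneness: bool = True

    # phase 1
    threshold_hu: float = -400.0
    roi_keep_largest: bool = True
    roi_fill_holes: bool = True

    # phase 2
    hessian_scale: float = 1.0
    t_convention: str = "sum"

    # phase 3
    sigma: float = 0.25
    lam: float = 100.0
    connectivity: int = 6
    lambda_in_exponent: bool = True
    lambda_in_energy: bool = True
    regional_as_capacity: bool = True
    keep_largest_component: bool = True
    solver: str = "auto"

    def graphcut_params(self) -> GraphCutParams:
        return GraphCutParams(
            sigma=self.sigma,
            lam=self.lam,
            connectivity=self.connectivity,
            lambda_in_exponent=self.lambda_in_exponent,
            lambda_in_energy=self.lambda_in_energy,
            regional_as_capacity=self.regional_as_capacity,
            keep_largest_component=self.keep_largest_component,
            solver=self.solver,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(
                f"unknown config keys: {sorted(unknown)}; known keys: {sorted(known)}"
            )
        return cls(**d)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        return cls.from_dict(d)


@dataclass
class PipelineResult:
    mask: BinaryMask
    roi: BinaryMask
    boneness: ImageVolume
    provenance: dict


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def segment_volume(vol: ImageVolume, seeds: SeedVolume,
                   config: PipelineConfig | None = None) -> PipelineResult:
    """Run the three phases on in-memory inputs."""
    if config is None:
        config = PipelineConfig()
    vol.require_same_grid(seeds, "seed image")
    roi = segment_body(vol, threshold_hu=config.threshold_hu,
                       keep_largest=config.roi_keep_largest,
                       fill_holes=config.roi_fill_holes).mask
    boneness = bje_map(vol, BonenessParams(hessian_scale=config.hessian_scale,
                                           roi=roi,
                                           t_convention=config.t_convention))
    mask = mincut_segment(boneness, seeds, roi=roi,
                          params=config.graphcut_params())
    provenance = {
        "software": {"name": "femurcut", "version": __version__},
        "parameters": config.to_dict(),
        "result": {"foreground_voxels": mask.count(),
                   "roi_voxels": roi.count()},
    }
    return PipelineResult(mask=mask, roi=roi, boneness=boneness,
                          provenance=provenance)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven pipeline run with provenance sidecar.

    Validates the configuration (paths exist) before any computation;
    writes the output mask, optionally the cached boneness map, and a
    ``<output>.provenance.json`` sidecar.
    """
    problems = []
    if not config.input_path:
        problems.append("input_path is not set")
    elif not os.path.exists(config.input_path):
        problems.append(f"input volume not found: {config.input_path}")
    if not config.seeds_path:
        problems.append("seeds_path is not set")
    elif not os.path.exists(config.seeds_path):
        problems.append(f"seed image not found: {config.seeds_path}")
    if not config.output_path:
        problems.append("output_path is not set")
    if problems:
        raise ValueError("invalid pipeline config: " + "; ".join(problems))

    vol = read_volume(config.input_path)
    seeds = load_seeds(config.seeds_path, vol)
    result = segment_volume(vol, seeds, config)
    result.provenance["inputs"] = {
        "volume": {"path": config.input_path, "sha256": _sha256(config.input_path)},
        "seeds": {"path": config.seeds_path, "sha256": _sha256(config.seeds_path)},
    }

    write_volume(result.mask, config.output_path)
    if config.save_boneness:
        stem, ext = _split_ext(config.output_path)
        write_volume(result.boneness, f"{stem}_bje{ext}")
    with open(f"{config.output_path}.provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2, sort_keys=True)
    return result


def _split_ext(path: str) -> tuple[str, str]:
    for ext in (".nii.gz", ".nii", ".mha", ".mhd", ".nrrd"):
        if path.endswith(ext):
            return path[: -len(ext)], ext
    stem, ext = os.path.splitext(path)
    return stem, ext
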