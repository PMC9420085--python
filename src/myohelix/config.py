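"""Run configuration for the end-to-end pipeline.

A :class:`RunConfig` gathers the parameter blocks of every stage (helix,
mask, noise, diffraction, indexing) plus the output directory and the
single seed from which all randomness flows.  Unknown keys are rejected and
the structure round-trips losslessly through YAML/JSON.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

from .helix import HelixParams, ParameterError
from .render import Motif
from .synth import NoiseModel

__all__ = ["ConfigError", "RunConfig"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass(frozen=True)
class MaskBlock:
    motif: str = "bunny_ears"
    nm_per_px: float = 1.0
    width_px: int = 120
    height_px: int = 1032
    lobe_length: float = 6.0
    lobe_width: float = 3.0
    dot_radius: float = 2.0

    def to_motif(self) -> Motif:
        return Motif(
            shape=self.motif,  # type: ignore[arg-type]
            lobe_length=self.lobe_length,
            lobe_width=self.lobe_width,
            dot_radius=self.dot_radius,
        )


@dataclass(frozen=True)
class DiffractionBlock:
    window: str = "none"
    min_prominence: float = 0.02
    max_order: int = 24


@dataclass(frozen=True)
class IndexingBlock:
    candidates: tuple[float, ...] = (72.0, 172.0)


def _build(cls, data: dict, label: str):
    unknown = set(data) - set(cls.__dataclass_fields__)
    if unknown:
        raise ConfigError(f"unknown key(s) in {label!r} block: {sorted(unknown)}")
    if cls is IndexingBlock and "candidates" in data:
        data = dict(data, candidates=tuple(data["candidates"]))
    try:
        return cls(**data)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(f"invalid {label!r} block: {exc}") from exc


@dataclass(frozen=True)
class RunConfig:
    helix: HelixParams = field(default_factory=HelixParams)
    mask: MaskBlock = field(default_factory=MaskBlock)
    noise: NoiseModel = field(default_factory=NoiseModel)
    diffraction: DiffractionBlock = field(default_factory=DiffractionBlock)
    indexing: IndexingBlock = field(default_factory=IndexingBlock)
    output_dir: str = "myohelix-run"
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "helix": self.helix.to_dict(),
            "mask": asdict(self.mask),
            "noise": self.noise.to_dict(),
            "diffraction": asdict(self.diffraction),
            "indexing": {"candidates": list(self.indexing.candidates)},
            "output_dir": self.output_dir,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {"helix", "mask", "noise", "diffraction", "indexing", "output_dir", "seed"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            helix = HelixParams.from_dict(data.get("helix", {}))
        except ParameterError as exc:
            raise ConfigError(f"invalid 'helix' block: {exc}") from exc
        try:
            noise = NoiseModel.from_dict(data.get("noise", {}))
        except ParameterError as exc:
            raise ConfigError(f"invalid 'noise' block: {exc}") from exc
        cfg = cls(
            helix=helix,
            mask=_build(MaskBlock, data.get("mask", {}), "mask"),
            noise=noise,
            diffraction=_build(
                DiffractionBlock, data.get("diffraction", {}), "diffraction"
            ),
            indexing=_build(IndexingBlock, data.get("indexing", {}), "indexing"),
            output_dir=str(data.get("output_dir", "myohelix-run")),
            seed=int(data.get("seed", 0)),
        )
        # the noise seed follows the run seed unless set explicitly
        if "noise" in data and "seed" in data["noise"]:
            return cfg
        return replace(cfg, noise=replace(cfg.noise, seed=cfg.seed))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]
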