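"""Run configuration: a schema-validated YAML surface over the library.

Unknown keys are rejected so that typos fail loudly before any work starts.
Every command writes a provenance record (config hash, seed, versions)
beside its outputs.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .model import DECODER_VARIANTS

__all__ = ["RunConfig", "load_config", "write_provenance"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ModelSection(_Strict):
    preset: str = Field("paper", pattern="^(paper|small|tiny|custom)$")
    stem_channels: int | None = Field(None, ge=1)
    kernel_N: int = Field(7, ge=3)
    kernel_small: int = Field(3, ge=1)
    use_shuffle: bool = True
    use_attention: bool = True
    decoder_variant: str = "feat3_guided_residual"
    decoder_widths: list[int] | None = None
    guide_widths: list[int] | None = None
    num_classes: int = Field(4, ge=2)

    def build(self):
        from .model import ModelConfig

        if self.preset == "paper":
            return ModelConfig.paper(
                decoder_variant=self.decoder_variant,
                kernel_N=self.kernel_N,
                use_shuffle=self.use_shuffle,
                num_classes=self.num_classes,
            )
        if self.preset in ("small", "tiny"):
            return getattr(ModelConfig, self.preset)(
                decoder_variant=self.decoder_variant, num_classes=self.num_classes
            )
        s = self.stem_channels
        if s is None:
            raise ValueError("custom preset requires stem_channels")
        return ModelConfig(
            stem_channels=s,
            stage_widths=(2 * s, 4 * s, 16 * s),
            kernel_N=self.kernel_N,
            kernel_small=self.kernel_small,
            use_shuffle=self.use_shuffle,
            use_attention=self.use_attention,
            decoder_variant=self.decoder_variant,
            decoder_widths=tuple(self.decoder_widths or (24, 96, 132, 28)),
            guide_widths=tuple(self.guide_widths or (96, 58)),
            num_classes=self.num_classes,
        )


class TrainSection(_Strict):
    initial_lr: float = Field(0.001, gt=0)
    batch_size: int = Field(4, ge=1)
    epochs: int = Field(400, ge=1)
    eval_every: int = Field(5, ge=1)
    target_miou: float | None = Field(None, gt=0, le=1)


class SceneSection(_Strict):
    size: int = Field(512, ge=32)
    n: int = Field(8, ge=1)
    soybean_fraction: float = Field(0.22, ge=0, le=1)
    graminoid_fraction: float = Field(0.08, ge=0, le=1)
    broadleaf_fraction: float = Field(0.10, ge=0, le=1)
    occlusion_rate: float = Field(0.3, ge=0, le=1)

    def spec(self, seed):
        from .synthetic import SceneSpec

        return SceneSpec(
            size=self.size,
            target_fractions={
                "soybean": self.soybean_fraction,
                "graminoid_weed": self.graminoid_fraction,
                "broadleaf_weed": self.broadleaf_fraction,
            },
            occlusion_rate=self.occlusion_rate,
            seed=seed,
        )


class DataSection(_Strict):
    image_dir: str | None = None
    annotation_dir: str | None = None
    crop_size: int = Field(512, ge=32)
    crops_per_image: int = Field(1, ge=1)


class RunConfig(_Strict):
    seed: int = 0
    output_dir: str = "runs"
    model: ModelSection = ModelSection()
    train: TrainSection = TrainSection()
    scene: SceneSection = SceneSection()
    data: DataSection = DataSection()


def load_config(path=None, **overrides) -> RunConfig:
    payload = {}
    if path is not None:
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
    for key, value in overrides.items():
        if value is None:
            continue
        section, _, name = key.partition(".")
        if name:
            payload.setdefault(section, {})[name] = value
        else:
            payload[key] = value
    return RunConfig(**payload)


def write_provenance(cfg: RunConfig, out_dir, extra=None):
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blob = cfg.model_dump_json()
    record = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "config": json.loads(blob),
        "seed": cfg.seed,
        "versions": {
            "dcsanet": __version__,
            "numpy": np.__version__,
            "python": platform.python_version(),
        },
    }
    if extra:
        record.update(extra)
    path = out / "provenance.json"
    with open(path, "w") as fh:
        json.dump(record, fh, indent=2)
    return path
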