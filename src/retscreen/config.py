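"""Run configuration: one YAML-serialisable tree covering the generator,
the patch grid, the encoder, the head, training and the robustness suite.

Two presets are provided:

* ``desk`` — a reduced-scale configuration (64x64 images, P=8, E=64, L=4,
  4 heads, fusion depths {2,4}) that trains in minutes on one CPU;
* ``full`` — the GPU-scale configuration (512x512, P=16, E=768, L=12,
  12 heads); included for completeness, not runnable at desk scale.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .encoder import EncoderConfig
from .evaluation import PerturbationSpec
from .preprocessing import PatchGrid
from .synthetic import SyntheticConfig, config_from_jsonable, _config_to_jsonable
from .training import AugmentationConfig, TrainConfig


def default_perturbations() -> tuple[PerturbationSpec, ...]:
    return (
        PerturbationSpec("brightness_down", (0.1, 0.3, 0.5)),
        PerturbationSpec("brightness_up", (0.1, 0.3, 0.5)),
        PerturbationSpec("contrast_down", (0.2, 0.4, 0.6)),
        PerturbationSpec("gaussian_blur", (0.5, 1.0, 2.0)),
        PerturbationSpec("gaussian_noise", (0.05, 0.1, 0.3)),
    )


@dataclass
class RunConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    target_size: int = 64
    patch_size: int = 8
    n_layers: int = 4
    embed_dim: int = 64
    n_heads: int = 4
    neighborhood_radius: int = 1
    alpha_mode: str = "fixed_linear"
    alpha_constant: float = 1.0
    fusion_depths: tuple = (2, 4)
    stabilized: bool = True
    use_positional: bool = True
    init_sd: float = 0.1
    head_dim: int = 32
    n_samples: int = 512
    split_fracs: tuple = (0.7, 0.1, 0.2)
    train: TrainConfig = field(default_factory=TrainConfig)
    perturbations: tuple = field(default_factory=default_perturbations)
    out_dir: str = "runs/latest"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.target_size % self.patch_size != 0:
            raise ValueError(
                f"target_size {self.target_size} must be divisible by "
                f"patch_size {self.patch_size}")
        if self.synthetic.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.synthetic.image_size} must be divisible "
                f"by patch_size {self.patch_size}")
        if max(self.fusion_depths) > self.n_layers:
            raise ValueError("fusion_depths must not exceed n_layers")

    @property
    def patch_grid(self) -> PatchGrid:
        return PatchGrid(target_size=self.target_size,
                         patch_size=self.patch_size,
                         n_channels=self.synthetic.n_channels)

    @property
    def encoder(self) -> EncoderConfig:
        return EncoderConfig(
            patch_grid=self.patch_grid, n_layers=self.n_layers,
            embed_dim=self.embed_dim, n_heads=self.n_heads,
            neighborhood_radius=self.neighborhood_radius,
            alpha_mode=self.alpha_mode, alpha_constant=self.alpha_constant,
            fusion_depths=tuple(self.fusion_depths),
            stabilized=self.stabilized, use_positional=self.use_positional,
            init_sd=self.init_sd)

    # -- serialisation -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["synthetic"] = _config_to_jsonable(self.synthetic)
        d["train"] = dataclasses.asdict(self.train)
        d["perturbations"] = [
            {"kind": p.kind, "levels": list(p.levels), "seed": p.seed}
            for p in self.perturbations]
        d["fusion_depths"] = list(self.fusion_depths)
        d["split_fracs"] = list(self.split_fracs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "synthetic" in d:
            d["synthetic"] = config_from_jsonable(d["synthetic"])
        if "train" in d:
            t = dict(d["train"])
            if "augmentation" in t:
                t["augmentation"] = AugmentationConfig(**t["augmentation"])
            d["train"] = TrainConfig(**t)
        if "perturbations" in d:
            d["perturbations"] = tuple(
                PerturbationSpec(kind=p["kind"], levels=tuple(p["levels"]),
                                 seed=p.get("seed", 0))
                for p in d["perturbations"])
        d["fusion_depths"] = tuple(d.get("fusion_depths", (2, 4)))
        d["split_fracs"] = tuple(d.get("split_fracs", (0.7, 0.1, 0.2)))
        return cls(**d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=float).encode()
        ).hexdigest()[:16]

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = RunConfig.from_dict(self.to_dict())
        cfg.seed = seed
        cfg.synthetic = dataclasses.replace(cfg.synthetic, seed=seed)
        cfg.train = dataclasses.replace(cfg.train, seed=seed)
        return cfg


def preset(name: str) -> RunConfig:
    """Named configurations; see the module docstring."""
    if name in ("desk", "table4_desk"):
        return RunConfig()
    if name in ("full", "table4"):
        return RunConfig(
            synthetic=SyntheticConfig(image_size=512),
            target_size=512, patch_size=16, n_layers=12, embed_dim=768,
            n_heads=12, fusion_depths=(4, 8, 12), head_dim=256,
            init_sd=0.02,
            n_samples=2048,
            train=TrainConfig(epochs=60, batch_size=24, lr0=1e-4))
    raise ValueError(f"unknown preset {name!r}; available: desk, full")


def load_config(path, preset_name: str | None = None) -> RunConfig:
    if path is not None:
        with open(path) as fh:
            return RunConfig.from_yaml(fh.read())
    return preset(preset_name or "desk")
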