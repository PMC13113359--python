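"""Checkpointing and run logging.

A checkpoint is a single ``.npz`` archive holding every parameter tensor
under its named key plus a JSON header (version, encoder/head geometry,
channel stats, thresholds, seed, config hash).  Loading verifies the
version field and fails loudly on truncated archives.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import numpy as np

from .encoder import EncoderConfig
from .pipeline import CHECKPOINT_VERSION, ScreeningModel
from .preprocessing import ChannelStats, PatchGrid

logger = logging.getLogger("retscreen")


class CheckpointError(RuntimeError):
    pass


def save_checkpoint(model: ScreeningModel, path, config_hash: str = "") -> None:
    cfg = model.encoder_config
    header = {
        "version": CHECKPOINT_VERSION,
        "encoder": {
            "target_size": cfg.patch_grid.target_size,
            "patch_size": cfg.patch_grid.patch_size,
            "n_channels": cfg.patch_grid.n_channels,
            "n_layers": cfg.n_layers, "embed_dim": cfg.embed_dim,
            "n_heads": cfg.n_heads,
            "neighborhood_radius": cfg.neighborhood_radius,
            "alpha_mode": cfg.alpha_mode, "alpha_constant": cfg.alpha_constant,
            "fusion_depths": list(cfg.fusion_depths),
            "hidden_mult": cfg.hidden_mult, "activation": cfg.activation,
            "stabilized": cfg.stabilized, "use_positional": cfg.use_positional,
            "init_sd": cfg.init_sd,
        },
        "head_dim": model.head_dim,
        "class_names": list(model.class_names),
        "stats": {"means": model.channel_stats.means.tolist(),
                  "sds": model.channel_stats.sds.tolist(),
                  "n_images": model.channel_stats.n_images},
        "thresholds": (None if model.thresholds is None
                       else list(map(float, model.thresholds))),
        "seed": model.seed, "best_epoch": model.best_epoch,
        "config_hash": config_hash,
    }
    arrays = {f"param::{k}": np.asarray(v) for k, v in model.params.items()}
    np.savez(path, header=json.dumps(header), **arrays)


def load_checkpoint(path, expected_config_hash: str | None = None) -> ScreeningModel:
    try:
        with np.load(path, allow_pickle=False) as archive:
            header = json.loads(str(archive["header"]))
            params = {k[len("param::"):]: archive[k]
                      for k in archive.files if k.startswith("param::")}
    except Exception as exc:  # zipfile/np errors on truncated files
        raise CheckpointError(f"cannot read checkpoint {path}: {exc}") from exc
    if header.get("version") != CHECKPOINT_VERSION:
        raise CheckpointError(
            f"checkpoint version {header.get('version')} is incompatible "
            f"with this build (expected {CHECKPOINT_VERSION})")
    if expected_config_hash and header.get("config_hash") and \
            header["config_hash"] != expected_config_hash:
        raise CheckpointError(
            "checkpoint was produced under a different configuration "
            f"(hash {header['config_hash']} != {expected_config_hash})")
    enc = header["encoder"]
    grid = PatchGrid(target_size=enc["target_size"],
                     patch_size=enc["patch_size"],
                     n_channels=enc["n_channels"])
    config = EncoderConfig(
        patch_grid=grid, n_layers=enc["n_layers"], embed_dim=enc["embed_dim"],
        n_heads=enc["n_heads"], neighborhood_radius=enc["neighborhood_radius"],
        alpha_mode=enc["alpha_mode"], alpha_constant=enc["alpha_constant"],
        fusion_depths=tuple(enc["fusion_depths"]),
        hidden_mult=enc["hidden_mult"], activation=enc["activation"],
        stabilized=enc["stabilized"], use_positional=enc["use_positional"],
        init_sd=enc.get("init_sd", 0.1))
    stats = ChannelStats(means=np.asarray(header["stats"]["means"]),
                         sds=np.asarray(header["stats"]["sds"]),
                         n_images=header["stats"]["n_images"])
    thresholds = (None if header["thresholds"] is None
                  else np.asarray(header["thresholds"]))
    return ScreeningModel(encoder_config=config, params=params,
                          channel_stats=stats,
                          class_names=tuple(header["class_names"]),
                          head_dim=header["head_dim"], thresholds=thresholds,
                          seed=header["seed"], best_epoch=header["best_epoch"])


class RunLogger:
    """Plain-text logging plus a machine-readable JSONL event stream."""

    def __init__(self, out_dir, name: str = "run"):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.events_path = self.out_dir / f"{name}.events.jsonl"
        if not logger.handlers:
            handler = logging.StreamHandler(sys.stderr)
            handler.setFormatter(logging.Formatter(
                "%(asctime)s %(name)s %(levelname)s %(message)s"))
            logger.addHandler(handler)
        logger.setLevel(logging.INFO)

    def event(self, kind: str, **fields) -> None:
        record = {"time": time.time(), "event": kind, **fields}
        with open(self.events_path, "a") as fh:
            fh.write(json.dumps(record, default=_jsonable) + "\n")
        logger.info("%s %s", kind, {k: v for k, v in fields.items()
                                    if not isinstance(v, (dict, list))})

    def log_environment(self, config) -> None:
        import numpy
        import scipy
        import sklearn
        import skimage
        self.event("environment",
                   numpy=numpy.__version__, scipy=scipy.__version__,
                   sklearn=sklearn.__version__, skimage=skimage.__version__,
                   config=config.to_dict() if hasattr(config, "to_dict") else config,
                   seed=getattr(config, "seed", None))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    return str(obj)
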