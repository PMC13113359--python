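"""End-to-end glue: the bundled screening model and the
simulate -> train -> threshold -> evaluate pipeline used by the CLI, the
test bench and the reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import head as head_mod
from .encoder import EncoderConfig, encoder_forward, init_encoder_params
from .head import HeadParams, init_head_params, select_thresholds
from .preprocessing import ChannelStats, fit_channel_stats, preprocess
from .synthetic import FundusDataset, LabeledFundusSample
from .training import TrainConfig, train

CHECKPOINT_VERSION = 1


@dataclass
class ScreeningModel:
    """Encoder + head parameters plus the frozen preprocessing state."""

    encoder_config: EncoderConfig
    params: dict                      # encoder params + "head.ws"/"head.wc"
    channel_stats: ChannelStats
    class_names: tuple
    head_dim: int
    thresholds: np.ndarray | None = None
    seed: int = 0
    best_epoch: int = -1
    version: int = CHECKPOINT_VERSION

    @property
    def grid(self):
        return self.encoder_config.patch_grid

    def head_params(self) -> HeadParams:
        return HeadParams(screening_projection=self.params["head.ws"],
                          class_weights=self.params["head.wc"])


def build_model(encoder_config: EncoderConfig, train_samples,
                class_names, head_dim: int = 32, seed: int = 0) -> ScreeningModel:
    """Fit channel stats on the training partition and initialise all
    parameters from one seed."""
    stats = fit_channel_stats([s.image for s in train_samples])
    rng = np.random.default_rng(seed)
    params = init_encoder_params(encoder_config, rng=rng)
    hp = init_head_params(encoder_config.embed_dim, head_dim,
                          len(class_names), rng=rng)
    params["head.ws"] = hp.screening_projection
    params["head.wc"] = hp.class_weights
    return ScreeningModel(encoder_config=encoder_config, params=params,
                          channel_stats=stats, class_names=tuple(class_names),
                          head_dim=head_dim, seed=seed)


def prepare_batch(samples, model: ScreeningModel):
    """Preprocess samples into (patches (B, N, Pd), labels (B, C)) using the
    ground-truth FOV masks."""
    patches = np.stack([
        preprocess(s.image, model.channel_stats, model.grid, s.fov_mask)[0]
        for s in samples]) if samples else np.zeros(
            (0, model.grid.n_patches, model.grid.patch_dim))
    y = (np.stack([s.labels for s in samples]).astype(float)
         if samples else np.zeros((0, len(model.class_names))))
    return patches, y


def predict_proba(model: ScreeningModel, samples,
                  batch_size: int = 32) -> np.ndarray:
    """Per-class probabilities for a list of samples."""
    hp = model.head_params()
    out = []
    for start in range(0, len(samples), batch_size):
        patches, _ = prepare_batch(samples[start:start + batch_size], model)
        fwd = encoder_forward(patches, model.params, model.encoder_config,
                              store_attention=False)
        probs, _ = head_mod.head_forward(fwd["fused"], hp)
        out.append(probs)
    return np.concatenate(out) if out else np.zeros((0, len(model.class_names)))


def predict(model: ScreeningModel, samples) -> head_mod.Prediction:
    probs = predict_proba(model, samples)
    thr = (model.thresholds if model.thresholds is not None
           else np.full(len(model.class_names), 0.5))
    return head_mod.Prediction(probabilities=probs,
                               decisions=(probs >= thr).astype(np.int8),
                               thresholds=np.asarray(thr))


def attention_for_sample(model: ScreeningModel, sample: LabeledFundusSample):
    """Forward one sample keeping attention maps; returns (probs,
    attention list per layer of dicts with (H, N, N) matrices, mask)."""
    patches, _ = prepare_batch([sample], model)
    fwd = encoder_forward(patches, model.params, model.encoder_config,
                          store_attention=True)
    hp = model.head_params()
    probs, _ = head_mod.head_forward(fwd["fused"], hp)
    attention = [{k: a[k][0] for k in a} for a in fwd["attention"]]
    return probs[0], attention


def fit_validation_thresholds(model: ScreeningModel, dataset: FundusDataset):
    """Fixed per-class decision thresholds selected on the validation split."""
    probs = predict_proba(model, dataset.val)
    labels = np.stack([s.labels for s in dataset.val])
    model.thresholds = select_thresholds(probs, labels, model.class_names)
    return model.thresholds


def train_pipeline(dataset: FundusDataset, encoder_config: EncoderConfig,
                   train_config: TrainConfig, head_dim: int = 32,
                   seed: int | None = None):
    """build -> train -> select thresholds.  Returns (model, history)."""
    seed = train_config.seed if seed is None else seed
    model = build_model(encoder_config, dataset.train, dataset.class_names,
                        head_dim=head_dim, seed=seed)
    model, history = train(model, dataset, train_config)
    fit_validation_thresholds(model, dataset)
    return model, history


def evaluate_pipeline(model: ScreeningModel, samples):
    """Threshold-based decisions + full metrics report on held-out samples."""
    from .evaluation import compute_metrics

    pred = predict(model, samples)
    labels = np.stack([s.labels for s in samples])
    return compute_metrics(pred.decisions, pred.probabilities, labels,
                           class_names=model.class_names)


def predictions_frame(model: ScreeningModel, samples,
                      files=None) -> pd.DataFrame:
    """CSV-ready table: file, per-class probability, decision, threshold."""
    pred = predict(model, samples)
    rows = []
    for i in range(len(samples)):
        row = {"file": files[i] if files is not None else f"sample_{i:05d}"}
        for c, name in enumerate(model.class_names):
            row[f"prob_{name}"] = pred.probabilities[i, c]
            row[f"decision_{name}"] = int(pred.decisions[i, c])
            row[f"threshold_{name}"] = pred.thresholds[c]
        rows.append(row)
    return pd.DataFrame(rows)
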