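"""Empirical-risk training: stochastic augmentation, exponentially decayed
learning rate, AdamW updates (with a plain-SGD mode matching the bare
gradient-descent update rule exactly), and early stopping on validation
loss.

All randomness flows from the single seed in :class:`TrainConfig`.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import head as head_mod
from .encoder import encoder_backward, encoder_forward
from .synthetic import LabeledFundusSample

# parameters that behave like gains/offsets/logits are excluded from
# decoupled weight decay
_NO_DECAY_TOKENS = ("pos", "ln1", "ln2", "fusion_logits", "alpha")


@dataclass(frozen=True)
class AugmentationConfig:
    hflip_prob: float = 0.5
    vflip_prob: float = 0.5
    rotation_max: float = 15.0     # degrees
    brightness_jitter: float = 0.1  # multiplicative range +-
    contrast_jitter: float = 0.1
    enabled: bool = True

    def __post_init__(self) -> None:
        for p in (self.hflip_prob, self.vflip_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("flip probabilities must lie in [0,1]")


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 16
    optimizer: str = "adamw"  # "adamw" | "plain_sgd"
    lr0: float = 5e-3
    decay: float = 0.97
    decay_unit: str = "epoch"  # "epoch" | "step"
    weight_decay: float = 1e-2
    early_stop_patience: int = 10
    seed: int = 0
    augmentation: AugmentationConfig = field(default_factory=AugmentationConfig)

    def __post_init__(self) -> None:
        if self.lr0 < 0:
            raise ValueError("lr0 must be >= 0")
        if not 0.0 < self.decay <= 1.0:
            raise ValueError("decay must lie in (0,1]")
        if self.decay_unit not in ("epoch", "step"):
            raise ValueError("decay_unit must be 'epoch' or 'step'")


def lr_at(t: int, config: TrainConfig) -> float:
    """Exponential schedule eta_t = eta_0 * gamma^t (t in steps or epochs,
    per ``decay_unit``)."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return config.lr0 * config.decay ** t


# ---------------------------------------------------------------------------
# augmentation


def augment(sample: LabeledFundusSample, config: AugmentationConfig,
            rng: np.random.Generator) -> LabeledFundusSample:
    """Stochastic flips, rotation (masks transformed identically),
    brightness factor and contrast adjustment about the FOV mean.
    Labels and group id are unchanged."""
    img = sample.image
    fov = sample.fov_mask
    lesion = sample.lesion_mask
    if rng.random() < config.hflip_prob:
        img = img[:, ::-1]
        fov = fov[:, ::-1]
        lesion = lesion[:, ::-1]
    if rng.random() < config.vflip_prob:
        img = img[::-1]
        fov = fov[::-1]
        lesion = lesion[::-1]
    if config.rotation_max > 0:
        angle = rng.uniform(-config.rotation_max, config.rotation_max)
        img = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1,
                             mode="constant", cval=0.0)
        fov = ndimage.rotate(fov.astype(float), angle, reshape=False, order=1,
                             mode="constant", cval=0.0) >= 0.5
        lesion = ndimage.rotate(lesion.astype(float), angle, reshape=False,
                                order=1, mode="constant", cval=0.0) >= 0.5
    img = np.ascontiguousarray(img)
    fov = np.ascontiguousarray(fov)
    if config.brightness_jitter > 0:
        factor = rng.uniform(1.0 - config.brightness_jitter,
                             1.0 + config.brightness_jitter)
        img = np.where(fov[..., None], img * factor, img)
    if config.contrast_jitter > 0:
        factor = rng.uniform(1.0 - config.contrast_jitter,
                             1.0 + config.contrast_jitter)
        mean = img[fov].mean(axis=0) if fov.any() else 0.0
        img = np.where(fov[..., None], (img - mean) * factor + mean, img)
    img = np.clip(img, 0.0, 1.0)
    return LabeledFundusSample(
        image=img, fov_mask=fov, lesion_mask=np.ascontiguousarray(lesion),
        labels=sample.labels, severity=sample.severity,
        group_id=sample.group_id, lesion_log=sample.lesion_log)


# ---------------------------------------------------------------------------
# optimizers over parameter dicts


class AdamW:
    """Decoupled-weight-decay Adam (beta = (0.9, 0.999), eps = 1e-8)."""

    def __init__(self, param_keys, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: 0.0 for k in param_keys}
        self.v = {k: 0.0 for k in param_keys}
        self.t = 0

    def step(self, params: dict, grads: dict, lr: float,
             weight_decay: float = 0.0) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            if weight_decay and not any(tok in k for tok in _NO_DECAY_TOKENS):
                p -= lr * weight_decay * p
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


class PlainSGD:
    """The bare update Theta_{t+1} = Theta_t - eta * grad, verbatim."""

    def __init__(self, param_keys):
        pass

    def step(self, params: dict, grads: dict, lr: float,
             weight_decay: float = 0.0) -> None:
        for k, p in params.items():
            g = grads.get(k)
            if g is not None:
                p -= lr * g


def make_optimizer(config: TrainConfig, param_keys):
    if config.optimizer == "adamw":
        return AdamW(param_keys)
    if config.optimizer == "plain_sgd":
        return PlainSGD(param_keys)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


# ---------------------------------------------------------------------------
# loss + gradients through encoder and head


def model_loss_and_grads(patches: np.ndarray, y: np.ndarray, params: dict,
                         config) -> tuple[float, np.ndarray, dict]:
    """Mean-over-batch multi-label cross-entropy, probabilities, and
    gradients for every parameter (encoder + head)."""
    fwd = encoder_forward(patches, params, config, want_cache=True,
                          store_attention=False)
    hp = head_mod.HeadParams(screening_projection=params["head.ws"],
                             class_weights=params["head.wc"])
    probs, hcache = head_mod.head_forward(fwd["fused"], hp)
    B = probs.shape[0]
    loss = sum(head_mod.loss_multi(y[i], probs[i]) for i in range(B)) / B
    dh, d_ws, d_wc = head_mod.head_backward(probs, np.asarray(y, dtype=float),
                                            hcache, hp)
    grads = encoder_backward(dh, fwd, params, config)
    grads["head.ws"] = d_ws
    grads["head.wc"] = d_wc
    return loss, probs, grads


def model_loss(patches: np.ndarray, y: np.ndarray, params: dict, config) -> float:
    fwd = encoder_forward(patches, params, config, store_attention=False)
    hp = head_mod.HeadParams(screening_projection=params["head.ws"],
                             class_weights=params["head.wc"])
    probs, _ = head_mod.head_forward(fwd["fused"], hp)
    B = probs.shape[0]
    return sum(head_mod.loss_multi(y[i], probs[i]) for i in range(B)) / B


# ---------------------------------------------------------------------------
# the training loop


def train(model, dataset, config: TrainConfig):
    """Minimise the empirical risk over augmented mini-batches.

    ``model`` is a :class:`retscreen.pipeline.ScreeningModel`; its params
    are updated in place and the best-validation-epoch snapshot is restored
    at the end.  Returns (model, history) where history is a pandas
    DataFrame with epoch, train_loss, val_loss and lr columns.
    """
    import pandas as pd

    from .pipeline import prepare_batch

    rng = np.random.default_rng(config.seed)
    train_samples = dataset.train
    val_patches, val_y = prepare_batch(dataset.val, model)
    aug_enabled = config.augmentation.enabled

    if not aug_enabled:  # static inputs: preprocess once
        static_patches, static_y = prepare_batch(train_samples, model)

    optimizer = make_optimizer(config, model.params.keys())
    history = []
    best_val = np.inf
    best_params = None
    best_epoch = -1
    since_improve = 0
    step = 0
    n = len(train_samples)

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        seen = 0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            if aug_enabled:
                batch = [augment(train_samples[i], config.augmentation, rng)
                         for i in idx]
                patches, y = prepare_batch(batch, model)
            else:
                patches, y = static_patches[idx], static_y[idx]
            loss, _, grads = model_loss_and_grads(patches, y, model.params,
                                                  model.encoder_config)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting {start}")
            t = epoch if config.decay_unit == "epoch" else step
            lr = lr_at(t, config)
            optimizer.step(model.params, grads, lr, config.weight_decay)
            epoch_loss += loss * len(idx)
            seen += len(idx)
            step += 1
        val_loss = model_loss(val_patches, val_y, model.params,
                              model.encoder_config) if len(val_y) else np.nan
        history.append({"epoch": epoch, "train_loss": epoch_loss / seen,
                        "val_loss": val_loss,
                        "lr": lr_at(epoch if config.decay_unit == "epoch"
                                    else step - 1, config)})
        if len(val_y) and val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = copy.deepcopy(model.params)
            best_epoch = epoch
            since_improve = 0
        else:
            since_improve += 1
            if len(val_y) and since_improve >= config.early_stop_patience:
                break

    if best_params is not None:
        model.params = best_params
        model.best_epoch = best_epoch
    return model, pd.DataFrame(history)


def replicate_seeds(base_config: TrainConfig, seeds=(1, 2, 3)):
    """The three-seed replication protocol: one TrainConfig per seed."""
    return [replace(base_config, seed=s) for s in seeds]


def replication_summary(reports):
    """Mean +- sd over replicate runs for the headline metrics.

    ``reports`` is a sequence of MetricsReport; returns a DataFrame with
    one row per metric and mean/sd columns (population sd over seeds).
    """
    import pandas as pd

    keys = ("accuracy", "macro_f1", "sensitivity", "specificity", "auroc")
    rows = []
    for key in keys:
        vals = np.array([getattr(r, key) for r in reports], dtype=float)
        rows.append({"metric": key, "mean": np.nanmean(vals),
                     "sd": np.nanstd(vals), "n_seeds": len(vals)})
    return pd.DataFrame(rows)
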