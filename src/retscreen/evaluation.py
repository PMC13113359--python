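"""Screening metrics, degradation-robustness suite, attention-alignment
interpretability metrics, and cross-domain retention.

Metric conventions
------------------
Per class: sensitivity = tp/(tp+fn), specificity = tn/(tn+fp),
F1 = 2tp/(2tp+fp+fn), accuracy = (tp+tn)/n.  Multi-label aggregation is
macro (unweighted class mean).  AUROC is the rank statistic with half
credit for ties; a class with a single label value on the evaluated set
has no AUROC and is excluded from the macro mean with a warning.

The stability index of a degradation suite is the fraction of samples
whose per-class thresholded decisions are identical across the clean image
and every degradation level.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else np.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else np.nan

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else np.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total


@dataclass(frozen=True)
class PerturbationSpec:
    kind: str  # brightness_down | brightness_up | contrast_down | gaussian_blur | gaussian_noise
    levels: tuple  # ordered severity values, strictly increasing
    seed: int = 0

    _KINDS = ("brightness_down", "brightness_up", "contrast_down",
              "gaussian_blur", "gaussian_noise")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        lv = tuple(self.levels)
        if any(b <= a for a, b in zip(lv, lv[1:])):
            raise ValueError("levels must be strictly increasing in severity")


@dataclass
class MetricsReport:
    accuracy: float
    macro_f1: float
    sensitivity: float
    specificity: float
    auroc: float
    per_class: pd.DataFrame
    confusion: list = field(default_factory=list)
    robustness: dict = field(default_factory=dict)
    stability_index: float | None = None
    attention: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {"accuracy": self.accuracy, "macro_f1": self.macro_f1,
             "sensitivity": self.sensitivity, "specificity": self.specificity,
             "auroc": self.auroc,
             "per_class": self.per_class.to_dict(orient="records")}
        if self.robustness:
            d["robustness"] = self.robustness
        if self.stability_index is not None:
            d["stability_index"] = self.stability_index
        if self.attention:
            d["attention"] = self.attention
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), default=float, **kwargs)


def binary_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUROC (Mann-Whitney with half credit for ties)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return np.nan
    return float(roc_auc_score(labels, scores))


def compute_metrics(decisions: np.ndarray, probabilities: np.ndarray,
                    labels: np.ndarray, class_names=None) -> MetricsReport:
    """Confusion-derived metrics and AUROC, per class plus macro means."""
    dec = np.atleast_2d(np.asarray(decisions))
    probs = np.atleast_2d(np.asarray(probabilities))
    y = np.atleast_2d(np.asarray(labels))
    if not (dec.shape == probs.shape == y.shape):
        raise ValueError("decisions, probabilities and labels must align")
    n, C = y.shape
    names = list(class_names) if class_names is not None else [
        f"class_{c}" for c in range(C)]
    rows = []
    confusion = []
    for c in range(C):
        tp = int(np.sum((dec[:, c] == 1) & (y[:, c] == 1)))
        fp = int(np.sum((dec[:, c] == 1) & (y[:, c] == 0)))
        tn = int(np.sum((dec[:, c] == 0) & (y[:, c] == 0)))
        fn = int(np.sum((dec[:, c] == 0) & (y[:, c] == 1)))
        cc = ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)
        confusion.append(cc)
        auroc_c = binary_auroc(probs[:, c], y[:, c])
        if np.isnan(auroc_c):
            warnings.warn(f"AUROC undefined for class {names[c]!r} "
                          "(single label value); excluded from the macro mean")
        rows.append({"class": names[c], "accuracy": cc.accuracy,
                     "f1": cc.f1, "sensitivity": cc.sensitivity,
                     "specificity": cc.specificity, "auroc": auroc_c,
                     "n_pos": tp + fn})
    per_class = pd.DataFrame(rows)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        macro = {k: float(np.nanmean(per_class[k].to_numpy(dtype=float)))
                 for k in ("accuracy", "f1", "sensitivity", "specificity",
                           "auroc")}
    return MetricsReport(accuracy=macro["accuracy"], macro_f1=macro["f1"],
                         sensitivity=macro["sensitivity"],
                         specificity=macro["specificity"],
                         auroc=macro["auroc"], per_class=per_class,
                         confusion=confusion)


# ---------------------------------------------------------------------------
# image degradations


def perturb(image: np.ndarray, spec: PerturbationSpec, level_index: int,
            rng: np.random.Generator | None = None,
            fov_mask: np.ndarray | None = None) -> np.ndarray:
    """Apply one degradation level; the FOV mask is unchanged."""
    level = float(spec.levels[level_index])
    img = np.array(image, dtype=float, copy=True)
    fov = (np.ones(img.shape[:2], dtype=bool) if fov_mask is None
           else np.asarray(fov_mask, dtype=bool))
    inside = fov[..., None]
    if spec.kind == "brightness_down":
        img = np.where(inside, img * (1.0 - level), img)
    elif spec.kind == "brightness_up":
        img = np.where(inside, img * (1.0 + level), img)
    elif spec.kind == "contrast_down":
        mean = img[fov].mean(axis=0) if fov.any() else 0.0
        img = np.where(inside, img * (1.0 - level) + mean * level, img)
    elif spec.kind == "gaussian_blur":
        if level > 0:
            img = ndimage.gaussian_filter(img, sigma=(level, level, 0))
    elif spec.kind == "gaussian_noise":
        if level > 0:
            if rng is None:
                rng = np.random.default_rng(spec.seed)
            img = np.where(inside, img + rng.normal(0.0, level, img.shape), img)
    return np.clip(img, 0.0, 1.0)


def robustness_suite(model, test_samples, specs,
                     metric_keys=("accuracy", "macro_f1", "auroc")) -> dict:
    """Clean-vs-degraded evaluation.

    For each perturbation: per-level metrics, performance drop
    (clean metric minus mean degraded metric, in percentage points) and a
    per-perturbation stability index; plus the suite-wide stability index.
    """
    import dataclasses

    from .pipeline import evaluate_pipeline, predict

    clean_report = evaluate_pipeline(model, test_samples)
    clean_dec = predict(model, test_samples).decisions
    labels = np.stack([s.labels for s in test_samples])
    out = {"clean": {k: getattr(clean_report, k if k != "macro_f1" else "macro_f1")
                     for k in metric_keys},
           "perturbations": {}}
    stable_all = np.ones(len(test_samples), dtype=bool)
    for spec in specs:
        rng = np.random.default_rng(spec.seed)
        level_metrics = []
        stable_spec = np.ones(len(test_samples), dtype=bool)
        for li in range(len(spec.levels)):
            degraded = [dataclasses.replace(
                s, image=perturb(s.image, spec, li, rng=rng, fov_mask=s.fov_mask))
                for s in test_samples]
            report = evaluate_pipeline(model, degraded)
            dec = predict(model, degraded).decisions
            same = np.all(dec == clean_dec, axis=1)
            stable_spec &= same
            level_metrics.append(
                {"level": float(spec.levels[li]),
                 **{k: getattr(report, k) for k in metric_keys}})
        stable_all &= stable_spec
        drops = {k: 100.0 * (out["clean"][k]
                             - float(np.mean([m[k] for m in level_metrics])))
                 for k in metric_keys}
        out["perturbations"][spec.kind] = {
            "levels": level_metrics,
            "drop_pp": drops,
            "stability_index": float(stable_spec.mean()),
        }
    out["stability_index"] = float(stable_all.mean())
    out["n_samples"] = len(test_samples)
    return out


# ---------------------------------------------------------------------------
# attention alignment


def _patch_overlap(mask: np.ndarray, grid) -> np.ndarray:
    """Per-patch booleans: does any pixel of ``mask`` fall in the patch?"""
    P = grid.patch_size
    m = np.asarray(mask, dtype=bool)
    tiled = m.reshape(grid.grid_rows, P, grid.grid_cols, P)
    return tiled.any(axis=(1, 3)).ravel()


def attention_saliency(final_layer_attention: dict) -> np.ndarray:
    """Patch-level saliency: attention *received* by each token, averaged
    over heads and query rows (column means of the mixed maps).  Sums to 1
    because every row is stochastic."""
    a = final_layer_attention["a_mix"]  # (H, N, N)
    return a.mean(axis=(0, 1))


def attention_alignment(attention, lesion_mask: np.ndarray,
                        fov_mask: np.ndarray, grid) -> dict:
    """Split the saliency mass into lesion-overlapping patches
    (relevant_region_coverage), patches fully outside the FOV
    (misaligned_focus), and the in-FOV remainder (diffuse_attention).
    The three fractions partition unity.

    Raises for samples without lesions (coverage undefined).
    """
    lesion_patches = _patch_overlap(lesion_mask, grid)
    fov_patches = _patch_overlap(fov_mask, grid)
    if not lesion_patches.any():
        raise ValueError("no lesions in sample; coverage undefined")
    saliency = attention_saliency(attention[-1]) if isinstance(attention, list) \
        else attention_saliency(attention)
    saliency = saliency / saliency.sum()
    coverage = float(saliency[lesion_patches].sum())
    misaligned = float(saliency[~fov_patches & ~lesion_patches].sum())
    diffuse = float(saliency[fov_patches & ~lesion_patches].sum())
    return {"relevant_region_coverage": coverage,
            "misaligned_focus": misaligned,
            "diffuse_attention": diffuse,
            "lesion_patch_fraction": float(lesion_patches.mean())}


def attention_alignment_suite(model, samples) -> dict:
    """Aggregate alignment fractions over lesion-positive samples; samples
    without lesions are excluded and counted."""
    from .pipeline import attention_for_sample

    rows = []
    excluded = 0
    for s in samples:
        if not s.lesion_mask.any():
            excluded += 1
            continue
        _, attention = attention_for_sample(model, s)
        rows.append(attention_alignment(attention, s.lesion_mask, s.fov_mask,
                                        model.grid))
    agg = {k: float(np.mean([r[k] for r in rows])) for k in rows[0]} if rows else {}
    agg["n_samples"] = len(rows)
    agg["n_excluded_no_lesion"] = excluded
    return agg


def retention(in_domain_metric: float, cross_domain_metric: float) -> float:
    """Cross-domain performance as a percentage of in-domain performance
    (no capping above 100)."""
    if in_domain_metric == 0:
        raise ValueError("in-domain metric is zero; retention undefined")
    return 100.0 * cross_domain_metric / in_domain_metric


def save_saliency_overlay(image: np.ndarray, saliency: np.ndarray, grid,
                          path) -> None:
    """Write a PNG heatmap of patch saliency over the image."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sal_img = saliency.reshape(grid.grid_rows, grid.grid_cols)
    sal_img = np.kron(sal_img, np.ones((grid.patch_size, grid.patch_size)))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(image)
    ax.imshow(sal_img, cmap="inferno", alpha=0.45)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", dpi=120)
    plt.close(fig)
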