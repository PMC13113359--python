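"""Synthetic fundus-like image generator with known lesion ground truth.

Real screening datasets attach a single ordinal severity grade or a
multi-label disease vector to each colour fundus photograph.  This module
emulates that structure at small scale: a circular field of view (FOV) on a
dark background, an illumination gradient, vessel-like curvilinear
structures, an optic-disc blob, and planted bright/dark lesions whose
presence drives the label vector.  Because lesion masks are known exactly,
every downstream stage (masking, attention alignment, robustness) can be
tested against ground truth.

Lesion morphology is stylised: ``bright_spot`` lesions are Gaussian-profile
discs added to the red/green channels (exudate surrogate); ``dark_blob``
lesions are intensity depressions (haemorrhage surrogate).  Both give the
encoder a local, fine-grained signal analogous to microaneurysms and
small bleeds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class ConfigurationError(ValueError):
    """Raised when a synthetic-data configuration is internally inconsistent."""


@dataclass(frozen=True)
class LesionClass:
    """One disease surrogate: a lesion kind with prevalence and geometry."""

    name: str
    kind: str  # "bright_spot" | "dark_blob"
    prevalence: float
    count_range: tuple[int, int] = (2, 5)
    radius_range_px: tuple[float, float] = (2.5, 5.0)

    def __post_init__(self) -> None:
        if self.kind not in ("bright_spot", "dark_blob"):
            raise ConfigurationError(f"unknown lesion kind {self.kind!r}")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError(
                f"prevalence of {self.name!r} must lie in [0,1], got {self.prevalence}"
            )
        if self.count_range[0] < 1 or self.count_range[1] < self.count_range[0]:
            raise ConfigurationError(f"bad count_range for {self.name!r}")
        if self.radius_range_px[0] <= 0:
            raise ConfigurationError(f"bad radius_range_px for {self.name!r}")


def default_lesion_classes() -> tuple[LesionClass, ...]:
    """Two-class default mirroring the bright/dark dichotomy of exudates vs
    haemorrhages, with the abnormal classes in the minority as in screening
    populations."""
    return (
        LesionClass("exudate", "bright_spot", prevalence=0.45),
        LesionClass("hemorrhage", "dark_blob", prevalence=0.30),
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator configuration.

    ``severity_step`` is the staircase constant k in
    grade = min(4, total_lesions // k), yielding 5 ordinal grades.
    ``cooccurrence_boost`` is added to a class's prevalence when an earlier
    class is already present (diseases co-occur in multi-label screening).
    """

    image_size: int = 64
    n_channels: int = 3
    fov_radius_frac: float = 0.9
    lesion_classes: tuple[LesionClass, ...] = field(default_factory=default_lesion_classes)
    vessel_count: int = 4
    illumination_gradient_strength: float = 0.15
    noise_sd: float = 0.02
    seed: int = 0
    severity_step: int = 2
    cooccurrence_boost: float = 0.0
    samples_per_group: tuple[int, int] = (1, 3)

    def __post_init__(self) -> None:
        if self.image_size < 8:
            raise ConfigurationError("image_size too small")
        if self.n_channels != 3:
            raise ConfigurationError("only 3-channel colour images are supported")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ConfigurationError("fov_radius_frac must lie in (0,1]")
        if self.illumination_gradient_strength < 0 or self.noise_sd < 0:
            raise ConfigurationError("gradient strength and noise sd must be >= 0")
        fov_radius = self.fov_radius_frac * self.image_size / 2.0
        for cls in self.lesion_classes:
            if cls.radius_range_px[1] > fov_radius:
                raise ConfigurationError(
                    f"lesion radius up to {cls.radius_range_px[1]} px for class "
                    f"{cls.name!r} exceeds the FOV radius {fov_radius:.1f} px"
                )

    @property
    def class_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.lesion_classes)

    @property
    def fov_radius_px(self) -> float:
        return self.fov_radius_frac * self.image_size / 2.0


@dataclass
class LabeledFundusSample:
    """A synthetic image with exhaustive ground truth."""

    image: np.ndarray        # (H, W, 3) float in [0, 1]
    fov_mask: np.ndarray     # (H, W) bool, single filled disc
    lesion_mask: np.ndarray  # (H, W) bool, union of planted lesions
    labels: np.ndarray       # (C,) int 0/1; labels[c] = 1 iff >=1 lesion of class c
    severity: int            # ordinal grade 0..4
    group_id: int            # patient surrogate
    lesion_log: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# single-sample generation


def _disc(yy: np.ndarray, xx: np.ndarray, cy: float, cx: float, r: float) -> np.ndarray:
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _paint_vessels(image: np.ndarray, fov: np.ndarray, start: tuple[float, float],
                   count: int, rng: np.random.Generator) -> None:
    """Dark curvilinear random walks radiating from the optic disc."""
    size = image.shape[0]
    n_steps = int(size * 1.2)
    for _ in range(count):
        heading = rng.uniform(0, 2 * np.pi)
        y, x = start
        ys, xs = [], []
        for _ in range(n_steps):
            heading += rng.normal(0.0, 0.25)
            y += np.sin(heading)
            x += np.cos(heading)
            if not (0 <= int(y) < size and 0 <= int(x) < size):
                break
            ys.append(int(y))
            xs.append(int(x))
        if not ys:
            continue
        ys_a = np.asarray(ys)
        xs_a = np.asarray(xs)
        depth = np.zeros(image.shape[:2])
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                yy = np.clip(ys_a + dy, 0, size - 1)
                xx = np.clip(xs_a + dx, 0, size - 1)
                w = 1.0 if (dy == 0 and dx == 0) else 0.4
                np.maximum.at(depth, (yy, xx), w)
        depth *= fov
        image[..., 0] -= 0.10 * depth
        image[..., 1] -= 0.18 * depth
        image[..., 2] -= 0.06 * depth


def _place_lesions(config: SyntheticConfig, rng: np.random.Generator,
                   yy: np.ndarray, xx: np.ndarray, cy: float, cx: float,
                   image: np.ndarray, lesion_mask: np.ndarray):
    """Plant lesions class by class; centres are rejection-sampled inside the
    FOV with the full disc contained and without overlap between lesions, so
    the union mask area equals the sum of per-lesion areas."""
    fov_r = config.fov_radius_px
    labels = np.zeros(len(config.lesion_classes), dtype=np.int8)
    log: list[dict] = []
    placed: list[tuple[float, float, float]] = []
    any_present = False
    for c, cls in enumerate(config.lesion_classes):
        p = cls.prevalence + (config.cooccurrence_boost if any_present else 0.0)
        present = rng.random() < min(p, 1.0)
        if not present:
            continue
        n_lesions = int(rng.integers(cls.count_range[0], cls.count_range[1] + 1))
        for _ in range(n_lesions):
            radius = rng.uniform(*cls.radius_range_px)
            for _attempt in range(200):
                ang = rng.uniform(0, 2 * np.pi)
                dist = np.sqrt(rng.random()) * max(fov_r - radius - 1.0, 0.0)
                ly = cy + dist * np.sin(ang)
                lx = cx + dist * np.cos(ang)
                if all((ly - py) ** 2 + (lx - px) ** 2 > (radius + pr + 1.0) ** 2
                       for py, px, pr in placed):
                    break
            else:
                continue  # could not place without overlap; skip this lesion
            placed.append((ly, lx, radius))
            d2 = (yy - ly) ** 2 + (xx - lx) ** 2
            footprint = d2 <= radius * radius
            profile = np.exp(-d2 / (2.0 * (radius / 2.0) ** 2))
            if cls.kind == "bright_spot":
                amp = rng.uniform(0.35, 0.60)
                image[..., 0] += amp * profile
                image[..., 1] += 0.8 * amp * profile
            else:
                amp = rng.uniform(0.35, 0.60)
                image -= amp * profile[..., None]
            lesion_mask |= footprint
            labels[c] = 1
            log.append({
                "class": cls.name, "kind": cls.kind,
                "y": float(ly), "x": float(lx), "radius": float(radius),
                "area": int(footprint.sum()),
            })
        any_present = any_present or bool(labels[c])
    return labels, log


def generate_sample(config: SyntheticConfig, rng: np.random.Generator,
                    group_id: int = 0) -> LabeledFundusSample:
    """Draw one labelled synthetic fundus image.

    The background outside the FOV is exactly zero; the severity grade is
    the deterministic staircase min(4, total_lesions // severity_step).
    """
    size = config.image_size
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    cy = cx = (size - 1) / 2.0
    fov_r = config.fov_radius_px
    fov = _disc(yy, xx, cy, cx, fov_r)

    base = np.array([0.62, 0.35, 0.15]) + rng.normal(0.0, 0.03, size=3)
    image = np.ones((size, size, 3)) * base

    # illumination gradient across a random direction
    theta = rng.uniform(0, 2 * np.pi)
    proj = ((yy - cy) * np.sin(theta) + (xx - cx) * np.cos(theta)) / max(fov_r, 1.0)
    image *= (1.0 + config.illumination_gradient_strength * proj)[..., None]

    # optic disc: pale whitish blob off-centre (brighter in blue than the
    # orange fundus background, unlike the yellow bright-spot lesions)
    ang = rng.uniform(0, 2 * np.pi)
    od_y = cy + 0.55 * fov_r * np.sin(ang)
    od_x = cx + 0.55 * fov_r * np.cos(ang)
    od_r = 0.10 * size
    od_profile = np.exp(-(((yy - od_y) ** 2 + (xx - od_x) ** 2) / (2 * (od_r / 1.5) ** 2)))
    image[..., 0] += 0.25 * od_profile
    image[..., 1] += 0.25 * od_profile
    image[..., 2] += 0.25 * od_profile

    _paint_vessels(image, fov, (od_y, od_x), config.vessel_count, rng)

    lesion_mask = np.zeros((size, size), dtype=bool)
    labels, log = _place_lesions(config, rng, yy, xx, cy, cx, image, lesion_mask)

    if config.noise_sd > 0:
        image += rng.normal(0.0, config.noise_sd, size=image.shape)

    image = np.clip(image, 0.0, 1.0) * fov[..., None]
    lesion_mask &= fov

    total = sum(1 for entry in log)
    severity = int(min(4, total // config.severity_step))
    return LabeledFundusSample(
        image=image, fov_mask=fov, lesion_mask=lesion_mask,
        labels=labels, severity=severity, group_id=group_id, lesion_log=log,
    )


# ---------------------------------------------------------------------------
# dataset generation with patient-level splits


@dataclass
class FundusDataset:
    samples: list[LabeledFundusSample]
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    config: SyntheticConfig
    seed: int

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.config.class_names

    @property
    def train(self) -> list[LabeledFundusSample]:
        return [self.samples[i] for i in self.train_idx]

    @property
    def val(self) -> list[LabeledFundusSample]:
        return [self.samples[i] for i in self.val_idx]

    @property
    def test(self) -> list[LabeledFundusSample]:
        return [self.samples[i] for i in self.test_idx]


def _split_groups(n_groups: int, split_fracs: tuple[float, float, float],
                  rng: np.random.Generator) -> list[np.ndarray]:
    """Assign whole groups to partitions, sizes within +-1 group of the
    requested fractions (largest-remainder apportionment)."""
    order = rng.permutation(n_groups)
    raw = np.array(split_fracs, dtype=float) * n_groups
    counts = np.floor(raw).astype(int)
    remainder = n_groups - counts.sum()
    for j in np.argsort(-(raw - counts))[:remainder]:
        counts[j] += 1
    out, pos = [], 0
    for c in counts:
        out.append(np.sort(order[pos:pos + c]))
        pos += c
    return out


def generate_dataset(config: SyntheticConfig, n: int,
                     split_fracs: tuple[float, float, float] = (0.7, 0.1, 0.2),
                     seed: int | None = None) -> FundusDataset:
    """Generate ``n`` samples grouped into patient surrogates and split at
    the group level, so samples sharing a ``group_id`` never span partitions.
    """
    if n < 10:
        raise ConfigurationError("n must be >= 10")
    fr = np.array(split_fracs, dtype=float)
    if np.any(fr < 0) or not np.isclose(fr.sum(), 1.0):
        raise ConfigurationError("split_fracs must be non-negative and sum to 1")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    # group sizes: 1..k images per patient surrogate
    sizes = []
    total = 0
    lo, hi = config.samples_per_group
    while total < n:
        s = int(rng.integers(lo, hi + 1))
        s = min(s, n - total)
        sizes.append(s)
        total += s
    n_groups = len(sizes)
    n_partitions = int(np.count_nonzero(fr))
    if n_groups < n_partitions:
        raise ConfigurationError(
            f"{n_groups} distinct groups cannot fill {n_partitions} partitions")

    group_parts = _split_groups(n_groups, tuple(fr), rng)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n)
    samples: list[LabeledFundusSample] = []
    group_of_sample = []
    i = 0
    for g, s in enumerate(sizes):
        for _ in range(s):
            samples.append(generate_sample(config, np.random.default_rng(children[i]),
                                           group_id=g))
            group_of_sample.append(g)
            i += 1
    group_of_sample = np.asarray(group_of_sample)

    idx_parts = []
    for part in group_parts:
        member = np.isin(group_of_sample, part)
        idx_parts.append(np.flatnonzero(member))
    return FundusDataset(samples=samples, train_idx=idx_parts[0],
                         val_idx=idx_parts[1], test_idx=idx_parts[2],
                         config=config, seed=seed)


# ---------------------------------------------------------------------------
# on-disk form: PNG images/masks + labels CSV + manifest JSON


def _config_to_jsonable(config: SyntheticConfig) -> dict:
    d = dataclasses.asdict(config)
    d["lesion_classes"] = [dataclasses.asdict(c) for c in config.lesion_classes]
    return d


def config_from_jsonable(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["lesion_classes"] = tuple(
        LesionClass(name=c["name"], kind=c["kind"], prevalence=c["prevalence"],
                    count_range=tuple(c["count_range"]),
                    radius_range_px=tuple(c["radius_range_px"]))
        for c in d["lesion_classes"])
    d["samples_per_group"] = tuple(d["samples_per_group"])
    return SyntheticConfig(**d)


def write_dataset(dataset: FundusDataset, out_dir, image_format: str = "png") -> dict:
    """Write images (8-bit PNG or float32 TIFF), masks (single-channel PNG),
    one labels CSV and a manifest JSON.  Returns the manifest dict."""
    import imageio.v3 as iio
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(exist_ok=True)
    rows = []
    split_of = np.full(len(dataset.samples), "train", dtype=object)
    split_of[dataset.val_idx] = "val"
    split_of[dataset.test_idx] = "test"
    for i, s in enumerate(dataset.samples):
        stem = f"sample_{i:05d}"
        if image_format == "png":
            iio.imwrite(out / "images" / f"{stem}.png",
                        np.round(s.image * 255).astype(np.uint8))
            img_name = f"images/{stem}.png"
        elif image_format == "tiff":
            import tifffile
            tifffile.imwrite(out / "images" / f"{stem}.tiff", s.image.astype(np.float32))
            img_name = f"images/{stem}.tiff"
        else:
            raise ValueError(f"unknown image format {image_format!r}")
        iio.imwrite(out / "masks" / f"{stem}_fov.png",
                    (s.fov_mask * 255).astype(np.uint8))
        iio.imwrite(out / "masks" / f"{stem}_lesion.png",
                    (s.lesion_mask * 255).astype(np.uint8))
        row = {"file": img_name, "group_id": s.group_id,
               "severity": s.severity, "split": split_of[i]}
        for c, name in enumerate(dataset.class_names):
            row[name] = int(s.labels[c])
        rows.append(row)
    labels = pd.DataFrame(rows)
    labels.to_csv(out / "labels.csv", index=False)
    label_hash = hashlib.sha256(
        labels.to_csv(index=False).encode()).hexdigest()
    manifest = {
        "format_version": 1,
        "n_samples": len(dataset.samples),
        "image_format": image_format,
        "config": _config_to_jsonable(dataset.config),
        "seed": dataset.seed,
        "class_names": list(dataset.class_names),
        "split_sizes": {"train": int(len(dataset.train_idx)),
                        "val": int(len(dataset.val_idx)),
                        "test": int(len(dataset.test_idx))},
        "labels_sha256": label_hash,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def load_dataset(data_dir) -> FundusDataset:
    """Read a dataset previously written by :func:`write_dataset`."""
    import imageio.v3 as iio
    from pathlib import Path

    data = Path(data_dir)
    with open(data / "manifest.json") as fh:
        manifest = json.load(fh)
    config = config_from_jsonable(manifest["config"])
    labels = pd.read_csv(data / "labels.csv")
    samples = []
    for i, row in labels.iterrows():
        stem = Path(row["file"]).stem
        img = iio.imread(data / row["file"])
        if img.dtype == np.uint8:
            img = img.astype(float) / 255.0
        fov = iio.imread(data / "masks" / f"{stem}_fov.png") > 127
        lesion = iio.imread(data / "masks" / f"{stem}_lesion.png") > 127
        lab = np.array([int(row[name]) for name in manifest["class_names"]],
                       dtype=np.int8)
        samples.append(LabeledFundusSample(
            image=img, fov_mask=fov, lesion_mask=lesion, labels=lab,
            severity=int(row["severity"]), group_id=int(row["group_id"])))
    split = labels["split"].to_numpy()
    return FundusDataset(
        samples=samples,
        train_idx=np.flatnonzero(split == "train"),
        val_idx=np.flatnonzero(split == "val"),
        test_idx=np.flatnonzero(split == "test"),
        config=config, seed=int(manifest["seed"]))
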