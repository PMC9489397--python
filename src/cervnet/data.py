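"""Dataset handling: image-folder I/O, stratified 90/10 split, augmentation, and a
synthetic colposcopy-like image generator.

The expected on-disk layout is ``root/<label-int>/*.jpg|png`` with integer labels
0–4: 0 normal, 1 LSIL, 2 HSIL, 3 cervical cancer, 4 cervical neoplasm.  The clinical
reference inventory for this scheme (2352/780/2532/408/924 images, 6,996 in total
from 1,189 patients) is available as :data:`TABLE1_COUNTS` and can be mirrored at any
scale by the synthetic generator.

The generator draws, per class, a base hue, a number of brighter elliptical blobs and
a sinusoidal texture frequency, then adds Gaussian pixel noise.  At ``noise_sd=0``
the class-conditional mean colors are separated by construction, so a trivial
nearest-mean-color classifier is perfect; raising ``noise_sd`` makes classes
increasingly confusable.  It emulates class imbalance and patient grouping, not the
anatomy, optics or illumination variability of real colposcopy frames.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from PIL import Image

from .errors import (ConfigurationError, EmptyDatasetError, InvalidShapeError,
                     StratificationError)

__all__ = [
    "LabelScheme", "ImageRecord", "DatasetInventory", "SyntheticConfig",
    "DEFAULT_LABELS", "TABLE1_COUNTS", "scaled_table1_counts",
    "load_image_folder", "inventory", "stratified_split",
    "TrainTransform", "EvalTransform", "compute_channel_stats",
    "generate_synthetic_dataset", "write_image_folder", "write_manifest",
]

DEFAULT_LABELS: Dict[int, str] = {
    0: "normal",
    1: "LSIL",
    2: "HSIL",
    3: "cervical cancer",
    4: "cervical neoplasm",
}

#: Published per-class image counts of the clinical cervigram dataset.
TABLE1_COUNTS: Dict[int, int] = {0: 2352, 1: 780, 2: 2532, 3: 408, 4: 924}


def scaled_table1_counts(divisor: int) -> Dict[int, int]:
    """Clinical class-imbalance profile scaled down by an integer divisor (floor)."""
    if divisor < 1:
        raise ConfigurationError("divisor must be >= 1")
    return {k: v // divisor for k, v in TABLE1_COUNTS.items()}


@dataclass(frozen=True)
class LabelScheme:
    """Mapping from integer label to class name; labels must be 0..K-1."""

    names: Dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABELS))

    def __post_init__(self):
        labels = sorted(self.names)
        if labels != list(range(len(labels))) or not labels:
            raise ConfigurationError("labels must be consecutive integers from 0")

    @property
    def num_classes(self) -> int:
        return len(self.names)

    def __contains__(self, label: int) -> bool:
        return label in self.names


@dataclass
class ImageRecord:
    """One labelled image, either on disk or as in-memory RGB pixels."""

    label: int
    path: Optional[Path] = None
    pixels: Optional[np.ndarray] = None  # (H, W, 3) uint8
    group_id: Optional[str] = None

    def load(self) -> np.ndarray:
        """Return (H, W, 3) uint8 RGB pixels."""
        if self.pixels is not None:
            return self.pixels
        with Image.open(self.path) as im:
            return np.asarray(im.convert("RGB"))


@dataclass
class DatasetInventory:
    per_class_counts: Dict[int, int]

    @property
    def total(self) -> int:
        return sum(self.per_class_counts.values())


def inventory(records: Sequence[ImageRecord]) -> DatasetInventory:
    """Exact per-class counts and total of a record list."""
    counts: Dict[int, int] = {}
    for r in records:
        counts[r.label] = counts.get(r.label, 0) + 1
    return DatasetInventory(per_class_counts=counts)


def load_image_folder(root, scheme: Optional[LabelScheme] = None) -> List[ImageRecord]:
    """Read an image-folder dataset; ordering is lexicographic by path.

    Unreadable files are skipped with a warning; an entirely empty dataset raises
    :class:`EmptyDatasetError`.
    """
    root = Path(root)
    scheme = scheme or LabelScheme()
    records: List[ImageRecord] = []
    skipped = 0
    for sub in sorted(root.iterdir() if root.is_dir() else []):
        if not sub.is_dir() or not sub.name.lstrip("-").isdigit():
            continue
        label = int(sub.name)
        if label not in scheme:
            warnings.warn(f"directory {sub} has no label in the scheme; skipped")
            continue
        for f in sorted(sub.iterdir()):
            if f.suffix.lower() not in (".jpg", ".jpeg", ".png"):
                continue
            try:
                with Image.open(f) as im:
                    im.verify()
            except Exception:
                skipped += 1
                continue
            records.append(ImageRecord(label=label, path=f))
    if skipped:
        warnings.warn(f"skipped {skipped} unreadable image file(s)")
    if not records:
        raise EmptyDatasetError(f"no readable labelled images under {root}")
    return records


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def stratified_split(records: Sequence[ImageRecord], train_fraction: float = 0.90,
                     seed: int = 0, group_aware: bool = False):
    """Deterministic stratified train/validation partition.

    Per class the train count is round-half-up(count·fraction), then classes are
    nudged by ±1 (largest-remainder order) so the global train count matches
    round-half-up(total·fraction) within one record, with at least one record per
    class in each subset.  ``group_aware=True`` keeps all records sharing a
    ``group_id`` (e.g. one patient's images) in the same subset, trading exact
    per-class counts for leakage-free splitting.
    """
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    inv = inventory(records)
    for label, count in inv.per_class_counts.items():
        if count < 2:
            raise StratificationError(
                f"class {label} has {count} record(s); at least 2 required")
    rng = np.random.default_rng(seed)
    by_class: Dict[int, List[ImageRecord]] = {}
    for r in records:
        by_class.setdefault(r.label, []).append(r)

    if group_aware:
        train: List[ImageRecord] = []
        val: List[ImageRecord] = []
        for label in sorted(by_class):
            groups: Dict[str, List[ImageRecord]] = {}
            for i, r in enumerate(by_class[label]):
                groups.setdefault(r.group_id if r.group_id is not None else f"_solo{i}",
                                  []).append(r)
            keys = sorted(groups)
            if len(keys) < 2:
                raise StratificationError(
                    f"class {label} has a single patient group; cannot split group-aware")
            rng.shuffle(keys)
            quota = train_fraction * len(by_class[label])
            taken = 0
            # greedy: fill train until the quota, always leaving the last group for val
            for j, k in enumerate(keys):
                if taken < quota and j < len(keys) - 1:
                    train.extend(groups[k])
                    taken += len(groups[k])
                else:
                    val.extend(groups[k])
        return train, val

    quotas: Dict[int, int] = {}
    fracs: Dict[int, float] = {}
    for label in sorted(by_class):
        c = len(by_class[label])
        q = _round_half_up(c * train_fraction)
        q = min(max(q, 1), c - 1)
        quotas[label] = q
        fracs[label] = c * train_fraction - math.floor(c * train_fraction)
    target = _round_half_up(inv.total * train_fraction)
    diff = target - sum(quotas.values())
    order = sorted(quotas, key=lambda l: -fracs[l] if diff > 0 else fracs[l])
    for label in order:
        if diff == 0:
            break
        c = len(by_class[label])
        if diff > 0 and quotas[label] < c - 1:
            quotas[label] += 1
            diff -= 1
        elif diff < 0 and quotas[label] > 1:
            quotas[label] -= 1
            diff += 1

    train, val = [], []
    for label in sorted(by_class):
        idx = rng.permutation(len(by_class[label]))
        q = quotas[label]
        for pos, i in enumerate(idx):
            (train if pos < q else val).append(by_class[label][i])
    return train, val


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def _resize_short(img: np.ndarray, short: int) -> np.ndarray:
    """Resize so the shorter side equals ``short`` (bilinear, PIL backend)."""
    h, w = img.shape[:2]
    if min(h, w) == short:
        return img
    if h <= w:
        nh, nw = short, max(1, round(w * short / h))
    else:
        nh, nw = max(1, round(h * short / w)), short
    pil = Image.fromarray(img)
    return np.asarray(pil.resize((nw, nh), Image.BILINEAR))


def compute_channel_stats(records: Sequence[ImageRecord]) -> Tuple[np.ndarray, np.ndarray]:
    """Per-channel mean and sd of the pixel values (scaled to [0, 1]) of a record set."""
    s = np.zeros(3)
    s2 = np.zeros(3)
    n = 0
    for r in records:
        x = r.load().astype(np.float64) / 255.0
        s += x.sum(axis=(0, 1))
        s2 += (x ** 2).sum(axis=(0, 1))
        n += x.shape[0] * x.shape[1]
    mean = s / n
    var = s2 / n - mean ** 2
    return mean, np.sqrt(np.maximum(var, 1e-12))


class EvalTransform:
    """Deterministic eval pipeline: resize shorter side, center crop, standardize.

    Output is a ``(3, size, size)`` float array, per-channel ``(x − mean) / sd`` on
    [0, 1]-scaled pixels.
    """

    def __init__(self, size: int = 224, resize_short: Optional[int] = 256,
                 mean: Sequence[float] = (0.5, 0.5, 0.5),
                 std: Sequence[float] = (0.25, 0.25, 0.25)):
        self.size = size
        self.resize_short = resize_short
        self.mean = np.asarray(mean, dtype=np.float64)
        self.std = np.asarray(std, dtype=np.float64)

    def _prepare(self, img: np.ndarray) -> np.ndarray:
        if self.resize_short is not None:
            img = _resize_short(img, self.resize_short)
        if img.shape[0] < self.size or img.shape[1] < self.size:
            raise InvalidShapeError(
                f"image {img.shape[:2]} smaller than crop {self.size} after resize")
        return img

    def _standardize(self, crop: np.ndarray) -> np.ndarray:
        x = crop.astype(np.float64) / 255.0
        x = (x - self.mean) / self.std
        return x.transpose(2, 0, 1)

    def __call__(self, img: np.ndarray) -> np.ndarray:
        img = self._prepare(img)
        top = (img.shape[0] - self.size) // 2
        left = (img.shape[1] - self.size) // 2
        return self._standardize(img[top:top + self.size, left:left + self.size])


class TrainTransform(EvalTransform):
    """Training pipeline: resize, random crop, random horizontal and vertical flips
    (p=0.5 each), standardize.  All randomness flows from the generator passed in."""

    def __init__(self, size: int = 224, resize_short: Optional[int] = 256,
                 mean: Sequence[float] = (0.5, 0.5, 0.5),
                 std: Sequence[float] = (0.25, 0.25, 0.25),
                 hflip: bool = True, vflip: bool = True,
                 rng: Optional[np.random.Generator] = None):
        super().__init__(size, resize_short, mean, std)
        self.hflip = hflip
        self.vflip = vflip
        self.rng = rng if rng is not None else np.random.default_rng(0)

    def __call__(self, img: np.ndarray) -> np.ndarray:
        img = self._prepare(img)
        top = int(self.rng.integers(0, img.shape[0] - self.size + 1))
        left = int(self.rng.integers(0, img.shape[1] - self.size + 1))
        crop = img[top:top + self.size, left:left + self.size]
        if self.hflip and self.rng.random() < 0.5:
            crop = crop[:, ::-1]
        if self.vflip and self.rng.random() < 0.5:
            crop = crop[::-1]
        return self._standardize(np.ascontiguousarray(crop))


# ---------------------------------------------------------------------------
# synthetic generator
# ---------------------------------------------------------------------------

#: Per-class generative recipe: (base hue, blob count, texture frequency in cycles).
DEFAULT_CLASS_SIGNAL: Dict[int, Tuple[float, int, float]] = {
    0: (0.02, 2, 2.0),
    1: (0.18, 3, 3.5),
    2: (0.38, 4, 5.0),
    3: (0.60, 5, 6.5),
    4: (0.82, 6, 8.0),
}


@dataclass
class SyntheticConfig:
    per_class_counts: Dict[int, int] = field(
        default_factory=lambda: {k: 50 for k in DEFAULT_LABELS})
    image_size: int = 256
    class_signal: Dict[int, Tuple[float, int, float]] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_SIGNAL))
    noise_sd: float = 0.05
    images_per_patient: int = 6
    seed: int = 0

    def __post_init__(self):
        if any(v < 0 for v in self.per_class_counts.values()):
            raise ConfigurationError("per-class counts must be >= 0")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.image_size < 8:
            raise ConfigurationError("image_size must be >= 8")


def _hsv_to_rgb(h: np.ndarray, s: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Vectorised HSV→RGB on arrays in [0, 1]; returns stacked (..., 3)."""
    h6 = (h % 1.0) * 6.0
    i = np.floor(h6).astype(int) % 6
    f = h6 - np.floor(h6)
    p = v * (1 - s)
    q = v * (1 - s * f)
    t = v * (1 - s * (1 - f))
    r = np.choose(i, [v, q, p, p, t, v])
    g = np.choose(i, [t, v, v, q, p, p])
    b = np.choose(i, [p, p, t, v, v, q])
    return np.stack([r, g, b], axis=-1)


def _render_image(label: int, signal: Tuple[float, int, float], size: int,
                  noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    hue, blob_count, tex_freq = signal
    yy, xx = np.mgrid[0:size, 0:size] / size
    sat = np.full((size, size), 0.65)
    val = 0.55 + 0.1 * np.sin(2 * np.pi * tex_freq * xx) * np.sin(2 * np.pi * tex_freq * yy)
    hmap = np.full((size, size), hue) + 0.01 * np.sin(2 * np.pi * yy)
    for _ in range(blob_count):
        cy, cx = rng.random(2)
        ry, rx = 0.08 + 0.12 * rng.random(2)
        mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 < 1.0
        val = np.where(mask, np.minimum(val + 0.25, 1.0), val)
        hmap = np.where(mask, hmap + 0.03, hmap)
    img = _hsv_to_rgb(hmap, sat, val)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_synthetic_dataset(config: SyntheticConfig) -> List[ImageRecord]:
    """Generate in-memory labelled RGB images, reproducible from ``config.seed``.

    Consecutive images of a class share a ``group_id`` (a synthetic "patient" of
    ``images_per_patient`` frames), so group-aware splitting is exercised too.
    """
    rng = np.random.default_rng(config.seed)
    records: List[ImageRecord] = []
    for label in sorted(config.per_class_counts):
        count = config.per_class_counts[label]
        signal = config.class_signal[label]
        for i in range(count):
            pix = _render_image(label, signal, config.image_size, config.noise_sd, rng)
            gid = f"c{label}p{i // max(1, config.images_per_patient)}"
            records.append(ImageRecord(label=label, pixels=pix, group_id=gid))
    return records


def write_image_folder(records: Sequence[ImageRecord], root) -> List[Path]:
    """Write records as ``root/<label>/img_<i>.png``; returns the written paths."""
    root = Path(root)
    paths = []
    counters: Dict[int, int] = {}
    for r in records:
        i = counters.get(r.label, 0)
        counters[r.label] = i + 1
        d = root / str(r.label)
        d.mkdir(parents=True, exist_ok=True)
        p = d / f"img_{i:05d}.png"
        Image.fromarray(r.load()).save(p)
        paths.append(p)
    return paths


def write_manifest(records: Sequence[ImageRecord], path, subset_of: Optional[dict] = None):
    """CSV manifest (path,label,subset,group_id); ``subset_of`` maps id(record)→name."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["path", "label", "subset", "group_id"])
        for r in records:
            subset = subset_of.get(id(r), "") if subset_of else ""
            w.writerow([str(r.path) if r.path else "", r.label, subset,
                        r.group_id or ""])
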