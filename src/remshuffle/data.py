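"""Dataset manifest handling, the stratified 8:2 split, per-class
augmentation expansion, and the robustness perturbations.

Images are 8-bit RGB arrays of shape (H, W, 3).  Datasets live on disk as
class-per-subdirectory folders (``root/<class_code>/*.png``) with a CSV
manifest (columns: crop, class_name, class_code, n_original, n_augmented,
n_test, factor).  Filenames carry no label information.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from math import floor
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

AUGMENT_OPS = ("brighten", "darken", "rot90", "rot180", "rot270",
               "rotate_free", "hflip", "vflip")

MANIFEST_COLUMNS = ["crop", "class_name", "class_code", "n_original",
                    "n_augmented", "n_test", "factor"]


# ---------------------------------------------------------------------------
# manifest
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ManifestRecord:
    crop: str
    class_name: str
    class_code: str
    n_original: int       # original training images (80% of the class)
    n_augmented: int      # training images after expansion
    n_test: int           # held-out test images (20%, floored)
    factor: int           # integer expansion factor

    def __post_init__(self):
        if self.factor < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.n_augmented != self.factor * self.n_original:
            raise ValueError(
                f"{self.class_code}: n_augmented {self.n_augmented} != "
                f"factor {self.factor} x n_original {self.n_original}")


class DatasetManifest:
    """Per-class bookkeeping for a class-per-folder image dataset."""

    def __init__(self, records: list[ManifestRecord]):
        if not records:
            raise ValueError("empty manifest")
        self.records = list(records)

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def class_codes(self) -> list[str]:
        return [r.class_code for r in self.records]

    @property
    def crops(self) -> list[str]:
        return list(dict.fromkeys(r.crop for r in self.records))

    def totals(self) -> dict[str, int]:
        return {
            "n_original": sum(r.n_original for r in self.records),
            "n_augmented": sum(r.n_augmented for r in self.records),
            "n_test": sum(r.n_test for r in self.records),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(r) for r in self.records],
                            columns=MANIFEST_COLUMNS)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        records = [
            ManifestRecord(
                crop=str(row.crop), class_name=str(row.class_name),
                class_code=str(row.class_code),
                n_original=int(row.n_original),
                n_augmented=int(row.n_augmented),
                n_test=int(row.n_test), factor=int(row.factor),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    @classmethod
    def from_csv(cls, path) -> "DatasetManifest":
        return cls.from_frame(pd.read_csv(path))


# ---------------------------------------------------------------------------
# split
# ---------------------------------------------------------------------------

def split_counts(n: int, test_ratio: float = 0.2) -> tuple[int, int]:
    """(n_train, n_test) under the floored stratified split rule."""
    if not 0 < test_ratio < 1:
        raise ValueError("test_ratio must be in (0, 1)")
    if n < 1:
        raise ValueError("empty class")
    n_test = floor(test_ratio * n)
    return n - n_test, n_test


def split_dataset(class_items: dict[str, list], test_ratio: float = 0.2,
                  seed: int = 0) -> tuple[dict[str, list], dict[str, list]]:
    """Stratified random split: per class, floor(test_ratio*n) items go to
    the test set (chosen uniformly under ``seed``), the rest to training.
    The two sides partition the input exactly."""
    rng = np.random.default_rng(seed)
    train: dict[str, list] = {}
    test: dict[str, list] = {}
    for cls in sorted(class_items):
        items = list(class_items[cls])
        _, n_test = split_counts(len(items), test_ratio)
        test_idx = set(rng.choice(len(items), size=n_test, replace=False).tolist())
        test[cls] = [it for i, it in enumerate(items) if i in test_idx]
        train[cls] = [it for i, it in enumerate(items) if i not in test_idx]
    return train, test


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _as_image(img) -> np.ndarray:
    a = np.asarray(img)
    if a.ndim != 3 or a.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    return a.astype(np.uint8)


def adjust_brightness(img: np.ndarray, factor: float) -> np.ndarray:
    """Multiply intensities by ``factor`` and clip to [0, 255]."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    a = _as_image(img).astype(np.float64) * factor
    return np.clip(np.rint(a), 0, 255).astype(np.uint8)


def rotate_image(img: np.ndarray, angle: float) -> np.ndarray:
    """Rotate about the center with reflective fill; dimensions preserved."""
    a = _as_image(img)
    # exact lossless path for quarter turns that preserve the dimensions
    if angle % 180 == 0 or (angle % 90 == 0 and a.shape[0] == a.shape[1]):
        return np.ascontiguousarray(np.rot90(a, int(angle // 90) % 4))
    out = ndimage.rotate(a.astype(np.float64), angle, axes=(0, 1),
                         reshape=False, mode="reflect", order=1)
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def flip_image(img: np.ndarray, axis: str) -> np.ndarray:
    a = _as_image(img)
    if axis == "h":
        return a[:, ::-1].copy()
    if axis == "v":
        return a[::-1].copy()
    raise ValueError(f"unknown flip axis {axis!r}")


def augment_image(img: np.ndarray, op: str,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply one named augmentation; same pixel dimensions, label preserved.

    brighten/darken multiply by 1.3/0.7; rot90/180/270 are exact; rotate_free
    draws an angle uniformly in [-30, 30] degrees from ``rng``; hflip/vflip
    are exact mirrors.
    """
    if op == "brighten":
        return adjust_brightness(img, 1.3)
    if op == "darken":
        return adjust_brightness(img, 0.7)
    if op in ("rot90", "rot180", "rot270"):
        return rotate_image(img, int(op[3:]))
    if op == "rotate_free":
        if rng is None:
            raise ValueError("rotate_free needs an rng")
        return rotate_image(img, float(rng.uniform(-30, 30)))
    if op == "hflip":
        return flip_image(img, "h")
    if op == "vflip":
        return flip_image(img, "v")
    raise ValueError(f"unknown augmentation op {op!r}")


def expand_training_set(manifest: DatasetManifest,
                        images_by_class: dict[str, list[np.ndarray]],
                        seed: int = 0) -> dict[str, list[np.ndarray]]:
    """Expand each class to its manifest expansion factor.

    Every original image contributes itself plus (factor - 1) augmented
    variants, the ops cycled deterministically per image index under the run
    seed, so the per-class output count equals the manifest's augmented
    column exactly.
    """
    out: dict[str, list[np.ndarray]] = {}
    for rec in manifest:
        imgs = images_by_class[rec.class_code]
        if len(imgs) != rec.n_original:
            raise ValueError(
                f"{rec.class_code}: got {len(imgs)} images, manifest says "
                f"{rec.n_original}")
        rng = np.random.default_rng([seed, len(rec.class_code),
                                     *map(ord, rec.class_code)])
        expanded: list[np.ndarray] = []
        for idx, img in enumerate(imgs):
            expanded.append(_as_image(img))
            for j in range(rec.factor - 1):
                op = AUGMENT_OPS[(idx + j) % len(AUGMENT_OPS)]
                expanded.append(augment_image(img, op, rng))
        assert len(expanded) == rec.n_augmented
        out[rec.class_code] = expanded
    return out


# ---------------------------------------------------------------------------
# robustness perturbations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PerturbationSpec:
    """A test-time corruption: gaussian_noise (sigma on the 0-255 scale),
    rotate (degrees) or brightness (multiplier)."""

    kind: str
    sigma: float = 25.0
    angle: float = 15.0
    factor: float = 1.0

    def __post_init__(self):
        if self.kind not in ("gaussian_noise", "rotate", "brightness"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.factor <= 0:
            raise ValueError("brightness factor must be positive")


#: the robustness battery: 15/30 degree rotations, additive gaussian noise,
#: darkened and brightened test images
ROBUSTNESS_BATTERY = {
    "rotate_15": PerturbationSpec("rotate", angle=15),
    "rotate_30": PerturbationSpec("rotate", angle=30),
    "gaussian_noise": PerturbationSpec("gaussian_noise", sigma=25),
    "brightness_down": PerturbationSpec("brightness", factor=0.6),
    "brightness_up": PerturbationSpec("brightness", factor=1.4),
}


def perturb_image(img: np.ndarray, spec: PerturbationSpec,
                  seed: int = 0) -> np.ndarray:
    """Apply a corruption; dimensions preserved, deterministic under seed."""
    a = _as_image(img)
    if spec.kind == "gaussian_noise":
        if spec.sigma == 0:
            return a.copy()
        rng = np.random.default_rng(seed)
        noisy = a.astype(np.float64) + rng.normal(0, spec.sigma, a.shape)
        return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
    if spec.kind == "rotate":
        return rotate_image(a, spec.angle)
    return adjust_brightness(a, spec.factor)


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

def save_image(img: np.ndarray, path) -> None:
    Image.fromarray(_as_image(img), mode="RGB").save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def load_class_folders(root) -> dict[str, list[np.ndarray]]:
    """Read a class-per-subdirectory image tree into per-class lists."""
    root = Path(root)
    out: dict[str, list[np.ndarray]] = {}
    for sub in sorted(p for p in root.iterdir() if p.is_dir()):
        files = sorted(list(sub.glob("*.png")) + list(sub.glob("*.jpg")))
        out[sub.name] = [load_image(f) for f in files]
    return out


def images_to_training_arrays(images_by_class: dict[str, list[np.ndarray]],
                              class_order: list[str] | None = None,
                              ) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Stack per-class image lists into (X, y) with X in NCHW float [0, 1]
    scaled and centered (mean 0.5, std 0.5 per channel)."""
    order = class_order or sorted(images_by_class)
    xs, ys = [], []
    for label, cls in enumerate(order):
        for img in images_by_class[cls]:
            xs.append(img)
            ys.append(label)
    x = np.stack(xs).astype(np.float64) / 255.0
    x = (x - 0.5) / 0.5
    x = x.transpose(0, 3, 1, 2)
    return x, np.asarray(ys, dtype=np.int64), order
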