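"""Deterministic generator of leaf-disease-like image datasets.

Each image is a cluttered earthy background with an elliptical green "leaf"
in the middle; disease classes differ *only* in their lesion parameters
(spot count, radius and color ranges), never in background or leaf
statistics, so any learnable class signal lives in the lesions.  The
generator is bit-deterministic under (spec, seed) and writes the same
class-per-folder layout + CSV manifest that the data pipeline consumes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .data import DatasetManifest, ManifestRecord, save_image


@dataclass(frozen=True)
class LesionSpec:
    """Per-class lesion appearance: number of spots, spot radius in px, and
    the mean RGB color (jittered per spot)."""

    spots: tuple[int, int] = (0, 0)          # inclusive count range
    radius: tuple[float, float] = (2.0, 4.0)  # px
    color: tuple[int, int, int] = (110, 70, 30)
    color_jitter: int = 15

    def __post_init__(self):
        if self.spots[0] < 0 or self.spots[1] < self.spots[0]:
            raise ValueError("invalid spot count range")
        if self.radius[0] <= 0 or self.radius[1] < self.radius[0]:
            raise ValueError("invalid radius range")


@dataclass(frozen=True)
class SynthSpec:
    """A synthetic dataset: class lesion specs, per-class counts, image size,
    background clutter level and difficulty."""

    class_specs: dict[str, LesionSpec]
    n_train: int = 100
    n_test: int = 25
    image_size: int = 64
    clutter: int = 12          # number of background distractor blobs
    difficulty: str = "easy"
    seed: int = 0

    def __post_init__(self):
        if not self.class_specs:
            raise ValueError("need at least one class")
        if self.n_train < 1 or self.n_test < 1:
            raise ValueError("images_per_class must be positive")
        if self.image_size < 16:
            raise ValueError("image_size too small")

    @property
    def n_classes(self) -> int:
        return len(self.class_specs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def easy_spec(seed: int = 0, n_train: int = 100, n_test: int = 25,
              image_size: int = 64) -> SynthSpec:
    """Four well-separated classes: healthy (no lesions) plus three lesion
    types with disjoint color/count/size signatures."""
    classes = {
        "healthy": LesionSpec(spots=(0, 0)),
        "brown_spot": LesionSpec(spots=(6, 10), radius=(2.5, 4.5),
                                 color=(120, 60, 20)),
        "yellow_rust": LesionSpec(spots=(12, 18), radius=(1.5, 2.5),
                                  color=(230, 200, 40)),
        "white_mold": LesionSpec(spots=(3, 5), radius=(5.0, 8.0),
                                 color=(235, 235, 235)),
    }
    return SynthSpec(class_specs=classes, n_train=n_train, n_test=n_test,
                     image_size=image_size, difficulty="easy", seed=seed)


def hard_spec(seed: int = 0, n_train: int = 100, n_test: int = 25,
              image_size: int = 64) -> SynthSpec:
    """Four classes with overlapping lesion parameter ranges (same palette
    family, overlapping counts/radii) — strictly harder than ``easy_spec``."""
    classes = {
        "healthy": LesionSpec(spots=(0, 1), radius=(1.5, 2.0),
                              color=(150, 120, 60)),
        "spot_a": LesionSpec(spots=(4, 9), radius=(2.0, 4.0),
                             color=(140, 90, 40)),
        "spot_b": LesionSpec(spots=(6, 12), radius=(2.0, 4.5),
                             color=(160, 110, 50)),
        "spot_c": LesionSpec(spots=(3, 8), radius=(2.5, 5.0),
                             color=(150, 100, 45), color_jitter=30),
    }
    return SynthSpec(class_specs=classes, n_train=n_train, n_test=n_test,
                     image_size=image_size, difficulty="hard", seed=seed)


def manifest_shaped_spec(manifest: DatasetManifest, image_size: int = 32,
                         scale: float = 0.05, seed: int = 0) -> SynthSpec:
    """A spec with one class per manifest record (counts scaled down), for
    exercising manifest/count plumbing at desk scale."""
    hue_cycle = [(120, 60, 20), (230, 200, 40), (235, 235, 235),
                 (180, 40, 40), (90, 40, 90), (40, 60, 160)]
    classes = {}
    for i, rec in enumerate(manifest):
        classes[rec.class_code] = LesionSpec(
            spots=(2 + i % 5, 4 + i % 5), radius=(1.5, 3.0),
            color=hue_cycle[i % len(hue_cycle)])
    n_train = max(int(min(r.n_original for r in manifest) * scale), 2)
    n_test = max(int(min(r.n_test for r in manifest) * scale), 1)
    return SynthSpec(class_specs=classes, n_train=n_train, n_test=n_test,
                     image_size=image_size, seed=seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _draw_disk(img: np.ndarray, cy: float, cx: float, r: float,
               color: np.ndarray) -> None:
    s = img.shape[0]
    yy, xx = np.ogrid[:s, :s]
    mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
    img[mask] = color


def render_leaf_image(lesion: LesionSpec, rng: np.random.Generator,
                      image_size: int = 64, clutter: int = 12,
                      return_mask: bool = False):
    """One synthetic leaf photograph: textured background + distractor blobs
    + green leaf ellipse + class-specific lesion spots, all inside the leaf.

    With ``return_mask=True`` also returns the boolean leaf-ellipse mask.
    """
    s = image_size
    # earthy textured background
    base = np.array([95.0, 80.0, 60.0])
    img = base + rng.normal(0, 12, (s, s, 3))
    # background clutter: random earthy blobs, identical law for every class
    for _ in range(clutter):
        cy, cx = rng.uniform(0, s, 2)
        r = rng.uniform(2, s / 6)
        color = rng.uniform(40, 150, 3)
        _draw_disk(img, cy, cx, r, color)
    # leaf ellipse
    cy, cx = s / 2 + rng.uniform(-s * 0.05, s * 0.05, 2)
    ay = rng.uniform(0.30, 0.42) * s
    ax = rng.uniform(0.30, 0.42) * s
    minor = min(ay, ax)
    if lesion.radius[1] > minor:
        raise ValueError("lesion radius exceeds the leaf minor axis")
    yy, xx = np.ogrid[:s, :s]
    leaf_mask = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    leaf_color = np.array([60.0, 140.0, 55.0]) + rng.normal(0, 8, 3)
    texture = rng.normal(0, 6, (s, s, 3))
    img[leaf_mask] = leaf_color + texture[leaf_mask]
    # lesions, fully inside the leaf ellipse
    n_spots = int(rng.integers(lesion.spots[0], lesion.spots[1] + 1))
    for _ in range(n_spots):
        r = rng.uniform(*lesion.radius)
        # sample a center whose whole disk fits in the ellipse
        for _attempt in range(100):
            ang = rng.uniform(0, 2 * np.pi)
            rho = rng.uniform(0, 1)
            py = cy + np.sqrt(rho) * (ay - r) * np.sin(ang)
            px = cx + np.sqrt(rho) * (ax - r) * np.cos(ang)
            if ((py - cy) / (ay - r)) ** 2 + ((px - cx) / (ax - r)) ** 2 <= 1:
                break
        color = np.clip(np.array(lesion.color, dtype=float)
                        + rng.normal(0, lesion.color_jitter, 3), 0, 255)
        _draw_disk(img, py, px, r, color)
    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    if return_mask:
        return out, leaf_mask
    return out


# ---------------------------------------------------------------------------
# dataset assembly
# ---------------------------------------------------------------------------

def generate_images(spec: SynthSpec) -> tuple[dict[str, list[np.ndarray]],
                                              dict[str, list[np.ndarray]]]:
    """(train, test) per-class image lists, deterministic under spec.seed."""
    train: dict[str, list[np.ndarray]] = {}
    test: dict[str, list[np.ndarray]] = {}
    for ci, (code, lesion) in enumerate(spec.class_specs.items()):
        rng = np.random.default_rng([spec.seed, ci])
        imgs = [render_leaf_image(lesion, rng, spec.image_size, spec.clutter)
                for _ in range(spec.n_train + spec.n_test)]
        train[code] = imgs[: spec.n_train]
        test[code] = imgs[spec.n_train:]
    return train, test


def generate_arrays(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray,
                                              np.ndarray, np.ndarray, list[str]]:
    """(X_train, y_train, X_test, y_test, class_order) in normalized NCHW."""
    from .data import images_to_training_arrays

    train, test = generate_images(spec)
    order = list(spec.class_specs)
    xtr, ytr, _ = images_to_training_arrays(train, order)
    xte, yte, _ = images_to_training_arrays(test, order)
    return xtr, ytr, xte, yte, order


def synthetic_manifest(spec: SynthSpec, factor: int = 1) -> DatasetManifest:
    records = [
        ManifestRecord(crop="synthetic", class_name=code, class_code=code,
                       n_original=spec.n_train,
                       n_augmented=factor * spec.n_train,
                       n_test=spec.n_test, factor=factor)
        for code in spec.class_specs
    ]
    return DatasetManifest(records)


def generate_dataset(spec: SynthSpec, out_dir) -> DatasetManifest:
    """Write the dataset to disk: train/<class>/*.png, test/<class>/*.png,
    manifest.csv and the resolved spec as JSON.  Returns the manifest."""
    out = Path(out_dir)
    train, test = generate_images(spec)
    for split, images in (("train", train), ("test", test)):
        for code, imgs in images.items():
            d = out / split / code
            d.mkdir(parents=True, exist_ok=True)
            for i, img in enumerate(imgs):
                save_image(img, d / f"img_{i:05d}.png")
    manifest = synthetic_manifest(spec)
    manifest.to_csv(out / "manifest.csv")
    (out / "spec.json").write_text(json.dumps(spec.to_dict(), indent=2))
    return manifest
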