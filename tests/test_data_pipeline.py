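"""Dataset arithmetic and image transforms: the floored stratified split
reproduces the reference manifest's printed (train, test) pairs, expansion
reproduces the augmented counts, and all transforms are label- and
dimension-preserving."""

import numpy as np
import pytest

from remshuffle.data import (
    AUGMENT_OPS,
    DatasetManifest,
    ManifestRecord,
    PerturbationSpec,
    ROBUSTNESS_BATTERY,
    adjust_brightness,
    augment_image,
    expand_training_set,
    flip_image,
    perturb_image,
    rotate_image,
    split_counts,
    split_dataset,
)
from remshuffle.manifest_presets import field_crop_manifest

RNG = np.random.default_rng(2024)


def random_image(size=16, rng=RNG):
    return rng.integers(0, 256, (size, size, 3), dtype=np.uint8)


# ---------------------------------------------------------------------------
# manifest + split arithmetic
# ---------------------------------------------------------------------------

def test_reference_manifest_totals():
    m = field_crop_manifest()
    assert len(m) == 22
    assert m.totals() == {"n_original": 6732, "n_augmented": 22217,
                          "n_test": 1676}
    assert len(m.crops) == 6


def test_floored_split_reconstructs_every_reference_pair():
    """Reapplying the 20% floored split to each class's reconstructed total
    must give back every printed (train, test) pair."""
    for rec in field_crop_manifest():
        n_total = rec.n_original + rec.n_test
        n_train, n_test = split_counts(n_total, 0.2)
        assert (n_train, n_test) == (rec.n_original, rec.n_test), rec.class_code


@pytest.mark.parametrize("n,expected", [(273, (219, 54)), (412, (330, 82)),
                                        (5, (4, 1))])
def test_split_counts_examples(n, expected):
    assert split_counts(n, 0.2) == expected


def test_split_dataset_partitions_each_class():
    items = {"a": list(range(273)), "b": list(range(31))}
    train, test = split_dataset(items, 0.2, seed=11)
    for cls, pool in items.items():
        assert len(test[cls]) == int(0.2 * len(pool))
        assert sorted(train[cls] + test[cls]) == pool
        assert set(train[cls]).isdisjoint(test[cls])


def test_split_dataset_is_seeded_and_random():
    items = {"a": list(range(100))}
    t1, _ = split_dataset(items, 0.2, seed=1)
    t2, _ = split_dataset(items, 0.2, seed=1)
    t3, _ = split_dataset(items, 0.2, seed=2)
    assert t1 == t2
    assert t1 != t3


def test_split_rejects_bad_input():
    with pytest.raises(ValueError):
        split_dataset({"a": []}, 0.2, 0)
    with pytest.raises(ValueError):
        split_counts(10, 1.5)


def test_manifest_record_consistency_enforced():
    with pytest.raises(ValueError):
        ManifestRecord("c", "n", "X1", n_original=10, n_augmented=25,
                       n_test=2, factor=2)
    with pytest.raises(ValueError):
        ManifestRecord("c", "n", "X1", n_original=10, n_augmented=0,
                       n_test=2, factor=0)


def test_manifest_csv_roundtrip(tmp_path):
    m = field_crop_manifest()
    path = tmp_path / "manifest.csv"
    m.to_csv(path)
    back = DatasetManifest.from_csv(path)
    assert back.to_frame().equals(m.to_frame())


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def test_brightness_identity_and_clipping():
    img = random_image()
    np.testing.assert_array_equal(adjust_brightness(img, 1.0), img)
    hot = np.full((4, 4, 3), 200, dtype=np.uint8)
    assert np.all(adjust_brightness(hot, 1.3) == 255)  # 260 clips to 255
    dark = adjust_brightness(hot, 0.7)
    assert np.all(dark == 140)


def test_flips_are_involutions():
    img = random_image()
    np.testing.assert_array_equal(flip_image(flip_image(img, "h"), "h"), img)
    np.testing.assert_array_equal(flip_image(flip_image(img, "v"), "v"), img)
    assert not np.array_equal(flip_image(img, "h"), img)


def test_rotations_preserve_dimensions():
    img = random_image(17)
    for angle in (15, 30, 90, 180, 270, -22.5):
        out = rotate_image(img, angle)
        assert out.shape == img.shape
    np.testing.assert_array_equal(rotate_image(rotate_image(img, 180), 180), img)


def test_augment_ops_contract():
    img = random_image()
    rng = np.random.default_rng(0)
    for op in AUGMENT_OPS:
        out = augment_image(img, op, rng)
        assert out.shape == img.shape and out.dtype == np.uint8
    with pytest.raises(ValueError):
        augment_image(img, "solarize")


def test_expansion_matches_manifest_counts_exactly():
    records = [
        ManifestRecord("synthetic", "a", "a", 5, 40, 1, 8),   # factor 8
        ManifestRecord("synthetic", "b", "b", 4, 4, 1, 1),    # factor 1
        ManifestRecord("synthetic", "c", "c", 3, 9, 1, 3),
    ]
    manifest = DatasetManifest(records)
    images = {r.class_code: [random_image(12) for _ in range(r.n_original)]
              for r in records}
    out = expand_training_set(manifest, images, seed=0)
    for r in records:
        assert len(out[r.class_code]) == r.n_augmented
    # factor 1 leaves the class untouched
    for orig, got in zip(images["b"], out["b"]):
        np.testing.assert_array_equal(orig, got)
    # originals always appear first in each image's block
    np.testing.assert_array_equal(out["a"][0], images["a"][0])
    with pytest.raises(ValueError):
        expand_training_set(manifest, {**images, "a": images["a"][:-1]}, 0)


def test_expansion_factor_times_count_reproduces_reference_augmented_column():
    for rec in field_crop_manifest():
        assert rec.factor * rec.n_original == rec.n_augmented
    assert sum(r.factor * r.n_original for r in field_crop_manifest()) == 22217


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

def test_perturbation_spec_validation():
    with pytest.raises(ValueError):
        PerturbationSpec("blur")
    with pytest.raises(ValueError):
        PerturbationSpec("gaussian_noise", sigma=-1)
    with pytest.raises(ValueError):
        PerturbationSpec("brightness", factor=0)


def test_zero_sigma_noise_is_identity():
    img = random_image()
    out = perturb_image(img, PerturbationSpec("gaussian_noise", sigma=0), 0)
    np.testing.assert_array_equal(out, img)


def test_noise_is_deterministic_under_seed_and_dimension_preserving():
    img = random_image(32)
    spec = PerturbationSpec("gaussian_noise", sigma=25)
    a = perturb_image(img, spec, seed=3)
    b = perturb_image(img, spec, seed=3)
    c = perturb_image(img, spec, seed=4)
    np.testing.assert_array_equal(a, b)
    assert not np.array_equal(a, c)
    assert a.shape == img.shape


def test_noise_mean_absolute_change_matches_folded_normal():
    # on mid-gray, |N(0, 25^2)| has mean 25*sqrt(2/pi) ~ 19.95
    img = np.full((64, 64, 3), 128, dtype=np.uint8)
    out = perturb_image(img, PerturbationSpec("gaussian_noise", sigma=25), 0)
    mac = np.abs(out.astype(float) - 128).mean()
    assert mac == pytest.approx(25 * np.sqrt(2 / np.pi), rel=0.05)


def test_robustness_battery_contract():
    img = random_image(20)
    assert set(ROBUSTNESS_BATTERY) == {"rotate_15", "rotate_30",
                                       "gaussian_noise", "brightness_down",
                                       "brightness_up"}
    for spec in ROBUSTNESS_BATTERY.values():
        out = perturb_image(img, spec, 0)
        assert out.shape == img.shape
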