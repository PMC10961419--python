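"""Reference dataset manifest for the 22-class, 6-crop field leaf-disease
collection: per class, the crop, the original training count (80% of the
class), the augmented training count, the held-out test count (20%, floored)
and the integer expansion factor.  Used for split/augmentation arithmetic and
as the shape template for synthetic datasets."""

from __future__ import annotations

from .data import DatasetManifest, ManifestRecord

# crop, class name, code, n_original(train), n_augmented, n_test
_ROWS = [
    ("Apple", "Alternaria leaf spot", "A1", 219, 1095, 54),
    ("Apple", "Grey spot", "A2", 131, 1048, 32),
    ("Apple", "Health", "A3", 516, 1032, 129),
    ("Apple", "Mosaic", "A4", 137, 1096, 34),
    ("Apple", "Powdery mildew", "A5", 549, 1098, 137),
    ("Apple", "Rust", "A6", 447, 894, 111),
    ("Apple", "Scab", "A7", 477, 954, 119),
    ("Bean", "Angular leaf spot", "B1", 264, 1056, 66),
    ("Bean", "Bean rust", "B2", 264, 1056, 66),
    ("Bean", "Healthy", "B3", 264, 1056, 66),
    ("Maize", "Gray leaf spot", "M1", 398, 1194, 99),
    ("Maize", "Health", "M2", 265, 1060, 66),
    ("Maize", "Northern leaf blight", "M3", 419, 1257, 104),
    ("Maize", "Northern leaf spot", "M4", 441, 882, 110),
    ("Strawberry", "Calcium deficiency", "S1", 378, 1134, 94),
    ("Strawberry", "Healthy", "S2", 369, 1107, 92),
    ("Sugarcane", "Bacterial blight", "SU1", 80, 640, 20),
    ("Sugarcane", "Healthy", "SU2", 80, 640, 20),
    ("Sugarcane", "Red rot", "SU3", 80, 640, 20),
    ("Wheat", "Powdery mildew", "W1", 208, 1040, 51),
    ("Wheat", "Smut", "W2", 330, 990, 82),
    ("Wheat", "Rust", "W3", 416, 1248, 104),
]


def field_crop_manifest() -> DatasetManifest:
    """The 22-class reference manifest (6 crops, 6732 train / 1676 test
    originals, 22217 augmented training images)."""
    records = [
        ManifestRecord(
            crop=crop, class_name=name, class_code=code,
            n_original=before, n_augmented=after, n_test=test,
            factor=after // before,
        )
        for crop, name, code, before, after, test in _ROWS
    ]
    return DatasetManifest(records)


def crop_grouping(manifest: DatasetManifest | None = None) -> dict[int, str]:
    """Class index -> crop name map, in manifest order."""
    m = manifest or field_crop_manifest()
    return {i: r.crop for i, r in enumerate(m.records)}
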