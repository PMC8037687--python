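"""Per-pixel classification of cubes into residue label maps.

Every pixel's band-intercepted spectrum is classified independently, the
predicted class indices are reassembled into an H x W image, and a leaf-level
residue call is made by majority vote over the leaf region.  Per-pixel errors
grow with the number of mixed components, but the majority label remains a
robust leaf-level identification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .peak_tables import CLASS_NAMES
from .preprocess import DEFAULT_BAND, band_indices
from .synthetic import HyperCube

__all__ = [
    "LabelMap",
    "DEFAULT_PALETTE",
    "predict_map",
    "majority_call",
    "render_map",
    "read_map",
    "save_labels_csv",
]

#: Categorical 9-class palette (class label -> RGB), colorblind-conscious.
DEFAULT_PALETTE = {
    1: (64, 64, 64),      # BG: dark gray tape
    2: (102, 194, 165),   # CK
    3: (252, 141, 98),    # BNL
    4: (141, 160, 203),   # BCM
    5: (231, 138, 195),   # TBZ
    6: (166, 216, 84),    # M1
    7: (255, 217, 47),    # M2
    8: (229, 196, 148),   # M3
    9: (179, 179, 179),   # M4
}


@dataclass
class LabelMap:
    """H x W integer class predictions reconstructed into an image."""

    labels: np.ndarray
    class_names: dict = field(default_factory=lambda: dict(CLASS_NAMES))
    source_cube_id: str = ""
    majority_class: int | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("label map must be 2-D")
        bad = set(np.unique(self.labels)) - set(self.class_names)
        if bad:
            raise ValueError(f"labels outside 1..9: {sorted(bad)}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape


def predict_map(model, cube: HyperCube, band=DEFAULT_BAND) -> LabelMap:
    """Classify every pixel of a cube independently.

    The per-pixel spectra are intercepted to ``band`` and must match the
    feature convention the model was trained on.  Prediction at (i, j) equals
    classifying that pixel's spectrum alone (pixelwise independence).
    """
    idx = band_indices(cube.grid.values, *band)
    n_feat = getattr(
        model, "n_features_in_", getattr(getattr(model, "estimator", None),
                                         "n_features_in_", None)
    )
    if n_feat is not None and n_feat != len(idx):
        raise ValueError(
            f"band {band} yields {len(idx)} features but the model was "
            f"trained on {n_feat}"
        )
    h, w, _ = cube.data.shape
    X = cube.data.reshape(h * w, -1)[:, idx]
    labels = np.asarray(model.predict(X)).reshape(h, w)
    lm = LabelMap(labels, source_cube_id=f"class{cube.true_class}_seed{cube.seed}")
    lm.majority_class = majority_call(lm, cube.leaf_mask)
    return lm


def majority_call(label_map: LabelMap | np.ndarray, leaf_mask: np.ndarray) -> int:
    """Modal predicted label over the leaf region (class 1 if mask empty).

    Ties break deterministically toward the smallest class index.
    """
    labels = label_map.labels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    leaf_mask = np.asarray(leaf_mask, dtype=bool)
    if labels.shape != leaf_mask.shape:
        raise ValueError("mask shape does not match label map")
    if not leaf_mask.any():
        return 1
    return int(np.bincount(labels[leaf_mask]).argmax())


def render_map(label_map: LabelMap, path, palette: dict | None = None) -> str:
    """Write a lossless PNG (one pixel per label) plus a JSON legend sidecar."""
    palette = palette or DEFAULT_PALETTE
    missing = set(label_map.class_names) - set(palette)
    if missing:
        raise ValueError(f"palette lacks colors for classes {sorted(missing)}")
    h, w = label_map.labels.shape
    rgb = np.zeros((h, w, 3), dtype=np.uint8)
    for cls, color in palette.items():
        rgb[label_map.labels == cls] = color
    path = str(path)
    try:
        Image.fromarray(rgb).save(path, format="PNG")
        legend = {
            str(cls): {"name": label_map.class_names.get(cls, str(cls)),
                       "rgb": list(palette[cls])}
            for cls in sorted(label_map.class_names)
        }
        with open(path + ".legend.json", "w") as fh:
            json.dump(legend, fh, indent=2)
    except OSError as exc:
        raise OSError(f"failed writing label map to {path}: {exc}") from exc
    return path


def save_labels_csv(label_map: LabelMap, path) -> None:
    """Raw label matrix as integer CSV (one row per image row)."""
    np.savetxt(path, label_map.labels, fmt="%d", delimiter=",")


def read_map(path, palette: dict | None = None) -> np.ndarray:
    """Invert :func:`render_map`: recover the label matrix from the PNG."""
    palette = palette or DEFAULT_PALETTE
    rgb = np.asarray(Image.open(path).convert("RGB"))
    labels = np.zeros(rgb.shape[:2], dtype=int)
    for cls, color in palette.items():
        labels[np.all(rgb == np.asarray(color, dtype=np.uint8), axis=2)] = cls
    return labels
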