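"""Reading and writing the package's on-disk artifacts.

Feature tables travel as delimited text (header row of feature names,
final ``label`` column) or parquet; masks as two-column delimited text;
images as PNG/JPEG trees with one subdirectory per class.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .selection import FeatureMatrix, SelectionMask


def write_feature_table(path, X: FeatureMatrix, labels=None) -> None:
    path = Path(path)
    frame = X.to_frame(labels)
    if path.suffix == ".parquet":
        frame.to_parquet(path)
    else:
        frame.to_csv(path, sep="\t", index=False)


def read_feature_table(path):
    """Returns ``(FeatureMatrix, labels-or-None)``."""
    path = Path(path)
    if path.suffix == ".parquet":
        frame = pd.read_parquet(path)
    else:
        frame = pd.read_csv(path, sep="\t")
    labels = None
    if "label" in frame.columns:
        labels = frame.pop("label").to_numpy()
    return FeatureMatrix(values=frame.to_numpy(float),
                         feature_names=list(frame.columns)), labels


def write_mask(path, mask: SelectionMask, feature_names) -> None:
    mask.to_frame(feature_names).to_csv(path, sep="\t", index=False)


def read_mask(path) -> SelectionMask:
    frame = pd.read_csv(path, sep="\t")
    return SelectionMask(mask=frame["selected"].to_numpy(bool), source="file")


def save_image(path, img: np.ndarray) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8)).save(path)


def load_image(path) -> np.ndarray:
    return np.asarray(Image.open(path))


def save_image_tree(root, images, labels, class_names=("no", "yes")) -> None:
    """Write images into ``root/<class>/img_*.png`` by label."""
    root = Path(root)
    counters = {}
    for img, label in zip(images, labels):
        name = class_names[int(label)]
        sub = root / name
        sub.mkdir(parents=True, exist_ok=True)
        i = counters.get(name, 0)
        counters[name] = i + 1
        save_image(sub / f"img_{i:04d}.png", img)


def load_image_tree(root, class_names=("no", "yes")):
    """Read a class-per-subdirectory image tree.

    Labels map subdirectory ``no`` (no pest) to 0 and ``yes`` (pest) to
    1; files are read in sorted order for reproducibility.
    """
    root = Path(root)
    images, labels = [], []
    for label, name in enumerate(class_names):
        sub = root / name
        if not sub.is_dir():
            raise FileNotFoundError(f"missing class directory: {sub}")
        for path in sorted(sub.iterdir()):
            if path.suffix.lower() in (".png", ".jpg", ".jpeg"):
                images.append(load_image(path))
                labels.append(label)
    return images, np.asarray(labels)
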