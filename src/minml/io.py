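"""Reading and writing feature tables, image datasets and run configs."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .dmeans import FeatureDataset
from .imaging import PreprocessConfig, preprocess_pipeline

__all__ = [
    "load_feature_csv",
    "save_feature_csv",
    "load_gray_image",
    "load_image_dataset",
    "RunConfig",
]


def load_feature_csv(path, label_column: str = "label") -> FeatureDataset:
    """Read a delimited feature table: rows = patterns, columns =
    attributes plus one label column.

    Attribute positions are 1-based in column order (label column
    excluded).  Any missing cell is a hard error naming its row and
    column; exactly two classes are required.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    na = df.isna()
    if na.values.any():
        row = int(np.argwhere(na.values)[0][0])
        col = df.columns[int(np.argwhere(na.values)[0][1])]
        raise ValueError(f"missing value at row {row}, column {col!r} in {path}")
    labels = df[label_column].to_numpy()
    attrs = df.drop(columns=[label_column])
    try:
        patterns = attrs.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric attribute values in {path}: {exc}") from exc
    return FeatureDataset(patterns, labels)


def save_feature_csv(ds: FeatureDataset, path, label_column: str = "label") -> None:
    """Write a feature table as CSV (attributes a1..an + label column)."""
    df = pd.DataFrame(ds.patterns, columns=[f"a{i}" for i in range(1, ds.n + 1)])
    df[label_column] = ds.labels
    # %.17g round-trips any float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def load_gray_image(path) -> np.ndarray:
    """Read an 8-bit grayscale raster; color inputs are converted by the
    standard luminance weights."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), dtype=np.uint8)


def load_image_dataset(
    root, config: PreprocessConfig | None = None
) -> tuple[FeatureDataset, list]:
    """Load a two-class image directory and preprocess every image.

    ``<root>/<class_name>/*.png|jpg`` — exactly two class subdirectories,
    each non-empty.  Images are visited in sorted path order (so the
    dataset, and hence the LOOCV folds, are reproducible), run through
    :func:`minml.imaging.preprocess_pipeline` and flattened.

    Returns the flattened dataset and the sorted list of image paths.
    """
    root = Path(root)
    config = config or PreprocessConfig()
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if len(class_dirs) != 2:
        raise ValueError(f"expected exactly two class subdirectories under {root}")
    patterns, labels, paths = [], [], []
    shape = None
    for class_dir in class_dirs:
        files = sorted(
            p for p in class_dir.iterdir()
            if p.suffix.lower() in (".png", ".jpg", ".jpeg")
        )
        if not files:
            raise ValueError(f"class directory {class_dir} contains no images")
        for f in files:
            img = load_gray_image(f)
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(
                    f"inconsistent image shape {img.shape} for {f}, expected {shape}"
                )
            patterns.append(preprocess_pipeline(img, config).pattern)
            labels.append(class_dir.name)
            paths.append(f)
    return FeatureDataset(np.asarray(patterns, dtype=float), np.asarray(labels, dtype=object)), paths


@dataclass
class RunConfig:
    """Everything needed to reproduce a run exactly."""

    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    mode: str = "signed"
    k_schedule: list | None = None
    tie_policy: str = "below"
    positive_label: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "preprocess": self.preprocess.to_dict(),
            "mode": self.mode,
            "k_schedule": self.k_schedule,
            "tie_policy": self.tie_policy,
            "positive_label": self.positive_label,
            "seed": self.seed,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        pre = payload.pop("preprocess", None)
        cfg = cls(**payload)
        if pre is not None:
            cfg.preprocess = PreprocessConfig.from_dict(pre)
        return cfg

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
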