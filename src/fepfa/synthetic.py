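"""Synthetic study data: planted-signal feature matrices and phantom images.

The real study data are four-class dementia-stage MRI scans whose deep
features arrive as an N x 2,048 real matrix. This module generates a
stand-in with the same post-extraction shape: a minority of columns carry
class signal (Gaussian class means on a scaled one-hot simplex), the rest
are label-independent N(0, 1) noise. A simple geometric phantom image with
a corner marker serves as the fixture for the augmentation and enhancement
operators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image


@dataclass
class LabeledFeatureMatrix:
    """N samples x d features with integer class labels in {0..C-1}.

    The container every selection and classification stage acts on.
    """

    values: np.ndarray
    labels: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        n, d = self.values.shape
        if d < 1:
            raise ValueError("need at least one feature")
        if self.labels.shape != (n,):
            raise ValueError("labels length must match the number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values must be finite (no missing entries)")
        classes = np.unique(self.labels)
        if n < classes.size:
            raise ValueError("need at least one sample per class")
        if not self.feature_ids:
            self.feature_ids = [f"f{j}" for j in range(d)]
        if len(self.feature_ids) != d:
            raise ValueError("feature_ids length must match feature count")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(np.unique(self.labels).size)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values, columns=self.feature_ids)
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, label_col: str = "label") -> "LabeledFeatureMatrix":
        df = pd.read_csv(path)
        if label_col not in df.columns:
            raise ValueError(f"missing label column {label_col!r}")
        labels = df[label_col].to_numpy(dtype=int)
        feats = df.drop(columns=[label_col])
        return cls(feats.to_numpy(dtype=float), labels, list(feats.columns))


@dataclass
class PlantedTruth:
    """Ground truth for recovery experiments: which columns carry signal."""

    informative_mask: np.ndarray
    effect_size: float

    def __post_init__(self) -> None:
        self.informative_mask = np.asarray(self.informative_mask, dtype=bool)
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.effect_size > 0 and not self.informative_mask.any():
            raise ValueError("positive effect_size requires informative features")


@dataclass
class ImageGrid:
    """H x W (optionally x3) intensity grid in [0, 1], origin top-left."""

    intensities: np.ndarray

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (2, 3):
            raise ValueError("image must be 2-D or H x W x 3")
        if self.intensities.ndim == 3 and self.intensities.shape[2] != 3:
            raise ValueError("color images must have exactly 3 channels")
        h, w = self.intensities.shape[:2]
        if h < 1 or w < 1:
            raise ValueError("image dimensions must be positive")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if self.intensities.min() < 0 or self.intensities.max() > 1:
            raise ValueError("intensities must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    def to_png(self, path: str | Path) -> None:
        arr = np.clip(np.round(self.intensities * 255), 0, 255).astype(np.uint8)
        Image.fromarray(arr).save(path)

    @classmethod
    def from_png(cls, path: str | Path) -> "ImageGrid":
        arr = np.asarray(Image.open(path))
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
        return cls(arr.astype(float) / 255.0)


def make_gaussian_feature_data(
    n_per_class: int,
    n_classes: int,
    d: int,
    d_informative: int,
    effect_size: float,
    seed: int,
) -> tuple[LabeledFeatureMatrix, PlantedTruth]:
    """Draw a balanced labeled matrix with planted informative columns.

    Informative columns are assigned round-robin to classes. The mean
    vector of class c is ``effect_size`` times the unit-norm indicator
    pattern over its owned columns (a scaled simplex vertex), so every
    class-mean pair is separated by exactly ``effect_size * sqrt(2)`` —
    symmetric difficulty across the four dementia-stage stand-in classes,
    with each individual column carrying only a fraction of the signal so
    that subset search has a real error gradient. Unit variance throughout;
    remaining columns are N(0, 1) independent of the labels.
    """
    if n_per_class < 2 or n_classes < 2:
        raise ValueError("need n_per_class >= 2 and n_classes >= 2")
    if not 0 <= d_informative <= d:
        raise ValueError("need 0 <= d_informative <= d")
    if d < 1:
        raise ValueError("need at least one feature")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if effect_size > 0 and d_informative == 0:
        raise ValueError("positive effect_size requires d_informative >= 1")

    rng = np.random.default_rng(seed)
    n = n_per_class * n_classes
    labels = np.repeat(np.arange(n_classes), n_per_class)
    values = rng.standard_normal((n, d))

    informative = np.zeros(d, dtype=bool)
    informative[:d_informative] = True
    owner = np.arange(d_informative) % n_classes  # round-robin class assignment
    for c in range(n_classes):
        owned = np.flatnonzero(owner == c)
        if owned.size:
            shift = effect_size / np.sqrt(owned.size)  # unit-norm class pattern
            for j in owned:
                values[labels == c, j] += shift

    # shuffle rows so class blocks are not contiguous
    order = rng.permutation(n)
    data = LabeledFeatureMatrix(values[order], labels[order])
    return data, PlantedTruth(informative, effect_size)


def make_phantom_image(
    h: int,
    w: int,
    fg_level: float,
    bg_level: float,
    shape: str = "disc",
    seed: int = 0,
) -> ImageGrid:
    """Centered bright shape on a darker background, marker pixel top-left.

    The marker breaks every reflection/rotation symmetry so flips and
    quarter-turns are detectable in tests. The phantom is noise-free and
    therefore independent of ``seed`` (kept for interface symmetry).
    """
    if h < 1 or w < 1:
        raise ValueError("dimensions must be positive")
    if not (0 <= bg_level < fg_level <= 1):
        raise ValueError("need 0 <= bg_level < fg_level <= 1")
    if shape not in ("disc", "square"):
        raise ValueError(f"unknown shape {shape!r}")

    img = np.full((h, w), bg_level, dtype=float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = min(h, w) / 4.0
    yy, xx = np.mgrid[0:h, 0:w]
    if shape == "disc":
        inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    else:
        inside = (np.abs(yy - cy) <= r) & (np.abs(xx - cx) <= r)
    img[inside] = fg_level
    img[0, 0] = fg_level  # corner marker
    return ImageGrid(img)


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a boolean mask as a one-column CSV of 0/1."""
    pd.DataFrame({"selected": np.asarray(mask, dtype=int)}).to_csv(path, index=False)


def load_mask(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path)
    return df.iloc[:, 0].to_numpy(dtype=int).astype(bool)
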