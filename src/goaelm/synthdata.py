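"""Synthetic stand-ins for restricted clinical MRI data.

The motivating task — two-class (tumor vs. no-tumor) classification of
brain MRI slices — uses access-restricted clinical images, so this module
generates download-free surrogates at two levels of realism:

* **feature clusters** — two isotropic Gaussian clouds with a controllable
  separation, standing in for already-extracted image features (fast unit
  tests, classifier behaviour);
* **toy head images** — a mid-gray head ellipse on a dark background with
  additive Gaussian noise; positive-class images carry one bright
  ellipsoidal blob ("tumor") placed inside the head (exercises the full
  preprocess → convolve → classify pipeline).

Neither surrogate models MRI physics, multi-modality acquisitions, or
tumor morphology; they provide a labeled signal of tunable difficulty.
All generators are bit-reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from sklearn.model_selection import train_test_split

from .elm import TrainingSet

__all__ = [
    "FeatureDatasetSpec",
    "ImageDatasetSpec",
    "generate_feature_dataset",
    "generate_synthetic_images",
    "split_dataset",
    "easy_image_spec",
]


@dataclass(frozen=True)
class FeatureDatasetSpec:
    """Two Gaussian clusters whose means sit ``class_separation`` sigmas apart."""

    n_samples: int = 200
    n_features: int = 5
    class_separation: float = 4.0
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 4 or self.n_features < 1:
            raise ValueError("need n_samples >= 4 and n_features >= 1")
        if self.class_separation < 0:
            raise ValueError("class_separation must be nonnegative")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class_balance must lie in (0,1)")


def generate_feature_dataset(spec: FeatureDatasetSpec) -> TrainingSet:
    """Isotropic unit-variance clusters separated along a random unit vector."""
    rng = np.random.default_rng(spec.seed)
    direction = rng.standard_normal(spec.n_features)
    direction /= np.linalg.norm(direction)
    n1 = int(round(spec.n_samples * spec.class_balance))
    n0 = spec.n_samples - n1
    offset = spec.class_separation * direction
    X0 = rng.standard_normal((n0, spec.n_features))
    X1 = rng.standard_normal((n1, spec.n_features)) + offset
    X = np.vstack([X0, X1])
    y = np.concatenate([np.zeros(n0, dtype=int), np.ones(n1, dtype=int)])
    perm = rng.permutation(spec.n_samples)
    return TrainingSet.from_class_labels(X[perm], y[perm])


@dataclass(frozen=True)
class ImageDatasetSpec:
    """Toy head phantoms; positives carry one bright blob inside the head."""

    n_images: int = 200
    image_size: int = 227
    tumor_fraction: float = 0.5
    blob_radius_range: Tuple[int, int] = (10, 22)
    blob_intensity_lift: float = 0.35
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.tumor_fraction < 1.0):
            raise ValueError("tumor_fraction must lie in (0,1)")
        lo, hi = self.blob_radius_range
        if not (0 < lo <= hi < self.image_size * 0.3):
            raise ValueError("blob radii must be positive and fit inside the head")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def easy_image_spec(n_images: int = 200, seed: int = 0) -> ImageDatasetSpec:
    """A high-lift, low-noise configuration for end-to-end smoke studies."""
    return ImageDatasetSpec(
        n_images=n_images,
        blob_intensity_lift=0.45,
        noise_sd=0.02,
        seed=seed,
    )


_BACKGROUND = 0.05
_HEAD_LEVEL = 0.45


def _render_phantom(
    spec: ImageDatasetSpec, rng: np.random.Generator, with_blob: bool
) -> np.ndarray:
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s].astype(float)
    cy = cx = (s - 1) / 2.0
    # head ellipse fills most of the frame, slightly taller than wide
    ry, rx = 0.46 * s, 0.38 * s
    head = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    img = np.full((s, s), _BACKGROUND)
    img[head] = _HEAD_LEVEL
    if with_blob:
        r = rng.uniform(*spec.blob_radius_range)
        # placement within the inner 60% of the head so resizing never clips
        theta = rng.uniform(0.0, 2.0 * np.pi)
        rho = np.sqrt(rng.uniform(0.0, 1.0)) * 0.6
        by = cy + rho * ry * np.sin(theta)
        bx = cx + rho * rx * np.cos(theta)
        stretch = rng.uniform(0.7, 1.3)
        blob = ((yy - by) / (r * stretch)) ** 2 + ((xx - bx) / r) ** 2 <= 1.0
        img[blob] += spec.blob_intensity_lift
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, 1.0)


def generate_synthetic_images(
    spec: ImageDatasetSpec, out_dir: Union[str, Path]
) -> pd.DataFrame:
    """Write PNG phantoms + ``manifest.csv`` (+ spec YAML) to ``out_dir``.

    Returns the manifest DataFrame (columns: filepath, label) whose rows
    match the files on disk; filepaths are relative to ``out_dir``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    n_pos = int(round(spec.n_images * spec.tumor_fraction))
    labels = np.concatenate(
        [np.ones(n_pos, dtype=int), np.zeros(spec.n_images - n_pos, dtype=int)]
    )
    rng.shuffle(labels)
    rows = []
    for i, label in enumerate(labels):
        img = _render_phantom(spec, rng, with_blob=bool(label))
        name = f"img_{i:05d}.png"
        Image.fromarray((img * 255).astype(np.uint8)).save(out_dir / name)
        rows.append({"filepath": name, "label": int(label)})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    (out_dir / "spec.yaml").write_text(yaml.safe_dump(asdict(spec)))
    return manifest


def split_dataset(
    manifest: pd.DataFrame, train_fraction: float = 0.8, seed: int = 0
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-label random split, disjoint and exhaustive."""
    if not (0.0 < train_fraction < 1.0):
        raise ValueError("train_fraction must lie in (0,1)")
    counts = manifest["label"].value_counts()
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members to split")
    train, test = train_test_split(
        manifest,
        train_size=train_fraction,
        stratify=manifest["label"],
        random_state=seed,
    )
    return train.reset_index(drop=True), test.reset_index(drop=True)
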