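"""Resizing, CLAHE contrast enhancement, hold-out splitting and grade grouping.

The preprocessing chain is order-fixed: resize -> CLAHE -> rescale to [0, 1].
Applying the chain twice is NOT equivalent to applying it once (CLAHE is not
idempotent); callers must run it exactly once per image.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from skimage import exposure, transform

from .errors import (
    ConfigurationError,
    InvalidGeometryError,
    InvalidInputError,
    InvalidSplitError,
)
from .phantom import ImageRecord, LabeledImageSet

#: CLAHE histogram bins assumed when converting the published clip limit
#: (expressed as a multiple of the uniform bin height) to skimage's
#: fraction-of-tile-pixels convention.
_CLAHE_NBINS = 256


@dataclass(frozen=True)
class PreprocConfig:
    target_size: tuple[int, int] = (112, 112)
    clahe_clip_limit: float = 5.0
    clahe_tile_grid: tuple[int, int] = (8, 8)
    intensity_rescale: bool = True

    def __post_init__(self):
        if min(self.target_size) <= 0:
            raise ConfigurationError("target_size must be positive")
        if self.clahe_clip_limit <= 0:
            raise ConfigurationError("clahe_clip_limit must be > 0")
        if min(self.clahe_tile_grid) < 1:
            raise ConfigurationError("clahe_tile_grid must be >= (1, 1)")


def resize_image(image: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Anti-aliased resize of a grayscale image to ``target_size``; uint8 out."""
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("cannot resize an empty image")
    if image.shape == tuple(target_size):
        return image.astype(np.uint8, copy=True)
    out = transform.resize(
        image.astype(np.float64),
        target_size,
        order=1,
        anti_aliasing=image.shape[0] > target_size[0],
        preserve_range=True,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def apply_clahe(
    image: np.ndarray,
    clip_limit: float = 5.0,
    tile_grid: tuple[int, int] = (8, 8),
) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on an 8-bit image.

    ``clip_limit`` follows the convention of a multiple of the mean histogram
    bin height per tile (so 5.0 means "clip bins above 5x uniform"); it is
    converted to skimage's normalized fraction internally.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise InvalidInputError("cannot equalize an empty image")
    h, w = image.shape
    if h < tile_grid[0] or w < tile_grid[1]:
        raise InvalidGeometryError(
            f"image {image.shape} smaller than tile grid {tile_grid}"
        )
    if image.std() == 0:
        # degenerate histogram: equalization is a no-op
        return image.astype(np.uint8, copy=True)
    kernel = (max(h // tile_grid[0], 1), max(w // tile_grid[1], 1))
    out = exposure.equalize_adapthist(
        image.astype(np.uint8),
        kernel_size=kernel,
        clip_limit=clip_limit / _CLAHE_NBINS,
        nbins=_CLAHE_NBINS,
    )
    return np.clip(np.round(out * 255.0), 0, 255).astype(np.uint8)


def rescale_intensity(image: np.ndarray) -> np.ndarray:
    """Map 8-bit gray levels to float32 in [0, 1] for network input."""
    return np.asarray(image, dtype=np.float32) / 255.0


def preprocess_stack(
    images: np.ndarray, config: PreprocConfig = PreprocConfig()
) -> np.ndarray:
    """Apply resize -> CLAHE -> rescale to a (n, H, W) stack; returns (n, h, w, 1)."""
    out = []
    for img in images:
        img = resize_image(img, config.target_size)
        img = apply_clahe(img, config.clahe_clip_limit, config.clahe_tile_grid)
        out.append(rescale_intensity(img) if config.intensity_rescale else img)
    stacked = np.stack(out)
    return stacked[..., np.newaxis]


@dataclass(frozen=True)
class SplitSpec:
    test_fraction: float = 0.20
    valid_fraction_of_train: float = 0.10
    stratified: bool = True
    seed: int = 0

    def __post_init__(self):
        for f in (self.test_fraction, self.valid_fraction_of_train):
            if not 0.0 < f < 1.0:
                raise ConfigurationError("split fractions must lie in (0, 1)")


def holdout_split(dataset: LabeledImageSet, spec: SplitSpec) -> LabeledImageSet:
    """Tag every record train/valid/test; disjoint, exhaustive, seed-reproducible.

    When stratified, the 80/20 hold-out and the 10%-of-train validation
    carve-out are applied within each grade, so per-grade proportions in every
    partition match the full set to within one record.
    """
    if len(dataset) == 0:
        raise InvalidSplitError("cannot split an empty dataset")
    rng = np.random.default_rng(spec.seed)
    grades = dataset.grades

    if spec.stratified:
        groups = [np.flatnonzero(grades == g) for g in range(5) if np.any(grades == g)]
    else:
        groups = [np.arange(len(dataset))]

    assignment = np.empty(len(dataset), dtype=object)
    for idx in groups:
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_test = int(round(spec.test_fraction * n))
        n_valid = int(round(spec.valid_fraction_of_train * (n - n_test)))
        if n - n_test - n_valid <= 0:
            raise InvalidSplitError(
                f"split of {n} records leaves no training data "
                f"(test={n_test}, valid={n_valid})"
            )
        assignment[idx[:n_test]] = "test"
        assignment[idx[n_test:n_test + n_valid]] = "valid"
        assignment[idx[n_test + n_valid:]] = "train"

    records = [
        ImageRecord(r.path, r.grade, split=assignment[i])
        for i, r in enumerate(dataset.records)
    ]
    return LabeledImageSet(records)


def split_counts(n_per_grade: Sequence[int], spec: SplitSpec = SplitSpec()) -> dict:
    """Per-grade train/valid/test counts implied by the hold-out rule alone."""
    out = {"train": [], "valid": [], "test": []}
    for n in n_per_grade:
        n_test = int(round(spec.test_fraction * n))
        n_valid = int(round(spec.valid_fraction_of_train * (n - n_test)))
        out["test"].append(n_test)
        out["valid"].append(n_valid)
        out["train"].append(n - n_test - n_valid)
    return out


_SCHEME_TABLES = {
    "FIVE": (0, 1, 2, 3, 4),
    "FOUR": (0, 0, 1, 2, 3),
    "THREE": (0, 0, 1, 2, 2),
    "TWO": (0, 0, 1, 1, 1),
}


@dataclass(frozen=True)
class GroupingScheme:
    """Order-preserving map from KL grades {0..4} onto k coarse classes."""

    name: str
    mapping: Callable[[int], int] = field(compare=False)
    n_classes: int

    @classmethod
    def by_name(cls, name: str) -> "GroupingScheme":
        key = name.upper()
        if key not in _SCHEME_TABLES:
            raise ConfigurationError(
                f"unknown grouping scheme {name!r}; expected one of "
                f"{sorted(_SCHEME_TABLES)}"
            )
        table = _SCHEME_TABLES[key]
        return cls(name=key, mapping=table.__getitem__, n_classes=max(table) + 1)


def map_grades(labels: Sequence[int], scheme: GroupingScheme | str) -> np.ndarray:
    """Apply a grouping scheme to a KL-grade vector."""
    if isinstance(scheme, str):
        scheme = GroupingScheme.by_name(scheme)
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() > 4):
        raise InvalidInputError("KL grades must lie in 0..4")
    return np.array([scheme.mapping(g) for g in labels], dtype=int)
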