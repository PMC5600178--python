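"""Descriptor extraction and hybrid feature-matrix assembly.

Each image contributes four descriptor blocks — msd (20), hog (81), hu (7),
zm (25) — assembled column-wise in that fixed order; the full hybrid is
133-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .preprocess import BinaryRoi, PreprocessConfig, preprocess, to_grayscale
from .msd import msd_vector, MSD_NAMES
from .hog import hog_descriptor, HOG_NAMES
from .hu import hu_from_mask, HU_NAMES
from .zernike import zernike_vector, zernike_names

BLOCK_ORDER = ("msd", "hog", "hu", "zm")
BLOCK_SIZES = {"msd": 20, "hog": 81, "hu": 7, "zm": 25}
BLOCK_NAMES = {
    "msd": [f"msd_{i:02d}" for i in range(1, 21)],
    "hog": HOG_NAMES,
    "hu": HU_NAMES,
    "zm": zernike_names(8),
}
#: machine-readable map from msd_XX column to the descriptor it holds
MSD_NAME_MAP = dict(zip(BLOCK_NAMES["msd"], MSD_NAMES))


@dataclass
class FeatureMatrix:
    """Samples x descriptors table with column names and class labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[1] != len(self.feature_names):
            raise InvalidInputError("values/feature_names width mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise InvalidInputError("feature names must be unique")
        if np.isnan(self.values).any():
            raise InvalidInputError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, columns: np.ndarray) -> "FeatureMatrix":
        cols = np.asarray(columns)
        return FeatureMatrix(
            self.values[:, cols],
            [self.feature_names[i] for i in cols],
            self.labels,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "label", self.labels)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FeatureMatrix":
        labels = df["label"].to_numpy()
        feats = df.drop(columns=["label"])
        return cls(feats.to_numpy(float), list(feats.columns), labels)


def extract_blocks(
    image: np.ndarray,
    roi: BinaryRoi | None = None,
    config: PreprocessConfig | None = None,
    hog_on_mask: bool = False,
) -> dict[str, np.ndarray]:
    """All four descriptor blocks for one image.

    If ``roi`` is not supplied the image is preprocessed first. HOG uses
    the masked grayscale crop by default (``hog_on_mask=True`` switches to
    the silhouette).
    """
    if roi is None:
        roi = preprocess(image, config)
    gray = to_grayscale(image)
    r0, c0 = roi.offset
    h, w = roi.mask.shape
    crop = gray[r0 : r0 + h, c0 : c0 + w]
    if crop.shape != roi.mask.shape:  # image was rescaled during preprocess
        crop = np.where(roi.mask, 0.0, 255.0)
        hog_on_mask = True
    msd = msd_vector(roi)
    return {
        "msd": np.array([msd[name] for name in MSD_NAMES]),
        "hog": hog_descriptor(crop, roi.mask, on_mask=hog_on_mask),
        "hu": hu_from_mask(roi.mask),
        "zm": zernike_vector(roi.mask),
    }


def assemble_features(
    per_image_blocks: list[dict[str, np.ndarray]],
    labels: np.ndarray,
    combo: tuple[str, ...] = BLOCK_ORDER,
) -> FeatureMatrix:
    """Concatenate the requested blocks column-wise in fixed order.

    ``combo`` is a subset of {msd, hog, hu, zm}; assembly order is always
    msd, hog, hu, zm regardless of the order given.
    """
    combo_set = set(combo)
    unknown = combo_set - set(BLOCK_ORDER)
    if unknown:
        raise InvalidInputError(f"unknown blocks: {sorted(unknown)}")
    if not combo_set:
        raise InvalidInputError("combo must name at least one block")
    use = [b for b in BLOCK_ORDER if b in combo_set]
    missing = [
        i
        for i, blocks in enumerate(per_image_blocks)
        if any(b not in blocks for b in use)
    ]
    if missing:
        raise InvalidInputError(f"images missing requested blocks: {missing}")
    rows = [np.concatenate([blocks[b] for b in use]) for blocks in per_image_blocks]
    names = [n for b in use for n in BLOCK_NAMES[b]]
    return FeatureMatrix(np.vstack(rows), names, labels)


def extract_features(
    images: list[np.ndarray],
    labels: np.ndarray,
    combo: tuple[str, ...] = BLOCK_ORDER,
    config: PreprocessConfig | None = None,
    hog_on_mask: bool = False,
) -> FeatureMatrix:
    """Preprocess + extract + assemble a whole image list."""
    blocks = [
        extract_blocks(img, config=config, hog_on_mask=hog_on_mask) for img in images
    ]
    return assemble_features(blocks, labels, combo)
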