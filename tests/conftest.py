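import numpy as np
import pytest

import leafmorph as lm
from leafmorph.features import extract_features
from leafmorph.preprocess import clean_and_crop


def disk_mask(radius: int, pad: int = 4) -> np.ndarray:
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:size, :size]
    c = radius + pad
    return (xx - c) ** 2 + (yy - c) ** 2 <= radius**2


def rect_mask(h: int, w: int, pad: int = 4) -> np.ndarray:
    mask = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    mask[pad : pad + h, pad : pad + w] = True
    return mask


def roi_of(mask: np.ndarray) -> lm.BinaryRoi:
    return clean_and_crop(mask, margin=2)


def smooth_silhouette(rotation: float = 0.0, scale: float = 220.0) -> np.ndarray:
    """Anti-aliased coverage map of a smooth, strongly asymmetric blade
    (two deep lobes, maximal apex taper, no thin appendages); ~29,000 px.

    The sub-pixel coverage weights make moment computations accurate
    enough to resolve 2%-level rotation/scale invariance; thin structures
    like a petiole stub rasterize too noisily for that."""
    from leafmorph.synth import render_silhouette

    params = lm.LeafParams(
        aspect=1.8,
        apex_taper=0.45,
        lobe_count=2,
        lobe_depth=0.45,
        serration_amp=0.0,
        petiole_len=0.0,
        rotation=rotation,
        scale=scale,
    )
    return render_silhouette(params, canvas=640, supersample=8)


def leaf_mask(rotation: float = 0.0, seed: int = 3, canvas: int = 256, **kwargs) -> np.ndarray:
    """Ground-truth mask of an asymmetric synthetic leaf (>= 5000 px)."""
    defaults = dict(
        aspect=2.4,
        apex_taper=0.3,
        lobe_count=3,
        lobe_depth=0.25,
        serration_amp=0.04,
        serration_freq=11,
        petiole_len=0.15,
        petiole_angle=0.2,
        scale=90.0,
    )
    defaults.update(kwargs)
    _, mask = lm.generate_leaf(
        lm.LeafParams(rotation=rotation, **defaults), seed=seed, canvas=canvas
    )
    return mask


def aa_disk(radius: int, supersample: int = 4, pad: int = 4) -> np.ndarray:
    """Anti-aliased disk: per-pixel coverage fractions in [0, 1]."""
    size = 2 * radius + 2 * pad + 1
    hi = size * supersample
    yy, xx = np.mgrid[:hi, :hi]
    c = (radius + pad) * supersample + (supersample - 1) / 2
    d = ((xx - c) ** 2 + (yy - c) ** 2) <= (radius * supersample) ** 2
    return d.reshape(size, supersample, size, supersample).mean(axis=(1, 3))


@pytest.fixture(scope="session")
def reference_dataset():
    """The 10-class, separation-0.9, 30-per-class study dataset."""
    return lm.generate_dataset(
        n_classes=10, n_per_class=30, separation=0.9, seed=0
    )


@pytest.fixture(scope="session")
def reference_features(reference_dataset):
    """Full 133-column hybrid feature matrix of the reference dataset."""
    ds = reference_dataset
    return extract_features(ds.images, ds.labels)
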