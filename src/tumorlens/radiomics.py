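"""Radiomic shape and first-order intensity descriptors of a segmented ROI.

The shape panel is computed on the largest connected component of the
binary mask (8-connectivity, single-tumor framing): pixel area, boundary
perimeter, eccentricity and solidity from region moments and the convex
hull, circularity ``4 pi area / perimeter^2``, and the equivalent
diameter of a same-area disk. The intensity panel uses all masked
pixels: mean, std, min, max, standardized skewness, excess kurtosis,
and the Shannon entropy (bits) of the G=8 uniformly quantized
histogram — the same quantization the texture stage uses.
"""

from __future__ import annotations

import numpy as np
from skimage import measure

from tumorlens.texture import quantize

__all__ = [
    "SHAPE_FEATURE_NAMES",
    "INTENSITY_FEATURE_NAMES",
    "shape_features",
    "intensity_features",
    "radiomic_features",
]

SHAPE_FEATURE_NAMES = (
    "shape_area",
    "shape_perimeter",
    "shape_eccentricity",
    "shape_solidity",
    "shape_circularity",
    "shape_equivalent_diameter",
)

INTENSITY_FEATURE_NAMES = (
    "intensity_mean",
    "intensity_std",
    "intensity_min",
    "intensity_max",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_entropy",
)


def _check_mask(mask) -> np.ndarray:
    m = np.asarray(mask)
    uniq = np.unique(m)
    if not np.all(np.isin(uniq, (0, 1))):
        raise ValueError("mask must be binary (values 0/1)")
    m = m.astype(bool)
    if not m.any():
        raise ValueError("mask is empty: no foreground pixel")
    return m


def shape_features(mask) -> dict:
    """Shape descriptors of the largest connected mask component.

    Returns a dict keyed by :data:`SHAPE_FEATURE_NAMES`. Circularity is
    1 for an ideal disk and decreases for irregular boundaries (it may
    slightly exceed 1 on small rasterized regions, where the discrete
    perimeter underestimates the continuous one).
    """
    m = _check_mask(mask)
    labels = measure.label(m, connectivity=2)
    regions = measure.regionprops(labels)
    region = max(regions, key=lambda r: r.area)
    area = float(region.area)
    perimeter = float(region.perimeter)
    if perimeter > 0:
        circularity = 4.0 * np.pi * area / perimeter**2
    else:
        circularity = 1.0  # single pixel: degenerate, maximally compact
    return {
        "shape_area": area,
        "shape_perimeter": perimeter,
        "shape_eccentricity": float(region.eccentricity),
        "shape_solidity": float(region.solidity),
        "shape_circularity": circularity,
        "shape_equivalent_diameter": float(region.equivalent_diameter_area),
    }


def intensity_features(image, mask, levels: int = 8) -> dict:
    """First-order intensity statistics over all masked pixels.

    Skewness and kurtosis are standardized third and fourth central
    moments (kurtosis with the -3 excess convention); both are defined
    as 0 for a constant ROI. Entropy is the base-2 Shannon entropy of
    the ``levels``-bin quantized histogram of the masked pixels.
    """
    arr = np.asarray(image, dtype=float)
    m = _check_mask(mask)
    if m.shape != arr.shape:
        raise ValueError(f"image shape {arr.shape} != mask shape {m.shape}")
    vals = arr[m]
    mean = float(vals.mean())
    # a constant ROI must report exactly zero spread, not rounding residue
    std = 0.0 if vals.max() == vals.min() else float(vals.std())
    if std > 0:
        z = (vals - mean) / std
        skew = float(np.mean(z**3))
        kurt = float(np.mean(z**4) - 3.0)
    else:
        skew = 0.0
        kurt = 0.0
    q = quantize(np.clip(vals, 0.0, 1.0), levels=levels)
    counts = np.bincount(q, minlength=levels).astype(float)
    p = counts / counts.sum()
    nz = p[p > 0]
    entropy = float(max(0.0, -np.sum(nz * np.log2(nz))))  # avoid -0.0
    return {
        "intensity_mean": mean,
        "intensity_std": std,
        "intensity_min": float(vals.min()),
        "intensity_max": float(vals.max()),
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_entropy": entropy,
    }


def radiomic_features(image, mask, levels: int = 8) -> dict:
    """Full radiomic panel: shape then intensity, in ledger order."""
    out = shape_features(mask)
    out.update(intensity_features(image, mask, levels=levels))
    return out
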