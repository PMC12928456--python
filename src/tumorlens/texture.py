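"""Gray-level co-occurrence matrices and Haralick-style texture features.

A GLCM for offset (distance ``d``, angle ``theta``) counts how often the
quantized intensity pair ``(i, j)`` occurs at two pixels separated by
that offset:

    P(i, j, d, theta) = sum_{x,y} delta(I(x, y) = i) * delta(I(x', y') = j)

with ``(x', y')`` the offset neighbor and only in-bounds (and in-mask,
when a mask is given) pairs counted. Four scalar features summarize the
normalized matrix:

    contrast     = sum (i - j)^2 P(i, j)
    correlation  = sum (i - mu_i)(j - mu_j) P(i, j) / (sigma_i sigma_j)
    energy       = sum P(i, j)^2            (angular second moment)
    homogeneity  = sum P(i, j) / (1 + (i - j)^2)

Conventions (stated once, used everywhere): the row axis points down;
the angle-to-offset map is theta=0: (drow, dcol) = (0, +d), 45: (-d, +d),
90: (-d, 0), 135: (-d, -d). Matrices are symmetric by default (the
directional count plus its transpose), the common Haralick convention,
which also stabilizes the correlation feature. Default quantization is
G = 8 uniform gray levels, which keeps matrices dense on small ROIs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ANGLES",
    "GLCMatrix",
    "TextureFeatureVector",
    "quantize",
    "compute_glcm",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
    "texture_features",
]

#: The four standard co-occurrence angles, in degrees.
ANGLES = (0, 45, 90, 135)

#: angle -> (row offset, col offset) per unit distance; row axis points down.
_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class GLCMatrix:
    """A co-occurrence table for one (distance, angle) offset."""

    table: np.ndarray
    levels: int
    distance: int
    angle: int
    symmetric: bool = True
    normalized: bool = True

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        if self.table.shape != (self.levels, self.levels):
            raise ValueError(
                f"table shape {self.table.shape} != ({self.levels}, {self.levels})"
            )
        if np.any(self.table < 0):
            raise ValueError("co-occurrence counts must be nonnegative")


@dataclass
class TextureFeatureVector:
    """Named texture features for every (distance, angle), plus aggregates."""

    values: np.ndarray
    names: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size:
            raise ValueError("feature-name ledger length does not match values")

    def as_dict(self) -> dict:
        return dict(zip(self.names, self.values.tolist()))


def quantize(image, levels: int = 8) -> np.ndarray:
    """Uniformly bin a [0, 1] image onto integer gray levels {0..levels-1}.

    Bin edges are uniform on [0, 1]; the right endpoint 1.0 maps to the
    top level. Monotone: x <= y implies bin(x) <= bin(y).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    arr = np.asarray(image, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image must lie in [0, 1]; apply min-max normalization first")
    q = np.floor(arr * levels).astype(np.int64)
    return np.minimum(q, levels - 1)


def compute_glcm(
    quantized,
    d: int = 1,
    theta: int = 0,
    levels: int = 8,
    symmetric: bool = True,
    normalized: bool = True,
    mask=None,
) -> GLCMatrix:
    """Build the co-occurrence matrix for one (distance, angle) offset.

    Parameters
    ----------
    quantized : 2-D integer array with values in {0..levels-1}.
    d : pixel distance >= 1.
    theta : angle in degrees, one of 0, 45, 90, 135.
    symmetric : add the transpose so P(i,j) = P(j,i).
    normalized : divide by the total pair count so entries sum to 1.
    mask : optional boolean array; a pair is counted only when both of
        its endpoints lie inside the mask.

    Raises
    ------
    ValueError if no valid pixel pair exists (ROI too small for ``d``).
    """
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {sorted(_OFFSETS)}, got {theta}")
    if d < 1:
        raise ValueError(f"distance must be >= 1, got {d}")
    grid = np.asarray(quantized)
    if grid.min() < 0 or grid.max() >= levels:
        raise ValueError(f"quantized values must lie in [0, {levels - 1}]")
    n_rows, n_cols = grid.shape
    drow, dcol = (_OFFSETS[theta][0] * d, _OFFSETS[theta][1] * d)

    # Slice out all in-bounds (source, neighbor) pairs at the offset.
    r0 = max(0, -drow)
    r1 = min(n_rows, n_rows - drow)
    c0 = max(0, -dcol)
    c1 = min(n_cols, n_cols - dcol)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(
            f"no valid pixel pair for d={d}, theta={theta} on a "
            f"{n_rows}x{n_cols} grid"
        )
    src = grid[r0:r1, c0:c1]
    dst = grid[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol]

    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m.shape != grid.shape:
            raise ValueError("mask shape does not match image shape")
        valid = m[r0:r1, c0:c1] & m[r0 + drow : r1 + drow, c0 + dcol : c1 + dcol]
        src = src[valid]
        dst = dst[valid]
    else:
        src = src.ravel()
        dst = dst.ravel()

    if src.size == 0:
        raise ValueError(
            f"no valid pixel pair inside the ROI for d={d}, theta={theta}"
        )

    table = np.zeros((levels, levels), dtype=float)
    np.add.at(table, (src, dst), 1.0)
    if symmetric:
        table = table + table.T
    if normalized:
        table = table / table.sum()
    return GLCMatrix(
        table=table,
        levels=levels,
        distance=d,
        angle=theta,
        symmetric=symmetric,
        normalized=normalized,
    )


def _require_normalized(P: GLCMatrix):
    if not P.normalized:
        raise ValueError("feature requires a normalized GLCM (entries summing to 1)")


def _index_grids(levels: int):
    i = np.arange(levels, dtype=float)
    return np.meshgrid(i, i, indexing="ij")


def glcm_contrast(P: GLCMatrix) -> float:
    """Intensity contrast between neighboring pixels: sum (i-j)^2 P(i,j)."""
    _require_normalized(P)
    ii, jj = _index_grids(P.levels)
    return float(np.sum((ii - jj) ** 2 * P.table))


def glcm_correlation(P: GLCMatrix) -> float:
    """Linear correlation of a pixel with its offset neighbor, in [-1, 1].

    Uses the marginal means and standard deviations of the normalized
    table. A single-level ROI has zero marginal variance; the feature is
    then undefined and 0 is returned with a warning so batch extraction
    over blank ROIs does not abort.
    """
    _require_normalized(P)
    ii, jj = _index_grids(P.levels)
    p_i = P.table.sum(axis=1)
    p_j = P.table.sum(axis=0)
    i = np.arange(P.levels, dtype=float)
    mu_i = float(np.sum(i * p_i))
    mu_j = float(np.sum(i * p_j))
    var_i = float(np.sum((i - mu_i) ** 2 * p_i))
    var_j = float(np.sum((i - mu_j) ** 2 * p_j))
    denom = np.sqrt(var_i * var_j)
    if denom == 0:
        warnings.warn(
            "degenerate GLCM (single gray level): correlation undefined, returning 0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    cov = float(np.sum((ii - mu_i) * (jj - mu_j) * P.table))
    return cov / denom


def glcm_energy(P: GLCMatrix) -> float:
    """Angular second moment sum P(i,j)^2 — uniformity of the texture."""
    _require_normalized(P)
    return float(np.sum(P.table**2))


def glcm_homogeneity(P: GLCMatrix) -> float:
    """Inverse difference moment sum P(i,j) / (1 + (i-j)^2)."""
    _require_normalized(P)
    ii, jj = _index_grids(P.levels)
    return float(np.sum(P.table / (1.0 + (ii - jj) ** 2)))


_FEATURE_FUNCS = (
    ("contrast", glcm_contrast),
    ("correlation", glcm_correlation),
    ("energy", glcm_energy),
    ("homogeneity", glcm_homogeneity),
)


def texture_features(
    image,
    mask=None,
    distances=(1, 2),
    levels: int = 8,
    symmetric: bool = True,
) -> TextureFeatureVector:
    """All four GLCM features over every (distance, angle) combination.

    The image is quantized to ``levels`` uniform gray levels, then for
    each distance and each of the four standard angles a symmetric
    normalized GLCM is built (restricted to ``mask`` when given) and the
    four features evaluated. A per-feature mean and range over all
    (distance, angle) combinations is appended, giving a fixed feature
    order of length ``4 * len(distances) * 4 + 8`` — 40 for the default
    two distances.
    """
    q = quantize(np.asarray(image, dtype=float), levels=levels)
    per_angle_values = []
    names = []
    # feature -> list of per-(d, theta) values, for the aggregate block
    collected = {name: [] for name, _ in _FEATURE_FUNCS}
    try:
        for d in distances:
            for theta in ANGLES:
                P = compute_glcm(
                    q, d=d, theta=theta, levels=levels, symmetric=symmetric,
                    normalized=True, mask=mask,
                )
                for fname, func in _FEATURE_FUNCS:
                    val = func(P)
                    per_angle_values.append(val)
                    names.append(f"glcm_{fname}_d{d}_a{theta}")
                    collected[fname].append(val)
    except ValueError as exc:
        raise ValueError(f"texture extraction failed on ROI: {exc}") from exc

    values = list(per_angle_values)
    for fname, _ in _FEATURE_FUNCS:
        vals = np.asarray(collected[fname])
        values.append(float(vals.mean()))
        names.append(f"glcm_{fname}_mean")
        values.append(float(vals.max() - vals.min()))
        names.append(f"glcm_{fname}_range")
    return TextureFeatureVector(values=np.asarray(values), names=names)
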