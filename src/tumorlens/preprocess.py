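"""Intensity normalization, Gaussian denoising, and seeded augmentation.

All operations act on 2-D float grayscale arrays ("image grids"). The
denoising stage is a discrete 2-D Gaussian convolution,

    G(a, b) = 1 / (2 pi sigma^2) * exp(-(a^2 + b^2) / (2 sigma^2)),

truncated to an odd ``size x size`` window and renormalized to unit sum
(the continuous constant no longer sums to 1 after truncation, and unit
sum preserves constant images). Default sigma = 1.0 with a 5 x 5 window.

Augmentation applies one random similarity + elastic transform to an
image/mask pair: rotation within +/-15 degrees, zoom within +/-10 %,
pixel translation, optional flips, and a smoothed random displacement
field (elastic deformation). The image is resampled bilinearly, the mask
nearest-neighbor so labels stay binary; a fixed seed makes the transform
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "minmax_normalize",
    "gaussian_kernel",
    "gaussian_smooth",
    "uncertainty_product",
    "AugmentParams",
    "augment",
]


def _as_image(image) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.size == 0:
        raise ValueError(f"expected a nonempty 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite pixels")
    return arr


def minmax_normalize(image) -> np.ndarray:
    """Rescale pixel intensities to [0, 1] by min-max normalization.

    Computes ``(I - I_min) / (I_max - I_min)``. Rank-preserving and
    idempotent. A constant image has no dynamic range; it is mapped to
    all zeros with a warning rather than raising, so blank backgrounds
    flow through batch pipelines.
    """
    arr = _as_image(image)
    lo = arr.min()
    hi = arr.max()
    if hi == lo:
        warnings.warn(
            "constant image: min-max normalization has zero dynamic range; "
            "returning all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)


def gaussian_kernel(sigma: float = 1.0, size: int = 5, normalize: bool = True) -> np.ndarray:
    """Discrete 2-D Gaussian operator on an odd ``size x size`` grid.

    Parameters
    ----------
    sigma : float
        Standard deviation of the Gaussian, in pixels. Must be positive.
    size : int
        Odd window size >= 3; coordinates run over
        ``a, b in {-(size-1)/2, ..., (size-1)/2}``.
    normalize : bool
        If True (default) renormalize the truncated weights to unit sum.
        If False, return the continuous operator values
        ``exp(-(a^2+b^2)/(2 sigma^2)) / (2 pi sigma^2)`` — the center
        value is then ``1/(2 pi sigma^2)``.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if size < 3 or size % 2 == 0:
        raise ValueError(f"kernel size must be an odd integer >= 3, got {size}")
    half = size // 2
    a = np.arange(-half, half + 1, dtype=float)
    aa, bb = np.meshgrid(a, a, indexing="ij")
    weights = np.exp(-(aa**2 + bb**2) / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
    if normalize:
        weights = weights / weights.sum()
    return weights


def gaussian_smooth(image, sigma: float = 1.0, size: int = 5) -> np.ndarray:
    """Denoise an image by convolution with a normalized Gaussian kernel.

    Borders are handled by reflection, so images smaller than the kernel
    remain valid and constant images pass through unchanged.
    """
    arr = _as_image(image)
    kernel = gaussian_kernel(sigma=sigma, size=size)
    return ndimage.convolve(arr, kernel, mode="reflect")


def uncertainty_product(sigma: float = 4.0, size: int = 65) -> float:
    """Space-bandwidth product of the discretized 1-D Gaussian operator.

    The Gaussian is the minimizer of the uncertainty relation
    ``delta_a * delta_w >= 1/2`` between spatial spread and spectral
    spread. This evaluates both spreads for the discrete factor: the
    spatial standard deviation under the squared-magnitude weighting of
    the sampled kernel, and the spectral standard deviation under the
    squared magnitude of its discrete Fourier transform. For a finely
    sampled, generously truncated Gaussian the product approaches 1/2.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    if size < 3 or size % 2 == 0:
        raise ValueError(f"size must be an odd integer >= 3, got {size}")
    half = size // 2
    a = np.arange(-half, half + 1, dtype=float)
    g = np.exp(-(a**2) / (2.0 * sigma**2))
    w_spatial = g**2 / np.sum(g**2)
    delta_a = np.sqrt(np.sum(a**2 * w_spatial))

    spectrum = np.abs(np.fft.fft(np.fft.ifftshift(g)))
    omega = 2.0 * np.pi * np.fft.fftfreq(size)
    w_spec = spectrum**2 / np.sum(spectrum**2)
    delta_w = np.sqrt(np.sum(omega**2 * w_spec))
    return float(delta_a * delta_w)


@dataclass
class AugmentParams:
    """Ranges for one random augmentation draw.

    Defaults follow the standard MRI augmentation recipe: rotations
    within +/-15 degrees, zoom within +/-10 %, small translations,
    horizontal/vertical flips, and elastic deformation with displacement
    magnitude ``elastic_alpha`` (pixels) smoothed at scale
    ``elastic_sigma`` (pixels).
    """

    rotation_deg: float = 15.0
    zoom_frac: float = 0.10
    translate_px: float = 5.0
    flip_h: bool = True
    flip_v: bool = True
    elastic_alpha: float = 0.0
    elastic_sigma: float = 8.0
    seed: int = 0


def _elastic_displacement(shape, alpha, sigma, rng):
    """Smoothed random displacement field with overall magnitude alpha."""
    dr = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma, mode="reflect")
    dc = ndimage.gaussian_filter(rng.uniform(-1, 1, size=shape), sigma, mode="reflect")
    scale = max(np.abs(dr).max(), np.abs(dc).max(), 1e-12)
    return dr / scale * alpha, dc / scale * alpha


def augment(image, mask, params: AugmentParams):
    """Apply one seeded random geometric transform to an image/mask pair.

    The identical transform is applied to both arrays; the image is
    interpolated bilinearly and the mask nearest-neighbor so it stays
    binary. Output shapes equal input shapes. All randomness derives
    from ``params.seed``.

    Returns ``(augmented_image, augmented_mask)``.
    """
    arr = _as_image(image)
    m = np.asarray(mask)
    if m.shape != arr.shape:
        raise ValueError(f"image shape {arr.shape} != mask shape {m.shape}")
    rng = np.random.default_rng(params.seed)

    angle = rng.uniform(-params.rotation_deg, params.rotation_deg)
    zoom = 1.0 + rng.uniform(-params.zoom_frac, params.zoom_frac)
    t_r = rng.uniform(-params.translate_px, params.translate_px)
    t_c = rng.uniform(-params.translate_px, params.translate_px)
    do_flip_h = params.flip_h and rng.random() < 0.5
    do_flip_v = params.flip_v and rng.random() < 0.5

    # Inverse map: output coords -> input coords, rotation/zoom about center.
    theta = np.deg2rad(angle)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    center = (np.asarray(arr.shape, dtype=float) - 1.0) / 2.0
    rows, cols = np.meshgrid(
        np.arange(arr.shape[0], dtype=float),
        np.arange(arr.shape[1], dtype=float),
        indexing="ij",
    )
    r = rows - center[0] - t_r
    c = cols - center[1] - t_c
    src_r = (cos_t * r - sin_t * c) / zoom + center[0]
    src_c = (sin_t * r + cos_t * c) / zoom + center[1]

    if params.elastic_alpha > 0:
        dr, dc = _elastic_displacement(arr.shape, params.elastic_alpha, params.elastic_sigma, rng)
        src_r = src_r + dr
        src_c = src_c + dc

    coords = np.stack([src_r, src_c])
    out_img = ndimage.map_coordinates(arr, coords, order=1, mode="reflect")
    out_mask = ndimage.map_coordinates(m.astype(float), coords, order=0, mode="reflect")
    out_mask = out_mask.astype(m.dtype)

    if do_flip_h:
        out_img = out_img[:, ::-1]
        out_mask = out_mask[:, ::-1]
    if do_flip_v:
        out_img = out_img[::-1, :]
        out_mask = out_mask[::-1, :]
    return np.ascontiguousarray(out_img), np.ascontiguousarray(out_mask)
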