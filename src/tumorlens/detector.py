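"""Detection-stage primitives: objectness, box refinement, RoI Align,
instance-segmentation losses, a classical region proposer, and a
deep-feature stand-in.

The loss is the standard three-term instance-segmentation objective

    L = L_cls + L_bbox + L_mask

with cross-entropy classification loss, smooth-L1 box regression loss,
and pixelwise binary cross-entropy mask loss. Box refinement follows
the additive rule ``b_hat = b + delta`` (the literal formulation this
package adopts; the log-scale width/height parametrization common in
detection frameworks is a drop-in alternative, see docs/methods.md).

Coordinates are 0-based, half-open ``[min, max)``, row-major, with the
row axis pointing down — stated once here, used everywhere.

Training a convolutional backbone is out of scope at desk scale; a
deterministic classical proposer (Gaussian smoothing, Otsu threshold,
connected components) supplies regions, and :func:`deep_features`
provides a pluggable deep-path feature contract (default: RoI Align of
the smoothed image onto a 7x7 grid, D1 = 49) that a trained backbone
can replace without touching fusion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters, measure

from tumorlens.preprocess import gaussian_smooth

__all__ = [
    "BoundingBox",
    "RoiRecord",
    "DetectionLossReport",
    "objectness_probability",
    "apply_offsets",
    "roi_align",
    "classification_loss",
    "smooth_l1",
    "bbox_loss",
    "mask_loss",
    "total_loss",
    "propose_regions",
    "deep_features",
]

EPS = 1e-12  # probability clipping before any log

#: A focal lesion is a compact bright minority: if the Otsu foreground
#: covers more than this fraction of the image, the threshold is splitting
#: background fluctuation rather than isolating a lesion.
MAX_FOREGROUND_FRACTION = 0.3

#: Minimum component-to-background mean contrast, in units of the smoothed
#: image's global intensity spread (scale-free, so per-image min-max
#: normalization does not change the decision).
MIN_CONTRAST_RATIO = 2.0


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box, 0-based, half-open [min, max) in both axes."""

    row_min: int
    col_min: int
    row_max: int
    col_max: int

    def __post_init__(self):
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise ValueError(f"degenerate box {self.astuple()}")

    def astuple(self):
        return (self.row_min, self.col_min, self.row_max, self.col_max)

    @property
    def height(self):
        return self.row_max - self.row_min

    @property
    def width(self):
        return self.col_max - self.col_min


@dataclass
class RoiRecord:
    """One proposed region: box, objectness, and its pixel mask."""

    box: BoundingBox
    objectness: float
    raw_score: float
    mask: np.ndarray  # binary, over the box extent

    def __post_init__(self):
        if not (0.0 <= self.objectness <= 1.0):
            raise ValueError(f"objectness must be in [0,1], got {self.objectness}")
        if self.mask.shape != (self.box.height, self.box.width):
            raise ValueError("mask shape must match box extent")


@dataclass
class DetectionLossReport:
    cls_loss: float
    bbox_loss: float
    mask_loss: float
    total: float


def objectness_probability(raw_scores):
    """Sigmoid of raw proposal scores, numerically stable for |s| <= 700."""
    s = np.asarray(raw_scores, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("raw scores must be finite")
    out = np.empty_like(s)
    pos = s >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-s[pos]))
    es = np.exp(s[~pos])
    out[~pos] = es / (1.0 + es)
    return out if out.ndim else float(out)


def apply_offsets(anchor: BoundingBox, delta, image_shape=None) -> BoundingBox:
    """Refine an anchor box by coordinatewise additive offsets.

    ``delta`` is (d_row_min, d_col_min, d_row_max, d_col_max). The
    refined box is clipped to ``image_shape`` when given. A refinement
    that collapses the box to non-positive extent raises, flagging the
    proposal for discard.
    """
    d = [float(x) for x in delta]
    if len(d) != 4:
        raise ValueError("delta must have exactly 4 components")
    r0 = anchor.row_min + d[0]
    c0 = anchor.col_min + d[1]
    r1 = anchor.row_max + d[2]
    c1 = anchor.col_max + d[3]
    if image_shape is not None:
        h, w = image_shape
        r0, r1 = np.clip(r0, 0, h), np.clip(r1, 0, h)
        c0, c1 = np.clip(c0, 0, w), np.clip(c1, 0, w)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(
            f"offset {tuple(d)} collapses anchor {anchor.astuple()}: proposal discarded"
        )
    return BoundingBox(int(round(r0)), int(round(c0)), int(round(r1)), int(round(c1)))


def _bilinear(feature_map, r, c):
    """Bilinear interpolation at continuous (r, c); pixel centers at integers.

    Coordinates are clamped to the valid range (edge extension).
    """
    h, w = feature_map.shape
    r = np.clip(r, 0.0, h - 1.0)
    c = np.clip(c, 0.0, w - 1.0)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = r - r0
    fc = c - c0
    top = feature_map[r0, c0] * (1 - fc) + feature_map[r0, c1] * fc
    bot = feature_map[r1, c0] * (1 - fc) + feature_map[r1, c1] * fc
    return top * (1 - fr) + bot * fr


def roi_align(feature_map, box: BoundingBox, out_size=(7, 7), samples_per_bin: int = 2):
    """Resample a feature map over a box onto a fixed grid, sub-pixel exact.

    The box is divided into ``out_size`` equal bins; each output value is
    the average of ``samples_per_bin x samples_per_bin`` bilinear samples
    placed on a regular grid inside the bin. No coordinate snapping.
    """
    fm = np.asarray(feature_map, dtype=float)
    h, w = fm.shape
    if box.row_min < 0 or box.col_min < 0 or box.row_max > h or box.col_max > w:
        raise ValueError(f"box {box.astuple()} outside feature map of shape {fm.shape}")
    out_h, out_w = out_size
    if out_h < 1 or out_w < 1 or samples_per_bin < 1:
        raise ValueError("out_size and samples_per_bin must be >= 1")
    bin_h = box.height / out_h
    bin_w = box.width / out_w
    s = samples_per_bin
    # sample-point fractions within one bin: (k + 0.5)/s
    frac = (np.arange(s) + 0.5) / s
    out = np.zeros((out_h, out_w))
    # Box coordinates are half-open pixel-edge coordinates; the array value
    # at integer index p is the center of pixel p, i.e. box coordinate p+0.5.
    for bi in range(out_h):
        rr = box.row_min + bin_h * (bi + frac) - 0.5
        for bj in range(out_w):
            cc = box.col_min + bin_w * (bj + frac) - 0.5
            grid_r, grid_c = np.meshgrid(rr, cc, indexing="ij")
            out[bi, bj] = _bilinear(fm, grid_r, grid_c).mean()
    return out


def classification_loss(y, y_hat, reduction: str = "sum") -> float:
    """Binary cross-entropy over proposal labels (sum by default)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"label shape {y.shape} != probability shape {p.shape}")
    p = np.clip(p, EPS, 1.0 - EPS)
    terms = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(terms.mean() if reduction == "mean" else terms.sum())


def smooth_l1(x) -> np.ndarray:
    """Smooth-L1: 0.5 x^2 for |x| < 1, |x| - 0.5 beyond; continuous at 1."""
    x = np.abs(np.asarray(x, dtype=float))
    return np.where(x < 1.0, 0.5 * x**2, x - 0.5)


def bbox_loss(boxes, targets) -> float:
    """Smooth-L1 box regression loss, summed over coordinates and proposals."""
    b = np.asarray(boxes, dtype=float)
    t = np.asarray(targets, dtype=float)
    if b.shape != t.shape:
        raise ValueError(f"boxes shape {b.shape} != targets shape {t.shape}")
    if not (np.all(np.isfinite(b)) and np.all(np.isfinite(t))):
        raise ValueError("box coordinates must be finite")
    return float(smooth_l1(b - t).sum())


def mask_loss(y_p, y_hat_p, reduction: str = "sum") -> float:
    """Pixelwise binary cross-entropy between true and predicted masks."""
    yt = np.asarray(y_p, dtype=float)
    yp = np.asarray(y_hat_p, dtype=float)
    if yt.shape != yp.shape:
        raise ValueError(f"mask shape {yt.shape} != prediction shape {yp.shape}")
    yp = np.clip(yp, EPS, 1.0 - EPS)
    terms = -(yt * np.log(yp) + (1.0 - yt) * np.log(1.0 - yp))
    return float(terms.mean() if reduction == "mean" else terms.sum())


def total_loss(cls_loss: float, bbox_loss_value: float, mask_loss_value: float) -> DetectionLossReport:
    """Unweighted sum of the three detection loss terms."""
    for name, v in (("cls", cls_loss), ("bbox", bbox_loss_value), ("mask", mask_loss_value)):
        if v < 0:
            raise ValueError(f"{name} loss must be nonnegative, got {v}")
    return DetectionLossReport(
        cls_loss=float(cls_loss),
        bbox_loss=float(bbox_loss_value),
        mask_loss=float(mask_loss_value),
        total=float(cls_loss) + float(bbox_loss_value) + float(mask_loss_value),
    )


def propose_regions(image, min_area: int = 40, smooth_sigma: float = 1.0) -> list:
    """Deterministic classical region proposals for bright lesions.

    Pipeline: Gaussian smoothing -> Otsu intensity threshold ->
    connected components with area >= ``min_area``. Each surviving
    component becomes a :class:`RoiRecord` with its tight box, its pixel
    mask, and an objectness score: the component's mean-intensity
    contrast against the background, scaled by the global intensity
    spread and mapped through the sigmoid. Two scale-free guards make
    lesion-free images return an empty list: the Otsu foreground must be
    a compact minority (< 30% of pixels), and a component's contrast
    must exceed twice the image's global intensity spread.
    """
    arr = np.asarray(image, dtype=float)
    if arr.min() < 0 or arr.max() > 1:
        raise ValueError("image must lie in [0, 1]")
    smoothed = gaussian_smooth(arr, sigma=smooth_sigma, size=5)
    if np.ptp(smoothed) < 1e-6:
        return []
    thresh = filters.threshold_otsu(smoothed)
    fg = smoothed > thresh
    if not fg.any() or fg.all() or fg.mean() > MAX_FOREGROUND_FRACTION:
        return []
    labels = measure.label(fg, connectivity=2)
    bg_mean = smoothed[~fg].mean()
    spread = max(smoothed.std(), 1e-12)
    records = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        comp = labels == region.label
        contrast = smoothed[comp].mean() - bg_mean
        raw = contrast / spread
        if raw < MIN_CONTRAST_RATIO:
            continue
        r0, c0, r1, c1 = region.bbox
        box = BoundingBox(r0, c0, r1, c1)
        records.append(
            RoiRecord(
                box=box,
                objectness=float(objectness_probability(raw)),
                raw_score=float(raw),
                mask=comp[r0:r1, c0:c1].astype(np.uint8),
            )
        )
    records.sort(key=lambda r: r.objectness, reverse=True)
    return records


def deep_features(image, box: BoundingBox, out_size=(7, 7), smooth_sigma: float = 1.0):
    """Deep-path feature stand-in: RoI Align of the smoothed image.

    Returns a vector of length ``out_size[0] * out_size[1]`` (default
    D1 = 49), flattened row-major. The contract — fixed-length vector
    for any box — is what fusion depends on; a trained convolutional
    backbone can replace this extractor without touching fusion.
    """
    arr = np.asarray(image, dtype=float)
    smoothed = gaussian_smooth(arr, sigma=smooth_sigma, size=5)
    aligned = roi_align(smoothed, box, out_size=out_size, samples_per_bin=2)
    return aligned.ravel()
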