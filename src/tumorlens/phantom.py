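"""Synthetic MRI-like phantoms with texture-distinct tumor classes.

Each phantom is a [0, 1] grayscale slice: a noisy, slowly varying
background plus (for tumor classes) one bright lesion whose internal
texture identifies its class:

* ``heterogeneous`` (glioma-like) — salt-like multiscale noise inside
  the lesion: high local intensity variance, hence high GLCM contrast.
* ``homogeneous`` (meningioma-like) — a smoothed near-constant patch:
  low contrast, high homogeneity and energy.
* ``periodic`` (pituitary-like) — a sinusoidal grating: strongly
  anisotropic co-occurrence statistics (contrast depends on angle).
* ``background-only`` (non-tumor) — no lesion, empty mask.

Tumor outlines are random ellipses perturbed by low-frequency radial
noise, so boundaries are nonconvex and shape features are nontrivial.
Generation is fully determined by (spec, class, seed): the same triple
reproduces bit-identical pixels. Images are written to 8-bit grayscale
PNG; the round-trip back to [0, 1] is exact to 1/255 quantization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import measure

__all__ = ["ClassSpec", "PhantomSpec", "PhantomSample", "make_phantom", "make_dataset"]

TEXTURE_KINDS = ("heterogeneous", "homogeneous", "periodic", "background-only")


@dataclass(frozen=True)
class ClassSpec:
    """Descriptor of one phantom class."""

    name: str
    texture_kind: str
    base_intensity: float = 0.65
    noise_sigma: float = 0.05
    tumor_radius_range: tuple = (12, 24)
    tumor_count: int = 1

    def __post_init__(self):
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(
                f"unknown texture_kind {self.texture_kind!r}; valid: {TEXTURE_KINDS}"
            )
        if self.texture_kind == "background-only" and self.tumor_count != 0:
            raise ValueError("background-only class must have tumor_count = 0")
        if self.texture_kind != "background-only" and self.tumor_count < 1:
            raise ValueError("tumor class must have tumor_count >= 1")


def default_classes() -> tuple:
    """The four default classes emulating the three tumor types plus non-tumor."""
    return (
        ClassSpec("glioma-like", "heterogeneous", base_intensity=0.62, noise_sigma=0.16),
        ClassSpec("meningioma-like", "homogeneous", base_intensity=0.70, noise_sigma=0.02),
        ClassSpec("pituitary-like", "periodic", base_intensity=0.62, noise_sigma=0.02),
        ClassSpec("non-tumor", "background-only", tumor_count=0),
    )


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of the phantom population.

    ``background_intensity``/``background_noise_sigma`` control the
    non-lesion field; per-class appearance lives in ``classes``.
    """

    image_size: tuple = (128, 128)
    classes: tuple = field(default_factory=default_classes)
    background_intensity: float = 0.22
    background_noise_sigma: float = 0.02
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 16 or w < 16:
            raise ValueError("image_size must be at least 16x16")
        for cls in self.classes:
            r_min, r_max = cls.tumor_radius_range
            if r_min < 3:
                raise ValueError("tumor_radius_range minimum must be >= 3 px")
            if r_max >= min(self.image_size) / 2:
                raise ValueError(
                    "tumor_radius_range maximum must be < min(image_size)/2"
                )

    def class_names(self) -> list:
        return [c.name for c in self.classes]

    def get_class(self, name: str) -> ClassSpec:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(
            f"unknown class {name!r}; valid classes: {self.class_names()}"
        )

    def spec_hash(self) -> str:
        payload = repr(asdict(self)).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class PhantomSample:
    """One generated slice with its ground truth."""

    image: np.ndarray
    mask: np.ndarray
    boxes: list
    label: str
    provenance: tuple

    def __post_init__(self):
        if self.mask.any() and not self.boxes:
            raise ValueError("nonempty mask requires at least one box")
        if not self.mask.any() and self.boxes:
            raise ValueError("empty mask cannot have boxes")


def _tumor_mask(shape, center, radius, rng):
    """Rasterize a randomly oriented ellipse with low-frequency radial wobble."""
    h, w = shape
    rows, cols = np.mgrid[0:h, 0:w]
    dr = rows - center[0]
    dc = cols - center[1]
    phi0 = rng.uniform(0, np.pi)
    ratio = rng.uniform(0.6, 1.0)
    # rotate into ellipse axes
    u = np.cos(phi0) * dr + np.sin(phi0) * dc
    v = -np.sin(phi0) * dr + np.cos(phi0) * dc
    rho = np.sqrt((u / radius) ** 2 + (v / (radius * ratio)) ** 2)
    ang = np.arctan2(v, u)
    wobble = np.zeros(shape)
    for k in (2, 3, 5):
        wobble += rng.uniform(0.0, 0.08) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
    return rho <= 1.0 + wobble


def _fill_texture(shape, cls: ClassSpec, rng):
    """Interior intensity field for one lesion, before masking."""
    base = cls.base_intensity
    if cls.texture_kind == "heterogeneous":
        fine = rng.normal(0.0, 1.0, size=shape)
        coarse = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), 2.0)
        coarse = coarse / max(coarse.std(), 1e-12)
        return base + cls.noise_sigma * (0.75 * fine + 0.65 * coarse)
    if cls.texture_kind == "homogeneous":
        smooth = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), 3.0)
        smooth = smooth / max(smooth.std(), 1e-12)
        return base + cls.noise_sigma * smooth
    if cls.texture_kind == "periodic":
        period = rng.uniform(3.5, 5.0)
        phase = rng.uniform(0, 2 * np.pi)
        cols = np.arange(shape[1], dtype=float)
        grating = 0.18 * np.sin(2 * np.pi * cols / period + phase)
        tex = base + np.broadcast_to(grating, shape).copy()
        return tex + rng.normal(0.0, cls.noise_sigma, size=shape)
    raise ValueError(f"no texture recipe for kind {cls.texture_kind!r}")


def _boxes_from_mask(mask) -> list:
    """Tight half-open [r0, c0, r1, c1) box per connected component."""
    labels = measure.label(mask, connectivity=2)
    boxes = []
    for region in measure.regionprops(labels):
        r0, c0, r1, c1 = region.bbox
        boxes.append((int(r0), int(c0), int(r1), int(c1)))
    return boxes


def make_phantom(spec: PhantomSpec, class_tag: str, seed: int) -> PhantomSample:
    """Generate one phantom slice for ``class_tag`` under ``seed``.

    Returns a :class:`PhantomSample` whose mask marks exactly the
    synthesized tumor pixels and whose boxes are the tight bounding
    boxes of each mask component. Background-only classes return an
    all-zero mask and no boxes.
    """
    cls = spec.get_class(class_tag)  # raises KeyError naming valid tags
    tag_digest = int.from_bytes(hashlib.sha256(class_tag.encode()).digest()[:4], "big")
    rng = np.random.default_rng([int(seed) % (2**31), tag_digest])
    h, w = spec.image_size

    background = spec.background_intensity + 0.03 * _smooth_field((h, w), 6.0, rng)
    background = background + rng.normal(0.0, spec.background_noise_sigma, size=(h, w))
    image = background
    mask = np.zeros((h, w), dtype=bool)

    r_min, r_max = cls.tumor_radius_range
    for _ in range(cls.tumor_count):
        radius = rng.uniform(r_min, r_max)
        margin = int(np.ceil(radius * 1.3)) + 2
        center = (
            rng.uniform(margin, h - margin),
            rng.uniform(margin, w - margin),
        )
        lesion = _tumor_mask((h, w), center, radius, rng)
        lesion &= ~mask  # keep components disjoint in multi-tumor mode
        tex = _fill_texture((h, w), cls, rng)
        image = np.where(lesion, tex, image)
        mask |= lesion

    image = np.clip(image, 0.0, 1.0)
    return PhantomSample(
        image=image,
        mask=mask,
        boxes=_boxes_from_mask(mask),
        label=class_tag,
        provenance=(spec.spec_hash(), int(seed)),
    )


def _smooth_field(shape, sigma, rng):
    f = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma)
    return f / max(f.std(), 1e-12)


def _write_png(path, array01):
    img = Image.fromarray(np.round(np.clip(array01, 0, 1) * 255).astype(np.uint8), mode="L")
    img.save(path)


def make_dataset(spec: PhantomSpec, n_per_class: int, out_dir, seed: int):
    """Write a phantom dataset to ``out_dir`` and return its manifest.

    Generates ``n_per_class`` samples for every class in the spec,
    writing 8-bit grayscale image and mask PNGs, and returns a pandas
    DataFrame manifest with columns ``path, mask_path, label, split``
    (split initially ``unassigned``). Deterministic in (spec, seed).
    """
    import pandas as pd
    from pathlib import Path

    if n_per_class < 1:
        raise ValueError(f"n_per_class must be >= 1, got {n_per_class}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cls in enumerate(spec.classes):
        for i in range(n_per_class):
            sample_seed = (int(seed) * 9973 + ci * 1009 + i) % (2**31)
            sample = make_phantom(spec, cls.name, sample_seed)
            stem = f"{cls.name.replace(' ', '_')}_{i:04d}"
            img_path = out / f"{stem}.png"
            mask_path = out / f"{stem}_mask.png"
            _write_png(img_path, sample.image)
            _write_png(mask_path, sample.mask.astype(float))
            rows.append(
                {
                    "path": str(img_path),
                    "mask_path": str(mask_path),
                    "label": cls.name,
                    "split": "unassigned",
                }
            )
    return pd.DataFrame(rows)
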