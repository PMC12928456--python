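"""Dataset manifests, stratified splitting, and pipeline orchestration.

The manifest is a delimited table with header ``path,mask_path,label,split``.
Splitting is stratified per class with the round-half-up convention
train = round(0.8 n), val = round(0.1 n), test = remainder — the rule
that reproduces the canonical 2,451 / 307 / 306 partition of a
1,426 / 708 / 930 three-class dataset.

``run_pipeline`` executes the full chain on phantoms: generate ->
preprocess -> propose regions -> GLCM + radiomic features on the ROI ->
deep-path stand-in features -> standardize + fuse -> train the MLP head
on the training split -> evaluate on the held-out test split. The
evaluation JSON is deterministic under a fixed config; wall-clock stage
timings are written to a separate artifact so reruns stay bit-identical.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tumorlens import detector, fusion, metrics, phantom, preprocess, radiomics, texture

__all__ = [
    "DatasetManifest",
    "PipelineConfig",
    "stratified_split",
    "build_manifest",
    "read_manifest",
    "write_manifest",
    "extract_sample_features",
    "extract_feature_table",
    "train_and_evaluate",
    "run_pipeline",
]

logger = logging.getLogger("tumorlens")

MANIFEST_COLUMNS = ["path", "mask_path", "label", "split"]
SPLIT_TAGS = ("train", "val", "test", "unassigned")

DatasetManifest = pd.DataFrame  # alias: manifests are validated DataFrames


def _validate_manifest(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"malformed manifest: missing column(s) {missing}; "
            f"expected header {MANIFEST_COLUMNS}"
        )
    dupes = df["path"][df["path"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"duplicate manifest paths: {sorted(set(dupes))[:5]}")
    bad_tags = sorted(set(df["split"]) - set(SPLIT_TAGS))
    if bad_tags:
        raise ValueError(f"unknown split tag(s) {bad_tags}; valid: {SPLIT_TAGS}")
    return df


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(manifest: pd.DataFrame, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> pd.DataFrame:
    """Assign train/val/test tags, stratified per class.

    Per class of size n: train = round(f_train * n), val = round(f_val * n)
    (round half up), test = remainder. Membership within a class is
    randomized by ``seed``; counts depend only on class sizes.
    """
    df = _validate_manifest(manifest.copy())
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    split_col = pd.Series("unassigned", index=df.index)
    for label, group in df.groupby("label", sort=True):
        n = len(group)
        n_train = _round_half_up(fractions[0] * n)
        n_val = _round_half_up(fractions[1] * n)
        n_test = n - n_train - n_val
        if min(n_train, n_val, n_test) < 1:
            raise ValueError(
                f"class {label!r} has only {n} samples: cannot give every "
                "split at least one"
            )
        order = rng.permutation(n)
        tags = np.empty(n, dtype=object)
        tags[order[:n_train]] = "train"
        tags[order[n_train : n_train + n_val]] = "val"
        tags[order[n_train + n_val :]] = "test"
        split_col.loc[group.index] = tags
    df["split"] = split_col
    return df


def build_manifest(data_dir) -> pd.DataFrame:
    """Scan a phantom output directory into a manifest.

    Expects the layout written by :func:`tumorlens.phantom.make_dataset`:
    ``<label>_<idx>.png`` with sibling ``<label>_<idx>_mask.png``.
    """
    root = Path(data_dir)
    problems = []
    rows = []
    for img in sorted(root.glob("*.png")):
        if img.stem.endswith("_mask"):
            continue
        label = img.stem.rsplit("_", 1)[0].replace("_", " ")
        mask = img.with_name(img.stem + "_mask.png")
        if not mask.exists():
            problems.append(f"missing mask for {img.name}")
            continue
        rows.append(
            {"path": str(img), "mask_path": str(mask), "label": label,
             "split": "unassigned"}
        )
    if problems:
        raise FileNotFoundError("; ".join(problems))
    if not rows:
        raise FileNotFoundError(f"no phantom PNGs found under {root}")
    return _validate_manifest(pd.DataFrame(rows))


def write_manifest(manifest: pd.DataFrame, path):
    _validate_manifest(manifest).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    return _validate_manifest(df)


# ------------------------------------------------------------- configuration

@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs; round-trips through YAML."""

    image_size: tuple = (128, 128)
    n_per_class: int = 100
    smooth_sigma: float = 1.0
    smooth_size: int = 5
    glcm_levels: int = 8
    glcm_distances: tuple = (1, 2)
    min_proposal_area: int = 40
    features_on_smoothed: bool = False
    use_ground_truth_masks: bool = False
    fusion_mode: str = "fused"  # fused | glcm_only | deep_only
    hidden_sizes: tuple = (64, 32)
    epochs: int = 300
    batch_size: int = 32
    learning_rate: float = 0.01
    optimizer: str = "adam"
    split_fractions: tuple = (0.8, 0.1, 0.1)
    seed: int = 0
    out_dir: str = "tumorlens_run"

    def __post_init__(self):
        if self.fusion_mode not in ("fused", "glcm_only", "deep_only"):
            raise ValueError(f"unknown fusion_mode {self.fusion_mode!r}")

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("image_size", "glcm_distances", "hidden_sizes", "split_fractions"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


# -------------------------------------------------------- feature extraction

def _fallback_box(shape) -> detector.BoundingBox:
    """Centered half-size box used when no region is proposed."""
    h, w = shape
    return detector.BoundingBox(h // 4, w // 4, h // 4 + h // 2, w // 4 + w // 2)


def extract_sample_features(image, config: PipelineConfig, gt_mask=None):
    """Run preprocessing, segmentation and all feature extractors on one image.

    Returns ``(feature_dict, diagnostics)``. The diagnostics carry the
    chosen ROI mask and box, the denoised image, and whether the ROI
    came from a proposal, the ground-truth mask, or the no-detection
    fallback (a centered half-size box, so lesion-free images still
    yield a feature row describing background tissue).
    """
    norm = preprocess.minmax_normalize(image) if np.ptp(image) > 0 else np.asarray(image, float)
    smoothed = preprocess.gaussian_smooth(norm, sigma=config.smooth_sigma, size=config.smooth_size)

    proposals = detector.propose_regions(norm, min_area=config.min_proposal_area,
                                         smooth_sigma=config.smooth_sigma)
    roi_source = "proposal"
    if config.use_ground_truth_masks and gt_mask is not None and np.asarray(gt_mask).any():
        roi_mask = np.asarray(gt_mask, dtype=bool)
        boxes = phantom._boxes_from_mask(roi_mask)
        r0 = min(b[0] for b in boxes)
        c0 = min(b[1] for b in boxes)
        r1 = max(b[2] for b in boxes)
        c1 = max(b[3] for b in boxes)
        box = detector.BoundingBox(r0, c0, r1, c1)
        roi_source = "ground_truth"
    elif proposals:
        best = proposals[0]  # highest objectness
        box = best.box
        roi_mask = np.zeros(norm.shape, dtype=bool)
        roi_mask[box.row_min : box.row_max, box.col_min : box.col_max] = best.mask.astype(bool)
    else:
        box = _fallback_box(norm.shape)
        roi_mask = np.zeros(norm.shape, dtype=bool)
        roi_mask[box.row_min : box.row_max, box.col_min : box.col_max] = True
        roi_source = "fallback"

    feature_image = smoothed if config.features_on_smoothed else norm
    tex = texture.texture_features(
        feature_image, mask=roi_mask, distances=config.glcm_distances,
        levels=config.glcm_levels,
    )
    rad = radiomics.radiomic_features(feature_image, roi_mask.astype(np.uint8),
                                      levels=config.glcm_levels)
    deep = detector.deep_features(norm, box, smooth_sigma=config.smooth_sigma)

    features = {f"deep_{i}": v for i, v in enumerate(deep)}
    features.update(tex.as_dict())
    features.update(rad)
    diag = {
        "roi_mask": roi_mask,
        "box": box,
        "roi_source": roi_source,
        "smoothed": smoothed,
        "normalized": norm,
        "n_proposals": len(proposals),
    }
    return features, diag


def extract_feature_table(config: PipelineConfig):
    """Generate phantoms and extract one feature row per sample.

    Returns ``(table, spec)`` where the table has the fused feature
    columns plus ``label``, ``split`` (unassigned), ``roi_source`` and
    ``localization_accuracy`` (proposal mask vs ground truth; NaN for
    background-only samples).
    """
    spec = phantom.PhantomSpec(image_size=tuple(config.image_size), seed=config.seed)
    rows = []
    for ci, cls in enumerate(spec.classes):
        for i in range(config.n_per_class):
            sample_seed = (config.seed * 9973 + ci * 1009 + i) % (2**31)
            sample = phantom.make_phantom(spec, cls.name, sample_seed)
            feats, diag = extract_sample_features(sample.image, config, gt_mask=sample.mask)
            if sample.mask.any():
                loc, _ = metrics.localization_from_masks(sample.mask, diag["roi_mask"])
            else:
                loc = np.nan
            row = dict(feats)
            row.update(
                label=cls.name,
                split="unassigned",
                roi_source=diag["roi_source"],
                localization_accuracy=loc,
                sample_seed=sample_seed,
            )
            rows.append(row)
            logger.debug("extracted %s sample %d (roi=%s)", cls.name, i, diag["roi_source"])
    return pd.DataFrame(rows), spec


_META_COLUMNS = ("label", "split", "roi_source", "localization_accuracy", "sample_seed")


def _feature_columns(table: pd.DataFrame, mode: str):
    cols = [c for c in table.columns if c not in _META_COLUMNS]
    if mode == "fused":
        return cols
    if mode == "glcm_only":
        return [c for c in cols if not c.startswith("deep_")]
    if mode == "deep_only":
        return [c for c in cols if c.startswith("deep_")]
    raise ValueError(f"unknown fusion mode {mode!r}")


def train_and_evaluate(table: pd.DataFrame, config: PipelineConfig):
    """Split, standardize on train only, train the head, evaluate held-out.

    Returns ``(report, model, standardizer)``. The report contains the
    test-split classification metrics, the mean localization accuracy
    over test tumor samples, and the class ledger.
    """
    classes = sorted(table["label"].unique())
    manifest = pd.DataFrame(
        {
            "path": [f"mem://{i}" for i in range(len(table))],
            "mask_path": "",
            "label": table["label"].values,
            "split": "unassigned",
        }
    )
    manifest = stratified_split(manifest, fractions=config.split_fractions, seed=config.seed)
    table = table.copy()
    table["split"] = manifest["split"].values

    cols = _feature_columns(table, config.fusion_mode)
    train_mask = table["split"] == "train"
    X_train = table.loc[train_mask, cols].to_numpy(float)
    std = fusion.fit_standardizer(
        X_train, names=cols, split_tags=table.loc[train_mask, "split"].to_numpy()
    )
    label_to_idx = {c: i for i, c in enumerate(classes)}
    y = table["label"].map(label_to_idx).to_numpy()

    model = fusion.train_mlp(
        fusion.apply_standardizer(std, X_train),
        y[train_mask.to_numpy()],
        hidden_sizes=tuple(config.hidden_sizes),
        n_classes=len(classes),
        epochs=config.epochs,
        batch_size=config.batch_size,
        learning_rate=config.learning_rate,
        optimizer=config.optimizer,
        seed=config.seed,
    )

    report = {"classes": classes, "fusion_mode": config.fusion_mode, "splits": {}}
    for split in ("val", "test"):
        m = (table["split"] == split).to_numpy()
        X = fusion.apply_standardizer(std, table.loc[m, cols].to_numpy(float))
        pred, _ = fusion.mlp_forward(model, X)
        y_hat = np.argmax(np.atleast_2d(pred), axis=1)
        cr = metrics.classification_report(
            [classes[i] for i in y[m]], [classes[i] for i in y_hat], classes
        )
        cr["confusion_matrix"] = cr["confusion_matrix"].tolist()
        report["splits"][split] = cr
    report["accuracy"] = report["splits"]["test"]["accuracy"]
    loc = table.loc[(table["split"] == "test"), "localization_accuracy"].dropna()
    report["localization_accuracy"] = float(loc.mean()) if len(loc) else None
    return report, model, std


def run_pipeline(config: PipelineConfig):
    """Execute the full phantom pipeline and write its artifacts.

    Writes under ``config.out_dir``: ``features.csv``, ``model.json``,
    ``evaluation.json`` (deterministic under the config) and
    ``timings.json`` (wall-clock, excluded from the deterministic
    report). Returns the evaluation report dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.perf_counter()
    table, spec = extract_feature_table(config)
    timings["feature_extraction_s"] = time.perf_counter() - t0
    logger.info("extracted %d feature rows", len(table))

    t0 = time.perf_counter()
    report, model, std = train_and_evaluate(table, config)
    timings["train_eval_s"] = time.perf_counter() - t0

    # Denoising fidelity on a held-aside noisy/clean phantom pair per class.
    t0 = time.perf_counter()
    psnr_gain = _denoising_psnr_summary(spec, config)
    report["denoising"] = psnr_gain
    timings["psnr_eval_s"] = time.perf_counter() - t0
    total = sum(timings.values())
    timings["cpu_utilization"] = metrics.cpu_utilization(total, total)

    table.to_csv(out / "features.csv", index=False)
    fusion.save_model(model, out / "model.json", standardizer=std,
                      feature_names=std.names, class_names=report["classes"])
    with open(out / "evaluation.json", "w") as fh:
        json.dump(_sanitize(report), fh, indent=2, default=_json_default)
    with open(out / "timings.json", "w") as fh:
        json.dump(timings, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    logger.info("pipeline done: test accuracy %.3f", report["accuracy"])
    return report


def _denoising_psnr_summary(spec, config, noise_sigma=0.1, n=5):
    """Mean PSNR of noisy vs Gaussian-denoised phantoms against the clean image."""
    rng = np.random.default_rng(config.seed + 5000)
    noisy_vals, denoised_vals = [], []
    for i in range(n):
        clean = phantom.make_phantom(spec, spec.classes[0].name, int(rng.integers(2**31))).image
        noisy = np.clip(clean + rng.normal(0, noise_sigma, clean.shape), 0, 1)
        den = preprocess.gaussian_smooth(noisy, sigma=config.smooth_sigma, size=config.smooth_size)
        noisy_vals.append(metrics.psnr(clean, noisy))
        denoised_vals.append(metrics.psnr(clean, den))
    return {
        "noise_sigma": noise_sigma,
        "psnr_noisy_db": float(np.mean(noisy_vals)),
        "psnr_denoised_db": float(np.mean(denoised_vals)),
    }


def _sanitize(obj):
    """Make a report JSON-safe: +/-inf floats become the string "inf"."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, float) and np.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if obj in (float("inf"), float("-inf")):
        return "inf"
    raise TypeError(f"not JSON serializable: {type(obj)}")
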