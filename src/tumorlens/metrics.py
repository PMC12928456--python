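"""Evaluation metrics: image fidelity, localization, timing, classification.

PSNR is ``10 log10(MAX^2 / MSE)`` in decibels; identical images give the
+inf sentinel (serialized as the string ``"inf"``). Localization
accuracy is ``1 - E_d / d_max`` clipped to [0, 1], with ``E_d`` the
Euclidean distance between the predicted and true mask centroids and
``d_max`` defaulting to the image diagonal. CPU utilization is the pure
ratio of active to total observation time over supplied timings (no
hardware sampling — hardware numbers are not reproducible).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "mse",
    "psnr",
    "centroid_error",
    "localization_accuracy",
    "cpu_utilization",
    "classification_report",
]


def mse(a, b) -> float:
    """Mean squared pixel difference."""
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def psnr(reference, test, max_val: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf for identical images."""
    if max_val <= 0:
        raise ValueError(f"max_val must be positive, got {max_val}")
    err = mse(reference, test)
    if err == 0:
        return float("inf")
    return float(10.0 * np.log10(max_val**2 / err))


def _centroid(mask) -> np.ndarray:
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        raise ValueError("cannot take the centroid of an empty mask")
    rows, cols = np.nonzero(m)
    return np.array([rows.mean(), cols.mean()])


def centroid_error(mask_true, mask_pred) -> float:
    """Euclidean distance E_d between the two mask centroids, in pixels."""
    return float(np.linalg.norm(_centroid(mask_true) - _centroid(mask_pred)))


def localization_accuracy(e_d: float, d_max: float) -> float:
    """1 - E_d / d_max, clipped to [0, 1]."""
    if d_max <= 0:
        raise ValueError(f"d_max must be positive, got {d_max}")
    return float(np.clip(1.0 - e_d / d_max, 0.0, 1.0))


def localization_from_masks(mask_true, mask_pred, d_max: float = None):
    """Localization accuracy of a predicted mask against ground truth.

    ``d_max`` defaults to the image diagonal. An empty predicted mask is
    a missed detection: accuracy 0 with the ``no_detection`` flag set.
    Returns ``(accuracy, flags)``.
    """
    m_true = np.asarray(mask_true, dtype=bool)
    m_pred = np.asarray(mask_pred, dtype=bool)
    if d_max is None:
        d_max = float(np.hypot(*m_true.shape))
    if not m_pred.any():
        return 0.0, {"no_detection": True}
    e_d = centroid_error(m_true, m_pred)
    return localization_accuracy(e_d, d_max), {"no_detection": False}


def cpu_utilization(active_time: float, total_time: float) -> float:
    """Fraction of observation time the CPU spent actively processing."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if active_time < 0 or active_time > total_time:
        raise ValueError(
            f"active_time must lie in [0, total_time], got {active_time} > {total_time}"
        )
    return float(active_time / total_time)


def classification_report(y_true, y_pred, classes) -> dict:
    """Confusion matrix and per-class/macro classification metrics.

    Rows of the confusion matrix are true classes, columns predicted.
    Per class: precision TP/(TP+FP), recall (sensitivity) TP/(TP+FN),
    specificity TN/(TN+FP), and F1. Cells with a zero denominator yield
    0 and are flagged in ``zero_division_flags``.
    """
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    yt = list(y_true)
    yp = list(y_pred)
    if len(yt) != len(yp):
        raise ValueError("y_true and y_pred must have equal length")
    unknown = sorted({v for v in yt + yp if v not in index})
    if unknown:
        raise ValueError(f"unknown label(s) {unknown}; declared classes: {classes}")
    k = len(classes)
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(yt, yp):
        cm[index[t], index[p]] += 1
    n = cm.sum()
    accuracy = float(np.trace(cm) / n) if n else 0.0

    per_class = {}
    flags = []
    for i, c in enumerate(classes):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        tn = n - tp - fp - fn

        def safe_div(num, den, metric):
            if den == 0:
                flags.append((c, metric))
                return 0.0
            return float(num / den)

        precision = safe_div(tp, tp + fp, "precision")
        recall = safe_div(tp, tp + fn, "recall")
        specificity = safe_div(tn, tn + fp, "specificity")
        f1 = safe_div(2 * precision * recall, precision + recall, "f1") if (precision + recall) else 0.0
        if (precision + recall) == 0:
            flags.append((c, "f1"))
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "specificity": specificity,
            "f1": f1,
        }

    macro = {
        m: float(np.mean([per_class[c][m] for c in classes]))
        for m in ("precision", "recall", "specificity", "f1")
    }
    return {
        "confusion_matrix": cm,
        "classes": classes,
        "accuracy": accuracy,
        "per_class": per_class,
        "macro": macro,
        "zero_division_flags": flags,
    }
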