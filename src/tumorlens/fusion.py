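"""Feature-level fusion and the from-scratch MLP detection head.

Fusion z-score standardizes the deep-path vector (dimension D1) and the
handcrafted GLCM + radiomics vector (dimension D2) on the training
split only, then concatenates them into a unified representation of
dimension D1 + D2, carrying a feature-name ledger with provenance tags
so either part can be recovered exactly (the GLCM-only and deep-only
ablation arms are ledger slices).

The head is a fully connected feedforward network implemented from
scratch: per layer ``z = W x + b`` followed by an activation (ReLU
hidden layers; sigmoid for the binary head, softmax for the 4-class
head), trained by exact backpropagation with the plain gradient-descent
update ``W <- W - eta * dL/dW`` (Adam available as an option). Binary
loss is cross-entropy ``-[y log p + (1-y) log(1-p)]``; the multiclass
head uses its categorical extension.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureStandardizer",
    "fit_standardizer",
    "apply_standardizer",
    "FusedFeatureVector",
    "fuse",
    "MlpModel",
    "init_mlp",
    "mlp_forward",
    "bce_loss",
    "categorical_cross_entropy",
    "mlp_backward",
    "train_step",
    "train_mlp",
    "classify",
    "save_model",
    "load_model",
]

EPS = 1e-12


# ---------------------------------------------------------------- fusion

@dataclass
class FeatureStandardizer:
    """Per-feature mean/std estimated on the training split."""

    means: np.ndarray
    stds: np.ndarray
    names: list
    zero_variance: np.ndarray  # boolean flags for constant features


def fit_standardizer(features, names=None, split_tags=None) -> FeatureStandardizer:
    """Fit per-feature z-score parameters on training rows only.

    ``split_tags``, when provided, must flag every row as ``train``;
    any validation/test row raises, guarding against leakage. Standard
    deviations are population (ddof=0). Constant features are flagged;
    they standardize to 0.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table (rows x features)")
    if X.shape[0] < 2:
        raise ValueError("standardizer needs at least 2 training samples")
    if split_tags is not None:
        tags = np.asarray(split_tags)
        bad = tags != "train"
        if bad.any():
            raise ValueError(
                f"leakage guard: refusing to fit on {sorted(set(tags[bad]))} rows"
            )
    means = X.mean(axis=0)
    stds = X.std(axis=0)
    zero = stds == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant feature(s) flagged; they standardize to 0",
            RuntimeWarning,
            stacklevel=2,
        )
    if names is None:
        names = [f"f{i}" for i in range(X.shape[1])]
    return FeatureStandardizer(
        means=means, stds=stds, names=list(names), zero_variance=zero
    )


def apply_standardizer(s: FeatureStandardizer, features) -> np.ndarray:
    """Apply fitted z-scoring; constant features map to 0."""
    X = np.asarray(features, dtype=float)
    safe_stds = np.where(s.zero_variance, 1.0, s.stds)
    out = (X - s.means) / safe_stds
    if X.ndim == 1:
        out = np.where(s.zero_variance, 0.0, out)
    else:
        out[:, s.zero_variance] = 0.0
    return out


@dataclass
class FusedFeatureVector:
    """Standardized concatenation deep-part-first, with provenance ledger."""

    values: np.ndarray
    names: list
    provenance: list  # per-feature tag: deep | glcm | radiomics

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != self.values.size or len(self.provenance) != self.values.size:
            raise ValueError("ledger length does not match fused vector length")

    def part(self, tag: str) -> np.ndarray:
        """Slice the fused vector by provenance tag."""
        idx = [i for i, t in enumerate(self.provenance) if t == tag]
        return self.values[idx]


def _handcrafted_provenance(name: str) -> str:
    return "glcm" if name.startswith("glcm_") else "radiomics"


def fuse(deep_vec, handcrafted_vec, deep_names=None, handcrafted_names=None) -> FusedFeatureVector:
    """Concatenate standardized deep (D1) and handcrafted (D2) vectors.

    Deep part first. An empty deep part (D1 = 0) is permitted — the
    GLCM-only ablation arm. Provenance tags are ``deep`` for the deep
    part and ``glcm``/``radiomics`` for handcrafted features, inferred
    from the handcrafted ledger names.
    """
    d = np.asarray(deep_vec, dtype=float).ravel()
    h = np.asarray(handcrafted_vec, dtype=float).ravel()
    if deep_names is None:
        deep_names = [f"deep_{i}" for i in range(d.size)]
    if handcrafted_names is None:
        handcrafted_names = [f"hand_{i}" for i in range(h.size)]
    if len(deep_names) != d.size or len(handcrafted_names) != h.size:
        raise ValueError("ledger/value length mismatch")
    names = list(deep_names) + list(handcrafted_names)
    provenance = ["deep"] * d.size + [
        _handcrafted_provenance(n) for n in handcrafted_names
    ]
    return FusedFeatureVector(
        values=np.concatenate([d, h]), names=names, provenance=provenance
    )


# ------------------------------------------------------------------ MLP

VALID_ACTIVATIONS = ("relu", "sigmoid", "softmax", "linear")


@dataclass
class MlpModel:
    """Ordered (W, b, activation) layers plus training metadata."""

    weights: list
    biases: list
    activations: list
    learning_rate: float = 0.01
    seed: int = 0
    history: list = field(default_factory=list)

    def __post_init__(self):
        for act in self.activations:
            if act not in VALID_ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        for l in range(1, len(self.weights)):
            if self.weights[l].shape[1] != self.weights[l - 1].shape[0]:
                raise ValueError(
                    f"layer {l} input dim {self.weights[l].shape[1]} != "
                    f"layer {l - 1} output dim {self.weights[l - 1].shape[0]}"
                )

    @property
    def n_layers(self):
        return len(self.weights)


def init_mlp(layer_sizes, out_activation="softmax", hidden_activation="relu",
             learning_rate=0.01, seed=0) -> MlpModel:
    """He-style uniform seeded initialization for the given layer sizes."""
    rng = np.random.default_rng(seed)
    weights, biases, acts = [], [], []
    for l in range(len(layer_sizes) - 1):
        fan_in, fan_out = layer_sizes[l], layer_sizes[l + 1]
        limit = np.sqrt(6.0 / fan_in)
        weights.append(rng.uniform(-limit, limit, size=(fan_out, fan_in)))
        biases.append(np.zeros(fan_out))
        acts.append(hidden_activation if l < len(layer_sizes) - 2 else out_activation)
    return MlpModel(weights=weights, biases=biases, activations=acts,
                    learning_rate=learning_rate, seed=seed)


def _activate(z, act):
    if act == "relu":
        return np.maximum(z, 0.0)
    if act == "sigmoid":
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        ez = np.exp(z[~pos])
        out[~pos] = ez / (1.0 + ez)
        return out
    if act == "softmax":
        shifted = z - z.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        return e / e.sum(axis=-1, keepdims=True)
    return z


def mlp_forward(model: MlpModel, x):
    """Forward pass; returns (prediction, cache of per-layer activations).

    ``x`` may be one vector or a batch (n, d); the cache stores the
    pre-activation inputs each layer consumed, for backpropagation.
    """
    a = np.atleast_2d(np.asarray(x, dtype=float))
    if a.shape[1] != model.weights[0].shape[1]:
        raise ValueError(
            f"input dim {a.shape[1]} != first-layer dim {model.weights[0].shape[1]}"
        )
    cache = {"inputs": [a], "z": []}
    for W, b, act in zip(model.weights, model.biases, model.activations):
        z = a @ W.T + b
        a = _activate(z, act)
        cache["z"].append(z)
        cache["inputs"].append(a)
    pred = a[0] if np.asarray(x).ndim == 1 else a
    return pred, cache


def bce_loss(y, y_hat) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)], mean over samples."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(y_hat, dtype=float)
    if np.any((y != 0) & (y != 1)):
        raise ValueError("binary labels must be 0 or 1")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(np.mean(-(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))))


def categorical_cross_entropy(y_onehot, p) -> float:
    """Categorical cross-entropy -sum y log p, mean over samples."""
    y = np.atleast_2d(np.asarray(y_onehot, dtype=float))
    p = np.atleast_2d(np.asarray(p, dtype=float))
    rowsums = y.sum(axis=1)
    if np.any((y != 0) & (y != 1)) or not np.allclose(rowsums, 1.0):
        raise ValueError("labels must be one-hot rows")
    p = np.clip(p, EPS, 1.0 - EPS)
    return float(np.mean(-np.sum(y * np.log(p), axis=1)))


def _loss_and_output_delta(model, cache, y):
    """Loss and dL/dz at the output layer (mean-over-batch convention)."""
    out = cache["inputs"][-1]
    act = model.activations[-1]
    n = out.shape[0]
    if act == "sigmoid":
        y2 = np.atleast_2d(np.asarray(y, dtype=float))
        if y2.shape != out.shape:
            y2 = y2.reshape(out.shape)
        loss = bce_loss(y2, out)
        delta = (out - y2) / n
    elif act == "softmax":
        y2 = np.atleast_2d(np.asarray(y, dtype=float))
        loss = categorical_cross_entropy(y2, out)
        delta = (out - y2) / n
    else:
        raise ValueError(f"no loss defined for output activation {act!r}")
    return loss, delta


def mlp_backward(model: MlpModel, cache, y):
    """Exact backprop gradients for every layer.

    Returns ``(loss, weight_grads, bias_grads)`` where the gradients are
    of the mean-over-batch cross-entropy loss. Requires the cache from
    :func:`mlp_forward` on the same inputs.
    """
    if not cache or "inputs" not in cache or len(cache["inputs"]) != model.n_layers + 1:
        raise ValueError("stale or missing forward cache")
    loss, delta = _loss_and_output_delta(model, cache, y)
    w_grads = [None] * model.n_layers
    b_grads = [None] * model.n_layers
    for l in range(model.n_layers - 1, -1, -1):
        a_prev = cache["inputs"][l]
        w_grads[l] = delta.T @ a_prev
        b_grads[l] = delta.sum(axis=0)
        if l > 0:
            delta = delta @ model.weights[l]
            if model.activations[l - 1] == "relu":
                delta = delta * (cache["z"][l - 1] > 0)
            elif model.activations[l - 1] == "sigmoid":
                s = _activate(cache["z"][l - 1], "sigmoid")
                delta = delta * s * (1.0 - s)
    return loss, w_grads, b_grads


def train_step(model: MlpModel, X, y, optimizer_state=None) -> float:
    """One gradient-descent (or Adam) update in place; returns batch loss."""
    _, cache = mlp_forward(model, X)
    loss, w_grads, b_grads = mlp_backward(model, cache, y)
    eta = model.learning_rate
    if optimizer_state is None:
        for l in range(model.n_layers):
            model.weights[l] -= eta * w_grads[l]
            model.biases[l] -= eta * b_grads[l]
    else:
        _adam_update(model, w_grads, b_grads, optimizer_state)
    return loss


def _adam_update(model, w_grads, b_grads, state, beta1=0.9, beta2=0.999, eps=1e-8):
    state["t"] += 1
    t = state["t"]
    eta = model.learning_rate
    for l in range(model.n_layers):
        for key, grad, param in (
            ("w", w_grads[l], model.weights[l]),
            ("b", b_grads[l], model.biases[l]),
        ):
            m = state["m"][(key, l)] = beta1 * state["m"][(key, l)] + (1 - beta1) * grad
            v = state["v"][(key, l)] = beta2 * state["v"][(key, l)] + (1 - beta2) * grad**2
            m_hat = m / (1 - beta1**t)
            v_hat = v / (1 - beta2**t)
            param -= eta * m_hat / (np.sqrt(v_hat) + eps)


def _new_adam_state(model):
    zeros = lambda p: np.zeros_like(p)
    m = {}
    v = {}
    for l in range(model.n_layers):
        m[("w", l)] = zeros(model.weights[l])
        m[("b", l)] = zeros(model.biases[l])
        v[("w", l)] = zeros(model.weights[l])
        v[("b", l)] = zeros(model.biases[l])
    return {"t": 0, "m": m, "v": v}


def _to_onehot(labels, n_classes):
    y = np.zeros((len(labels), n_classes))
    y[np.arange(len(labels)), labels] = 1.0
    return y


def train_mlp(
    features,
    labels,
    hidden_sizes=(64, 32),
    n_classes=None,
    epochs=300,
    batch_size=32,
    learning_rate=0.01,
    optimizer="gd",
    hidden_activation="relu",
    seed=0,
) -> MlpModel:
    """Train the detection head on standardized features.

    ``labels`` are integer class indices. ``n_classes=1`` requests the
    binary head (single sigmoid output, labels 0/1); otherwise a
    softmax head with ``n_classes`` outputs is used. Mini-batch
    training with per-epoch seeded shuffling; loss history recorded per
    epoch. Deterministic under a fixed seed. Aborts on NaN loss.
    """
    X = np.asarray(features, dtype=float)
    y_int = np.asarray(labels, dtype=int)
    if n_classes is None:
        n_classes = int(y_int.max()) + 1
    if n_classes == 1:
        out_act, targets = "sigmoid", y_int.reshape(-1, 1).astype(float)
    else:
        out_act, targets = "softmax", _to_onehot(y_int, n_classes)
    model = init_mlp(
        [X.shape[1], *hidden_sizes, max(n_classes, 1)],
        out_activation=out_act,
        hidden_activation=hidden_activation,
        learning_rate=learning_rate,
        seed=seed,
    )
    state = _new_adam_state(model) if optimizer == "adam" else None
    rng = np.random.default_rng(seed + 1)
    n = X.shape[0]
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            loss = train_step(model, X[idx], targets[idx], optimizer_state=state)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"NaN/inf loss at epoch {epoch}; lower the learning rate"
                )
            epoch_loss += loss
            n_batches += 1
        model.history.append(epoch_loss / max(n_batches, 1))
    return model


def classify(model: MlpModel, fused):
    """Predict a class label and probabilities for one fused vector.

    Multiclass: argmax of the softmax probabilities. Binary (single
    sigmoid output): threshold at 0.5, with the tie ŷ = 0.5 resolved to
    the positive class. Returns ``(label_index, probabilities)``.
    """
    values = fused.values if isinstance(fused, FusedFeatureVector) else np.asarray(fused)
    pred, _ = mlp_forward(model, values)
    if model.activations[-1] == "sigmoid" and pred.size == 1:
        p = float(pred.ravel()[0])
        return (1 if p >= 0.5 else 0), np.array([1.0 - p, p])
    probs = np.asarray(pred).ravel()
    return int(np.argmax(probs)), probs


# -------------------------------------------------------------- persistence

def save_model(model: MlpModel, path, standardizer: FeatureStandardizer = None,
               feature_names=None, class_names=None):
    """Serialize a trained head (and optionally its standardizer) to JSON."""
    payload = {
        "format": "tumorlens-mlp-v1",
        "learning_rate": model.learning_rate,
        "seed": model.seed,
        "activations": model.activations,
        "weights": [W.tolist() for W in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "history": model.history,
        "feature_names": list(feature_names) if feature_names is not None else None,
        "class_names": list(class_names) if class_names is not None else None,
    }
    if standardizer is not None:
        payload["standardizer"] = {
            "means": standardizer.means.tolist(),
            "stds": standardizer.stds.tolist(),
            "names": standardizer.names,
            "zero_variance": standardizer.zero_variance.tolist(),
        }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_model(path):
    """Load a serialized head; returns (model, standardizer_or_None, meta)."""
    with open(path) as fh:
        payload = json.load(fh)
    model = MlpModel(
        weights=[np.asarray(W) for W in payload["weights"]],
        biases=[np.asarray(b) for b in payload["biases"]],
        activations=payload["activations"],
        learning_rate=payload["learning_rate"],
        seed=payload["seed"],
        history=payload["history"],
    )
    std = None
    if payload.get("standardizer"):
        s = payload["standardizer"]
        std = FeatureStandardizer(
            means=np.asarray(s["means"]),
            stds=np.asarray(s["stds"]),
            names=s["names"],
            zero_variance=np.asarray(s["zero_variance"], dtype=bool),
        )
    meta = {
        "feature_names": payload.get("feature_names"),
        "class_names": payload.get("class_names"),
    }
    return model, std, meta
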