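"""Tumor/non-tumor voxel classification with a four-layer backprop network.

A small fully connected network (10 texture features in, two logistic hidden
layers, one logistic output unit) is trained by full-batch gradient descent on
cross-entropy.  Inputs are standardized with statistics recorded from the
training set, so the saved model is self-contained; serialization is JSON and
round-trips bit-identically.

After thresholding the per-voxel probabilities, morphological closing then
opening cleans up small holes and isolated noise, and a batch edit list
stands in for interactive radiologist refinement.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ContractError, ValidationError
from .io import BinaryMask
from .liver import _ball

__all__ = [
    "ClassifierModel",
    "RefinementEdits",
    "train_classifier",
    "classify_voxels",
    "postprocess",
    "apply_refinement",
    "read_edits",
]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class ClassifierModel:
    """Weights, normalization and training metadata of the voxel classifier."""

    layer_sizes: tuple[int, ...]
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)
    feature_mean: np.ndarray = field(repr=False)
    feature_scale: np.ndarray = field(repr=False)
    seed: int = 0
    epochs: int = 0
    learning_rate: float = 0.0
    final_loss: float = float("nan")

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        """Tumor probability in (0, 1) for each feature row."""
        x = np.asarray(features, dtype=np.float64)
        if x.ndim == 1:
            x = x[None, :]
        if x.shape[1] != self.layer_sizes[0]:
            raise ContractError(
                f"expected {self.layer_sizes[0]} features, got {x.shape[1]}"
            )
        a = (x - self.feature_mean) / self.feature_scale
        for w, b in zip(self.weights, self.biases):
            a = _sigmoid(a @ w + b)
        return a.ravel()

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "layer_sizes": list(self.layer_sizes),
            "weights": [w.tolist() for w in self.weights],
            "biases": [b.tolist() for b in self.biases],
            "feature_mean": self.feature_mean.tolist(),
            "feature_scale": self.feature_scale.tolist(),
            "seed": self.seed,
            "epochs": self.epochs,
            "learning_rate": self.learning_rate,
            "final_loss": self.final_loss,
        }
        path.write_text(json.dumps(payload))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        path = Path(path)
        if not path.exists():
            raise ValidationError(f"no such model file: {path}")
        d = json.loads(path.read_text())
        return cls(
            layer_sizes=tuple(d["layer_sizes"]),
            weights=[np.asarray(w, dtype=np.float64) for w in d["weights"]],
            biases=[np.asarray(b, dtype=np.float64) for b in d["biases"]],
            feature_mean=np.asarray(d["feature_mean"], dtype=np.float64),
            feature_scale=np.asarray(d["feature_scale"], dtype=np.float64),
            seed=int(d["seed"]),
            epochs=int(d["epochs"]),
            learning_rate=float(d["learning_rate"]),
            final_loss=float(d["final_loss"]),
        )


def train_classifier(
    features: np.ndarray,
    labels: np.ndarray,
    hidden_sizes: tuple[int, int] = (16, 8),
    learning_rate: float = 0.5,
    epochs: int = 500,
    seed: int = 0,
    momentum: float = 0.9,
) -> ClassifierModel:
    """Train the 10-in / two-hidden-layer / 1-out logistic network.

    Full-batch gradient descent with classical momentum on mean
    cross-entropy; features are standardized with the training mean/std
    (std floored at 1e-12).  Deterministic for a fixed seed.  Plain
    momentum-free descent (``momentum=0``) converges too slowly through the
    saturating logistic hidden layers to be a usable default.

    Raises
    ------
    ValidationError
        On non-finite features (naming the first bad row).
    ContractError
        If only one class is present in ``labels``.
    """
    x = np.asarray(features, dtype=np.float64)
    y = np.asarray(labels, dtype=np.float64).ravel()
    if x.ndim != 2 or x.shape[0] != y.size:
        raise ContractError(f"features {x.shape} do not match {y.size} labels")
    bad = np.where(~np.isfinite(x).all(axis=1))[0]
    if bad.size:
        raise ValidationError(f"non-finite feature values in row {int(bad[0])}")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ContractError("labels must be binary 0/1")
    if classes.size < 2:
        raise ContractError("training needs at least one example of each class")

    mean = x.mean(axis=0)
    scale = np.maximum(x.std(axis=0), 1e-12)
    xs = (x - mean) / scale

    sizes = (x.shape[1], *hidden_sizes, 1)
    rng = np.random.default_rng(seed)
    weights = [
        rng.normal(0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:])
    ]
    biases = [np.zeros(fan_out) for fan_out in sizes[1:]]

    n = xs.shape[0]
    yt = y[:, None]
    vel_w = [np.zeros_like(w) for w in weights]
    vel_b = [np.zeros_like(b) for b in biases]
    loss = float("nan")
    for _ in range(epochs):
        # forward
        activations = [xs]
        for w, b in zip(weights, biases):
            activations.append(_sigmoid(activations[-1] @ w + b))
        out = activations[-1]
        eps = 1e-12
        loss = float(-np.mean(yt * np.log(out + eps) + (1 - yt) * np.log(1 - out + eps)))
        # backward: logistic output + cross-entropy -> delta = (out - y)
        delta = (out - yt) / n
        for layer in range(len(weights) - 1, -1, -1):
            a_prev = activations[layer]
            grad_w = a_prev.T @ delta
            grad_b = delta.sum(axis=0)
            if layer > 0:
                a = activations[layer]
                delta = (delta @ weights[layer].T) * a * (1 - a)
            vel_w[layer] = momentum * vel_w[layer] - learning_rate * grad_w
            vel_b[layer] = momentum * vel_b[layer] - learning_rate * grad_b
            weights[layer] = weights[layer] + vel_w[layer]
            biases[layer] = biases[layer] + vel_b[layer]

    return ClassifierModel(
        layer_sizes=sizes,
        weights=weights,
        biases=biases,
        feature_mean=mean,
        feature_scale=scale,
        seed=seed,
        epochs=epochs,
        learning_rate=learning_rate,
        final_loss=loss,
    )


def classify_voxels(
    model: ClassifierModel,
    coords: np.ndarray,
    features: np.ndarray,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    threshold: float = 0.5,
) -> BinaryMask:
    """Threshold per-voxel tumor probabilities into a mask over the ROI.

    A voxel is tumor iff its forward-pass probability is >= ``threshold``.
    ``coords`` and ``features`` come from :func:`hepavol.texture.feature_map`
    and must use the training feature order.
    """
    coords = np.asarray(coords)
    if coords.ndim != 2 or coords.shape[1] != 3 or coords.shape[0] != len(features):
        raise ContractError("coords must be (n, 3) and match the feature rows")
    proba = model.predict_proba(features)
    mask = np.zeros(shape, dtype=bool)
    sel = proba >= threshold
    mask[coords[sel, 0], coords[sel, 1], coords[sel, 2]] = True
    return BinaryMask(mask, spacing)


def postprocess(
    mask: BinaryMask, closing_radius_vox: int = 1, opening_radius_vox: int = 1
) -> BinaryMask:
    """Morphological closing (fill small holes) then opening (drop small noise).

    Both use ball structuring elements; the closing is computed on a padded
    grid so it is extensive, and radius 0 disables either step.
    """
    if closing_radius_vox < 0 or opening_radius_vox < 0:
        raise ContractError("radii must be >= 0")
    from .liver import closing_ball

    out = closing_ball(mask.data, closing_radius_vox)
    if opening_radius_vox > 0:
        out = ndimage.binary_opening(out, structure=_ball(opening_radius_vox))
    return BinaryMask(out, mask.spacing)


@dataclass
class RefinementEdits:
    """Batch stand-in for interactive mask editing: add/remove voxel lists."""

    edits: list[tuple[tuple[int, int, int], str]]

    def __post_init__(self):
        seen: dict[tuple[int, int, int], str] = {}
        for voxel, action in self.edits:
            voxel = tuple(int(c) for c in voxel)
            if action not in ("add", "remove"):
                raise ValidationError(f"unknown edit action {action!r}")
            if voxel in seen and seen[voxel] != action:
                raise ValidationError(f"conflicting actions for voxel {voxel}")
            seen[voxel] = action
        self.edits = [(tuple(int(c) for c in v), a) for v, a in self.edits]


def read_edits(path: str | Path) -> RefinementEdits:
    """Read an edits CSV with header ``z,y,x,action``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"z", "y", "x", "action"}
    if not required.issubset(df.columns):
        raise ValidationError(f"edits file must have columns {sorted(required)}")
    return RefinementEdits(
        [((int(r.z), int(r.y), int(r.x)), str(r.action)) for r in df.itertuples()]
    )


def apply_refinement(mask: BinaryMask, edits: RefinementEdits) -> BinaryMask:
    """Apply add/remove voxel edits; idempotent, out-of-grid indices rejected."""
    out = mask.data.copy()
    shape = np.asarray(out.shape)
    for voxel, action in edits.edits:
        idx = np.asarray(voxel)
        if np.any(idx < 0) or np.any(idx >= shape):
            raise ValidationError(f"edit voxel {voxel} outside grid {tuple(shape)}")
        out[voxel] = action == "add"
    return BinaryMask(out, mask.spacing)
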