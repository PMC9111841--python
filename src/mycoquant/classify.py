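"""Sampling-area classification into the four colonization classes.

A pluggable feature extractor turns each ~150 px sampling-area patch
into a fixed-length vector; a classifier head (RBF-kernel SVM or a
single fully-connected softmax layer) maps vectors to class labels.
The default "handcrafted" extractor — a joint RGB histogram plus
stain/texture statistics — needs no pretrained weights and keeps the
package self-contained; CNN backbones can be registered as additional
extractors through :func:`register_extractor`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import joblib
import numpy as np
from scipy import ndimage
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .core import ClassLabel, SamplingArea, validate_label
from .rotation import luminance

log = logging.getLogger(__name__)

N_CLASSES = 4


@dataclass
class FeatureVector:
    values: np.ndarray
    extractor_id: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature vector contains non-finite values")


# --------------------------------------------------------------------------
# feature extractors

_DARK_THRESHOLD = 110.0  # luminance below which a pixel counts as stained structure
_HIST_BINS = 4  # per channel -> 64-bin joint RGB histogram


def _handcrafted_features(patch: np.ndarray) -> np.ndarray:
    """Joint RGB histogram + stain morphology statistics.

    The histogram (4x4x4 bins, normalized to unit mass) captures the
    color composition — orange grid, blue-gray root tissue, dark
    trypan-blue structures, pale background.  The morphology block
    separates vesicle-like blobs (large compact dark components) from
    arbuscule-like filament textures (many small high-perimeter
    components) and measures how much root tissue is present at all.
    """
    px = patch.astype(np.float64)
    n = px.shape[0] * px.shape[1]
    idx = np.clip((px // (256 // _HIST_BINS)).astype(int), 0, _HIST_BINS - 1)
    flat = idx[..., 0] * _HIST_BINS * _HIST_BINS + idx[..., 1] * _HIST_BINS + idx[..., 2]
    hist = np.bincount(flat.ravel(), minlength=_HIST_BINS**3).astype(np.float64) / n

    lum = luminance(patch)
    gx = ndimage.sobel(lum, axis=1, mode="reflect")
    gy = ndimage.sobel(lum, axis=0, mode="reflect")
    mag = np.hypot(gx, gy)

    dark = lum < _DARK_THRESHOLD
    dark_frac = dark.mean()
    n_comp = 0
    mean_comp = 0.0
    perim_ratio = 0.0
    if dark.any():
        labeled, n_comp = ndimage.label(dark)
        sizes = np.bincount(labeled.ravel())[1:]
        mean_comp = float(sizes.mean()) / n
        eroded = ndimage.binary_erosion(dark)
        perim_ratio = float((dark & ~eroded).sum()) / float(dark.sum())
    blueish = (px[..., 2] > px[..., 0]) & (lum >= _DARK_THRESHOLD) & (lum < 210)
    stats = np.array(
        [
            lum.mean() / 255.0,
            lum.std() / 255.0,
            mag.mean() / 1020.0,
            mag.std() / 1020.0,
            dark_frac,
            n_comp / 50.0,
            mean_comp,
            perim_ratio,
            blueish.mean(),
            float(mag[dark].mean() / 1020.0) if dark.any() else 0.0,
        ]
    )
    return np.concatenate([hist, stats])


#: registry of feature extractors: id -> (function, input size)
_EXTRACTORS: dict[str, tuple[Callable[[np.ndarray], np.ndarray], int]] = {
    "handcrafted": (_handcrafted_features, 64),
}


def register_extractor(extractor_id: str, fn: Callable[[np.ndarray], np.ndarray], input_size: int = 224) -> None:
    """Register a feature extractor (e.g. a pretrained CNN backbone) under an id."""
    _EXTRACTORS[extractor_id] = (fn, input_size)


def extract_features(area: SamplingArea, extractor: str = "handcrafted") -> FeatureVector:
    """Deterministic feature vector for one sampling area."""
    if extractor not in _EXTRACTORS:
        raise ValueError(f"unknown extractor {extractor!r}; registered: {sorted(_EXTRACTORS)}")
    fn, size = _EXTRACTORS[extractor]
    return FeatureVector(values=fn(area.resized(size)), extractor_id=extractor)


def _feature_matrix(areas: Sequence[SamplingArea], extractor: str) -> np.ndarray:
    return np.stack([extract_features(a, extractor).values for a in areas])


# --------------------------------------------------------------------------
# classifier heads


from sklearn.base import BaseEstimator, ClassifierMixin


class SoftmaxHead(ClassifierMixin, BaseEstimator):
    """Single fully-connected softmax layer trained with minibatch Adam.

    Defaults follow the fine-tuning recipe used for the CNN heads:
    20 epochs, batch size 32, initial learning rate 1e-3 halved every
    5 epochs, Adam with weight decay 1e-5, cross-entropy loss.
    """

    def __init__(
        self,
        n_classes: int = N_CLASSES,
        epochs: int = 20,
        batch_size: int = 32,
        lr: float = 1e-3,
        lr_halve_every: int = 5,
        weight_decay: float = 1e-5,
        seed: int = 0,
    ) -> None:
        self.n_classes = n_classes
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.lr_halve_every = lr_halve_every
        self.weight_decay = weight_decay
        self.seed = seed

    @staticmethod
    def _softmax(z: np.ndarray) -> np.ndarray:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "SoftmaxHead":
        rng = np.random.default_rng(self.seed)
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        n, d = X.shape
        W = np.zeros((d, self.n_classes))
        b = np.zeros(self.n_classes)
        mW = np.zeros_like(W)
        vW = np.zeros_like(W)
        mb = np.zeros_like(b)
        vb = np.zeros_like(b)
        onehot = np.eye(self.n_classes)[y]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        t = 0
        for epoch in range(self.epochs):
            lr = self.lr * 0.5 ** (epoch // self.lr_halve_every)
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                sel = order[start : start + self.batch_size]
                Xb, Yb = X[sel], onehot[sel]
                probs = self._softmax(Xb @ W + b)
                gW = Xb.T @ (probs - Yb) / len(sel) + self.weight_decay * W
                gb = (probs - Yb).mean(axis=0)
                t += 1
                mW = beta1 * mW + (1 - beta1) * gW
                vW = beta2 * vW + (1 - beta2) * gW**2
                mb = beta1 * mb + (1 - beta1) * gb
                vb = beta2 * vb + (1 - beta2) * gb**2
                W -= lr * (mW / (1 - beta1**t)) / (np.sqrt(vW / (1 - beta2**t)) + eps)
                b -= lr * (mb / (1 - beta1**t)) / (np.sqrt(vb / (1 - beta2**t)) + eps)
        self.W_ = W
        self.b_ = b
        self.classes_ = np.arange(self.n_classes)
        return self

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self)
        return np.asarray(X) @ self.W_ + self.b_

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.decision_function(X), axis=1)


@dataclass
class ClassifierModel:
    """A trained head plus the extractor it expects and how it was trained."""

    kind: str  # "fc" | "svm"
    extractor_id: str
    estimator: object  # sklearn Pipeline (svm) or Pipeline with SoftmaxHead (fc)
    metadata: dict = field(default_factory=dict)

    def predict_features(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(self.estimator.predict(X), dtype=int)


def train_classifier(
    features: np.ndarray,
    labels: Sequence[int],
    kind: str = "svm",
    seed: int = 0,
    extractor_id: str = "handcrafted",
    svm_c: float = 1.0,
    svm_gamma: float = 0.25,
    class_weight: Optional[str] = None,
    **fc_kwargs,
) -> ClassifierModel:
    """Train an SVM (RBF kernel, C=1.0, gamma=0.25 by default) or FC head.

    Features are standardized inside the model.  Training is fully
    reproducible for a fixed seed.
    """
    X = np.asarray(features, dtype=np.float64)
    y = np.array([int(validate_label(l)) for l in labels])
    if len(X) != len(y):
        raise ValueError(f"{len(X)} feature rows but {len(y)} labels")
    present = set(np.unique(y).tolist())
    if len(present) < 2:
        missing = sorted(set(int(c) for c in ClassLabel) - present)
        raise ValueError(f"training set contains a single class; missing classes: {missing}")
    if kind == "svm":
        head = SVC(
            kernel="rbf", C=svm_c, gamma=svm_gamma, class_weight=class_weight, random_state=seed
        )
        meta = {"seed": seed, "C": svm_c, "gamma": svm_gamma, "class_weight": class_weight}
    elif kind == "fc":
        head = SoftmaxHead(seed=seed, **fc_kwargs)
        meta = {"seed": seed, **{k: getattr(head, k) for k in ("epochs", "batch_size", "lr", "weight_decay")}}
    else:
        raise ValueError(f"classifier kind must be 'fc' or 'svm', got {kind!r}")
    pipe = Pipeline([("scale", StandardScaler()), ("head", head)])
    pipe.fit(X, y)
    return ClassifierModel(kind=kind, extractor_id=extractor_id, estimator=pipe, metadata=meta)


def classify(model: ClassifierModel, areas: Sequence[SamplingArea]) -> list[ClassLabel]:
    """Predict one label per sampling area (order preserved)."""
    if len(areas) == 0:
        return []
    X = _feature_matrix(areas, model.extractor_id)
    return [ClassLabel(int(p)) for p in model.predict_features(X)]


def save_model(model: ClassifierModel, path: str | Path) -> None:
    joblib.dump(model, Path(path))


def load_model(path: str | Path) -> ClassifierModel:
    model = joblib.load(Path(path))
    if not isinstance(model, ClassifierModel):
        raise ValueError(f"{path} does not contain a ClassifierModel")
    return model


# --------------------------------------------------------------------------
# augmentation and evaluation


def augment_dataset(
    areas: Sequence[SamplingArea],
    seed: int = 0,
    n_crops: int = 2,
    crop_fraction: float = 0.8,
    keep_originals: bool = True,
    out_size: int = 224,
) -> list[SamplingArea]:
    """Flips plus random crops, all resized to ``out_size`` (bilinear).

    Each input yields its horizontal and vertical reflections and
    ``n_crops`` random square crops of side ``crop_fraction`` times the
    patch; labels are inherited.  With originals kept, one input
    produces ``1 + 2 + n_crops`` patches (n_crops=60 approximately
    matches a 5k -> 300k dataset expansion).
    """
    if not (0.0 < crop_fraction <= 1.0):
        raise ValueError("crop_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    out: list[SamplingArea] = []
    for area in areas:
        patch = area.resized(out_size)
        variants = []
        if keep_originals:
            variants.append(patch)
        variants.append(patch[:, ::-1])  # horizontal flip
        variants.append(patch[::-1, :])  # vertical flip
        side = patch.shape[0]
        crop = int(round(crop_fraction * side))
        for _ in range(n_crops):
            x = int(rng.integers(0, side - crop + 1))
            y = int(rng.integers(0, side - crop + 1))
            variants.append(
                SamplingArea(patch=np.ascontiguousarray(patch[y : y + crop, x : x + crop])).resized(out_size)
            )
        for v in variants:
            out.append(
                SamplingArea(
                    patch=np.ascontiguousarray(v), source_box=area.source_box, label=area.label
                )
            )
    return out


@dataclass
class EvaluationReport:
    """Cross-validated accuracy with a pooled 4x4 confusion matrix."""

    accuracy: float
    confusion: np.ndarray  # rows = true, cols = predicted
    fold_accuracies: list[float]

    def __post_init__(self) -> None:
        self.confusion = np.asarray(self.confusion, dtype=int)
        assert self.confusion.shape == (N_CLASSES, N_CLASSES)
        assert (self.confusion >= 0).all()

    @property
    def n_evaluated(self) -> int:
        return int(self.confusion.sum())

    @property
    def pooled_accuracy(self) -> float:
        return float(np.trace(self.confusion)) / max(self.n_evaluated, 1)


def cross_validate(
    areas: Sequence[SamplingArea],
    k: int = 5,
    kind: str = "svm",
    extractor: str = "handcrafted",
    seed: int = 0,
    **train_kwargs,
) -> EvaluationReport:
    """Stratified k-fold cross-validation of the extractor + head combo.

    Accuracy is the mean over folds; the confusion matrix is summed over
    folds so its row sums equal the per-class sample counts.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = np.array([int(a.label) for a in areas if a.label is not None])
    if len(labels) != len(areas):
        raise ValueError("every sampling area must carry a label for cross-validation")
    counts = np.bincount(labels, minlength=N_CLASSES)
    thin = [int(c) for c in np.flatnonzero((counts > 0) & (counts < k))]
    if thin:
        raise ValueError(f"classes {thin} have fewer than k={k} members; cannot stratify")
    X = _feature_matrix(areas, extractor)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    confusion = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    fold_accs: list[float] = []
    for fold, (tr, te) in enumerate(skf.split(X, labels)):
        model = train_classifier(
            X[tr], labels[tr], kind=kind, seed=seed + fold, extractor_id=extractor, **train_kwargs
        )
        pred = model.predict_features(X[te])
        fold_accs.append(float((pred == labels[te]).mean()))
        confusion += confusion_matrix(labels[te], pred, labels=list(range(N_CLASSES)))
        log.info("fold %d/%d accuracy %.3f", fold + 1, k, fold_accs[-1])
    return EvaluationReport(
        accuracy=float(np.mean(fold_accs)), confusion=confusion, fold_accuracies=fold_accs
    )
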