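"""Gaussian naive Bayes benign/malignant classification and evaluation.

Features are treated as conditionally independent Gaussians per class; the
decision is maximum a posteriori, with ties resolved in favor of the
malignant class (the clinically conservative choice -- a tie never misses a
cancer).  Evaluation follows the standard protocol: a stratified seeded
80/20 train/test split, a confusion matrix with "malignant" as the positive
class, and accuracy = (TP+TN)/n, specificity = TN/(FP+TN),
sensitivity = TP/(FN+TP).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

BENIGN = "benign"
MALIGNANT = "malignant"
CLASSES = (BENIGN, MALIGNANT)

__all__ = [
    "BENIGN",
    "MALIGNANT",
    "LabeledSample",
    "GaussianNBModel",
    "ConfusionCounts",
    "EvalMetrics",
    "stratified_split",
    "fit_gnb",
    "predict_gnb",
    "confusion_counts",
    "compute_metrics",
    "evaluate_pipeline",
]

_VAR_FLOOR_REL = 1e-9


@dataclass(frozen=True)
class LabeledSample:
    features: np.ndarray
    label: str
    id: str = ""

    def __post_init__(self) -> None:
        f = np.asarray(self.features, dtype=np.float64).ravel()
        object.__setattr__(self, "features", f)
        if self.label not in CLASSES:
            raise ValueError(f"label must be one of {CLASSES}, got {self.label!r}")
        if not np.isfinite(f).all():
            raise ValueError(f"sample {self.id!r} has non-finite features")


@dataclass
class GaussianNBModel:
    """Per-class priors, feature means and (floored) feature variances."""

    classes: tuple[str, ...]
    priors: np.ndarray
    means: np.ndarray  # (n_classes, n_features)
    variances: np.ndarray  # (n_classes, n_features), > 0
    var_floor: float
    feature_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if abs(self.priors.sum() - 1.0) > 1e-12:
            raise ValueError("priors must sum to 1")
        if (self.variances <= 0).any():
            raise ValueError("variances must be positive after flooring")

    def to_json(self) -> str:
        return json.dumps(
            {
                "classes": list(self.classes),
                "priors": self.priors.tolist(),
                "means": self.means.tolist(),
                "variances": self.variances.tolist(),
                "var_floor": self.var_floor,
                "feature_names": list(self.feature_names) if self.feature_names else None,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "GaussianNBModel":
        d = json.loads(text)
        return cls(
            classes=tuple(d["classes"]),
            priors=np.asarray(d["priors"]),
            means=np.asarray(d["means"]),
            variances=np.asarray(d["variances"]),
            var_floor=d["var_floor"],
            feature_names=tuple(d["feature_names"]) if d.get("feature_names") else None,
        )


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    accuracy: float
    specificity: float
    sensitivity: float


def stratified_split(
    samples: list[LabeledSample],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
) -> tuple[list[int], list[int]]:
    """Seeded train/test index split with floor(count * fraction) per class in train."""
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    rng = np.random.default_rng(seed)
    labels = np.array([s.label for s in samples])
    groups = [np.arange(len(samples))] if not stratify else [
        np.nonzero(labels == c)[0] for c in CLASSES
    ]
    train: list[int] = []
    test: list[int] = []
    for idx in groups:
        if stratify and len(idx) < 2:
            raise ValueError("each class needs >= 2 samples for a stratified split")
        perm = rng.permutation(idx)
        n_train = int(np.floor(len(idx) * train_fraction))
        train.extend(perm[:n_train].tolist())
        test.extend(perm[n_train:].tolist())
    return sorted(train), sorted(test)


def fit_gnb(train: list[LabeledSample], feature_names=None) -> GaussianNBModel:
    """Maximum-likelihood Gaussian naive Bayes fit.

    Priors are class frequencies; per-class per-feature means and variances
    are sample moments.  Variances are floored at 1e-9 times the largest
    pooled feature variance so a zero-variance feature cannot produce an
    infinite log-density.
    """
    labels = np.array([s.label for s in train])
    x = np.stack([s.features for s in train])
    for c in CLASSES:
        if (labels == c).sum() == 0:
            raise ValueError(f"class {c!r} absent from training data")
    floor = _VAR_FLOOR_REL * max(float(x.var(axis=0).max()), 1.0)
    priors, means, variances = [], [], []
    for c in CLASSES:
        xc = x[labels == c]
        priors.append(len(xc) / len(x))
        means.append(xc.mean(axis=0))
        variances.append(np.maximum(xc.var(axis=0), floor))
    return GaussianNBModel(
        classes=CLASSES,
        priors=np.array(priors),
        means=np.stack(means),
        variances=np.stack(variances),
        var_floor=floor,
        feature_names=tuple(feature_names) if feature_names is not None else None,
    )


def predict_gnb(model: GaussianNBModel, features) -> tuple[str, dict[str, float]]:
    """MAP label and normalized per-class posteriors for one feature vector.

    Log-posteriors are log prior plus summed Gaussian log-densities,
    normalized in log-space with max-subtraction.  An exact tie goes to the
    malignant class.
    """
    x = np.asarray(features, dtype=np.float64).ravel()
    if x.size != model.means.shape[1]:
        raise ValueError(f"feature dimension {x.size} != model dimension {model.means.shape[1]}")
    log_post = (
        np.log(model.priors)
        - 0.5 * np.sum(np.log(2 * np.pi * model.variances), axis=1)
        - 0.5 * np.sum((x - model.means) ** 2 / model.variances, axis=1)
    )
    p = np.exp(log_post - log_post.max())
    p /= p.sum()
    posteriors = dict(zip(model.classes, p.tolist()))
    i_mal = model.classes.index(MALIGNANT)
    if log_post[i_mal] >= log_post.max():  # argmax with tie -> malignant
        label = MALIGNANT
    else:
        label = model.classes[int(np.argmax(log_post))]
    return label, posteriors


def confusion_counts(truth, predicted, positive_class: str = MALIGNANT) -> ConfusionCounts:
    """Tally TP/TN/FP/FN with the given positive class."""
    truth, predicted = list(truth), list(predicted)
    if len(truth) != len(predicted):
        raise ValueError(f"length mismatch: {len(truth)} vs {len(predicted)}")
    t = np.array([lab == positive_class for lab in truth])
    p = np.array([lab == positive_class for lab in predicted])
    return ConfusionCounts(
        tp=int(np.sum(t & p)),
        tn=int(np.sum(~t & ~p)),
        fp=int(np.sum(~t & p)),
        fn=int(np.sum(t & ~p)),
    )


def compute_metrics(counts: ConfusionCounts) -> EvalMetrics:
    """Accuracy, specificity and sensitivity from the confusion counts.

    Raises for an empty table or a zero denominator (no actual negatives for
    specificity, no actual positives for sensitivity).
    """
    if counts.n == 0:
        raise ValueError("empty confusion table")
    if counts.fp + counts.tn == 0:
        raise ValueError("specificity undefined: no actual negatives")
    if counts.fn + counts.tp == 0:
        raise ValueError("sensitivity undefined: no actual positives")
    return EvalMetrics(
        accuracy=(counts.tn + counts.tp) / counts.n,
        specificity=counts.tn / (counts.fp + counts.tn),
        sensitivity=counts.tp / (counts.fn + counts.tp),
    )


def evaluate_pipeline(
    dataset: list[LabeledSample],
    train_fraction: float = 0.8,
    seed: int = 0,
    stratify: bool = True,
    feature_names=None,
) -> dict:
    """Split, fit, predict on the held-out set, and score.

    Returns a report dict with the metrics, confusion counts, split sizes,
    model and per-sample predictions; deterministic given the seed.
    """
    train_idx, test_idx = stratified_split(dataset, train_fraction, seed, stratify)
    model = fit_gnb([dataset[i] for i in train_idx], feature_names=feature_names)
    truth, predicted, rows = [], [], []
    for i in test_idx:
        s = dataset[i]
        label, post = predict_gnb(model, s.features)
        truth.append(s.label)
        predicted.append(label)
        rows.append(
            {"id": s.id or str(i), "truth": s.label, "predicted": label,
             "posterior_malignant": post[MALIGNANT]}
        )
    counts = confusion_counts(truth, predicted)
    metrics = compute_metrics(counts)
    return {
        "seed": seed,
        "train_fraction": train_fraction,
        "n_train": len(train_idx),
        "n_test": len(test_idx),
        "counts": counts,
        "metrics": metrics,
        "model": model,
        "predictions": rows,
    }
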