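"""Per-view linear SVM with calibrated class scores.

Each feature view gets its own linear-kernel SVM. Because the fusion rule
compares confidence *across* two different classifiers, raw SVM margins are
not usable directly — they live on classifier-specific scales. The classifier
therefore exposes calibrated probabilities mu(P) and mu(A) = 1 - mu(P),
obtained by fitting a Platt-style sigmoid

    mu(P | margin) = 1 / (1 + exp(-(a * margin + b))),   a > 0

to *out-of-sample* margins collected from an internal seeded 3-fold split of
the training data (fitting the sigmoid on resubstitution margins would
overstate confidence). A ``score_mode="margin"`` switch is available for
sensitivity analysis; it pushes the raw margin through a fixed unit-slope
sigmoid so scores remain complementary probabilities on [0, 1].

Features are z-scored per feature before the SVM, with the standardizer
fitted on training rows only (zero-variance features get scale 1). The
predicted label is P exactly when mu(P) >= 0.5 — a tie goes to P, favoring
sensitivity, since a missed dysplastic lesion is the clinically costly error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_io import FeatureView, Label

__all__ = ["ViewClassifier", "ClassifierOutput", "train", "predict"]

_MIN_SLOPE = 1e-6


@dataclass(frozen=True)
class ClassifierOutput:
    """Per-sample labels and complementary class scores from one classifier."""

    sample_ids: tuple[str, ...]
    labels: tuple[Label, ...]
    score_P: np.ndarray
    score_A: np.ndarray

    def __post_init__(self) -> None:
        sp = np.asarray(self.score_P, dtype=float)
        sa = np.asarray(self.score_A, dtype=float)
        object.__setattr__(self, "score_P", sp)
        object.__setattr__(self, "score_A", sa)
        n = len(self.sample_ids)
        if not (len(self.labels) == len(sp) == len(sa) == n):
            raise ValueError("misaligned classifier output fields")
        if np.any((sp < 0) | (sp > 1)):
            raise ValueError("score_P outside [0, 1]")
        if not np.allclose(sp + sa, 1.0, atol=1e-12):
            raise ValueError("score_P + score_A must equal 1")


@dataclass(frozen=True)
class ViewClassifier:
    """Trained linear separator + standardizer + sigmoid calibration."""

    view_name: str
    weights: np.ndarray          # d, in standardized feature space
    bias: float
    center: np.ndarray           # per-feature training mean
    scale: np.ndarray            # per-feature training sd (1 where sd == 0)
    calib_slope: float           # a > 0
    calib_intercept: float       # b
    regularization: float
    score_mode: str = "platt"    # "platt" | "margin"
    seed: int = 0

    @property
    def n_features(self) -> int:
        return len(self.weights)

    def margins(self, X: np.ndarray) -> np.ndarray:
        """Signed distance-like decision value; positive side is class P."""
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"feature dimension mismatch: classifier expects "
                f"{self.n_features}, got {X.shape[1]}"
            )
        Z = (X - self.center) / self.scale
        return Z @ self.weights + self.bias

    def calibrate(self, margin: np.ndarray) -> np.ndarray:
        """Monotone map from margin to mu(P)."""
        m = np.asarray(margin, dtype=float)
        if self.score_mode == "margin":
            z = m
        else:
            z = self.calib_slope * m + self.calib_intercept
        return 1.0 / (1.0 + np.exp(-z))

    # -- serialization -------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "view_name": self.view_name,
                "weights": self.weights.tolist(),
                "bias": self.bias,
                "center": self.center.tolist(),
                "scale": self.scale.tolist(),
                "calib_slope": self.calib_slope,
                "calib_intercept": self.calib_intercept,
                "regularization": self.regularization,
                "score_mode": self.score_mode,
                "seed": self.seed,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ViewClassifier":
        d = json.loads(text)
        return cls(
            view_name=d["view_name"],
            weights=np.asarray(d["weights"], dtype=float),
            bias=float(d["bias"]),
            center=np.asarray(d["center"], dtype=float),
            scale=np.asarray(d["scale"], dtype=float),
            calib_slope=float(d["calib_slope"]),
            calib_intercept=float(d["calib_intercept"]),
            regularization=float(d["regularization"]),
            score_mode=d["score_mode"],
            seed=int(d["seed"]),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def load(cls, path: str | Path) -> "ViewClassifier":
        return cls.from_json(Path(path).read_text())


def _standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    scale = np.where(sd > 0, sd, 1.0)  # zero-variance feature: scale 1
    return center, scale


def _fit_svm(Z: np.ndarray, y: np.ndarray, C: float) -> SVC:
    clf = SVC(kernel="linear", C=C)
    clf.fit(Z, y)
    return clf


def _platt_fit(margins: np.ndarray, y: np.ndarray, seed: int) -> tuple[float, float]:
    """Fit sigmoid a*m + b by logistic regression on held-out margins.

    The fit uses balanced class weights, i.e. the calibrated score is the
    posterior under an equal-prior convention. Under class imbalance an
    unweighted sigmoid absorbs the log prior odds into its intercept, which
    (i) drags the 0.5 decision threshold away from the SVM boundary and
    (ii) puts the two views' scores on prior-inflated scales that would bias
    the fusion's cross-classifier confidence comparison. The slope is floored
    at a tiny positive value so the calibrated score is always strictly
    increasing in the margin.
    """
    lr = LogisticRegression(
        C=1e6, solver="lbfgs", max_iter=1000, random_state=seed,
        class_weight="balanced",
    )
    lr.fit(margins.reshape(-1, 1), y)
    a = float(lr.coef_[0][0])
    b = float(lr.intercept_[0])
    if a < _MIN_SLOPE:
        a = _MIN_SLOPE
    return a, b


def train(
    view: FeatureView,
    labels: Sequence[Label],
    regularization: float = 1.0,
    seed: int = 0,
    score_mode: str = "platt",
) -> ViewClassifier:
    """Fit standardizer, linear SVM and Platt calibration on one view.

    The calibration sigmoid is fitted on margins of held-out thirds of the
    training data (seeded internal 3-fold stratified split), then the SVM is
    refitted on the full training set. Requires at least two samples of each
    class.
    """
    if score_mode not in ("platt", "margin"):
        raise ValueError(f"unknown score_mode {score_mode!r}")
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    labels = list(labels)
    if len(labels) != view.n_samples:
        raise ValueError("labels not aligned with view rows")
    y = np.array([1 if l is Label.P else 0 for l in labels], dtype=int)
    n_p, n_a = int(y.sum()), int(len(y) - y.sum())
    if n_p < 2 or n_a < 2:
        raise ValueError(
            f"need >= 2 samples of each class to train (got P={n_p}, A={n_a})"
        )

    X = view.matrix
    center, scale = _standardizer(X)
    Z = (X - center) / scale

    # out-of-sample margins for calibration
    n_splits = min(3, n_p, n_a)
    skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    oos_margin = np.empty(len(y))
    for tr, te in skf.split(Z, y):
        # inner split can lose a class only if n_splits > class count; guarded above
        sub = _fit_svm(Z[tr], y[tr], regularization)
        oos_margin[te] = sub.decision_function(Z[te])
    a, b = _platt_fit(oos_margin, y, seed)

    final = _fit_svm(Z, y, regularization)
    # SVC orders classes [0, 1]; decision_function is positive for class 1 (P)
    weights = final.coef_.ravel().astype(float)
    bias = float(final.intercept_[0])
    return ViewClassifier(
        view_name=view.view_name,
        weights=weights,
        bias=bias,
        center=center,
        scale=scale,
        calib_slope=a,
        calib_intercept=b,
        regularization=regularization,
        score_mode=score_mode,
        seed=seed,
    )


def predict(clf: ViewClassifier, view: FeatureView) -> ClassifierOutput:
    """Deterministic scores and labels for a view; label P iff mu(P) >= 0.5."""
    m = clf.margins(view.matrix)
    score_p = clf.calibrate(m)
    labels = tuple(Label.P if s >= 0.5 else Label.A for s in score_p)
    return ClassifierOutput(
        sample_ids=tuple(view.sample_ids),
        labels=labels,
        score_P=score_p,
        score_A=1.0 - score_p,
    )
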