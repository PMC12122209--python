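"""Stratified cross-validation and the imbalance-aware metric suite.

Metrics (P is the positive class): sensitivity SEN = TP/(TP+FN), specificity
SPE = TN/(TN+FP), precision PRE = TP/(TP+FP), balanced accuracy
BAC = (SEN+SPE)/2, and AUC computed as the Mann-Whitney rank statistic with
half-credit for tied scores. A ratio with a zero denominator is *flagged*
(None) rather than silently coerced; flagged values are excluded from fold
aggregates with a warning.

Folds are built by shuffling each class with a seeded RNG and dealing
round-robin — the simplest scheme under which per-fold minority counts differ
by at most one. Cross-validation fits every component (standardizer, SVM,
calibration) on the training folds only, so held-out metrics are free of
leakage by construction.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata

from . import classifier as vc
from .data_io import DatasetManifest, FeatureView, Label
from .fusion import FusionDecision, FusionPolicy, fuse

__all__ = [
    "FoldAssignment",
    "MetricSet",
    "CVReport",
    "CVConfig",
    "stratified_folds",
    "compute_metrics",
    "cross_validate",
]

MODELS = ("CP", "CA", "fusion")
METRICS = ("BAC", "SEN", "SPE", "PRE", "AUC")


@dataclass(frozen=True)
class FoldAssignment:
    k: int
    fold_of_sample: np.ndarray  # int fold index per sample, in [0, k)
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of_sample != fold)


@dataclass(frozen=True)
class MetricSet:
    """One model's metrics on one evaluation set.

    Undefined ratios (zero denominator) and AUC on a single-class truth set
    are None, never NaN.
    """

    TP: int
    FP: int
    TN: int
    FN: int
    SEN: Optional[float]
    SPE: Optional[float]
    PRE: Optional[float]
    BAC: Optional[float]
    AUC: Optional[float]

    @property
    def confusion(self) -> tuple[int, int, int, int]:
        return (self.TP, self.FP, self.TN, self.FN)

    def as_dict(self) -> dict:
        return {m: getattr(self, m) for m in METRICS}


@dataclass(frozen=True)
class CVReport:
    """Per-fold metric sets for each model plus mean +/- sd aggregates."""

    per_fold: dict  # model -> list[MetricSet], one per fold
    aggregate: dict  # model -> metric -> (mean, sd)
    decisions: list  # per fold: list[FusionDecision] on the test fold
    k: int
    seed: int

    def table(self) -> str:
        """Human-readable model x metric table (mean +/- sd across folds)."""
        lines = ["Model   " + "".join(f"{m:>16}" for m in METRICS)]
        for model in MODELS:
            cells = []
            for m in METRICS:
                mean, sd = self.aggregate[model][m]
                cells.append(
                    f"{mean:.3f} +/- {sd:.3f}" if mean is not None else "undefined"
                )
            lines.append(f"{model:<8}" + "".join(f"{c:>16}" for c in cells))
        return "\n".join(lines)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["model", "fold"] + list(METRICS) + ["TP", "FP", "TN", "FN"])
            for model in MODELS:
                for i, ms in enumerate(self.per_fold[model]):
                    w.writerow(
                        [model, i]
                        + [("" if getattr(ms, m) is None else repr(getattr(ms, m)))
                           for m in METRICS]
                        + list(ms.confusion)
                    )
                for m in METRICS:
                    mean, sd = self.aggregate[model][m]
                    if mean is not None:
                        w.writerow([model, f"mean_{m}", repr(mean), f"sd={sd!r}"])


@dataclass(frozen=True)
class CVConfig:
    k: int = 5
    seed: int = 0
    regularization: float = 1.0
    score_mode: str = "platt"
    policy: FusionPolicy = field(default_factory=FusionPolicy)


def stratified_folds(labels: Sequence[Label], k: int, seed: int) -> FoldAssignment:
    """Seeded stratified fold assignment: shuffle within class, deal round-robin.

    Per-class fold sizes differ by at most one; requires every class to have
    at least k members.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    labels = list(labels)
    y = np.array([l.value for l in labels])
    rng = np.random.default_rng(seed)
    fold = np.full(len(labels), -1, dtype=int)
    for cls in (Label.P, Label.A):
        idx = np.flatnonzero(y == cls.value)
        if len(idx) < k:
            raise ValueError(
                f"class {cls.value} has {len(idx)} samples, fewer than k={k}"
            )
        rng.shuffle(idx)
        fold[idx] = np.arange(len(idx)) % k
    return FoldAssignment(k=k, fold_of_sample=fold, seed=seed)


def _safe_ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def auc_mann_whitney(y_true: np.ndarray, score: np.ndarray) -> Optional[float]:
    """AUC as the normalized Mann-Whitney U with half-credit for score ties.

    Equals the probability that a random presence sample outscores a random
    absence sample, ties counted 1/2. None when truth has a single class.
    """
    pos = y_true == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(score)  # average ranks implement tie half-credit
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def compute_metrics(
    y_true: Sequence[Label],
    y_pred: Sequence[Label],
    score_P: Optional[Sequence[float]] = None,
) -> MetricSet:
    """Exact confusion counts and the metric suite; AUC only when scores given."""
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} truths vs {len(y_pred)} predictions"
        )
    t = np.array([l is Label.P for l in y_true], dtype=bool)
    p = np.array([l is Label.P for l in y_pred], dtype=bool)
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    tn = int(np.sum(~t & ~p))
    fn = int(np.sum(t & ~p))
    sen = _safe_ratio(tp, tp + fn)
    spe = _safe_ratio(tn, tn + fp)
    pre = _safe_ratio(tp, tp + fp)
    bac = (sen + spe) / 2 if sen is not None and spe is not None else None
    auc = None
    if score_P is not None:
        s = np.asarray(score_P, dtype=float)
        if len(s) != len(t):
            raise ValueError("score_P length mismatch")
        auc = auc_mann_whitney(t.astype(int), s)
    return MetricSet(TP=tp, FP=fp, TN=tn, FN=fn,
                     SEN=sen, SPE=spe, PRE=pre, BAC=bac, AUC=auc)


def _aggregate(per_fold: list[MetricSet]) -> dict:
    out = {}
    for m in METRICS:
        vals = [getattr(ms, m) for ms in per_fold]
        defined = [v for v in vals if v is not None]
        if len(defined) < len(vals):
            warnings.warn(
                f"metric {m} undefined in {len(vals) - len(defined)} fold(s); "
                "excluded from the aggregate",
                stacklevel=2,
            )
        if not defined:
            out[m] = (None, None)
        else:
            mean = float(np.mean(defined))
            sd = float(np.std(defined, ddof=1)) if len(defined) > 1 else 0.0
            out[m] = (mean, sd)
    return out


def cross_validate(
    manifest: DatasetManifest,
    view1: FeatureView,
    view2: FeatureView,
    config: CVConfig = CVConfig(),
) -> CVReport:
    """Stratified k-fold evaluation of both base classifiers and the fusion.

    View 1 feeds CP (the presence specialist), view 2 feeds CA (the absence
    specialist). Per fold, each view's standardizer, SVM and calibration are
    fitted on the training folds only; the held-out fold is scored, fused,
    and measured. Fully deterministic given the seed.
    """
    ids = manifest.sample_ids
    if list(view1.sample_ids) != ids or list(view2.sample_ids) != ids:
        raise ValueError("views are not aligned with the manifest sample order")
    labels = manifest.labels
    if any(l is None for l in labels):
        raise ValueError("manifest labels unset; call merge_labels first")

    folds = stratified_folds(labels, config.k, config.seed)
    labels_arr = np.array(labels, dtype=object)
    per_fold: dict = {m: [] for m in MODELS}
    all_decisions: list[list[FusionDecision]] = []

    for f in range(config.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        try:
            outs = {}
            for name, view in (("CP", view1), ("CA", view2)):
                train_view = FeatureView(
                    view.view_name,
                    tuple(np.array(view.sample_ids, dtype=object)[tr]),
                    view.matrix[tr],
                )
                test_view = FeatureView(
                    view.view_name,
                    tuple(np.array(view.sample_ids, dtype=object)[te]),
                    view.matrix[te],
                )
                clf = vc.train(
                    train_view,
                    list(labels_arr[tr]),
                    regularization=config.regularization,
                    seed=config.seed + f,
                    score_mode=config.score_mode,
                )
                outs[name] = vc.predict(clf, test_view)
        except Exception as e:
            raise RuntimeError(f"cross-validation failed at fold {f}: {e}") from e

        decisions = fuse(outs["CP"], outs["CA"], config.policy)
        all_decisions.append(decisions)
        y_te = list(labels_arr[te])
        for name in ("CP", "CA"):
            per_fold[name].append(
                compute_metrics(y_te, list(outs[name].labels), outs[name].score_P)
            )
        per_fold["fusion"].append(
            compute_metrics(
                y_te,
                [d.fused_label for d in decisions],
                [d.fused_score_P for d in decisions],
            )
        )

    aggregate = {m: _aggregate(per_fold[m]) for m in MODELS}
    return CVReport(
        per_fold=per_fold,
        aggregate=aggregate,
        decisions=all_decisions,
        k=config.k,
        seed=config.seed,
    )
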