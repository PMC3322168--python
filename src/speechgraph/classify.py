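"""Binary diagnostic classification from speech-graph measure vectors.

A Gaussian naive Bayes classifier is the native model: with a handful of
word-normalized graph measures per subject and cohorts of 8-20 subjects
per group, its low-variance class-conditional density estimates are hard
to beat, and its posterior is a natural ranking score for ROC analysis.
Any other classifier can be plugged in through the two-method contract
``fit(X, y)`` / ``score(X) -> P(positive)``.

Evaluation is by cross-validation — leave-one-out by default, which
spends every subject on both training and testing — with the usual
ranking and agreement metrics: ROC curve and trapezoid AUC, sensitivity
and specificity at a posterior threshold of 0.5, and Cohen's kappa
against the clinical labels.

The default feature subsets per group comparison are the word-normalized
measures that separate the groups best: N, E, ATD for schizophrenic vs
manic; N, L1, L2 for schizophrenic vs control; L1, L2, L3 for manic vs
control.  Topic-deviation measures (WN, WE) are excluded by design: they
require semantic annotation, and the classifier is meant to run on
purely grammatical structure.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd

from .errors import InsufficientDataError, UnknownFeatureError

__all__ = [
    "DEFAULT_FEATURES",
    "COMPARISON_GROUPS",
    "FeatureMatrix",
    "GaussianNaiveBayes",
    "cross_validate",
    "roc_points",
    "roc_auc",
    "sens_spec",
    "cohen_kappa",
    "ClassifierReport",
    "feature_matrix_from_table",
    "run_comparison",
]

#: per-comparison default feature subsets (word-normalized measures)
DEFAULT_FEATURES: dict[str, list[str]] = {
    "SxM": ["N_per_word", "E_per_word", "ATD_per_word"],
    "SxC": ["N_per_word", "L1_per_word", "L2_per_word"],
    "MxC": ["L1_per_word", "L2_per_word", "L3_per_word"],
}

COMPARISON_GROUPS: dict[str, tuple[str, str]] = {
    "SxM": ("schizophrenic", "manic"),
    "SxC": ("schizophrenic", "control"),
    "MxC": ("manic", "control"),
}


class Classifier(Protocol):
    """Minimal contract a pluggable classifier must satisfy."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "Classifier": ...

    def score(self, X: np.ndarray) -> np.ndarray:
        """Probability-like score for the positive class, in [0, 1]."""
        ...


@dataclass
class FeatureMatrix:
    """Rows = subjects, columns = selected features, binary labels."""

    X: np.ndarray
    y: np.ndarray  # 1 = positive class, 0 = negative class
    feature_names: list[str]
    subject_ids: list[str]
    positive_label: str = "positive"
    negative_label: str = "negative"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or len(self.X) != len(self.y):
            raise ValueError("X must be 2-D with one row per label")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    @property
    def n(self) -> int:
        return len(self.y)


class GaussianNaiveBayes:
    """Gaussian class-conditional naive Bayes with a variance floor.

    Priors are class frequencies; each feature gets an independent
    Gaussian per class, with the standard deviation floored at
    ``1e-6 x`` the global feature standard deviation (or 1 when that is
    zero) so a constant training feature cannot produce a degenerate
    density.  Posteriors are computed in log space.
    """

    SD_FLOOR_FACTOR = 1e-6

    def __init__(self) -> None:
        self.classes_: np.ndarray | None = None
        self.log_priors_: np.ndarray | None = None
        self.means_: np.ndarray | None = None
        self.sds_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GaussianNaiveBayes":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise InsufficientDataError("training data must contain two classes")
        if counts.min() < 2:
            raise InsufficientDataError(
                "every class needs at least 2 training rows"
            )
        global_sd = X.std(axis=0, ddof=0)
        floor = self.SD_FLOOR_FACTOR * np.where(global_sd > 0, global_sd, 1.0)
        self.classes_ = classes
        self.log_priors_ = np.log(counts / counts.sum())
        self.means_ = np.stack([X[y == c].mean(axis=0) for c in classes])
        sds = np.stack([X[y == c].std(axis=0, ddof=1) for c in classes])
        self.sds_ = np.maximum(sds, floor)
        return self

    def _joint_log_likelihood(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.empty((len(X), len(self.classes_)))
        for k in range(len(self.classes_)):
            mu, sd = self.means_[k], self.sds_[k]
            log_pdf = -0.5 * np.log(2 * np.pi * sd**2) - (X - mu) ** 2 / (2 * sd**2)
            out[:, k] = self.log_priors_[k] + log_pdf.sum(axis=1)
        return out

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Posterior over classes (columns ordered as ``classes_``)."""
        jll = self._joint_log_likelihood(X)
        jll -= jll.max(axis=1, keepdims=True)
        probs = np.exp(jll)
        return probs / probs.sum(axis=1, keepdims=True)

    def score(self, X: np.ndarray) -> np.ndarray:
        """Posterior probability of the largest class label (class 1)."""
        probs = self.predict_proba(X)
        positive_col = int(np.argmax(self.classes_))
        return probs[:, positive_col]


def _stratified_folds(
    y: np.ndarray, n_folds: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Index folds that preserve class balance; shuffled within class."""
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in np.unique(y):
        idx = np.flatnonzero(y == c)
        rng.shuffle(idx)
        for i, j in enumerate(idx):
            folds[i % n_folds].append(int(j))
    return [np.array(sorted(f), dtype=int) for f in folds]


def _balance_training_mask(
    y: np.ndarray, train_mask: np.ndarray, fold_index: int
) -> np.ndarray:
    """Equalize class counts in a training fold by rotating subjects out.

    Leave-one-out on a balanced cohort systematically under-represents
    the held-out subject's own class in every training fold (19 vs 20
    for 20-per-group cohorts).  That asymmetry — in the frequency priors
    and in the class-conditional estimates alike — anti-predicts the
    true class and biases cross-validated AUC pessimistically on
    uninformative features (stratification bias).  Trimming the larger
    class(es) down to the smallest training count restores symmetry;
    the trimmed indices rotate with the fold index so every subject
    participates in almost all folds and the procedure stays
    deterministic.
    """
    mask = train_mask.copy()
    counts = {c: int((y[mask] == c).sum()) for c in np.unique(y[mask])}
    target = min(counts.values())
    for c, cnt in counts.items():
        if cnt > target:
            members = np.flatnonzero(mask & (y == c))
            drop = [(fold_index + k) % cnt for k in range(cnt - target)]
            mask[members[drop]] = False
    return mask


def cross_validate(
    features: FeatureMatrix,
    classifier_factory: Callable[[], Classifier] = GaussianNaiveBayes,
    scheme: str = "loo",
    n_folds: int = 5,
    seed: Optional[int] = None,
    balance_training: bool = True,
) -> np.ndarray:
    """Score every subject with a model trained without it.

    ``scheme="loo"`` (default) leaves one subject out per fold;
    ``scheme="stratified"`` uses ``n_folds`` class-balanced folds drawn
    deterministically from ``seed``.  With ``balance_training`` (default)
    every training fold is trimmed to equal class counts, which removes
    the pessimistic stratification bias of leave-one-out scores (see
    :func:`_balance_training_mask`).  A training fold that loses an
    entire class is skipped with a warning and its subjects get NaN.
    """
    X, y = features.X, features.y
    if scheme == "loo":
        folds = [np.array([i]) for i in range(features.n)]
    elif scheme == "stratified":
        rng = np.random.default_rng(seed)
        folds = _stratified_folds(y, n_folds, rng)
    else:
        raise ValueError(f"unknown CV scheme: {scheme!r}")

    scores = np.full(features.n, np.nan)
    for fold_index, test_idx in enumerate(folds):
        train_mask = np.ones(features.n, dtype=bool)
        train_mask[test_idx] = False
        if len(np.unique(y[train_mask])) < 2:
            warnings.warn("training fold lost a class; fold skipped")
            continue
        if balance_training:
            train_mask = _balance_training_mask(y, train_mask, fold_index)
        model = classifier_factory()
        model.fit(X[train_mask], y[train_mask])
        scores[test_idx] = model.score(X[test_idx])
    return scores


def roc_points(
    scores: Sequence[float], labels: Sequence[int]
) -> list[tuple[float, float]]:
    """ROC curve as (false-positive rate, true-positive rate) points.

    Thresholds sweep the unique score values from high to low; tied
    scores collapse into a single threshold step.  The curve runs from
    (0, 0) to (1, 1) and is monotone nondecreasing in both coordinates.
    """
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s)
    s, lab = s[keep], lab[keep]
    n_pos = int((lab == 1).sum())
    n_neg = int((lab == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="stable")
    s, lab = s[order], lab[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:  # group tied scores
            tp += int(lab[j] == 1)
            fp += int(lab[j] == 0)
            j += 1
        points.append((fp / n_neg, tp / n_pos))
        i = j
    return points


def roc_auc(
    scores: Sequence[float], labels: Sequence[int]
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and the trapezoid-rule area under the curve."""
    points = roc_points(scores, labels)
    auc = 0.0
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        auc += (x1 - x0) * (y0 + y1) / 2.0
    return points, float(auc)


def sens_spec(
    scores: Sequence[float], labels: Sequence[int], threshold: float = 0.5
) -> tuple[float, float]:
    """Sensitivity TP/(TP+FN) and specificity TN/(TN+FP) at a threshold."""
    s = np.asarray(scores, dtype=float)
    lab = np.asarray(labels, dtype=int)
    keep = ~np.isnan(s)
    s, lab = s[keep], lab[keep]
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (lab == 1)).sum())
    fn = int(((pred == 0) & (lab == 1)).sum())
    tn = int(((pred == 0) & (lab == 0)).sum())
    fp = int(((pred == 1) & (lab == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    return tp / (tp + fn), tn / (tn + fp)


def cohen_kappa(predicted: Sequence[int], true: Sequence[int]) -> float:
    """Chance-corrected agreement kappa = (p_o - p_e) / (1 - p_e).

    Expected agreement p_e comes from the marginal label frequencies of
    the two raters.  When both raters are constant and identical
    (p_e = 1) kappa is defined as 1.
    """
    pred = np.asarray(predicted)
    tru = np.asarray(true)
    if len(pred) != len(tru):
        raise ValueError("label vectors must have equal length")
    n = len(pred)
    labels = np.union1d(pred, tru)
    p_o = float((pred == tru).mean())
    p_e = sum(
        float((pred == c).mean()) * float((tru == c).mean()) for c in labels
    )
    if np.isclose(p_e, 1.0):
        return 1.0 if p_o == 1.0 else 0.0
    return (p_o - p_e) / (1.0 - p_e)


@dataclass
class ClassifierReport:
    """Cross-validated evaluation of one binary group comparison."""

    comparison: str
    features: list[str]
    scores: list[float]
    labels: list[int]
    subject_ids: list[str]
    sensitivity: float
    specificity: float
    roc: list[tuple[float, float]]
    auc: float
    kappa: float
    scheme: str
    seed: Optional[int]
    threshold: float = 0.5
    meta: dict = field(default_factory=dict)

    def to_json(self, **dump_kwargs) -> str:
        payload = {
            "comparison": self.comparison,
            "features": self.features,
            "scheme": self.scheme,
            "seed": self.seed,
            "threshold": self.threshold,
            "subject_ids": self.subject_ids,
            "scores": self.scores,
            "labels": self.labels,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "roc_points": self.roc,
            "auc": self.auc,
            "kappa": self.kappa,
            **self.meta,
        }
        return json.dumps(payload, indent=2, **dump_kwargs)


def feature_matrix_from_table(
    table: pd.DataFrame,
    positive_group: str,
    negative_group: str,
    features: Sequence[str],
    group_col: str = "group",
) -> FeatureMatrix:
    """Select two groups and feature columns from a measure table.

    Rows with a missing value in any selected feature are dropped (with
    a warning) rather than imputed.
    """
    for f in features:
        if f not in table.columns:
            raise UnknownFeatureError(f"feature {f!r} not in measure table")
    sub = table[table[group_col].isin([positive_group, negative_group])].copy()
    if sub.empty or sub[group_col].nunique() < 2:
        raise ValueError(
            f"both groups {positive_group!r} and {negative_group!r} must be present"
        )
    mask = sub[list(features)].notna().all(axis=1)
    if not mask.all():
        warnings.warn(f"dropping {( ~mask).sum()} rows with missing feature values")
        sub = sub[mask]
    y = (sub[group_col] == positive_group).astype(int).to_numpy()
    ids = (
        sub["subject_id"].astype(str).tolist()
        if "subject_id" in sub.columns
        else [str(i) for i in sub.index]
    )
    return FeatureMatrix(
        X=sub[list(features)].to_numpy(dtype=float),
        y=y,
        feature_names=list(features),
        subject_ids=ids,
        positive_label=positive_group,
        negative_label=negative_group,
    )


def run_comparison(
    table: pd.DataFrame,
    comparison: str,
    features: Optional[Sequence[str]] = None,
    classifier_factory: Callable[[], Classifier] = GaussianNaiveBayes,
    scheme: str = "loo",
    n_folds: int = 5,
    seed: Optional[int] = None,
    threshold: float = 0.5,
    balance_training: bool = True,
) -> ClassifierReport:
    """Cross-validate one binary comparison end to end.

    ``comparison`` is one of SxM, SxC, MxC (first-named group is the
    positive class); ``features`` defaults to that comparison's standard
    word-normalized subset.
    """
    if comparison not in COMPARISON_GROUPS:
        raise ValueError(
            f"unknown comparison {comparison!r}; expected one of "
            f"{sorted(COMPARISON_GROUPS)}"
        )
    pos, neg = COMPARISON_GROUPS[comparison]
    feats = list(features) if features is not None else DEFAULT_FEATURES[comparison]
    fm = feature_matrix_from_table(table, pos, neg, feats)
    scores = cross_validate(
        fm, classifier_factory=classifier_factory, scheme=scheme,
        n_folds=n_folds, seed=seed, balance_training=balance_training,
    )
    points, auc = roc_auc(scores, fm.y)
    sens, spec = sens_spec(scores, fm.y, threshold=threshold)
    valid = ~np.isnan(scores)
    pred = (scores[valid] >= threshold).astype(int)
    kappa = cohen_kappa(pred, fm.y[valid])
    return ClassifierReport(
        comparison=comparison,
        features=feats,
        scores=[float(s) for s in scores],
        labels=[int(v) for v in fm.y],
        subject_ids=fm.subject_ids,
        sensitivity=sens,
        specificity=spec,
        roc=points,
        auc=auc,
        kappa=kappa,
        scheme=scheme,
        seed=seed,
        threshold=threshold,
        meta={"positive_label": fm.positive_label, "negative_label": fm.negative_label},
    )
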