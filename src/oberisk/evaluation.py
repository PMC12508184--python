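"""Confusion-matrix metrics and the leakage-safe 10-fold protocol.

Per-class one-vs-rest counts feed the four standard metrics

    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)          (recall)
    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    F-measure   = 2 * recall * precision / (recall + precision)

with 0/0 defined as 0.  Multi-class aggregation defaults to the unweighted
(macro) mean; micro and support-weighted variants are available.  The fold
report's headline accuracy is the overall fraction correct.

:func:`ten_fold_cv` re-runs the *entire* pipeline — preprocessing fit,
EC-QBA selection, ensemble training — inside each training fold, so no
imputation statistic, outlier fence, normalization bound, selected feature
or model weight ever sees the test fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import KFold, StratifiedKFold

from .ecqba import ECQBASelector
from .ensemble import MajorityVoteEnsemble, build_model_specs
from .preprocess import Preprocessor
from .schema import TableSchema


@dataclass
class ConfusionCounts:
    """Per-class one-vs-rest TP/TN/FP/FN plus the underlying matrix."""

    n_classes: int
    tp: np.ndarray
    tn: np.ndarray
    fp: np.ndarray
    fn: np.ndarray
    matrix: np.ndarray
    support: np.ndarray


def confusion_counts(y_true, y_pred, n_classes: int) -> ConfusionCounts:
    """One-vs-rest counts per class from the full confusion matrix."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty label vectors")
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors differ in length")
    for arr, what in ((y_true, "true"), (y_pred, "predicted")):
        if arr.min() < 0 or arr.max() >= n_classes:
            raise ValueError(f"{what} label out of range [0, {n_classes})")
    m = confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))
    tp = np.diag(m).astype(int)
    fp = m.sum(axis=0) - tp
    fn = m.sum(axis=1) - tp
    tn = m.sum() - tp - fp - fn
    return ConfusionCounts(
        n_classes=n_classes, tp=tp, tn=tn, fp=fp, fn=fn,
        matrix=m, support=m.sum(axis=1),
    )


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 defined as 0", stacklevel=3)
        return 0.0
    return num / den


def class_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Precision, sensitivity, accuracy, F-measure for one class's counts."""
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    precision = _safe_div(tp, tp + fp, "precision")
    sensitivity = _safe_div(tp, tp + fn, "sensitivity")
    accuracy = _safe_div(tp + tn, tp + tn + fp + fn, "accuracy")
    f_measure = _safe_div(2 * sensitivity * precision, sensitivity + precision, "F-measure")
    return {
        "precision": precision,
        "sensitivity": sensitivity,
        "accuracy": accuracy,
        "f_measure": f_measure,
    }


def macro_metrics(counts: ConfusionCounts, average: str = "macro") -> dict[str, float]:
    """Aggregate the per-class metrics (macro default; micro/weighted via flag)."""
    if counts.n_classes < 2:
        raise ValueError("need >= 2 classes")
    per_class = [
        class_metrics(counts.tp[c], counts.tn[c], counts.fp[c], counts.fn[c])
        for c in range(counts.n_classes)
    ]
    keys = per_class[0].keys()
    if average == "macro":
        return {k: float(np.mean([pc[k] for pc in per_class])) for k in keys}
    if average == "weighted":
        wts = counts.support / counts.support.sum()
        return {k: float(np.sum(wts * [pc[k] for pc in per_class])) for k in keys}
    if average == "micro":
        tp, tn = counts.tp.sum(), counts.tn.sum()
        fp, fn = counts.fp.sum(), counts.fn.sum()
        return class_metrics(tp, tn, fp, fn)
    raise ValueError(f"unknown average {average!r}")


@dataclass
class FoldReport:
    """Percent metrics for one test fold, plus pipeline provenance."""

    fold: int
    accuracy: float
    precision: float
    sensitivity: float
    f_measure: float
    selected_features: list[str] = field(default_factory=list)
    extras: dict = field(default_factory=dict)


@dataclass
class CVReport:
    folds: list[FoldReport]
    mean: dict[str, float]
    sd: dict[str, float]
    fold_assignment: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "folds": [
                {
                    "fold": f.fold,
                    "accuracy": f.accuracy,
                    "precision": f.precision,
                    "sensitivity": f.sensitivity,
                    "f_measure": f.f_measure,
                    "selected_features": f.selected_features,
                }
                for f in self.folds
            ],
            "mean": self.mean,
            "sd": self.sd,
        }


def fold_metrics(y_true, y_pred, n_classes: int, average: str = "macro") -> dict[str, float]:
    """Percent metrics for one fold: overall accuracy + averaged P/R/F."""
    counts = confusion_counts(y_true, y_pred, n_classes)
    agg = macro_metrics(counts, average=average)
    return {
        "accuracy": 100.0 * float(np.mean(np.asarray(y_true) == np.asarray(y_pred))),
        "precision": 100.0 * agg["precision"],
        "sensitivity": 100.0 * agg["sensitivity"],
        "f_measure": 100.0 * agg["f_measure"],
    }


def ten_fold_cv(
    df: pd.DataFrame,
    schema: TableSchema,
    seed: int = 0,
    n_splits: int = 10,
    preprocessor_params: dict | None = None,
    selector_params: dict | None = None,
    ensemble_params: dict | None = None,
    model_overrides: dict | None = None,
    stratified: bool = True,
    average: str = "macro",
) -> CVReport:
    """Stratified 10-fold cross-validation of the full pipeline.

    The preprocessor, EC-QBA selector and ensemble are re-fitted from scratch
    inside every training fold.  Falls back to unstratified folds (with a
    warning) when any class has fewer members than ``n_splits``.
    """
    df = df.reset_index(drop=True)
    y_all = df[schema.label_column].to_numpy()
    if stratified and np.min(np.bincount(y_all.astype(int))) < n_splits:
        warnings.warn("a class has fewer members than folds: using unstratified folds",
                      stacklevel=2)
        stratified = False
    if stratified:
        splitter = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(df, y_all)
    else:
        splitter = KFold(n_splits=n_splits, shuffle=True, random_state=seed)
        splits = splitter.split(df)

    n_classes = int(np.max(y_all)) + 1
    assignment = np.full(len(df), -1, dtype=int)
    folds: list[FoldReport] = []
    feature_names = schema.feature_names
    for fold_idx, (tr, te) in enumerate(splits, start=1):
        assignment[te] = fold_idx
        train_df = df.iloc[tr]
        test_df = df.iloc[te]

        prep = Preprocessor(schema=schema, **(preprocessor_params or {}))
        train_clean = prep.fit_transform(train_df)
        test_clean = prep.transform(test_df)

        X_tr = train_clean[feature_names].to_numpy(dtype=float)
        y_tr = train_clean[schema.label_column].to_numpy(dtype=int)
        X_te = test_clean[feature_names].to_numpy(dtype=float)
        y_te = test_clean[schema.label_column].to_numpy(dtype=int)

        selector = ECQBASelector(random_state=seed, **(selector_params or {}))
        selector.fit(X_tr, y_tr)
        sel_names = [feature_names[j] for j in selector.get_support(indices=True)]

        ens = MajorityVoteEnsemble(
            specs=build_model_specs(model_overrides),
            random_state=seed,
            **(ensemble_params or {}),
        )
        ens.fit(selector.transform(X_tr), y_tr)
        y_pred = ens.predict(selector.transform(X_te))

        m = fold_metrics(y_te, y_pred, n_classes, average=average)
        folds.append(
            FoldReport(
                fold=fold_idx,
                selected_features=sel_names,
                extras={
                    "outlier_bounds": prep.bounds_,
                    "preprocess_report": prep.report_,
                    "best_fitness": selector.best_fitness_,
                },
                **m,
            )
        )

    keys = ("accuracy", "precision", "sensitivity", "f_measure")
    mean = {k: float(np.mean([getattr(f, k) for f in folds])) for k in keys}
    sd = {k: float(np.std([getattr(f, k) for f in folds], ddof=1)) for k in keys}
    return CVReport(folds=folds, mean=mean, sd=sd, fold_assignment=assignment)
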