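"""Confusion-matrix metrics, label binarization and baseline harness.

Metrics follow the standard confusion-count definitions (specificity,
recall, precision, FDR = 1 - precision, accuracy, F1).  A metric whose
denominator is zero is reported as NaN rather than 0, so averaging over
repeats does not silently deflate; the averaging helpers skip NaN and
log when they do.

The baseline harness fits the three classic interpretable models with
fixed hyperparameters on log-scaled abundances:

==================  =================================================
Linear SVM          C=1, class_weight="balanced", kernel="linear"
Logistic regression C=0.1, class_weight="balanced", penalty="l1"
Random forest       class_weight="balanced", max_depth=5, n_estimators=100
==================  =================================================
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .imeta import (ImetaConfig, forward_batch, train_end_to_end, train_imeta)
from .otu_io import SampleMetadata

__all__ = ["ConfusionCounts", "MetricSet", "compute_metrics",
           "confusion_from_predictions", "binarize_labels", "run_baselines",
           "run_experiment"]

logger = logging.getLogger(__name__)

UNDEFINED = float("nan")


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class MetricSet:
    specificity: float
    recall: float
    precision: float
    fdr: float
    accuracy: float
    f1: float

    def as_dict(self) -> dict[str, float]:
        return vars(self).copy()


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else UNDEFINED


def compute_metrics(c: ConfusionCounts) -> MetricSet:
    """Standard confusion-count metrics; zero denominators give NaN."""
    if c.total == 0:
        raise ValueError("cannot compute metrics on all-zero counts")
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    f1 = (
        UNDEFINED
        if np.isnan(precision) or np.isnan(recall) or precision + recall == 0
        else 2 * precision * recall / (precision + recall)
    )
    return MetricSet(
        specificity=_ratio(c.tn, c.tn + c.fp),
        recall=recall,
        precision=precision,
        fdr=_ratio(c.fp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        f1=f1,
    )


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        tp=int(((y_true == 1) & (y_pred == 1)).sum()),
        fp=int(((y_true == 0) & (y_pred == 1)).sum()),
        tn=int(((y_true == 0) & (y_pred == 0)).sum()),
        fn=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def binarize_labels(
    metadata: SampleMetadata,
    attribute: str,
    positive_set: set[str],
    exclude_set: set[str] = frozenset({"NA"}),
) -> tuple[np.ndarray, list[str]]:
    """0/1 labels for one attribute; excluded sub-attributes are dropped.

    Returns ``(labels, retained_sample_ids)``.
    """
    if attribute not in metadata.attributes:
        raise KeyError(f"attribute {attribute!r} not in metadata")
    labels, kept = [], []
    for s, v in zip(metadata.sample_ids, metadata.values(attribute)):
        if v in exclude_set:
            continue
        labels.append(1 if v in positive_set else 0)
        kept.append(s)
    y = np.asarray(labels, dtype=int)
    if y.size and y.min() == 1:
        raise ValueError("no negative samples after binarization")
    if y.size == 0 or y.max() == 0:
        raise ValueError("no positive samples after binarization")
    return y, kept


_BASELINES = {
    "linear_svm": lambda seed: SVC(
        C=1, class_weight="balanced", kernel="linear", random_state=seed
    ),
    # l1_ratio=1 is the l1 penalty in current scikit-learn
    "logistic_regression": lambda seed: LogisticRegression(
        C=0.1, class_weight="balanced", l1_ratio=1.0, solver="liblinear",
        random_state=seed,
    ),
    "random_forest": lambda seed: RandomForestClassifier(
        class_weight="balanced", max_depth=5, n_estimators=100, random_state=seed
    ),
}


def _repeat_splits(y: np.ndarray, n_repeats: int, test_size: float, seed: int):
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, test_size=test_size, random_state=seed
    )
    return splitter.split(np.zeros_like(y), y)


def _mean_rows(df: pd.DataFrame) -> pd.DataFrame:
    metric_cols = [c for c in df.columns if c not in ("model", "repeat")]
    means = []
    for model, grp in df.groupby("model", sort=False):
        row = {"model": model, "repeat": "mean"}
        for c in metric_cols:
            vals = grp[c].astype(float)
            if vals.isna().any():
                logger.info("averaging %s for %s skips %d undefined repeat(s)",
                            c, model, int(vals.isna().sum()))
            row[c] = float(vals.mean(skipna=True))
        means.append(row)
    return pd.concat([df, pd.DataFrame(means)], ignore_index=True)


def run_baselines(
    X: np.ndarray,
    y: np.ndarray,
    n_repeats: int = 5,
    test_size: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit the three classic baselines on log-scaled abundances.

    Uses the same repeated stratified 80/20 protocol as the IMETA
    harness; returns one row per model per repeat plus a mean row per
    model.
    """
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes required")
    rows = []
    for rep, (tr, te) in enumerate(_repeat_splits(y, n_repeats, test_size, seed)):
        for name, make in _BASELINES.items():
            clf = make(seed + rep)
            clf.fit(X[tr], y[tr])
            c = confusion_from_predictions(y[te], clf.predict(X[te]))
            rows.append({"model": name, "repeat": rep, **compute_metrics(c).as_dict()})
    return _mean_rows(pd.DataFrame(rows))


def run_experiment(
    X: np.ndarray,
    S: np.ndarray | None,
    y: np.ndarray,
    E: np.ndarray,
    config: ImetaConfig,
    n_repeats: int = 5,
    test_size: float = 0.2,
    include_end_to_end: bool = True,
) -> pd.DataFrame:
    """Full comparison: IMETA, its end-to-end twin, and the three baselines."""
    X, y = np.asarray(X, dtype=float), np.asarray(y, dtype=int)
    rows = []
    for rep, (tr, te) in enumerate(
        _repeat_splits(y, n_repeats, test_size, config.seed)
    ):
        Str = S[tr] if S is not None else None
        Ste = S[te] if S is not None else None
        cfg = ImetaConfig(**{**vars(config), "seed": config.seed + rep})
        model = train_imeta(X[tr], Str, y[tr], E, cfg)
        pred = (forward_batch(model, X[te], Ste) >= 0.5).astype(int)
        c = confusion_from_predictions(y[te], pred)
        rows.append({"model": "imeta", "repeat": rep, **compute_metrics(c).as_dict()})
        if include_end_to_end:
            e2e = train_end_to_end(X[tr], Str, y[tr], cfg)
            pred = (forward_batch(e2e, X[te], Ste) >= 0.5).astype(int)
            c = confusion_from_predictions(y[te], pred)
            rows.append({"model": "end_to_end", "repeat": rep,
                         **compute_metrics(c).as_dict()})
    df = _mean_rows(pd.DataFrame(rows))
    base = run_baselines(X, y, n_repeats, test_size, config.seed)
    return pd.concat([df, base], ignore_index=True)
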