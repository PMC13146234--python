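"""Exploratory random-forest stay classifier and its evaluation metrics.

A small forest (10 trees, depth 5) over three per-stay features — dwell
time, mean RSSI, and RSSI variability (sample SD) — separates smoker from
nonsmoker stays.  Evaluation is on a stratified hold-out split with
stratified cross-validation on the training part; metric arithmetic
(confusion-matrix rates, weighted averages, rank-statistic AUC) is computed
here rather than delegated, so the same conventions apply whether scores
come from the forest or from a reconstructed confusion matrix.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_score, train_test_split

from .config import RandomForestSpec

FEATURES = ["dwell_min", "mean_rssi", "sd_rssi"]
POSITIVE = "smoker"
NEGATIVE = "nonsmoker"


@dataclass
class EvaluationReport:
    """Confusion matrix and derived metrics on the held-out test split.

    Class-conditional metrics that are undefined (empty class) are ``None``,
    never silently zero.
    """

    tn: int
    fp: int
    fn: int
    tp: int
    accuracy: float
    sensitivity: Optional[float]
    specificity: Optional[float]
    per_class: Dict[str, Dict[str, Optional[float]]]
    weighted: Dict[str, Optional[float]]
    auc: Optional[float] = None
    cv_accuracy: Optional[float] = None
    test_sizes: Dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "confusion": {"tn": self.tn, "fp": self.fp, "fn": self.fn, "tp": self.tp},
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "per_class": self.per_class,
            "weighted": self.weighted,
            "auc": self.auc,
            "cv_accuracy": self.cv_accuracy,
            "test_sizes": self.test_sizes,
        }


def auc_rank(y_true: Sequence[int], scores: Sequence[float]) -> Optional[float]:
    """AUC by the rank-sum (Mann-Whitney) statistic; ties count one half.

    Equals the probability that a random positive outscores a random
    negative.  ``None`` when either class is empty.
    """
    y = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _safe_div(num: float, den: float) -> Optional[float]:
    return num / den if den > 0 else None


def compute_metrics(
    confusion: Tuple[int, int, int, int],
    scores: Optional[Sequence[float]] = None,
    y_true: Optional[Sequence[int]] = None,
) -> EvaluationReport:
    """Derive the full evaluation report from a (TN, FP, FN, TP) matrix.

    The positive class is the smoker class.  When per-stay ``scores`` and
    ``y_true`` are supplied, AUC is added via the rank statistic.
    """
    tn, fp, fn, tp = (int(c) for c in confusion)
    if min(tn, fp, fn, tp) < 0:
        raise ValueError("confusion-matrix cells must be nonnegative")
    n = tn + fp + fn + tp
    if n == 0:
        raise ValueError("empty confusion matrix")

    sens = _safe_div(tp, tp + fn)  # smoker recall
    spec = _safe_div(tn, tn + fp)  # nonsmoker recall
    pos_prec = _safe_div(tp, tp + fp)
    neg_prec = _safe_div(tn, tn + fn)

    def f1(p: Optional[float], r: Optional[float]) -> Optional[float]:
        if p is None or r is None or (p + r) == 0:
            return None
        return 2 * p * r / (p + r)

    n_pos, n_neg = tp + fn, tn + fp
    per_class = {
        POSITIVE: {"precision": pos_prec, "recall": sens, "f1": f1(pos_prec, sens), "support": n_pos},
        NEGATIVE: {"precision": neg_prec, "recall": spec, "f1": f1(neg_prec, spec), "support": n_neg},
    }

    weighted: Dict[str, Optional[float]] = {}
    for metric in ("precision", "recall", "f1"):
        vals = [(per_class[POSITIVE][metric], n_pos), (per_class[NEGATIVE][metric], n_neg)]
        if any(v is None for v, w in vals if w > 0):
            weighted[metric] = None
        else:
            weighted[metric] = sum(v * w for v, w in vals if w > 0) / n

    auc = None
    if scores is not None and y_true is not None:
        auc = auc_rank(y_true, scores)

    return EvaluationReport(
        tn=tn,
        fp=fp,
        fn=fn,
        tp=tp,
        accuracy=(tn + tp) / n,
        sensitivity=sens,
        specificity=spec,
        per_class=per_class,
        weighted=weighted,
        auc=auc,
        test_sizes={POSITIVE: n_pos, NEGATIVE: n_neg},
    )


def train_and_evaluate(
    features: pd.DataFrame,
    labels: Sequence[str],
    spec: RandomForestSpec = RandomForestSpec(),
) -> EvaluationReport:
    """Fit the forest on a stratified training split and score the hold-out.

    ``features`` must carry the dwell/mean-RSSI/RSSI-SD columns; ``labels``
    are smoker/nonsmoker per stay.  Deterministic given ``spec.seed``.
    Raises on single-class input, where evaluation is undefined.
    """
    X = features[FEATURES].to_numpy(dtype=float)
    y = np.asarray([1 if l == POSITIVE else 0 for l in labels], dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("evaluation undefined: labels contain a single class")

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=spec.test_fraction, stratify=y, random_state=spec.seed
    )
    model = RandomForestClassifier(
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        min_samples_split=spec.min_samples_split,
        random_state=spec.seed,
    )

    cv_accuracy = None
    n_min = int(np.bincount(y_tr).min())
    folds = min(spec.cv_folds, n_min)
    if folds >= 2:
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        cv_accuracy = float(np.mean(cross_val_score(model, X_tr, y_tr, cv=cv)))

    model.fit(X_tr, y_tr)
    y_hat = model.predict(X_te)
    scores = model.predict_proba(X_te)[:, list(model.classes_).index(1)]

    tn = int(((y_te == 0) & (y_hat == 0)).sum())
    fp = int(((y_te == 0) & (y_hat == 1)).sum())
    fn = int(((y_te == 1) & (y_hat == 0)).sum())
    tp = int(((y_te == 1) & (y_hat == 1)).sum())
    report = compute_metrics((tn, fp, fn, tp), scores=scores, y_true=y_te)
    report.cv_accuracy = cv_accuracy
    return report
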