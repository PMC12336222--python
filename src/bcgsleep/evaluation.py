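"""Confusion matrices, staging metrics, 8:2 split and five-fold CV.

Class order is fixed to (N1, N2, N3, REM, W).  Per-class precision,
recall and F1 come from the one-vs-rest TP/FP/FN counts of the matrix;
overall metrics are the accuracy (trace/total), unweighted macro averages
and the multi-class Cohen kappa (p0 - pe)/(1 - pe) with
pe = sum_k row_k col_k / total^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_ORDER = ("N1", "N2", "N3", "REM", "W")

#: Published worked-example confusion matrices from a full-night BCG sleep
#: staging study (10,201 scored epochs; rows = true stage, cols = predicted,
#: order N1, N2, N3, REM, W).  Three feature-set stages of the same system:
#: 30-s HRV/RRV features only; plus long-window features; plus attention+
#: tree feature selection.  Used as arithmetic oracles for the metrics
#: engine and as realistic fixtures.
REFERENCE_MATRICES: dict[str, np.ndarray] = {
    "base": np.array(
        [
            [11, 249, 35, 95, 52],
            [39, 3361, 459, 424, 131],
            [9, 909, 972, 138, 52],
            [29, 788, 149, 1046, 171],
            [12, 256, 69, 229, 516],
        ]
    ),
    "longwin": np.array(
        [
            [50, 287, 18, 50, 37],
            [87, 3983, 157, 118, 69],
            [11, 279, 1735, 32, 23],
            [26, 127, 11, 1987, 32],
            [43, 146, 22, 55, 816],
        ]
    ),
    "selected": np.array(
        [
            [116, 252, 3, 34, 37],
            [63, 4143, 111, 61, 36],
            [1, 165, 1901, 6, 7],
            [9, 53, 0, 2115, 6],
            [46, 102, 13, 30, 891],
        ]
    ),
}


@dataclass
class ConfusionMatrix:
    counts: np.ndarray
    classes: tuple[str, ...] = CLASS_ORDER

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise ValueError("matrix shape must match the class list")
        if (self.counts < 0).any():
            raise ValueError("counts must be >= 0")

    @classmethod
    def from_predictions(cls, y_true, y_pred, classes=CLASS_ORDER) -> "ConfusionMatrix":
        from sklearn.metrics import confusion_matrix

        counts = confusion_matrix(y_true, y_pred, labels=list(classes))
        return cls(counts=counts, classes=tuple(classes))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.classes, columns=self.classes).to_csv(path)


def per_class_metrics(cm: ConfusionMatrix, c: str) -> dict[str, float]:
    """One-vs-rest precision / recall / F1 for class ``c`` (fractions)."""
    i = cm.classes.index(c)
    tp = cm.counts[i, i]
    fn = cm.counts[i].sum() - tp
    fp = cm.counts[:, i].sum() - tp
    precision = tp / (tp + fp) if tp + fp > 0 else np.nan
    recall = tp / (tp + fn) if tp + fn > 0 else np.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn > 0 else np.nan
    return {"precision": float(precision), "recall": float(recall), "f1": float(f1)}


def overall_metrics(cm: ConfusionMatrix) -> dict[str, float]:
    """Accuracy, macro precision/recall/F1 and multi-class Cohen kappa."""
    n = cm.total
    if n == 0:
        raise ValueError("empty confusion matrix")
    acc = float(np.trace(cm.counts) / n)
    per = [per_class_metrics(cm, c) for c in cm.classes]
    macro = {
        f"macro_{k}": float(np.nanmean([p[k] for p in per]))
        for k in ("precision", "recall", "f1")
    }
    p0 = acc
    pe = float(np.sum(cm.counts.sum(axis=1) * cm.counts.sum(axis=0)) / n**2)
    kappa = (p0 - pe) / (1 - pe) if pe < 1 else np.nan
    return {"accuracy": acc, **macro, "kappa": float(kappa)}


def binary_kappa(tp: int, fn: int, fp: int, tn: int) -> float:
    """Two-class chance-corrected agreement from the four counts."""
    cm = ConfusionMatrix(np.array([[tp, fn], [fp, tn]]), classes=("pos", "neg"))
    return overall_metrics(cm)["kappa"]


def split_8_2(table: pd.DataFrame, seed: int = 0):
    """Stratified 80/20 row split."""
    from sklearn.model_selection import train_test_split

    tr, te = train_test_split(
        table, test_size=0.2, random_state=seed, stratify=table["stage"]
    )
    return tr.reset_index(drop=True), te.reset_index(drop=True)


@dataclass
class CVResult:
    fold_metrics: list[dict] = field(default_factory=list)
    mean_metrics: dict = field(default_factory=dict)
    pooled: ConfusionMatrix | None = None


def cross_validate(
    table: pd.DataFrame,
    fit_predict,
    folds: int = 5,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV of a ``fit_predict(train_table, test_table)`` callable.

    All fitting — feature selection, SMOTE, classifier training — must
    happen inside ``fit_predict`` on the training table only.  Reports the
    across-fold mean of the overall metrics and the pooled matrix.
    """
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = table["stage"].to_numpy()
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    res = CVResult()
    pooled = np.zeros((len(CLASS_ORDER), len(CLASS_ORDER)), dtype=int)
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        tr = table.iloc[tr_idx].reset_index(drop=True)
        te = table.iloc[te_idx].reset_index(drop=True)
        if len(np.unique(tr["stage"])) < len(np.unique(y)):
            raise ValueError("a class is absent from a training fold")
        y_pred = np.asarray(fit_predict(tr, te))
        cm = ConfusionMatrix.from_predictions(te["stage"], y_pred)
        pooled += cm.counts
        res.fold_metrics.append(overall_metrics(cm))
    res.pooled = ConfusionMatrix(pooled)
    keys = res.fold_metrics[0]
    res.mean_metrics = {
        k: float(np.mean([m[k] for m in res.fold_metrics])) for k in keys
    }
    return res


def round_half_up_pct(x: float, decimals: int = 2) -> float:
    """Display rounding used for percentage tables (half away from zero)."""
    import decimal

    q = decimal.Decimal(10) ** -decimals
    return float(
        decimal.Decimal(repr(100 * x)).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )
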