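"""Regression and classification scores for signal prediction.

Regression: RMSE, NRMSE (RMSE normalized by the observed range of the true
signal), the coefficient of determination R² = 1 − SS_res/SS_tot, and the
normalized cross-correlation sequence between two signals.

Classification: accuracy = (tp+tn)/(tp+tn+fp+fn), precision = tp/(tp+fp),
recall = tp/(tp+fn), F1 = 2·precision·recall/(precision+recall), from
binary confusion counts or a multiclass confusion matrix (per-class
one-vs-rest plus macro and support-weighted averages).  Metrics with a zero
denominator are reported as 0 and flagged degenerate.

Report assembly mirrors the usual per-run score table: one row per
evaluated signal/action with layers, RMSE, NRMSE, R² and wall-clock times,
closed by an arithmetic-mean averages row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


def _pair(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    y_hat = np.asarray(y_hat, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("need at least one sample")
    if y.size != y_hat.size:
        raise ValueError(f"length mismatch: {y.size} vs {y_hat.size}")
    return y, y_hat


def rmse(y, y_hat) -> float:
    """Root mean squared error."""
    y, y_hat = _pair(y, y_hat)
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def nrmse(y, y_hat) -> float:
    """RMSE normalized by the observed range max(y) − min(y) of the true signal."""
    y, y_hat = _pair(y, y_hat)
    span = float(np.max(y) - np.min(y))
    if span == 0.0:
        raise ValueError("NRMSE undefined for a constant true signal (zero range)")
    return rmse(y, y_hat) / span


def r_squared(y, y_hat) -> float:
    """Coefficient of determination, 1 − SS_res/SS_tot."""
    y, y_hat = _pair(y, y_hat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined for a constant true signal")
    ss_res = float(np.sum((y - y_hat) ** 2))
    return 1.0 - ss_res / ss_tot


def cross_correlation(y, y_hat, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized (Pearson) cross-correlation at lags −max_lag..max_lag.

    The value at lag k is the Pearson correlation between the overlapping
    segments y[t] and ŷ[t − k]; a signal against itself gives 1 at lag 0,
    and a shifted copy peaks at the shift lag.  Returns (lags, values).
    """
    y, y_hat = _pair(y, y_hat)
    if max_lag < 0 or max_lag >= y.size:
        raise ValueError("max_lag must be in [0, len(y) - 1]")
    lags = np.arange(-max_lag, max_lag + 1)
    values = np.empty(lags.size)
    for i, k in enumerate(lags):
        if k >= 0:
            a, b = y[k:], y_hat[: y.size - k]
        else:
            a, b = y[: y.size + k], y_hat[-k:]
        a = a - a.mean()
        b = b - b.mean()
        denom = float(np.sqrt(np.sum(a**2) * np.sum(b**2)))
        values[i] = float(np.sum(a * b) / denom) if denom > 0 else 0.0
    return lags, values


@dataclass
class ConfusionCounts:
    """Binary confusion counts, or a square multiclass count matrix."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0
    matrix: np.ndarray | None = None
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.matrix is not None:
            self.matrix = np.asarray(self.matrix, dtype=int)
            if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
                raise ValueError("confusion matrix must be square")
            if np.any(self.matrix < 0):
                raise ValueError("counts must be non-negative")
            if not self.labels:
                self.labels = [str(i) for i in range(self.matrix.shape[0])]
            if len(self.labels) != self.matrix.shape[0]:
                raise ValueError("labels must match matrix size")
        elif min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        if self.matrix is not None:
            return int(self.matrix.sum())
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_labels(cls, y_true, y_pred, labels=None) -> "ConfusionCounts":
        """Build a multiclass confusion matrix (rows = true, cols = predicted)."""
        y_true = list(y_true)
        y_pred = list(y_pred)
        if len(y_true) != len(y_pred):
            raise ValueError("label sequences differ in length")
        if labels is None:
            labels = sorted(set(y_true) | set(y_pred))
        index = {lab: i for i, lab in enumerate(labels)}
        matrix = np.zeros((len(labels), len(labels)), dtype=int)
        for t, p in zip(y_true, y_pred):
            matrix[index[t], index[p]] += 1
        return cls(matrix=matrix, labels=[str(lab) for lab in labels])


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def classification_metrics(counts: ConfusionCounts) -> dict:
    """Accuracy/precision/recall/F1 from confusion counts.

    Binary counts give the four scalar scores; a multiclass matrix gives
    per-class one-vs-rest rows plus ``macro avg`` and support-``weighted``
    averages and the overall accuracy (trace / total).  Zero-denominator
    scores are 0 with ``degenerate`` listing which ones.
    """
    if counts.total == 0:
        raise ValueError("need at least one scored item")
    if counts.matrix is None:
        degenerate = []
        accuracy, _ = _safe_div(counts.tp + counts.tn, counts.total)
        precision, d1 = _safe_div(counts.tp, counts.tp + counts.fp)
        recall, d2 = _safe_div(counts.tp, counts.tp + counts.fn)
        f1, d3 = _safe_div(2 * precision * recall, precision + recall)
        for flag, name in ((d1, "precision"), (d2, "recall"), (d3, "f1")):
            if flag:
                degenerate.append(name)
        return {
            "accuracy": accuracy,
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "degenerate": degenerate,
        }

    m = counts.matrix
    per_class = {}
    supports = m.sum(axis=1)
    degenerate: dict[str, list[str]] = {}
    for i, label in enumerate(counts.labels):
        tp = int(m[i, i])
        fp = int(m[:, i].sum() - tp)
        fn = int(m[i, :].sum() - tp)
        precision, d1 = _safe_div(tp, tp + fp)
        recall, d2 = _safe_div(tp, tp + fn)
        f1, d3 = _safe_div(2 * precision * recall, precision + recall)
        flags = [n for f, n in ((d1, "precision"), (d2, "recall"), (d3, "f1")) if f]
        if flags:
            degenerate[label] = flags
        per_class[label] = {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": int(supports[i]),
        }
    total = counts.total
    accuracy = float(np.trace(m)) / total
    macro = {
        k: float(np.mean([per_class[lab][k] for lab in counts.labels]))
        for k in ("precision", "recall", "f1")
    }
    weighted = {
        k: float(
            sum(per_class[lab][k] * per_class[lab]["support"] for lab in counts.labels)
            / total
        )
        for k in ("precision", "recall", "f1")
    }
    return {
        "accuracy": accuracy,
        "per_class": per_class,
        "macro avg": macro,
        "weighted": weighted,
        "degenerate": degenerate,
    }


REPORT_COLUMNS = (
    "label",
    "layers",
    "rmse",
    "nrmse",
    "r_squared",
    "train_time_s",
    "test_time_s",
)
_NUMERIC = REPORT_COLUMNS[1:]


@dataclass
class PredictionReport:
    """Per-run score rows plus an arithmetic-mean averages row."""

    rows: list[dict]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("report needs at least one row")
        for row in self.rows:
            missing = set(REPORT_COLUMNS) - set(row)
            if missing:
                raise ValueError(f"report row missing fields: {sorted(missing)}")

    @property
    def averages(self) -> dict:
        avg = {"label": "Averages"}
        for col in _NUMERIC:
            avg[col] = float(np.mean([row[col] for row in self.rows]))
        return avg

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{c: r[c] for c in REPORT_COLUMNS} for r in self.rows + [self.averages]]
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self, path=None):
        payload = {"rows": self.rows, "averages": self.averages}
        if path is None:
            return json.dumps(payload, indent=1)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)
        return None


def build_report(per_run_scores: list[dict]) -> PredictionReport:
    """Assemble per-run score dicts into a :class:`PredictionReport`.

    Each dict needs label, layers, rmse, nrmse, r_squared, train_time_s,
    test_time_s (extra keys are ignored).
    """
    rows = []
    for run in per_run_scores:
        missing = set(REPORT_COLUMNS) - set(run)
        if missing:
            raise ValueError(f"report row missing fields: {sorted(missing)}")
        rows.append({c: run[c] for c in REPORT_COLUMNS})
    return PredictionReport(rows)
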