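"""Evaluation indexes for variable selection against a known truth set.

Four indexes summarize a selection result over p candidate features of
which t0 are true signals: the true positive rate TP/(TP+FN), the
Matthews correlation coefficient, a rank-based selection AUC over all
true-by-noise feature pairs (half credit for ties), and the estimated
false discovery rate FP/(FP+TP).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "MetricsReport",
    "confusion",
    "tpr",
    "fdr_hat",
    "mcc",
    "selection_auc",
    "score_selection",
]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    tpr: float
    mcc: float
    auc: float
    fdr_hat: float
    t0: int
    p: int


def confusion(
    selected, truth, p: int
) -> tuple[int, int, int, int]:
    """2x2 counts (tp, fp, fn, tn) over all p features."""
    selected = set(int(i) for i in selected)
    truth = set(int(i) for i in truth)
    if any(i >= p or i < 0 for i in selected | truth):
        raise ValueError("feature index out of range")
    tp_ = len(selected & truth)
    fp_ = len(selected - truth)
    fn_ = len(truth - selected)
    tn_ = p - tp_ - fp_ - fn_
    return tp_, fp_, fn_, tn_


def tpr(tp: int, fn: int) -> float:
    """Sensitivity TP/(TP+FN); undefined (error) when there are no truths."""
    if tp < 0 or fn < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("TPR undefined with no true signals")
    return tp / (tp + fn)


def fdr_hat(tp: int, fp: int) -> float:
    """Estimated FDR FP/(FP+TP); 0 by convention when nothing is selected."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        return 0.0
    return fp / (fp + tp)


def mcc(tp: int, fp: int, fn: int, tn: int) -> float:
    """Matthews correlation coefficient; 0 when a denominator factor is 0."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / np.sqrt(float(denom))


def _as_truth_indices(truth, p: int) -> np.ndarray:
    truth = np.asarray(truth)
    if truth.dtype == bool:
        if len(truth) != p:
            raise ValueError("boolean truth mask must have length p")
        return np.flatnonzero(truth)
    return truth.astype(int)


def selection_auc(scores, truth) -> float:
    """Rank AUC of the selection scores over true-vs-noise feature pairs.

    scores are per-feature selection probabilities (stability methods) or
    |coefficients| (plain penalized fits); truth is an index set or
    boolean mask of the t0 true signals.  Equals
    (1 / (t0 (p - t0))) * sum over true u, noise v of
    [score_u > score_v] + 0.5 [score_u = score_v], computed in
    O(p log p) via midranks.
    """
    scores = np.asarray(scores, dtype=float)
    p = len(scores)
    truth_idx = _as_truth_indices(truth, p)
    t0 = len(truth_idx)
    if t0 == 0 or t0 == p:
        raise ValueError("need 1 <= t0 < p true signals")
    is_true = np.zeros(p, dtype=bool)
    is_true[truth_idx] = True
    ranks = rankdata(scores)  # midranks give ties half credit
    rank_sum = ranks[is_true].sum()
    return float((rank_sum - t0 * (t0 + 1) / 2) / (t0 * (p - t0)))


def score_selection(selected, scores, truth, p: int) -> MetricsReport:
    """All four indexes for one selection result."""
    tp_, fp_, fn_, tn_ = confusion(selected, truth, p)
    truth_idx = _as_truth_indices(truth, p)
    return MetricsReport(
        tp=tp_,
        fp=fp_,
        fn=fn_,
        tn=tn_,
        tpr=tpr(tp_, fn_),
        mcc=mcc(tp_, fp_, fn_, tn_),
        auc=selection_auc(scores, truth_idx),
        fdr_hat=fdr_hat(tp_, fp_),
        t0=len(truth_idx),
        p=p,
    )


def write_metrics_table(table: pd.DataFrame, path) -> None:
    """Write the tidy (method, scenario, metric, mean, se, replicates) table."""
    table.to_csv(path, sep="\t", index=False)
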