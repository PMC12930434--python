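"""Benchmark metrics: confusion counts, FDR, power, MCC, AUROC, type-I error.

Conventions: an empty discovery set scores FDR 0; MCC is 0 when any
confusion-table marginal is zero; AUROC is the rank-based (Mann-Whitney)
probability that a signal region outranks a null one, ties counting 1/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError

__all__ = ["ConfusionCounts", "confusion", "fdr_power", "mcc", "auroc",
           "type1_error"]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


def confusion(calls, truth) -> ConfusionCounts:
    """2x2 counts of boolean calls vs boolean truth (NaNs dropped pairwise)."""
    c = np.asarray(calls, dtype=float)
    t = np.asarray(truth, dtype=float)
    if c.shape != t.shape:
        raise ValidationError("calls and truth must have equal length")
    ok = np.isfinite(c) & np.isfinite(t)
    c, t = c[ok] > 0.5, t[ok] > 0.5
    return ConfusionCounts(
        TP=int(np.sum(c & t)), FP=int(np.sum(c & ~t)),
        TN=int(np.sum(~c & ~t)), FN=int(np.sum(~c & t)),
    )


def fdr_power(cc: ConfusionCounts):
    """Empirical FDR = FP/max(1, TP+FP) and power = TP/max(1, TP+FN)."""
    fdr = cc.FP / max(1, cc.TP + cc.FP)
    power = cc.TP / max(1, cc.TP + cc.FN)
    return float(fdr), float(power)


def mcc(cc: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is zero."""
    tp, fp, tn, fn = cc.TP, cc.FP, cc.TN, cc.FN
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def auroc(scores, truth) -> float:
    """Rank-based AUROC; scores oriented so larger = more signal-like."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truth, dtype=float)
    if s.shape != t.shape:
        raise ValidationError("scores and truth must have equal length")
    ok = np.isfinite(s) & np.isfinite(t)
    s, t = s[ok], t[ok] > 0.5
    if t.all() or not t.any():
        return float("nan")
    return float(roc_auc_score(t.astype(int), s))


def type1_error(pvec, alpha: float = 0.05) -> float:
    """Fraction of non-NaN raw p-values below alpha (all-null analysis)."""
    p = np.asarray(pvec, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    return float(np.mean(p < alpha))
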