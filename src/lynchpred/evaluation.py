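"""Discrimination and classification metrics for carrier risk scores.

AUC is the Mann-Whitney concordance probability (ties count 1/2): the
probability that a randomly chosen carrier outscores a randomly chosen
non-carrier. Confidence intervals use the DeLong variance estimator, which
is deterministic and the standard choice for risk-score AUCs; paired AUC
differences reuse the same structural components.

Classification at a probability cut-off uses the rule score >= cutoff ->
test-positive, and reports exact integer confusion counts with percentages
rounded half-up to whole percent, the convention of clinical risk-model
tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.metrics import roc_curve

from .cohort import GENES
from .errors import ValidationError

__all__ = [
    "RocResult",
    "CutoffPerformance",
    "AucDifference",
    "auc",
    "per_gene_auc",
    "performance_at_cutoff",
    "binary_rule_performance",
    "compare_aucs",
]


# --- DeLong machinery -----------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    """Midranks of x (ties share the average rank), 1-based."""
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1.0
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(scores: np.ndarray, n_pos: int):
    """AUCs and DeLong covariance for k score vectors over shared subjects.

    ``scores`` is (k, n) with the first ``n_pos`` columns the positives.
    Returns (aucs shape (k,), covariance shape (k, k)).
    """
    k, n = scores.shape
    m = n - n_pos
    if n_pos == 0 or m == 0:
        raise ValidationError("both classes must be present")
    tx = np.empty((k, n_pos))
    ty = np.empty((k, m))
    tz = np.empty((k, n))
    for r in range(k):
        tx[r] = _midranks(scores[r, :n_pos])
        ty[r] = _midranks(scores[r, n_pos:])
        tz[r] = _midranks(scores[r])
    aucs = (tz[:, :n_pos].sum(axis=1) / (n_pos * m)
            - (n_pos + 1.0) / (2.0 * m))
    v01 = (tz[:, :n_pos] - tx) / m
    v10 = 1.0 - (tz[:, n_pos:] - ty) / n_pos
    sx = np.cov(v01, ddof=1) if n_pos > 1 else np.zeros((k, k))
    sy = np.cov(v10, ddof=1) if m > 1 else np.zeros((k, k))
    cov = np.atleast_2d(sx) / n_pos + np.atleast_2d(sy) / m
    return aucs, cov


@dataclass
class RocResult:
    """AUC with a 95% DeLong CI and the ROC point set."""

    auc: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    points: np.ndarray          # (m, 2) columns (fpr, tpr), (0,0) .. (1,1)
    se: float = float("nan")
    _scores: Optional[np.ndarray] = None
    _labels: Optional[np.ndarray] = None


@dataclass(frozen=True)
class CutoffPerformance:
    """Confusion counts and whole-percent sensitivity/specificity."""

    cutoff: float
    sensitivity: int            # % rounded half-up
    specificity: int            # % rounded half-up
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity_exact(self) -> float:
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity_exact(self) -> float:
        return 100.0 * self.tn / (self.tn + self.fp)


@dataclass(frozen=True)
class AucDifference:
    delta: float
    ci_low: float
    ci_high: float
    se: float
    z: float
    p: float


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype == bool:
        labels = labels.astype(int)
    if not np.isin(labels, (0, 1)).all():
        raise ValidationError("labels must be binary 0/1")
    return labels.astype(int)


def auc(scores: Sequence[float], labels: Sequence[int],
        alpha: float = 0.05) -> RocResult:
    """Mann-Whitney AUC with a DeLong (1 - alpha) confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    order = np.argsort(~labels.astype(bool), kind="mergesort")  # positives first
    a, cov = _delong(scores[order][None, :], n_pos)
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    zq = norm.ppf(1 - alpha / 2)
    fpr, tpr, _ = roc_curve(labels, scores)
    return RocResult(
        auc=float(a[0]),
        ci_low=float(np.clip(a[0] - zq * se, 0.0, 1.0)),
        ci_high=float(np.clip(a[0] + zq * se, 0.0, 1.0)),
        n_pos=n_pos, n_neg=n_neg,
        points=np.column_stack([fpr, tpr]),
        se=se, _scores=scores, _labels=labels,
    )


def per_gene_auc(scored: pd.DataFrame, gene: str,
                 score_choice: str = "overall",
                 score_col: Optional[str] = None) -> RocResult:
    """AUC contrasting carriers of one gene against non-mutation carriers.

    Positives are carriers of ``gene``; negatives are patients with
    mutation_status "none"; carriers of other genes are excluded. The score
    is the overall carrier probability (default) or the gene-specific one.
    """
    if gene not in GENES:
        raise ValidationError(f"gene must be one of {GENES}")
    if score_col is None:
        score_col = "p_overall" if score_choice == "overall" else f"p_{gene.lower()}"
    mask = scored["mutation_status"].isin([gene, "none"])
    sub = scored.loc[mask]
    labels = (sub["mutation_status"] == gene).to_numpy().astype(int)
    if labels.sum() == 0:
        raise ValidationError(f"no {gene} carriers in the scored cohort")
    return auc(sub[score_col].to_numpy(dtype=float), labels)


def _round_half_up_pct(x: float) -> int:
    return int(np.floor(x + 0.5))


def performance_at_cutoff(scores: Sequence[float], labels: Sequence[int],
                          cutoff: float) -> CutoffPerformance:
    """Sensitivity/specificity of the rule score >= cutoff -> positive."""
    if not (0.0 < cutoff < 1.0):
        raise ValidationError("cutoff must lie in (0, 1)")
    scores = np.asarray(scores, dtype=float)
    labels = _check_binary(labels)
    if scores.shape != labels.shape:
        raise ValidationError("scores and labels must have equal length")
    flagged = scores >= cutoff
    tp = int(np.sum(flagged & (labels == 1)))
    fp = int(np.sum(flagged & (labels == 0)))
    fn = int(np.sum(~flagged & (labels == 1)))
    tn = int(np.sum(~flagged & (labels == 0)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both classes must be present")
    return CutoffPerformance(
        cutoff=cutoff,
        sensitivity=_round_half_up_pct(100.0 * tp / (tp + fn)),
        specificity=_round_half_up_pct(100.0 * tn / (tn + fp)),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def binary_rule_performance(flags: Sequence[int],
                            labels: Sequence[int]) -> CutoffPerformance:
    """Performance of a binary rule (e.g. Bethesda fulfilment) vs labels."""
    flags = np.asarray(flags)
    labels = np.asarray(labels)
    if flags.shape != labels.shape:
        raise ValidationError("flags and labels must have equal length")
    flags = _check_binary(flags)
    labels = _check_binary(labels)
    tp = int(np.sum((flags == 1) & (labels == 1)))
    fp = int(np.sum((flags == 1) & (labels == 0)))
    fn = int(np.sum((flags == 0) & (labels == 1)))
    tn = int(np.sum((flags == 0) & (labels == 0)))
    if tp + fn == 0 or tn + fp == 0:
        raise ValidationError("both classes must be present")
    return CutoffPerformance(
        cutoff=0.5,
        sensitivity=_round_half_up_pct(100.0 * tp / (tp + fn)),
        specificity=_round_half_up_pct(100.0 * tn / (tn + fp)),
        tp=tp, fp=fp, tn=tn, fn=fn,
    )


def compare_aucs(roc_a: RocResult, roc_b: RocResult, paired: bool = True,
                 alpha: float = 0.05) -> AucDifference:
    """AUC(a) - AUC(b) with a DeLong-based confidence interval.

    Paired comparison requires the two results to come from the same
    subjects in the same order (identical labels); the DeLong covariance
    then accounts for the correlation of the two scores.
    """
    delta = roc_a.auc - roc_b.auc
    if paired:
        if roc_a._scores is None or roc_b._scores is None:
            raise ValidationError("paired comparison needs stored scores")
        la, lb = roc_a._labels, roc_b._labels
        if la.shape != lb.shape or not np.array_equal(la, lb):
            raise ValidationError(
                "paired comparison requires identical subjects and labels")
        order = np.argsort(~la.astype(bool), kind="mergesort")
        stacked = np.vstack([roc_a._scores[order], roc_b._scores[order]])
        aucs, cov = _delong(stacked, int(la.sum()))
        delta = float(aucs[0] - aucs[1])
        var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    else:
        var = roc_a.se ** 2 + roc_b.se ** 2
    se = float(np.sqrt(max(var, 0.0)))
    zq = norm.ppf(1 - alpha / 2)
    z = delta / se if se > 0 else (0.0 if delta == 0 else np.inf * np.sign(delta))
    p = float(2 * norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return AucDifference(delta=delta, ci_low=delta - zq * se,
                         ci_high=delta + zq * se, se=se, z=float(z), p=p)
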