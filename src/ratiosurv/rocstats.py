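"""Uncertainty and comparison statistics for ROC survival predictors.

AUC significance against the 0.5 null uses the Mann-Whitney normal
approximation with tie correction; confidence intervals come from a
stratified (per-class) bootstrap percentile; and two paired predictors are
compared for improvement with a stratified paired bootstrap of the ΔAUC
standard error and a normal-approximation one-sided p.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.stats import rankdata

from .containers import ValidationError
from .ratio import auc

log = logging.getLogger(__name__)


@dataclass
class RocTestResult:
    auc: float
    p: float
    ci_low: float
    ci_high: float
    method: str
    B: int
    seed: int
    unstable_ci: bool = False


@dataclass
class RocComparison:
    auc_1: float
    auc_2: float
    delta: float
    p: float
    B: int
    seed: int
    degenerate: bool = False


def _stratified_indices(pos: np.ndarray, neg: np.ndarray, B: int,
                        rng: np.random.Generator) -> np.ndarray:
    """B stratified resamples of sample indices, stacked as (n, B)."""
    ip = rng.choice(pos, size=(pos.size, B), replace=True)
    ineg = rng.choice(neg, size=(neg.size, B), replace=True)
    return np.vstack([ip, ineg])


def _auc_columns(scores_cols: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Survival-oriented AUC for every column of a (n, B) score matrix."""
    n_neg = int((labels == 0).sum())
    n_pos = int((labels == 1).sum())
    r = rankdata(scores_cols, axis=0)
    u = r[labels == 0].sum(axis=0) - n_neg * (n_neg + 1) / 2.0
    return u / (n_pos * n_neg)


def _mann_whitney_p(scores: np.ndarray, labels: np.ndarray) -> float:
    """Two-sided normal-approximation p for AUC != 0.5, tie-corrected."""
    n1 = int((labels == 0).sum())  # survivors: the concordant-high class
    n0 = int((labels == 1).sum())
    n = n1 + n0
    a = auc(scores, labels)
    u = a * n1 * n0
    mu = n1 * n0 / 2.0
    _, tie_counts = np.unique(scores, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (n * (n - 1)) if n > 1 else 0.0
    var = n1 * n0 / 12.0 * (n + 1 - tie_term)
    if var <= 0:
        return 1.0
    z = (u - mu) / np.sqrt(var)
    return float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def auc_significance(scores, labels, B: int = 2000, seed: int = 0) -> RocTestResult:
    """AUC with Mann-Whitney p vs 0.5 and stratified bootstrap percentile CI."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0
    scores, labels = scores[keep], labels[keep]
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    if pos.size == 0 or neg.size == 0:
        raise ValidationError("both outcome classes must be non-empty")
    point = auc(scores, labels)
    p = _mann_whitney_p(scores, labels)
    rng = np.random.default_rng(seed)
    idx = _stratified_indices(pos, neg, B, rng)
    blab = np.concatenate([np.ones(pos.size, dtype=int),
                           np.zeros(neg.size, dtype=int)])
    boots = _auc_columns(scores[idx], blab)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    unstable = min(pos.size, neg.size) < 5
    if unstable:
        log.warning("bootstrap CI flagged unstable: class of size < 5")
    return RocTestResult(point, p, float(min(lo, point)), float(max(hi, point)),
                         "mann-whitney + stratified bootstrap", B, seed, unstable)


def compare_auc_bootstrap(scores_1, scores_2, labels, B: int = 2000,
                          seed: int = 0, two_sided: bool = False) -> RocComparison:
    """One-sided bootstrap test that predictor 1 improves on predictor 2.

    Both predictors are scored on the same samples/labels.  A stratified
    paired bootstrap estimates sd(ΔAUC); z = (AUC1 - AUC2)/sd and
    p = 1 - Φ(z) (doubled if ``two_sided``).  Identical predictors return
    p = 1 with a degeneracy flag.
    """
    s1 = np.asarray(scores_1, dtype=float)
    s2 = np.asarray(scores_2, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if s1.shape != s2.shape or s1.shape != labels.shape:
        raise ValidationError("paired predictors must share samples and labels")
    keep = labels >= 0
    s1, s2, labels = s1[keep], s2[keep], labels[keep]
    a1, a2 = auc(s1, labels), auc(s2, labels)
    pos = np.flatnonzero(labels == 1)
    neg = np.flatnonzero(labels == 0)
    rng = np.random.default_rng(seed)
    idx = _stratified_indices(pos, neg, B, rng)
    blab = np.concatenate([np.ones(pos.size, dtype=int),
                           np.zeros(neg.size, dtype=int)])
    deltas = _auc_columns(s1[idx], blab) - _auc_columns(s2[idx], blab)
    sd = deltas.std(ddof=1)
    if sd == 0:
        log.warning("degenerate bootstrap sd (identical predictors?); p = 1")
        return RocComparison(a1, a2, a1 - a2, 1.0, B, seed, degenerate=True)
    z = (a1 - a2) / sd
    p = float(stats.norm.sf(z))
    if two_sided:
        p = float(min(1.0, 2 * stats.norm.sf(abs(z))))
    return RocComparison(a1, a2, a1 - a2, p, B, seed)
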