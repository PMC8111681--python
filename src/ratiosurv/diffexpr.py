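"""Pairwise differential expression between subtypes with FDR control.

TNBC is compared with each receptor-positive subtype by an unpaired
two-tailed Welch t-test on log2 abundances, with Benjamini-Hochberg FDR
across all genes per comparison.  Genes are counted as differentially
expressed at FDR < 0.05 and |log2 fold change| > 0.58 (a 50% change), and a
separate consistency filter keeps genes significant (raw p < 1e-4) with the
same direction of change in all three pairwise comparisons.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import ConfigError, ExpressionMatrix, ValidationError, log2_matrix
from .network import ModuleAssignment


class DEGCriteria:
    """Thresholds for DEG counting and the three-way consistency filter.

    ``fdr_max`` and ``abs_log2fc_min`` govern counting (FDR < 0.05,
    |log2FC| > 0.58 by default); ``consistency_p_max`` is the raw-p cut
    (1e-4) used by the three-comparison consistency filter — two distinct
    thresholds by design.
    """

    def __init__(self, fdr_max: float = 0.05, abs_log2fc_min: float = 0.58,
                 consistency_p_max: float = 1e-4):
        if min(fdr_max, abs_log2fc_min, consistency_p_max) <= 0:
            raise ConfigError("all DEG thresholds must be > 0")
        self.fdr_max = fdr_max
        self.abs_log2fc_min = abs_log2fc_min
        self.consistency_p_max = consistency_p_max


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg q-values (step-up), returned in input order."""
    p = np.asarray(p, dtype=float)
    if p.size and ((p < 0).any() or (p > 1).any() or ~np.isfinite(p).all()):
        raise ValidationError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def ttest_groups(x: ExpressionMatrix, group_a, group_b, comparison: str = "",
                 log_offset: float = 1.0, equal_var: bool = False) -> pd.DataFrame:
    """Per-gene Welch t-test of group A vs group B on log2 scale.

    Returns a frame indexed by gene with columns ``log2diff`` (mean A - mean
    B), ``t``, ``p`` (two-tailed), ``q`` (BH across all genes) and
    ``comparison``.  Genes with zero variance in both groups get p = 1 and a
    ``degenerate`` flag.
    """
    group_a, group_b = list(group_a), list(group_b)
    if set(group_a) & set(group_b):
        raise ValidationError("groups overlap")
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValidationError("both groups need >= 2 samples")
    logx = log2_matrix(x, log_offset)
    a = logx[group_a].to_numpy(dtype=float)
    b = logx[group_b].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    degenerate = (a.std(axis=1) == 0) & (b.std(axis=1) == 0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.nan_to_num(p, nan=1.0)
    res = pd.DataFrame({
        "log2diff": a.mean(axis=1) - b.mean(axis=1),
        "t": t,
        "p": p,
        "q": bh_fdr(p),
        "degenerate": degenerate,
    }, index=x.gene_ids)
    res["comparison"] = comparison
    return res


def count_degs(res: pd.DataFrame, crit: DEGCriteria | None = None) -> tuple[int, int]:
    """(n_up, n_down) at strict q < fdr_max and |log2diff| > abs_log2fc_min."""
    crit = crit or DEGCriteria()
    sig = res["q"] < crit.fdr_max
    n_up = int((sig & (res["log2diff"] > crit.abs_log2fc_min)).sum())
    n_down = int((sig & (res["log2diff"] < -crit.abs_log2fc_min)).sum())
    return n_up, n_down


def consistency_filter(res_list, crit: DEGCriteria | None = None) -> list[str]:
    """Genes significant (raw p) with identical direction in all 3 comparisons."""
    crit = crit or DEGCriteria()
    if len(res_list) != 3:
        raise ValidationError("consistency filter requires exactly 3 comparisons")
    genes = res_list[0].index
    for r in res_list[1:]:
        if not r.index.equals(genes):
            raise ValidationError("comparisons cover different gene universes")
    sig = np.ones(len(genes), dtype=bool)
    signs = []
    for r in res_list:
        sig &= (r["p"] < crit.consistency_p_max).to_numpy()
        signs.append(np.sign(r["log2diff"].to_numpy()))
    same_dir = (signs[0] == signs[1]) & (signs[1] == signs[2]) & (signs[0] != 0)
    return list(genes[sig & same_dir])


def rank_module_degs(res: pd.DataFrame, assign: ModuleAssignment, modules,
                     direction: str, top_n: int = 20) -> pd.DataFrame:
    """Top DEGs within the given modules and direction.

    Rank by ascending FDR, ties broken by descending |log2diff| then gene
    id.  ``direction`` is "up" (log2diff > 0) or "down".
    """
    modules = set(modules)
    labels = assign.labels.reindex(res.index)
    sub = res[labels.isin(modules)].copy()
    if direction == "up":
        sub = sub[sub["log2diff"] > 0]
    elif direction == "down":
        sub = sub[sub["log2diff"] < 0]
    else:
        raise ConfigError("direction must be 'up' or 'down'")
    sub["_abs"] = sub["log2diff"].abs()
    sub["_gene"] = sub.index
    sub = sub.sort_values(["q", "_abs", "_gene"],
                          ascending=[True, False, True])
    sub["module"] = labels.reindex(sub.index)
    return sub.drop(columns=["_abs", "_gene"]).head(top_n)
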