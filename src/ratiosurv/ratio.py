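"""Combinatorial gene-ratio screening scored by multi-horizon survival AUC.

The screen's unit is a numerator/denominator gene-set pair: within each
sample, the equal-weight combination (sum, after gene-wise unit-median
scaling) of numerator-side abundances is divided by the combination of
denominator-side abundances.  Numerator genes come from modules whose
expression tracks good prognosis, denominator genes from the anticorrelated
modules, so a larger ratio predicts better survival.  Every k:k subset pair
(k in {1,2,3} by default, plus the full panels) is enumerated and ranked by
the area under the survival ROC at a set of fixed time horizons.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import (ConfigError, ExpressionMatrix, SurvivalData,
                         ValidationError, unit_median_scale)

log = logging.getLogger(__name__)

# default screening horizons (days): 15 mo, 18 mo, 3 y, 5 y, 7.5 y
TNBC_HORIZONS = (456.25, 547.5, 1095.0, 1825.0, 2737.5)
# all-subtype variant replaces 7.5 y with 10 y
BRCA_HORIZONS = (456.25, 547.5, 1095.0, 1825.0, 3650.0)


@dataclass(frozen=True)
class RatioSpec:
    """An ordered numerator/denominator gene-set pair."""

    numerator: tuple
    denominator: tuple

    def __post_init__(self) -> None:
        if not self.numerator or not self.denominator:
            raise ValidationError("numerator and denominator must be non-empty")
        if set(self.numerator) & set(self.denominator):
            raise ValidationError("numerator and denominator overlap")

    def label(self) -> str:
        return "+".join(self.numerator) + "/" + "+".join(self.denominator)


@dataclass
class ScreenConfig:
    """Enumeration sizes, horizons, combination rule and ranking criterion."""

    sizes: tuple = (1, 2, 3)
    include_full: bool = True
    horizons: tuple = TNBC_HORIZONS
    combine: str = "sum"  # sum | mean | geometric-mean
    ranking: str = "max-AUC"  # max-AUC | mean-AUC
    top_n: int = 100

    def __post_init__(self) -> None:
        if any(k < 1 or k > 5 for k in self.sizes):
            raise ConfigError("sizes must be within 1..5")
        hs = list(self.horizons)
        if any(h <= 0 for h in hs) or hs != sorted(hs):
            raise ConfigError("horizons must be positive and ascending")
        if self.combine not in ("sum", "mean", "geometric-mean"):
            raise ConfigError(f"unknown combine rule {self.combine!r}")
        if self.ranking not in ("max-AUC", "mean-AUC"):
            raise ConfigError(f"unknown ranking {self.ranking!r}")


def enumerate_ratios(num_pool, den_pool, cfg: ScreenConfig | None = None
                     ) -> list[RatioSpec]:
    """All k:k numerator/denominator subset pairs in deterministic order.

    Subsets are taken in the pools' own (lexicographic-by-position) order;
    when ``include_full`` is set and the full pools do not duplicate an
    enumerated pair, the full ratio is appended last.
    """
    cfg = cfg or ScreenConfig()
    num_pool, den_pool = list(num_pool), list(den_pool)
    if set(num_pool) & set(den_pool):
        raise ValidationError("numerator and denominator pools overlap")
    specs = [
        RatioSpec(n, d)
        for k in sorted(cfg.sizes)
        for n in itertools.combinations(num_pool, k)
        for d in itertools.combinations(den_pool, k)
    ]
    if cfg.include_full:
        full = RatioSpec(tuple(num_pool), tuple(den_pool))
        if full not in specs:
            specs.append(full)
    return specs


def _combine(scaled: pd.DataFrame, genes, rule: str) -> np.ndarray:
    block = scaled.loc[list(genes)].to_numpy(dtype=float)
    if rule == "sum":
        return block.sum(axis=0)
    if rule == "mean":
        return block.mean(axis=0)
    # geometric mean; zeros floored at the smallest positive value
    pos = block[block > 0]
    floor = pos.min() / 2.0 if pos.size else 1.0
    return np.exp(np.log(np.clip(block, floor, None)).mean(axis=0))


def ratio_score(x: ExpressionMatrix, spec: RatioSpec, combine: str = "sum",
                scale: bool = True) -> pd.Series:
    """Per-sample equal-weight ratio score (higher = predicted better survival).

    Genes are unit-median scaled across the cohort (so no single
    high-abundance gene dominates), combined per side by ``combine``, and
    divided.  Samples with a zero denominator are scored against a floor of
    half the smallest positive denominator value in the cohort (flagged).
    """
    missing = [g for g in (*spec.numerator, *spec.denominator)
               if g not in x.values.index]
    if missing:
        raise ValidationError(f"genes absent from matrix: {missing}")
    genes = list(dict.fromkeys((*spec.numerator, *spec.denominator)))
    vals = x.values.loc[genes]
    scaled = unit_median_scale(vals) if scale else vals
    num = _combine(scaled, spec.numerator, combine)
    den = _combine(scaled, spec.denominator, combine)
    zero = den <= 0
    if zero.any():
        pos = den[den > 0]
        eps = pos.min() / 2.0 if pos.size else np.finfo(float).tiny
        log.warning("zero denominator for %d samples; floored at %.3g",
                    int(zero.sum()), eps)
        den = np.where(zero, eps, den)
    return pd.Series(num / den, index=x.sample_ids)


def horizon_labels(records: SurvivalData, t: float) -> pd.Series:
    """Fixed-horizon outcome labels: 1 = event by t, 0 = event-free through t.

    Samples censored before t are excluded (label -1): their status at the
    horizon is unknown.  Samples still under observation at t are negative
    regardless of later events.
    """
    if t <= 0:
        raise ValidationError("horizon must be positive")
    time = records.time.to_numpy(dtype=float)
    event = records.event.to_numpy(dtype=int)
    lab = np.full(time.shape, -1, dtype=int)
    lab[time >= t] = 0
    lab[(event == 1) & (time <= t)] = 1  # events-by-t win at time == t
    return pd.Series(lab, index=records.sample_ids)


def auc(scores, labels) -> float:
    """Survival-oriented ROC AUC by the Mann-Whitney rank formula.

    AUC = P(score_negative > score_positive) + 0.5 P(tie): concordance of a
    higher ratio with being event-free at the horizon.  Equals the
    trapezoidal area under the ROC of the survival-oriented score.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = labels == 1
    neg = labels == 0
    if not pos.any() or not neg.any():
        raise ValidationError("AUC needs at least one positive and one negative")
    r = rankdata(scores[pos | neg])
    lab = labels[pos | neg]
    n_pos, n_neg = int(pos.sum()), int(neg.sum())
    u = r[lab == 0].sum() - n_neg * (n_neg + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _auc_matrix(score_mat: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized survival-oriented AUC for each column of ``score_mat``."""
    keep = labels >= 0
    s = score_mat[keep]
    lab = labels[keep]
    n_neg = int((lab == 0).sum())
    n_pos = int((lab == 1).sum())
    r = rankdata(s, axis=0)
    u = r[lab == 0].sum(axis=0) - n_neg * (n_neg + 1) / 2.0
    return u / (n_pos * n_neg)


# ---------------------------------------------------------------------------
# pool assembly
# ---------------------------------------------------------------------------

def assemble_pools(numerator_sources: dict, denominator_sources: dict
                   ) -> tuple[list[str], list[str]]:
    """Union tagged candidate sources into the two screening pools.

    Each argument maps a source name (e.g. a ranked-DEG table, carryover
    list or interaction nomination) to a gene list.  Genes are deduplicated
    preserving first-seen order; per-source counts are logged; a gene tagged
    to both sides is an error.
    """
    def union(sources: dict) -> list[str]:
        seen: dict = {}
        for name, genes in sources.items():
            fresh = [g for g in genes if g not in seen]
            for g in fresh:
                seen[g] = name
            log.info("pool source %s: %d genes (%d new)", name, len(list(genes)),
                     len(fresh))
        return list(seen)

    num = union(numerator_sources)
    den = union(denominator_sources)
    both = set(num) & set(den)
    if both:
        raise ValidationError(f"genes tagged to both sides: {sorted(both)}")
    return num, den


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class RatioScreen:
    """Exhaustive ratio screen over candidate pools against survival data.

    ``fit()`` enumerates every configured k:k combination, scores every
    sample, computes the ROC AUC at each usable horizon and returns a
    ranked :class:`ScreenResult`.
    """

    def __init__(self, expr: ExpressionMatrix, records: SurvivalData,
                 num_pool, den_pool, config: ScreenConfig | None = None):
        self.expr = expr
        self.records = records.subset([s for s in expr.sample_ids
                                       if s in records.sample_ids])
        self.num_pool = list(num_pool)
        self.den_pool = list(den_pool)
        self.config = config or ScreenConfig()

    def _score_matrix(self, specs: list[RatioSpec]) -> np.ndarray:
        """Samples × specs score matrix via indicator-matrix products."""
        genes = list(dict.fromkeys(self.num_pool + self.den_pool))
        scaled = unit_median_scale(self.expr.values.loc[genes])
        sub = scaled.loc[:, self.records.sample_ids].to_numpy(dtype=float)
        gidx = {g: i for i, g in enumerate(genes)}
        rule = self.config.combine
        if rule == "geometric-mean":
            pos = sub[sub > 0]
            floor = pos.min() / 2.0 if pos.size else 1.0
            base = np.log(np.clip(sub, floor, None))
        else:
            base = sub
        n_ind = np.zeros((len(specs), len(genes)))
        d_ind = np.zeros((len(specs), len(genes)))
        for i, sp in enumerate(specs):
            wn = 1.0 / len(sp.numerator) if rule != "sum" else 1.0
            wd = 1.0 / len(sp.denominator) if rule != "sum" else 1.0
            for g in sp.numerator:
                n_ind[i, gidx[g]] = wn
            for g in sp.denominator:
                d_ind[i, gidx[g]] = wd
        num = n_ind @ base
        den = d_ind @ base
        if rule == "geometric-mean":
            num, den = np.exp(num), np.exp(den)
        zero = den <= 0
        if zero.any():
            pos = den[den > 0]
            eps = pos.min() / 2.0 if pos.size else np.finfo(float).tiny
            log.warning("floored %d zero denominators at %.3g",
                        int(zero.sum()), eps)
            den = np.where(zero, eps, den)
        return (num / den).T  # samples × specs

    #: specs scored per block; bounds peak memory for very large enumerations
    chunk_size: int = 100_000

    def fit(self) -> "ScreenResult":
        specs = enumerate_ratios(self.num_pool, self.den_pool, self.config)
        usable = []
        labels = {}
        for h in self.config.horizons:
            lab = horizon_labels(self.records, h).to_numpy()
            if (lab == 1).sum() == 0 or (lab == 0).sum() == 0:
                log.warning("horizon %.0f has an empty outcome class; skipped", h)
                continue
            usable.append(h)
            labels[h] = lab
        if not usable:
            raise ValidationError("no usable horizon (empty outcome classes)")
        aucs = {h: np.empty(len(specs)) for h in usable}
        for start in range(0, len(specs), self.chunk_size):
            block = specs[start:start + self.chunk_size]
            scores = self._score_matrix(block)
            for h in usable:
                aucs[h][start:start + len(block)] = _auc_matrix(scores,
                                                                labels[h])
        table = pd.DataFrame({f"auc@{h:g}": aucs[h] for h in usable})
        table.insert(0, "denominator", ["+".join(s.denominator) for s in specs])
        table.insert(0, "numerator", ["+".join(s.numerator) for s in specs])
        auc_cols = [f"auc@{h:g}" for h in usable]
        table["mean_auc"] = table[auc_cols].mean(axis=1)
        table["max_auc"] = table[auc_cols].max(axis=1)
        table["argmax_horizon"] = [usable[i] for i in
                                   table[auc_cols].to_numpy().argmax(axis=1)]
        key = (["max_auc", "mean_auc"] if self.config.ranking == "max-AUC"
               else ["mean_auc", "max_auc"])
        order = table.sort_values(key, ascending=False, kind="mergesort").index
        table["rank"] = pd.Series(np.arange(1, len(table) + 1), index=order)
        return ScreenResult(self, specs, table, usable)


class ScreenResult:
    """Ranked screen table plus gene-frequency and validation helpers."""

    def __init__(self, model: RatioScreen, specs: list[RatioSpec],
                 table: pd.DataFrame, horizons: list[float]):
        self.model = model
        self.specs = specs
        self.table = table
        self.horizons = horizons

    def top(self, n: int | None = None) -> pd.DataFrame:
        n = n or self.model.config.top_n
        return self.table.sort_values("rank").head(n)

    def rank_of(self, spec: RatioSpec) -> int:
        for i, s in enumerate(self.specs):
            if s == spec:
                return int(self.table["rank"].iloc[i])
        raise KeyError(f"spec not enumerated: {spec.label()}")

    def gene_frequency(self, n: int | None = None) -> pd.Series:
        """How often each gene appears among the top-n ranked combinations."""
        top_idx = self.top(n).index
        counts: dict = {}
        for i in top_idx:
            sp = self.specs[i]
            for g in (*sp.numerator, *sp.denominator):
                counts[g] = counts.get(g, 0) + 1
        return pd.Series(counts).sort_values(ascending=False)

    def summary(self) -> str:
        best = self.top(1).iloc[0]
        lines = [
            "Ratio screen summary",
            f"  combinations: {len(self.specs)}  horizons used: "
            + ", ".join(f"{h:g}" for h in self.horizons),
            f"  ranking: {self.model.config.ranking}",
            f"  top ratio: {best['numerator']}/{best['denominator']}",
            f"    max AUC {best['max_auc']:.3f} at t={best['argmax_horizon']:g}, "
            f"mean AUC {best['mean_auc']:.3f}",
        ]
        return "\n".join(lines)

    def plot_roc(self, spec: RatioSpec, horizon: float, ax=None):
        """ROC curve of one ratio at one horizon."""
        import matplotlib.pyplot as plt
        from sklearn.metrics import roc_curve

        ax = ax or plt.gca()
        s = ratio_score(self.model.expr, spec, self.model.config.combine)
        lab = horizon_labels(self.model.records, horizon)
        keep = lab >= 0
        # survival-oriented: event-free (label 0) is the "positive" signal
        fpr, tpr, _ = roc_curve(1 - lab[keep], s[self.model.records.sample_ids][keep])
        ax.plot(fpr, tpr, label=f"{spec.label()} @ {horizon:g}")
        ax.plot([0, 1], [0, 1], ls=":", c="grey")
        ax.set_xlabel("false positive rate")
        ax.set_ylabel("true positive rate")
        ax.legend(fontsize=7)
        return ax


def cross_platform_validate(spec: RatioSpec, x2: ExpressionMatrix,
                            records2: SurvivalData,
                            cfg: ScreenConfig | None = None) -> pd.Series:
    """Score a fixed ratio spec on a second cohort (no re-selection).

    The caller applies the same normalization used at discovery; this
    reports the per-horizon AUCs for the spec as-is.
    """
    cfg = cfg or ScreenConfig()
    missing = [g for g in (*spec.numerator, *spec.denominator)
               if g not in x2.values.index]
    if missing:
        raise ValidationError(f"genes missing from validation cohort: {missing}")
    shared = [s for s in x2.sample_ids if s in records2.sample_ids]
    rec = records2.subset(shared)
    s = ratio_score(x2, spec, cfg.combine).loc[shared]
    out = {}
    for h in cfg.horizons:
        lab = horizon_labels(rec, h)
        if (lab == 1).sum() == 0 or (lab == 0).sum() == 0:
            out[f"auc@{h:g}"] = np.nan
            continue
        out[f"auc@{h:g}"] = auc(s.to_numpy(), lab.to_numpy())
    ser = pd.Series(out, name=spec.label())
    ser["mean_auc"] = np.nanmean(list(out.values()))
    return ser
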