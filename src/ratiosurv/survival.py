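"""Kaplan-Meier estimation, Mantel-Cox log-rank tests and dichotomization
survival screens over module eigengenes and single genes.

Samples are split into high/low expression groups (median split by
default), compared by the log-rank test, and summarized by the
Mantel-Haenszel hazard ratio HR = (O_h/E_h)/(O_l/E_l) with a log-normal
95% CI.  At tied times, events precede censorings (standard convention).
The nomination filter selects genes with a significant
dose effect (log-rank p < 0.015 by default) on either side of the
anticorrelated module pair, honouring probe availability,
known-driver exclusions and alternate-platform p-value overrides.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (ConfigError, ExpressionMatrix, SurvivalData,
                         ValidationError, log2_matrix)
from .diffexpr import bh_fdr
from .network import EigengeneMatrix

log = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit survival curve with per-time at-risk/event counts."""

    event_times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def plot(self, ax=None, **kwargs):
        import matplotlib.pyplot as plt

        ax = ax or plt.gca()
        ts = np.concatenate([[0.0], self.event_times])
        ss = np.concatenate([[1.0], self.survival])
        ax.step(ts, ss, where="post", **kwargs)
        ax.set_xlabel("time")
        ax.set_ylabel("S(t)")
        ax.set_ylim(0, 1.05)
        return ax


def km_curve(records: SurvivalData) -> KMCurve:
    """Kaplan-Meier product-limit estimator S(t) = prod (1 - d_i/n_i).

    Events precede censorings at tied times: a subject censored at an event
    time is still at risk for that event.
    """
    t = records.time.to_numpy(dtype=float)
    e = records.event.to_numpy(dtype=int)
    if t.size == 0:
        raise ValidationError("need at least one record")
    times = np.unique(t[e == 1])
    surv, at_risk, events = [], [], []
    s = 1.0
    for ti in times:
        n_i = int(np.sum(t >= ti))  # censored-at-ti still at risk
        d_i = int(np.sum((t == ti) & (e == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        events.append(d_i)
    return KMCurve(times, np.array(surv), np.array(at_risk, dtype=int),
                   np.array(events, dtype=int))


@dataclass
class DichotomySurvivalResult:
    """Log-rank/HR summary for one dichotomized unit (module or gene)."""

    unit: str
    split_rule: str
    n_high: int
    n_low: int
    observed_high: float
    expected_high: float
    observed_low: float
    expected_low: float
    chi2: float
    p: float
    hr: float
    ci_low: float
    ci_high: float
    direction: str  # '+', '-' or 'ns'

    def as_dict(self) -> dict:
        return dict(unit=self.unit, split=self.split_rule, n_high=self.n_high,
                    n_low=self.n_low, chi2=self.chi2, p=self.p, hr=self.hr,
                    ci_low=self.ci_low, ci_high=self.ci_high,
                    direction=self.direction)


def logrank_hr(high: SurvivalData, low: SurvivalData, unit: str = "",
               split_rule: str = "median", alpha_ns: float = 0.05
               ) -> DichotomySurvivalResult:
    """Mantel-Cox log-rank test plus Mantel-Haenszel hazard ratio.

    HR = (O_high/E_high)/(O_low/E_low), 95% CI exp(ln HR ± 1.96 sqrt(1/E_h
    + 1/E_l)).  Direction '+' means high expression goes with high survival
    (HR of high vs low < 1), '-' the opposite; 'ns' when p >= ``alpha_ns``.
    """
    t1, e1 = high.time.to_numpy(float), high.event.to_numpy(int)
    t0, e0 = low.time.to_numpy(float), low.event.to_numpy(int)
    if len(t1) < 2 or len(t0) < 2:
        raise ValidationError("each group needs >= 2 records")
    if e1.sum() + e0.sum() == 0:
        raise ValidationError("no events in either group; log-rank undefined")

    all_t = np.concatenate([t1, t0])
    all_e = np.concatenate([e1, e0])
    times = np.unique(all_t[all_e == 1])

    o1 = e1.sum()
    o0 = e0.sum()
    exp1 = exp0 = 0.0
    var = 0.0
    for ti in times:
        n1 = np.sum(t1 >= ti)
        n0 = np.sum(t0 >= ti)
        n = n1 + n0
        d = np.sum((all_t == ti) & (all_e == 1))
        if n == 0:
            continue
        exp1 += d * n1 / n
        exp0 += d * n0 / n
        if n > 1:
            var += d * (n1 / n) * (n0 / n) * (n - d) / (n - 1)

    if var == 0:
        chi2, p = 0.0, 1.0
    else:
        chi2 = (o1 - exp1) ** 2 / var
        p = float(stats.chi2.sf(chi2, df=1))

    with np.errstate(divide="ignore", invalid="ignore"):
        hr = (o1 / exp1) / (o0 / exp0) if exp1 > 0 and exp0 > 0 and o0 > 0 else np.nan
        if np.isfinite(hr) and hr > 0:
            se = np.sqrt(1.0 / exp1 + 1.0 / exp0)
            ci_low = hr * np.exp(-1.96 * se)
            ci_high = hr * np.exp(1.96 * se)
        else:
            ci_low = ci_high = np.nan

    if p >= alpha_ns or not np.isfinite(hr):
        direction = "ns"
    else:
        direction = "+" if hr < 1 else "-"
    return DichotomySurvivalResult(unit, split_rule, len(t1), len(t0),
                                   float(o1), float(exp1), float(o0),
                                   float(exp0), float(chi2), p, float(hr),
                                   float(ci_low), float(ci_high), direction)


def dichotomize(values: pd.Series, rule: str = "median",
                threshold: float | None = None) -> pd.Series:
    """Split samples into 'high'/'low' (tertile rule also yields 'dropped').

    Median rule: value > median -> high, value < median -> low, ties at the
    median -> low.  Tertile-extremes keeps the top and bottom thirds.
    """
    values = values.astype(float)
    if len(values) < 4:
        raise ValidationError("need >= 4 samples to dichotomize")
    if values.nunique() == 1:
        raise ValidationError("all values identical; cannot dichotomize")
    if rule == "median":
        med = values.median()
        return pd.Series(np.where(values > med, "high", "low"),
                         index=values.index)
    if rule == "tertile-extremes":
        lo, hi = values.quantile([1 / 3, 2 / 3])
        lab = np.full(len(values), "dropped", dtype=object)
        lab[values <= lo] = "low"
        lab[values >= hi] = "high"
        return pd.Series(lab, index=values.index)
    if rule == "fixed":
        if threshold is None:
            raise ConfigError("fixed rule requires a threshold")
        return pd.Series(np.where(values > threshold, "high", "low"),
                         index=values.index)
    raise ConfigError(f"unknown dichotomization rule {rule!r}")


def _screen_values(values_by_unit: pd.DataFrame, records: SurvivalData,
                   rule: str = "median") -> pd.DataFrame:
    shared = [s for s in values_by_unit.index if s in records.sample_ids]
    rows = []
    for unit in values_by_unit.columns:
        labels = dichotomize(values_by_unit.loc[shared, unit], rule)
        hi = [s for s in shared if labels[s] == "high"]
        lo = [s for s in shared if labels[s] == "low"]
        res = logrank_hr(records.subset(hi), records.subset(lo), unit=unit,
                         split_rule=rule)
        rows.append(res.as_dict())
    out = pd.DataFrame(rows).set_index("unit")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


def eigengene_survival_screen(me: EigengeneMatrix, records: SurvivalData,
                              rule: str = "median") -> pd.DataFrame:
    """Dichotomized log-rank/HR per module eigengene, with BH q across modules."""
    return _screen_values(me.values, records, rule)


def gene_survival_screen(x: ExpressionMatrix, genes, records: SurvivalData,
                         rule: str = "median", log_offset: float = 1.0
                         ) -> pd.DataFrame:
    """Dichotomized log-rank/HR per gene (log2 scale), BH q across genes."""
    logx = log2_matrix(x, log_offset)
    vals = logx.loc[list(dict.fromkeys(genes))].T
    return _screen_values(vals, records, rule)


@dataclass
class NominationRules:
    """Rules for turning a single-gene survival screen into candidate panels."""

    logrank_p_max: float = 0.015
    require_probe: bool = True
    excluded_known_drivers: frozenset = frozenset({"ESR1"})
    alternate_platform_overrides: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.logrank_p_max < 1:
            raise ConfigError("logrank_p_max must lie in (0, 1)")


def nomination_filter(screen: pd.DataFrame, rules: NominationRules | None = None
                      ) -> tuple[list[str], list[str]]:
    """Select numerator (M2-side) and denominator (M12-side) gene panels.

    ``screen`` needs columns ``gene``, ``side`` ('M2' or 'M12'),
    ``logrank_p`` (NaN when no KM result), ``probe`` (bool).  A gene passes
    when min(log-rank p, any alternate-platform override) < logrank_p_max
    (strict), its probe is available (if required) and it is not an excluded
    known driver.  Returns (numerator panel, denominator panel) in input
    order.
    """
    rules = rules or NominationRules()
    num, den = [], []
    for _, row in screen.iterrows():
        gene = row["gene"]
        if gene in rules.excluded_known_drivers:
            continue
        if rules.require_probe and not bool(row.get("probe", True)):
            continue
        p = row.get("logrank_p", np.nan)
        override = rules.alternate_platform_overrides.get(gene, np.nan)
        cands = [v for v in (p, override) if np.isfinite(v)]
        best = min(cands) if cands else np.nan
        if not np.isfinite(best) or best >= rules.logrank_p_max:
            continue
        (num if row["side"] == "M2" else den).append(gene)
    return num, den
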