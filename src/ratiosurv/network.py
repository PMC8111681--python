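"""Weighted gene coexpression network: bicor adjacency, topological overlap,
module detection, eigengenes, kME and module–trait statistics.

The network is built WGCNA-style: a robust biweight-midcorrelation matrix is
raised to a soft-threshold power β (signed by default, so anticorrelated
gene communities stay in separate modules), converted to a topological
overlap dissimilarity, and clustered by average linkage with a static tree
cut.  Modules are summarized by eigengenes — the sign-oriented first
principal component of member expression — and each gene's module
membership strength is its Pearson correlation to the eigengene (kME).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, fcluster
from scipy.spatial.distance import squareform

from .containers import (ConfigError, ExpressionMatrix, TraitTable,
                         ValidationError, log2_matrix)

log = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"


# ---------------------------------------------------------------------------
# biweight midcorrelation
# ---------------------------------------------------------------------------

def _bicor_transform(x: np.ndarray) -> np.ndarray:
    """Tukey-biweight centred/weighted copy of ``x``, normalized to unit norm.

    The weight for observation i is w_i = (1 - u_i^2)^2 for |u_i| < 1 and 0
    otherwise, with u_i = (x_i - med(x)) / (9 MAD(x)).  A vector with zero
    MAD falls back to plain mean-centring (Pearson behaviour); a constant
    vector maps to the zero vector.
    """
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        centred = x - x.mean()
        if np.allclose(centred, 0):
            return np.zeros_like(x)
        log.debug("bicor: zero MAD, falling back to Pearson for one vector")
        return centred / np.linalg.norm(centred)
    u = (x - med) / (9.0 * mad)
    w = (1.0 - u**2) ** 2 * (np.abs(u) < 1)
    xt = (x - med) * w
    nrm = np.linalg.norm(xt)
    if nrm == 0:
        return np.zeros_like(x)
    return xt / nrm


def bicor(x, y) -> float:
    """Biweight midcorrelation of two equal-length vectors, in [-1, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("bicor requires two equal-length 1-d vectors")
    if x.size < 3:
        raise ValidationError("bicor requires n >= 3")
    xt = _bicor_transform(x)
    yt = _bicor_transform(y)
    if not xt.any() or not yt.any():
        raise ValidationError("bicor undefined for a constant vector")
    return float(np.clip(xt @ yt, -1.0, 1.0))


def bicor_matrix(rows: np.ndarray) -> np.ndarray:
    """Pairwise bicor of the rows of a 2-d array.

    The biweight weights depend only on each row's own median/MAD, so the
    matrix is a plain inner product of per-row transformed vectors.
    Constant rows yield zero correlation to everything (flagged by caller).
    """
    rows = np.asarray(rows, dtype=float)
    t = np.empty_like(rows)
    for i in range(rows.shape[0]):
        t[i] = _bicor_transform(rows[i])
    c = np.clip(t @ t.T, -1.0, 1.0)
    np.fill_diagonal(c, 1.0)
    return c


def bicor_pvalue(r: float, n: int) -> float:
    """Two-tailed Student p for a correlation: t = r sqrt(n-2)/sqrt(1-r^2)."""
    r = float(np.clip(r, -1.0, 1.0))
    if n < 3:
        raise ValidationError("need n >= 3 for a correlation p-value")
    if abs(r) >= 1.0:
        return float(np.finfo(float).tiny)
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(max(p, np.finfo(float).tiny))


# ---------------------------------------------------------------------------
# adjacency and topological overlap
# ---------------------------------------------------------------------------

@dataclass
class NetworkConfig:
    """Soft-threshold power, sign mode and module-detection parameters."""

    beta: float = 12.0
    signed: bool = True
    min_module_size: int = 30
    cut_height: float = 0.99  # fraction of the maximum linkage merge height
    merge_corr: float = 0.75
    hub_threshold: float = 0.6
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.beta < 1:
            raise ConfigError("beta must be >= 1")
        if self.min_module_size < 2:
            raise ConfigError("min_module_size must be >= 2")
        if not 0 < self.cut_height < 1:
            raise ConfigError("cut_height must lie in (0, 1)")


def adjacency(corr: np.ndarray, cfg: NetworkConfig) -> np.ndarray:
    """Soft-threshold a correlation matrix: signed ((1+r)/2)^β, unsigned |r|^β."""
    corr = np.asarray(corr, dtype=float)
    if not np.allclose(corr, corr.T):
        raise ValidationError("correlation matrix must be symmetric")
    if cfg.signed:
        a = ((1.0 + corr) / 2.0) ** cfg.beta
    else:
        a = np.abs(corr) ** cfg.beta
    np.fill_diagonal(a, 1.0)
    return a


def tom(adj: np.ndarray) -> np.ndarray:
    """Topological overlap matrix of a [0,1] adjacency matrix.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with the
    sum over u != i, j and k_i the connectivity sum_{u != i} a_iu.
    """
    adj = np.asarray(adj, dtype=float)
    if not np.allclose(adj, adj.T):
        raise ValidationError("adjacency must be symmetric")
    a0 = adj.copy()
    np.fill_diagonal(a0, 0.0)
    shared = a0 @ a0
    k = a0.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (shared + a0) / (kmin + 1.0 - a0)
    t = np.nan_to_num(t, nan=0.0)
    np.fill_diagonal(t, 1.0)
    return np.clip(t, 0.0, 1.0)


def pick_soft_threshold(corr: np.ndarray, betas=None, signed: bool = True,
                        r2_target: float = 0.80, n_bins: int = 10):
    """Smallest β whose connectivity distribution fits a scale-free model.

    Fits log10 p(k) ~ log10 k over ``n_bins`` connectivity bins for each
    candidate power and returns (chosen β, table of (β, R², mean k)).
    """
    betas = list(betas) if betas is not None else [1, 2, 3, 4, 5, 6, 8, 10, 12, 14, 16, 18, 20]
    rows = []
    chosen = None
    cfg_base = dict(min_module_size=2)
    for b in betas:
        a = adjacency(corr, NetworkConfig(beta=b, signed=signed, **cfg_base))
        np.fill_diagonal(a, 0.0)
        k = a.sum(axis=1)
        if np.allclose(k, k[0]):
            r2 = 0.0
        else:
            hist, edges = np.histogram(k, bins=n_bins)
            centres = 0.5 * (edges[1:] + edges[:-1])
            keep = (hist > 0) & (centres > 0)
            if keep.sum() < 3:
                r2 = 0.0
            else:
                lk, lp = np.log10(centres[keep]), np.log10(hist[keep] / hist.sum())
                slope, _, r, *_ = stats.linregress(lk, lp)
                r2 = r**2 if slope < 0 else 0.0
        rows.append((b, r2, float(k.mean())))
        if chosen is None and r2 >= r2_target:
            chosen = b
    table = pd.DataFrame(rows, columns=["beta", "r2", "mean_k"])
    return chosen, table


# ---------------------------------------------------------------------------
# module detection
# ---------------------------------------------------------------------------

@dataclass
class ModuleAssignment:
    """Gene → module labels (M1..Mk by descending size, or UNASSIGNED)."""

    labels: pd.Series

    def module_names(self) -> list[str]:
        sizes = self.labels[self.labels != UNASSIGNED].value_counts()
        return sorted(sizes.index, key=lambda m: int(m[1:]))

    def members(self, module: str) -> list[str]:
        return list(self.labels.index[self.labels == module])

    def sizes(self) -> pd.Series:
        return self.labels[self.labels != UNASSIGNED].value_counts()


def _renumber_by_size(labels: pd.Series) -> pd.Series:
    sizes = labels[labels != UNASSIGNED].value_counts()
    mapping = {old: f"M{i + 1}" for i, old in enumerate(sizes.index)}
    mapping[UNASSIGNED] = UNASSIGNED
    return labels.map(mapping)


def detect_modules(diss: np.ndarray, gene_ids, cfg: NetworkConfig,
                   log_expr: pd.DataFrame | None = None) -> ModuleAssignment:
    """Average-linkage clustering of a TOM dissimilarity with a static cut.

    The tree is cut at ``cfg.cut_height`` times the maximum merge height;
    clusters smaller than ``cfg.min_module_size`` become UNASSIGNED.  When
    ``log_expr`` (log2-scale genes × samples) is supplied, modules whose
    eigengenes correlate above ``cfg.merge_corr`` are merged iteratively.
    Labels are renumbered by descending module size.
    """
    gene_ids = list(gene_ids)
    n = len(gene_ids)
    diss = np.asarray(diss, dtype=float)
    if diss.shape != (n, n):
        raise ValidationError("dissimilarity shape does not match gene ids")
    if n < cfg.min_module_size:
        log.warning("fewer genes (%d) than min_module_size; all UNASSIGNED", n)
        return ModuleAssignment(pd.Series(UNASSIGNED, index=gene_ids))
    d = (diss + diss.T) / 2.0
    np.fill_diagonal(d, 0.0)
    link = average(squareform(d, checks=False))
    height = cfg.cut_height * link[:, 2].max()
    flat = fcluster(link, t=height, criterion="distance")

    labels = pd.Series([f"C{c}" for c in flat], index=gene_ids)
    sizes = labels.value_counts()
    small = sizes.index[sizes < cfg.min_module_size]
    labels[labels.isin(small)] = UNASSIGNED

    if log_expr is not None:
        labels = _merge_correlated_modules(labels, log_expr, cfg)
    return ModuleAssignment(_renumber_by_size(labels))


def _merge_correlated_modules(labels: pd.Series, log_expr: pd.DataFrame,
                              cfg: NetworkConfig) -> pd.Series:
    """Iteratively merge module pairs whose eigengenes correlate > merge_corr."""
    labels = labels.copy()
    while True:
        mods = [m for m in labels.unique() if m != UNASSIGNED]
        if len(mods) < 2:
            return labels
        mes = {}
        for m in mods:
            sub = log_expr.loc[labels.index[labels == m]]
            mes[m] = _eigengene_of(sub)[0]
        me_df = pd.DataFrame(mes)
        corr = me_df.corr()
        np.fill_diagonal(corr.values, -np.inf)
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        if corr.values[i, j] <= cfg.merge_corr:
            return labels
        a, b = corr.index[i], corr.columns[j]
        log.info("merging modules %s and %s (eigengene r=%.3f)", a, b,
                 corr.values[i, j])
        labels[labels == b] = a


# ---------------------------------------------------------------------------
# eigengenes and kME
# ---------------------------------------------------------------------------

@dataclass
class EigengeneMatrix:
    """Samples × modules eigengene values plus per-module variance explained."""

    values: pd.DataFrame
    variance_explained: dict[str, float] = field(default_factory=dict)

    @property
    def modules(self) -> list[str]:
        return list(self.values.columns)


def _eigengene_of(log_sub: pd.DataFrame) -> tuple[np.ndarray, float]:
    """First right-singular vector of standardized member rows, sign-oriented.

    Returns (unit-norm eigengene over samples, variance-explained share).
    """
    arr = log_sub.to_numpy(dtype=float)
    mean = arr.mean(axis=1, keepdims=True)
    sd = arr.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (arr - mean) / sd
    if z.shape[0] == 1:
        v = z[0] / (np.linalg.norm(z[0]) or 1.0)
        return v, 1.0
    u, s, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    var = float(s[0] ** 2 / (s**2).sum()) if s.sum() > 0 else 0.0
    # orient so that the mean member correlation with the eigengene is > 0
    corrs = z @ v
    if corrs.mean() < 0:
        v = -v
    return v, var


def module_eigengenes(x: ExpressionMatrix, assign: ModuleAssignment,
                      log_offset: float = 1.0) -> EigengeneMatrix:
    """Per-module eigengene: weighted first principal component on log2 scale."""
    logx = log2_matrix(x, log_offset)
    cols, var = {}, {}
    for m in assign.module_names():
        members = assign.members(m)
        if not members:
            continue
        if len(members) == 1:
            log.warning("module %s has a single gene; eigengene is that gene", m)
        v, ve = _eigengene_of(logx.loc[members])
        cols[m] = v
        var[m] = ve
    values = pd.DataFrame(cols, index=x.sample_ids)
    return EigengeneMatrix(values, var)


@dataclass
class KMETable:
    """Gene × module Pearson correlations with own-module hub flags."""

    kme: pd.DataFrame
    own_module: pd.Series
    hub: pd.Series
    flagged_constant: list[str] = field(default_factory=list)


def kme(x: ExpressionMatrix, me: EigengeneMatrix, assign: ModuleAssignment,
        log_offset: float = 1.0, hub_threshold: float = 0.6) -> KMETable:
    """Pearson correlation of each gene (log2 scale) with every eigengene."""
    logx = log2_matrix(x, log_offset).to_numpy(dtype=float)
    genes = x.gene_ids
    gc = logx - logx.mean(axis=1, keepdims=True)
    gsd = gc.std(axis=1)
    constant = gsd == 0
    gsd[constant] = 1.0
    gz = gc / gsd[:, None]

    mv = me.values.to_numpy(dtype=float).T  # modules × samples
    mc = mv - mv.mean(axis=1, keepdims=True)
    msd = mc.std(axis=1)
    msd[msd == 0] = 1.0
    mz = mc / msd[:, None]

    n = logx.shape[1]
    table = pd.DataFrame(np.clip(gz @ mz.T / n, -1, 1), index=genes,
                         columns=me.modules)
    table.loc[constant, :] = 0.0
    flagged = [g for g, c in zip(genes, constant) if c]
    if flagged:
        log.warning("constant genes recorded with kME 0: %s", flagged[:10])

    own = assign.labels.reindex(genes).fillna(UNASSIGNED)
    own_kme = pd.Series(
        [table.at[g, m] if m in table.columns else np.nan
         for g, m in own.items()], index=genes)
    hub = own_kme >= hub_threshold
    return KMETable(table, own, hub, flagged)


# ---------------------------------------------------------------------------
# module-trait statistics and relatedness
# ---------------------------------------------------------------------------

def module_trait_stats(me: EigengeneMatrix, traits: TraitTable,
                       trait_cols=None) -> pd.DataFrame:
    """Module–trait correlation table plus subtype separation tests.

    For each quantitative or binary trait column: bicor (Pearson for
    two-valued traits, where the MAD degenerates) with a two-tailed Student
    p.  Per module: Kruskal-Wallis p across the four subtypes and a Wilcoxon
    rank-sum p for TNBC versus pooled non-TNBC.
    """
    tt = traits.table.loc[[s for s in me.values.index if s in traits.table.index]]
    mevals = me.values.loc[tt.index]
    if trait_cols is None:
        trait_cols = [c for c in tt.columns
                      if c != "subtype" and pd.api.types.is_numeric_dtype(tt[c])]
    rows = []
    for m in me.modules:
        ev = mevals[m]
        kw_p = wil_p = np.nan
        if "subtype" in tt.columns:
            groups = [ev[tt["subtype"] == s].to_numpy() for s in
                      ("LumA", "LumB", "HER2", "TNBC")]
            groups = [g for g in groups if len(g) >= 5]
            if len(groups) >= 2:
                kw_p = stats.kruskal(*groups).pvalue
            tn = ev[tt["subtype"] == "TNBC"].to_numpy()
            rest = ev[tt["subtype"] != "TNBC"].to_numpy()
            if len(tn) >= 5 and len(rest) >= 5:
                wil_p = stats.ranksums(tn, rest).pvalue
        for c in trait_cols:
            vals = tt[c]
            ok = vals.notna()
            if ok.sum() < 3:
                log.warning("trait %s has <3 non-missing values; skipped", c)
                continue
            v = vals[ok].astype(float).to_numpy()
            e = ev[ok].to_numpy()
            if len(np.unique(v)) <= 2:
                r = float(np.corrcoef(e, v)[0, 1]) if v.std() > 0 else 0.0
            else:
                r = bicor(e, v)
            rows.append({"module": m, "trait": c, "bicor": r,
                         "p": bicor_pvalue(r, ok.sum()),
                         "kruskal_p": kw_p, "wilcoxon_tnbc_p": wil_p})
    return pd.DataFrame(rows)


def module_relatedness(me: EigengeneMatrix, cut: float = 0.25):
    """Average-linkage clustering of eigengenes with distance 1 - Pearson.

    Returns (scipy linkage matrix, flat cluster labels at ``cut``).
    """
    if len(me.modules) < 2:
        raise ValidationError("need at least 2 modules for relatedness")
    corr = np.corrcoef(me.values.to_numpy(dtype=float).T)
    d = 1.0 - corr
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    link = average(squareform(d, checks=False))
    flat = fcluster(link, t=cut, criterion="distance")
    return link, pd.Series(flat, index=me.modules)


def regress_covariates(x: ExpressionMatrix, traits: TraitTable, covariates,
                       log_offset: float = 1.0) -> ExpressionMatrix:
    """OLS-residualize each gene on the named covariates (log2 scale).

    Residuals keep the gene's mean; the matrix is mapped back to linear
    scale so downstream stages see the same container contract.
    """
    covariates = list(covariates)
    if not covariates:
        return ExpressionMatrix(x.values.copy())
    tt = traits.table.loc[x.sample_ids, covariates].astype(float)
    design = np.column_stack([np.ones(len(tt)), tt.to_numpy()])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        corr = np.corrcoef(tt.to_numpy().T)
        idx = np.argwhere(np.triu(np.abs(corr) > 1 - 1e-10, k=1))
        pair = (covariates[idx[0][0]], covariates[idx[0][1]]) if len(idx) else tuple(covariates)
        raise ValidationError(f"collinear covariates: {pair}")
    logx = log2_matrix(x, log_offset).to_numpy(dtype=float)
    coef, *_ = np.linalg.lstsq(design, logx.T, rcond=None)
    resid = logx.T - design @ coef
    out = resid.T + logx.mean(axis=1, keepdims=True)
    linear = np.clip(2.0 ** out - log_offset, 0.0, None)
    return ExpressionMatrix(pd.DataFrame(linear, index=x.gene_ids,
                                         columns=x.sample_ids))


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

class CoexpressionNetwork:
    """Coexpression-network model over an expression matrix.

    ``fit()`` computes the bicor correlation matrix, soft-thresholded
    adjacency, topological overlap, module assignment, eigengenes and kME,
    returning a :class:`CoexpressionResult`.
    """

    def __init__(self, expr: ExpressionMatrix, config: NetworkConfig | None = None):
        self.expr = expr
        self.config = config or NetworkConfig()

    def fit(self) -> "CoexpressionResult":
        cfg = self.config
        logx = log2_matrix(self.expr, cfg.log_offset)
        corr = bicor_matrix(logx.to_numpy(dtype=float))
        adj = adjacency(corr, cfg)
        t = tom(adj)
        assign = detect_modules(1.0 - t, self.expr.gene_ids, cfg, log_expr=logx)
        me = module_eigengenes(self.expr, assign, cfg.log_offset)
        kmetab = kme(self.expr, me, assign, cfg.log_offset, cfg.hub_threshold)
        return CoexpressionResult(self, assign, me, kmetab)


class CoexpressionResult:
    """Fitted network: module assignment, eigengenes and kME table."""

    def __init__(self, model: CoexpressionNetwork, modules: ModuleAssignment,
                 eigengenes: EigengeneMatrix, kme_table: KMETable):
        self.model = model
        self.modules = modules
        self.eigengenes = eigengenes
        self.kme = kme_table

    def trait_stats(self, traits: TraitTable, trait_cols=None) -> pd.DataFrame:
        return module_trait_stats(self.eigengenes, traits, trait_cols)

    def relatedness(self, cut: float = 0.25):
        return module_relatedness(self.eigengenes, cut)

    def summary(self) -> str:
        sizes = self.modules.sizes()
        n_un = int((self.modules.labels == UNASSIGNED).sum())
        lines = ["Coexpression network summary",
                 f"  genes: {self.model.expr.n_genes}  samples: {self.model.expr.n_samples}",
                 f"  beta={self.model.config.beta} signed={self.model.config.signed}",
                 f"  modules: {len(sizes)}  unassigned genes: {n_un}"]
        for m in self.modules.module_names():
            ve = self.eigengenes.variance_explained.get(m, float("nan"))
            n_hub = int((self.kme.hub & (self.kme.own_module == m)).sum())
            lines.append(f"    {m}: {sizes[m]} genes, varExpl={ve:.2f}, hubs={n_hub}")
        return "\n".join(lines)
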