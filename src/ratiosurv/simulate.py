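"""Seedable synthetic breast-cancer cohort generator.

The generator emulates the statistical structure the pipeline assumes:
block-coexpressed gene modules driven by per-sample latent factors, one
strongly anticorrelated module pair whose factors shift with tumour
subtype (mirroring the up-in-TNBC / down-in-TNBC module duo), and
right-censored survival whose hazard depends on a planted
numerator/denominator gene-ratio score.

Latent log2-expression is x_gs = mu_g + lambda_g f_{m(g),s} + eps_gs;
abundances are 2**x so the linear-scale non-negativity contract holds.
Survival is exponential with hazard h0 exp(gamma z_s), z_s the standardized
log planted-ratio score, under uniform administrative censoring.  A
"binormal" label mode instead produces a single-horizon outcome whose
class-conditional score distributions are exactly binormal (unit sd, mean
gap ``binormal_gap``), the regime where AUC has the closed form
Phi(gap / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (ConfigError, ExpressionMatrix, SurvivalData,
                         TraitTable)
from .ratio import RatioSpec, ratio_score

# TCGA-like subtype counts 92 TNBC : 226 LumA : 118 LumB : 57 HER2, rescaled
SUBTYPE_PROPS = {"LumA": 226 / 493, "LumB": 118 / 493,
                 "HER2": 57 / 493, "TNBC": 92 / 493}


@dataclass
class SimulationConfig:
    """Cohort-simulation parameters (defaults emulate the study conditions)."""

    n_genes: int = 1000
    n_samples: int = 493
    module_sizes: tuple = (150, 120, 100, 80, 60, 40)
    loading: float = 1.0          # module factor loading scale
    loading_jitter: float = 0.2   # per-gene uniform jitter around `loading`
    rho_ab: float = -0.8          # factor correlation of the anticorrelated pair
    anticorr_pair: tuple = (0, 1)
    subtype_props: dict = field(default_factory=lambda: dict(SUBTYPE_PROPS))
    delta: float = 1.5            # TNBC shift on the anticorrelated factors
    noise_sd: float = 0.7
    mu_range: tuple = (3.0, 8.0)
    n_planted: int = 3            # planted k:k ratio size
    gamma: float = -0.7           # log-hazard per sd of planted score
    h0: float = 0.0005            # baseline hazard per day
    censor_window: float = 3650.0
    label_model: str = "exponential"  # exponential | binormal
    binormal_gap: float = 1.0
    binormal_horizon: float = 1825.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho_ab < 0:
            raise ConfigError("rho_ab must lie in [-1, 0)")
        if abs(sum(self.subtype_props.values()) - 1.0) > 1e-9:
            raise ConfigError("subtype proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd must be > 0")
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigError("module sizes exceed n_genes")
        a, b = self.anticorr_pair
        if self.n_planted > min(self.module_sizes[a], self.module_sizes[b]):
            raise ConfigError("planted ratio larger than its host modules")
        if self.label_model not in ("exponential", "binormal"):
            raise ConfigError(f"unknown label_model {self.label_model!r}")


def default_module_sizes(n_genes: int) -> tuple:
    """Module sizes proportional to the default layout (55% of genes in six
    modules, the rest background), scaled to ``n_genes``."""
    fractions = (0.15, 0.12, 0.10, 0.08, 0.06, 0.04)
    sizes = tuple(max(5, int(round(f * n_genes))) for f in fractions)
    if sum(sizes) > n_genes:
        raise ConfigError(f"n_genes={n_genes} too small for six modules")
    return sizes


@dataclass
class SyntheticCohort:
    """Simulated expression + traits + survival with full ground truth."""

    expr: ExpressionMatrix
    traits: TraitTable
    survival: SurvivalData
    true_modules: pd.Series         # gene -> module label or 'NOISE'
    factors: pd.DataFrame           # samples × modules latent factors
    planted: RatioSpec
    planted_score_z: pd.Series      # standardized log planted-ratio score
    config: SimulationConfig


def expected_planted_auc(cfg: SimulationConfig) -> float:
    """Closed-form AUC Phi(gap / sqrt(2)) for the binormal label model."""
    if cfg.label_model != "binormal":
        raise ConfigError("closed-form AUC applies to the binormal label model")
    return float(stats.norm.cdf(cfg.binormal_gap / np.sqrt(2.0)))


def _subtype_vector(cfg: SimulationConfig, rng) -> np.ndarray:
    names = list(cfg.subtype_props)
    counts = np.floor(np.array([cfg.subtype_props[s] for s in names])
                      * cfg.n_samples).astype(int)
    while counts.sum() < cfg.n_samples:
        counts[np.argmax([cfg.subtype_props[s] for s in names])] += 1
    labels = np.repeat(names, counts)
    rng.shuffle(labels)
    return labels


def simulate_cohort(cfg: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a full synthetic cohort, reproducible from ``cfg.seed``."""
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    n_mod = len(cfg.module_sizes)
    ia, ib = cfg.anticorr_pair

    subtype = _subtype_vector(cfg, rng)
    # severity continuum for the anticorrelated pair: LumA none -> TNBC full
    shift_frac = {"LumA": 0.0, "LumB": 1 / 6, "HER2": 1 / 3, "TNBC": 1.0}
    frac = np.array([shift_frac[s] for s in subtype])

    factors = rng.standard_normal((cfg.n_samples, n_mod))
    # joint draw for the anticorrelated pair
    cov = np.array([[1.0, cfg.rho_ab], [cfg.rho_ab, 1.0]])
    chol = np.linalg.cholesky(cov)
    pair = rng.standard_normal((cfg.n_samples, 2)) @ chol.T
    factors[:, ia] = pair[:, 0] - cfg.delta * frac   # down in TNBC (M2-like)
    factors[:, ib] = pair[:, 1] + cfg.delta * frac   # up in TNBC (M12-like)

    gene_ids = [f"G{i:04d}" for i in range(cfg.n_genes)]
    sample_ids = [f"S{i:04d}" for i in range(cfg.n_samples)]
    module_of = np.full(cfg.n_genes, -1)
    start = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of[start:start + size] = m
        start += size

    lam = cfg.loading * rng.uniform(1.0 - cfg.loading_jitter,
                                    1.0 + cfg.loading_jitter, cfg.n_genes)
    mu = rng.uniform(*cfg.mu_range, cfg.n_genes)
    eps = rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_samples))
    logx = mu[:, None] + eps
    assigned = module_of >= 0
    logx[assigned] += lam[assigned, None] * factors[:, module_of[assigned]].T

    expr = ExpressionMatrix(pd.DataFrame(2.0 ** logx, index=gene_ids,
                                         columns=sample_ids))
    mod_names = [f"TM{m + 1}" for m in range(n_mod)]
    true_modules = pd.Series(
        [mod_names[m] if m >= 0 else "NOISE" for m in module_of],
        index=gene_ids)

    members_a = [g for g, m in zip(gene_ids, module_of) if m == ia]
    members_b = [g for g, m in zip(gene_ids, module_of) if m == ib]
    planted = RatioSpec(tuple(members_a[:cfg.n_planted]),
                        tuple(members_b[:cfg.n_planted]))

    score = ratio_score(expr, planted)
    logs = np.log(score.to_numpy())
    z = (logs - logs.mean()) / logs.std()
    zser = pd.Series(z, index=sample_ids)

    if cfg.label_model == "binormal":
        time, event = _binormal_labels(z, cfg, rng)
    else:
        hazard = cfg.h0 * np.exp(cfg.gamma * z)
        t_event = rng.exponential(1.0 / hazard)
        c = rng.uniform(0.0, cfg.censor_window, cfg.n_samples)
        event = (t_event <= c).astype(int)
        time = np.minimum(t_event, c)

    survival = SurvivalData(pd.Series(time, index=sample_ids),
                            pd.Series(event, index=sample_ids),
                            endpoint="PFI", time_unit="days")
    tnbc = (subtype == "TNBC").astype(int)
    traits = TraitTable(pd.DataFrame({"subtype": subtype, "TNBC": tnbc},
                                     index=sample_ids))
    fdf = pd.DataFrame(factors, index=sample_ids, columns=mod_names)
    return SyntheticCohort(expr, traits, survival, true_modules, fdf,
                           planted, zser, cfg)


def _binormal_labels(z: np.ndarray, cfg: SimulationConfig, rng
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Single-horizon outcomes with exactly binormal class-conditional scores.

    A reference sample of the balanced two-Gaussian mixture (means
    ±gap/2, unit sd) is drawn; its component labels are transferred to the
    cohort by matching score ranks, so the joint distribution of (score
    rank, outcome) is exactly that of a true binormal sample.  Survivors
    (high score) get censoring-free follow-up past the nominal horizon;
    cases get an event at half the horizon.
    """
    n = z.size
    comp = rng.integers(0, 2, n)  # 1 = survivor (high-score component)
    ref = rng.standard_normal(n) + (comp - 0.5) * cfg.binormal_gap
    order_ref = np.argsort(ref)
    order_z = np.argsort(z)
    label = np.empty(n, dtype=int)
    label[order_z] = comp[order_ref]  # survivor flag, rank-matched
    h = cfg.binormal_horizon
    time = np.where(label == 1, 1.5 * h, 0.5 * h)
    event = 1 - label
    return time.astype(float), event.astype(int)
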