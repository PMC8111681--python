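"""Core data containers and I/O for the ratio-screening pipeline.

Expression data are linear-scale, non-negative gene × sample abundances
(FPKM-like or array intensities).  Traits carry the four intrinsic breast
cancer subtypes plus binary/quantitative covariates; survival records are
right-censored (time, event) pairs for a named endpoint such as PFI or RFS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SUBTYPES = ("LumA", "LumB", "HER2", "TNBC")


class ValidationError(ValueError):
    """Raised when an input violates a container invariant."""


class ConfigError(ValueError):
    """Raised for invalid configuration values."""


@dataclass
class ExpressionMatrix:
    """Linear-scale non-negative abundances, genes in rows, samples in columns.

    Parameters
    ----------
    values : pandas.DataFrame
        Gene × sample abundance matrix.  The index holds gene identifiers,
        the columns sample identifiers; both must be unique and every entry
        must be finite and non-negative.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            dups = v.index[v.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated gene ids: {dups[:5]}")
        if v.columns.has_duplicates:
            dups = v.columns[v.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicated sample ids: {dups[:5]}")
        arr = v.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)])


@dataclass
class TraitTable:
    """Per-sample subtype, binary traits and quantitative covariates."""

    table: pd.DataFrame  # index = sample ids; columns include 'subtype'

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValidationError("duplicated sample ids in trait table")
        if "subtype" in self.table.columns:
            bad = set(self.table["subtype"].dropna()) - set(SUBTYPES)
            if bad:
                raise ValidationError(f"unknown subtype labels: {sorted(bad)}")
            if "TNBC" in self.table.columns:
                sub = self.table.dropna(subset=["subtype", "TNBC"])
                want = (sub["subtype"] == "TNBC").astype(int)
                if not (sub["TNBC"].astype(int) == want).all():
                    raise ValidationError("TNBC binary trait inconsistent with subtype")
        if "batch" in self.table.columns:
            log.warning(
                "trait table contains a 'batch' covariate; inputs are assumed "
                "batch-corrected upstream — no correction is applied here"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subtype_samples(self, subtype: str) -> list[str]:
        return list(self.table.index[self.table["subtype"] == subtype])


@dataclass
class SurvivalData:
    """Right-censored survival records for one endpoint.

    ``time`` is non-negative (unit recorded in ``time_unit``); ``event`` is
    1 for an observed event and 0 for censoring.
    """

    time: pd.Series
    event: pd.Series
    endpoint: str = "PFI"
    time_unit: str = "days"

    def __post_init__(self) -> None:
        self.time = self.time.astype(float)
        self.event = self.event.astype(int)
        if not self.time.index.equals(self.event.index):
            raise ValidationError("time and event indexed by different samples")
        if (self.time < 0).any():
            raise ValidationError("negative survival time")
        if not self.event.isin([0, 1]).all():
            raise ValidationError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.time.index)

    def subset(self, sample_ids) -> "SurvivalData":
        ids = list(sample_ids)
        return SurvivalData(
            self.time.loc[ids], self.event.loc[ids], self.endpoint, self.time_unit
        )


@dataclass
class NormalizationSpec:
    """How to normalize an expression matrix (samples first, then genes)."""

    sample_method: str = "total-scaling"  # none | total-scaling | median-centering-on-log
    gene_method: str = "none"  # none | unit-median | z-on-log
    log_offset: float = 1.0

    def __post_init__(self) -> None:
        if self.log_offset <= 0:
            raise ConfigError("log_offset must be > 0")
        if self.sample_method not in ("none", "total-scaling", "median-centering-on-log"):
            raise ConfigError(f"unknown sample_method {self.sample_method!r}")
        if self.gene_method not in ("none", "unit-median", "z-on-log"):
            raise ConfigError(f"unknown gene_method {self.gene_method!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, delimiter: str = "\t", max_missing_frac: float = 0.2
) -> ExpressionMatrix:
    """Read a genes × samples table (first column gene ids, header sample ids).

    Duplicated gene ids are collapsed to the row with the highest mean
    abundance; rows with more than ``max_missing_frac`` missing entries are
    dropped, remaining missing entries are median-imputed.  Both actions are
    logged.
    """
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    except Exception as exc:  # noqa: BLE001 - surface as parse error
        raise ValidationError(f"could not parse expression table {path}: {exc}") from exc
    if df.shape[1] == 0:
        raise ValidationError(f"no sample columns found in {path}")
    df = df.apply(pd.to_numeric, errors="raise")

    frac_missing = df.isna().mean(axis=1)
    to_drop = frac_missing > max_missing_frac
    if to_drop.any():
        log.info("dropping %d genes with >%d%% missing values",
                 int(to_drop.sum()), int(100 * max_missing_frac))
        df = df.loc[~to_drop]
    if df.isna().any().any():
        med = df.median(axis=1)
        df = df.apply(lambda row: row.fillna(med[row.name]), axis=1)
        log.info("median-imputed remaining missing values")

    if df.index.has_duplicates:
        # positional argmax per duplicated id (label-based idxmax is
        # ambiguous on a duplicated index)
        means_arr = df.mean(axis=1).to_numpy()
        pos: dict = {}
        for i, gene in enumerate(df.index):
            if gene not in pos or means_arr[i] > means_arr[pos[gene]]:
                pos[gene] = i
        log.info("collapsed %d duplicated gene ids by max-mean row",
                 int(df.index.duplicated().sum()))
        df = df.iloc[sorted(pos.values())]
    return ExpressionMatrix(df)


def write_expression_matrix(x: ExpressionMatrix, path, delimiter: str = "\t",
                            seed: int | None = None) -> None:
    """Write TSV with a header comment recording tool version and seed."""
    from ratiosurv import __version__

    with open(path, "w") as fh:
        fh.write(f"# ratiosurv {__version__} seed={seed}\n")
        x.values.to_csv(fh, sep=delimiter, index_label="gene")


def read_trait_table(path, delimiter: str = "\t") -> TraitTable:
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    return TraitTable(df)


def read_survival(path, delimiter: str = "\t", endpoint: str = "PFI",
                  time_col: str = "time", event_col: str = "event") -> SurvivalData:
    df = pd.read_csv(path, sep=delimiter, index_col=0, comment="#")
    return SurvivalData(df[time_col], df[event_col], endpoint=endpoint)


# ---------------------------------------------------------------------------
# normalization / QC
# ---------------------------------------------------------------------------

def normalize(x: ExpressionMatrix, spec: NormalizationSpec) -> ExpressionMatrix:
    """Apply sample-wise then gene-wise normalization.

    ``total-scaling`` rescales every sample (column) so its total equals the
    cohort-median column total, preserving non-negativity for downstream
    ratio scoring.  ``unit-median`` rescales each gene (row) so its nonzero
    median is 1 (all-zero rows are left unchanged).
    """
    df = x.values.copy()

    if spec.sample_method == "total-scaling":
        totals = df.sum(axis=0)
        if (totals == 0).any():
            bad = list(totals.index[totals == 0])
            raise ValidationError(f"all-zero sample columns: {bad}")
        target = float(totals.median())
        df = df * (target / totals)
    elif spec.sample_method == "median-centering-on-log":
        logd = np.log2(df + spec.log_offset)
        logd = logd - logd.median(axis=0)
        df = (2.0 ** logd) - spec.log_offset
        df = df.clip(lower=0.0)

    if spec.gene_method == "unit-median":
        df = unit_median_scale(df)
    elif spec.gene_method == "z-on-log":
        # z-scores mapped back through 2**z: per-gene order is preserved and
        # the non-negativity contract of ExpressionMatrix holds
        logd = np.log2(df + spec.log_offset)
        sd = logd.std(axis=1, ddof=1).replace(0.0, 1.0)
        z = logd.sub(logd.mean(axis=1), axis=0).div(sd, axis=0)
        df = 2.0 ** z

    return ExpressionMatrix(df)


def unit_median_scale(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each row so its nonzero median is 1; all-zero rows unchanged."""
    arr = df.to_numpy(dtype=float)
    med = np.empty(arr.shape[0])
    for i, row in enumerate(arr):
        nz = row[row > 0]
        med[i] = np.median(nz) if nz.size else 1.0
    return df.div(pd.Series(med, index=df.index), axis=0)


def log2_matrix(x: ExpressionMatrix, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise log2(value + offset)."""
    if offset <= 0:
        raise ConfigError("offset must be > 0")
    return np.log2(x.values + offset)


def remove_outlier_samples(
    x: ExpressionMatrix, z_cut: float = -2.5
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop samples with anomalously low standardized network connectivity.

    Per-sample connectivity is the sum of its Pearson correlations to all
    other samples; samples whose standardized connectivity falls below
    ``z_cut`` (which must be negative) are excluded.
    """
    if z_cut >= 0:
        raise ConfigError("z_cut must be negative")
    if x.n_samples < 3:
        raise ValidationError("need at least 3 samples for outlier detection")
    arr = x.values.to_numpy(dtype=float)
    centred = arr - arr.mean(axis=0)
    sd = centred.std(axis=0)
    sd[sd == 0] = 1.0
    std = centred / sd
    corr = (std.T @ std) / arr.shape[0]
    k = corr.sum(axis=1) - np.diag(corr)
    spread = k.std()
    if spread == 0:
        z = np.zeros_like(k)
    else:
        z = (k - k.mean()) / spread
    keep = z >= z_cut
    excluded = [s for s, ok in zip(x.sample_ids, keep) if not ok]
    if excluded:
        log.info("excluded %d outlier samples: %s", len(excluded), excluded[:10])
    kept = ExpressionMatrix(x.values.loc[:, keep])
    return kept, excluded
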