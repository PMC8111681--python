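"""Gene-set overlap enrichment: exact hypergeometric overrepresentation and
a batched one-tailed Fisher test with BH FDR."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ValidationError
from .diffexpr import bh_fdr


@dataclass
class OverlapTest:
    """Overlap of a query set (n) with a target class (K) in a universe (N)."""

    k: int
    n: int
    K: int
    N: int
    odds_ratio: float
    p: float

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.n, self.K)):
            raise ValidationError("impossible overlap count")
        if self.N < self.n + self.K - self.k:
            raise ValidationError("universe smaller than the union of the sets")


def hypergeom_overlap(k: int, n: int, K: int, N: int) -> OverlapTest:
    """Upper-tail exact hypergeometric test P(X >= k) for overrepresentation.

    The odds ratio is the sample OR of the 2x2 overlap table,
    k(N-n-K+k) / ((n-k)(K-k)); infinite when a margin cell is empty.
    """
    if not (0 <= k <= min(n, K)) or N < n + K - k or min(n, K, N) < 0:
        raise ValidationError(f"impossible counts k={k} n={n} K={K} N={N}")
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    a, b, c, d = k, n - k, K - k, N - n - K + k
    if b * c == 0:
        orat = np.inf if a * d > 0 else np.nan
    else:
        orat = (a * d) / (b * c)
    return OverlapTest(k, n, K, N, float(orat), min(p, 1.0))


def batch_fisher(sets: dict, target, universe) -> pd.DataFrame:
    """One-tailed Fisher exact test of each named set against the target.

    All sets must lie in the universe; q-values are BH across the batch.
    """
    universe = set(universe)
    if not universe:
        raise ValidationError("empty universe")
    target = set(target) & universe
    rows = []
    for name, genes in sets.items():
        genes = set(genes)
        if not genes <= universe:
            raise ValidationError(f"set {name!r} not contained in universe")
        k = len(genes & target)
        n, K, N = len(genes), len(target), len(universe)
        table = [[k, n - k], [K - k, N - n - K + k]]
        orat, p = stats.fisher_exact(table, alternative="greater")
        capped = not np.isfinite(orat)
        rows.append({"set": name, "k": k, "n": n, "K": K, "N": N,
                     "odds_ratio": orat, "or_capped": capped, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out
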