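import numpy as np
import pandas as pd
import pytest

from ratiosurv.containers import ExpressionMatrix, SurvivalData


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_expr(arr, gene_prefix="g", sample_prefix="s") -> ExpressionMatrix:
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        arr,
        index=[f"{gene_prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"{sample_prefix}{j}" for j in range(arr.shape[1])]))


def make_surv(times, events, prefix="s") -> SurvivalData:
    idx = [f"{prefix}{i}" for i in range(len(times))]
    return SurvivalData(pd.Series(list(times), index=idx, dtype=float),
                        pd.Series(list(events), index=idx))


@pytest.fixture
def small_cohort():
    """Small block-structured synthetic cohort shared across tests."""
    from ratiosurv.simulate import SimulationConfig, simulate_cohort

    cfg = SimulationConfig(n_genes=80, n_samples=200,
                           module_sizes=(20, 20, 15, 15), seed=11)
    return simulate_cohort(cfg)
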