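import numpy as np
import pandas as pd
import pytest

from prognosig.types import ExpressionMatrix, SurvivalTable


def make_survival(times, events, ids=None, unit="months", **covariates):
    ids = ids or [f"s{i}" for i in range(len(times))]
    df = pd.DataFrame({"time": times, "event": events}, index=ids)
    for name, vals in covariates.items():
        df[name] = vals
    return SurvivalTable(data=df, time_unit=unit)


def make_expression(values, genes=None, samples=None, unit="array_log"):
    arr = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        values=pd.DataFrame(arr, index=genes, columns=samples), unit=unit
    )


@pytest.fixture
def six_sample_survival():
    """All-events fixture with an interleaved binary covariate (non-monotone)."""
    return make_survival([1, 2, 3, 4, 5, 6], [1, 1, 1, 1, 1, 1])


@pytest.fixture
def tied_survival():
    """Ten samples with tied event times and censoring."""
    return make_survival(
        [2, 2, 3, 3, 3, 5, 6, 6, 8, 9],
        [1, 1, 1, 0, 1, 1, 0, 1, 1, 0],
    )


@pytest.fixture(scope="session")
def small_planted_cohort():
    """Small cohort with planted prognostic genes, shared across tests."""
    from prognosig.synthetic import SyntheticConfig, generate_cohort

    cfg = SyntheticConfig(
        n_genes=120,
        n_samples=150,
        n_planted_adverse=4,
        n_planted_favorable=3,
        beta_magnitude=1.0,
        censor_rate_target=0.2,
        seed=11,
    )
    return generate_cohort(cfg)
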