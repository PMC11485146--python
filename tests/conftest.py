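import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from cupronet.io import ExpressionMatrix, SurvivalTable

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def make_expression(values, scale="log2", condition=None, genes=None, samples=None):
    """Small helper to assemble an ExpressionMatrix from a raw array."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    condition = condition or ["tumour"] * len(samples)
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples),
        scale=scale,
        condition=pd.Series(condition, index=samples),
    )


def make_survival(time, event, samples=None):
    samples = samples or [f"p{i}" for i in range(len(time))]
    return SurvivalTable(pd.DataFrame(
        {"time": np.asarray(time, dtype=float), "event": np.asarray(event, dtype=int)},
        index=pd.Index(samples, name="sample_id"),
    ))


def exponential_cohort(rng, x, beta, lam0=0.001, horizon=3000.0):
    """Exponential PH survival for a covariate vector; returns SurvivalTable."""
    rate = lam0 * np.exp(beta * np.asarray(x))
    t_event = rng.exponential(1.0 / rate)
    t_cens = rng.uniform(0.0, horizon, size=len(x))
    return make_survival(np.minimum(t_event, t_cens), (t_event <= t_cens).astype(int))


@pytest.fixture(scope="session")
def small_cohort():
    """One modest synthetic cohort shared by read-only tests."""
    from cupronet.simulate import default_cohort_config, simulate_cohort
    return simulate_cohort(default_cohort_config(11, n_tumour=250, n_normal=120))
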