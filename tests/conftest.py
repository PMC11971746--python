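import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from compmix.compositional import softmax_rows
from compmix.inference import MCMCConfig, fit
from compmix.model import ModelData, default_spec


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def quick_mcmc(seed: int = 1, **overrides) -> MCMCConfig:
    """Short sampler settings used throughout the test suite."""
    kwargs = dict(chains=1, warmup=200, draws=200, target_accept=0.9,
                  max_treedepth=9, seed=seed)
    kwargs.update(overrides)
    return MCMCConfig(**kwargs)


def small_gaussian_problem(seed=0, n=60, m=8, signal=(2, 2.0)):
    """A small BGLM-style dataset with one strong coefficient."""
    rng = np.random.default_rng(seed)
    table = softmax_rows(rng.standard_normal((n, m)))
    beta = np.zeros(m)
    idx, val = signal
    beta[idx] = val
    y = table.Z @ beta + rng.standard_normal(n)
    return table, beta, y


@pytest.fixture(scope="session")
def optimism_fits():
    """(loo deviance, in-sample deviance) for 10 small simulated BGLM fits."""
    from compmix.evaluation import compute_metrics

    out = []
    for rep in range(10):
        rng = np.random.default_rng(100 + rep)
        table = softmax_rows(rng.standard_normal((40, 6)))
        beta = np.array([1.0, -1.0, 0.0, 0.0, 0.0, 0.0])
        y = table.Z @ beta + rng.standard_normal(40)
        data = ModelData(y=y, Z=table.Z, family="gaussian")
        result = fit(default_spec("gaussian", "BGLM", 6), data,
                     quick_mcmc(seed=rep, warmup=120, draws=120))
        out.append((
            compute_metrics(result, data, mode="loo").deviance,
            compute_metrics(result, data, mode="in_sample").deviance,
        ))
    return out


@pytest.fixture(scope="session")
def brute_force_loo():
    """PSIS elpd vs exact leave-one-out (8 refits) on an n=8, m=2 model.

    The tiny-data posterior has heavy tails, so the fits use the package's
    own divergence remedy (half-t local/global priors) and 2 chains.
    Returns (psis_elpd, exact_elpd).
    """
    import math
    import warnings

    from scipy.special import logsumexp

    from compmix.evaluation import psis_loo

    rng = np.random.default_rng(5)
    n, m = 8, 2
    table = softmax_rows(rng.standard_normal((n, m)))
    y = 1.0 * rng.standard_normal(n)
    spec = default_spec("gaussian", "BGLM", m, local_prior="half-t",
                        global_prior="half-t", dispersion_prior_scale=1.0)
    data = ModelData(y=y, Z=table.Z, family="gaussian")
    cfg = dict(chains=2, warmup=300, target_accept=0.95, max_treedepth=9)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        full = fit(spec, data, MCMCConfig(seed=11, draws=1500, **cfg))
        loo = psis_loo(full, data)
        exact = 0.0
        for i in range(n):
            keep = np.arange(n) != i
            data_i = ModelData(y=y[keep], Z=table.Z[keep], family="gaussian")
            fit_i = fit(spec, data_i, MCMCConfig(seed=111 + i, draws=1000, **cfg))
            beta0 = fit_i.stacked("beta0")
            beta = fit_i.stacked("beta_star")
            phi = fit_i.stacked("dispersion")
            eta_i = beta0 + table.Z[i] @ beta.T
            ll = (
                -0.5 * math.log(2 * math.pi)
                - np.log(phi)
                - 0.5 * ((y[i] - eta_i) / phi) ** 2
            )
            exact += float(logsumexp(ll) - math.log(len(ll)))
    return loo.elpd_loo, exact


@pytest.fixture(scope="session")
def tiny_bglm_fit():
    """Session-cached tiny gaussian BGLM fit reused by several tests."""
    rng = np.random.default_rng(7)
    n, m = 50, 6
    table = softmax_rows(rng.standard_normal((n, m)))
    beta = np.zeros(m)
    beta[1] = 1.5
    y = table.Z @ beta + rng.standard_normal(n)
    data = ModelData(y=y, Z=table.Z, family="gaussian")
    spec = default_spec("gaussian", "BGLM", m)
    result = fit(spec, data, quick_mcmc(seed=3, warmup=150, draws=150))
    return result, data
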