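"""Predictive-quality metrics and approximate leave-one-out cross-validation.

Deviance is -2 * sum of pointwise log predictive density.  In ``loo`` mode
the pointwise density is the PSIS-smoothed importance-sampling estimate of
the leave-one-out predictive density and the predictive means are the
importance-weighted posterior means; ``in_sample`` mode uses the plain
posterior.  Pareto smoothing is delegated to :func:`arviz.psislw`.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
from scipy.special import expit, logsumexp
from sklearn.metrics import roc_auc_score

from compmix.inference import PosteriorFit
from compmix.model import ModelData

__all__ = [
    "MetricsReport",
    "LooResult",
    "deviance",
    "mse",
    "mae",
    "r2",
    "misclassification",
    "auc",
    "psis_loo",
    "compute_metrics",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
PARETO_K_WARN = 0.7


@dataclass
class MetricsReport:
    """One row of model-quality measures; fields are family-dependent."""

    mode: str  # "in_sample" | "loo"
    family: str
    deviance: float
    mse: float
    mae: Optional[float] = None
    r2: Optional[float] = None
    auc: Optional[float] = None
    misclassification: Optional[float] = None

    def to_dict(self) -> dict:
        return {k: v for k, v in asdict(self).items() if v is not None}


def deviance(y: np.ndarray, mu: np.ndarray, phi: float = 1.0, family: str = "gaussian") -> float:
    """-2 * sum log p(y_i | mu_i, phi) under the family's density.

    ``mu`` is on the mean scale (identity-link eta for gaussian, predicted
    probability for binomial).
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    if y.shape != mu.shape:
        raise ValueError("y and mu must have equal length")
    if family == "gaussian":
        if phi <= 0:
            raise ValueError("phi must be positive")
        ll = -0.5 * _LOG_2PI - np.log(phi) - 0.5 * ((y - mu) / phi) ** 2
    elif family == "binomial":
        mu = np.clip(mu, 1e-300, 1.0 - 1e-16)
        ll = y * np.log(mu) + (1.0 - y) * np.log1p(-mu)
    else:
        raise ValueError(f"unknown family {family!r}")
    return float(-2.0 * ll.sum())


def mse(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.mean((y - yhat) ** 2))


def mae(y: np.ndarray, yhat: np.ndarray) -> float:
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.mean(np.abs(y - yhat)))


def r2(y: np.ndarray, yhat: np.ndarray) -> float:
    """1 - SSE/SST about the mean of y."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise ValueError("r2 undefined for constant y")
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sst


def misclassification(y: np.ndarray, yhat: np.ndarray) -> float:
    """Fraction with |y_i - yhat_i| > 0.5 (the boundary counts as correct)."""
    y, yhat = np.asarray(y, float), np.asarray(yhat, float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("y must be binary 0/1")
    if y.shape != yhat.shape:
        raise ValueError("y and yhat must have equal length")
    return float(np.mean(np.abs(y - yhat) > 0.5))


def auc(y: np.ndarray, scores: np.ndarray) -> float:
    """Mann-Whitney AUC: P(random positive outscores random negative), ties 1/2."""
    y = np.asarray(y, float)
    if len(np.unique(y)) < 2:
        raise ValueError("AUC requires both classes present")
    return float(roc_auc_score(y, np.asarray(scores, float)))


@dataclass
class LooResult:
    elpd_pointwise: np.ndarray
    elpd_loo: float
    se: float
    pareto_k: np.ndarray
    loo_means: np.ndarray  # importance-weighted LOO predictive means
    log_weights: np.ndarray  # n x S, normalized smoothed log weights

    @property
    def deviance(self) -> float:
        return -2.0 * self.elpd_loo


def psis_loo(fit: PosteriorFit, data: ModelData) -> LooResult:
    """Pareto-smoothed importance-sampling LOO from one posterior sample.

    Raw importance ratios 1/p(y_i | theta^s) are tail-smoothed by a
    generalized-Pareto fit; elpd_i = log sum_s w_is p(y_i | theta^s).
    Warns when more than 10% of the shape diagnostics exceed 0.7.
    """
    from arviz.stats import psislw  # local import: arviz is slow to import

    log_lik = fit.log_lik_matrix  # (S, n)
    lw, k = psislw(-log_lik.T)  # input/ouput (n, S), lw normalized
    lw = np.asarray(lw)
    k = np.asarray(k)
    elpd_i = logsumexp(lw + log_lik.T, axis=1)

    # LOO predictive means under the smoothed weights
    beta0 = fit.stacked("beta0")
    beta = fit.stacked("beta_star")
    eta = beta0[None, :] + data.Z @ beta.T  # (n, S)
    if "u" in fit.draws:
        eta = eta + fit.stacked("u").T
    mu = eta if fit.spec.family == "gaussian" else expit(eta)
    w = np.exp(lw)
    loo_means = np.sum(w * mu, axis=1)

    frac_bad = float(np.mean(k > PARETO_K_WARN))
    if frac_bad > 0.10:
        warnings.warn(
            f"{frac_bad:.0%} of Pareto-k diagnostics exceed {PARETO_K_WARN}; "
            "PSIS-LOO may be unreliable, consider exact refits for those points",
            UserWarning,
            stacklevel=2,
        )
    n = len(elpd_i)
    return LooResult(
        elpd_pointwise=elpd_i,
        elpd_loo=float(elpd_i.sum()),
        se=float(np.sqrt(n * np.var(elpd_i))),
        pareto_k=k,
        loo_means=loo_means,
        log_weights=lw,
    )


def compute_metrics(fit: PosteriorFit, data: ModelData, mode: str = "loo") -> MetricsReport:
    """Assemble the family-appropriate metric set in the requested mode."""
    y = data.y
    if mode == "loo":
        loo = psis_loo(fit, data)
        yhat = loo.loo_means
        dev = loo.deviance
    elif mode == "in_sample":
        from compmix.inference import predict

        yhat = predict(fit, data.Z, include_u="u" in fit.draws)
        # in-sample deviance: -2 * sum log posterior-mean predictive density
        elpd_i = logsumexp(
            fit.log_lik_matrix - np.log(fit.log_lik_matrix.shape[0]), axis=0
        )
        dev = float(-2.0 * elpd_i.sum())
    else:
        raise ValueError("mode must be 'loo' or 'in_sample'")

    if data.family == "gaussian":
        return MetricsReport(
            mode=mode,
            family="gaussian",
            deviance=dev,
            mse=mse(y, yhat),
            mae=mae(y, yhat),
            r2=r2(y, yhat),
        )
    return MetricsReport(
        mode=mode,
        family="binomial",
        deviance=dev,
        mse=mse(y, yhat),
        auc=auc(y, yhat),
        misclassification=misclassification(y, yhat),
    )
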