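"""NUTS sampling, posterior summaries, and prediction.

A self-contained implementation of the No-U-Turn sampler (multinomial
variant, dual-averaging step-size adaptation, Stan-style warmup windows)
driving the analytic-gradient posterior from :mod:`compmix.model`.  The
mass matrix is dense for moderate dimensions -- the soft sum-to-zero
constraint and collinear compositional predictors create stiff directions
that are not axis-aligned -- and diagonal for large ones.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
import time
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.linalg import solve_triangular
from scipy.special import expit

from compmix.model import ModelData, ModelSpec, UnconstrainedPosterior

__all__ = [
    "MCMCConfig",
    "PosteriorFit",
    "fit",
    "posterior_summary",
    "predict",
    "split_rhat",
    "ess_bulk",
]

_DIVERGENCE_ENERGY = 1000.0
_DENSE_METRIC_MAX_DIM = 150


@dataclass
class MCMCConfig:
    chains: int = 4
    warmup: int = 1000
    draws: int = 1000
    target_accept: float = 0.95
    max_treedepth: int = 12
    seed: int = 0
    metric: str = "auto"  # "auto" | "diag" | "dense"

    def __post_init__(self) -> None:
        if min(self.chains, self.warmup, self.draws, self.max_treedepth) <= 0:
            raise ValueError("chains, warmup, draws, max_treedepth must be positive")
        if not 0.0 < self.target_accept < 1.0:
            raise ValueError("target_accept must lie in (0, 1)")
        if self.metric not in ("auto", "diag", "dense"):
            raise ValueError("metric must be 'auto', 'diag' or 'dense'")


@dataclass
class PosteriorFit:
    """Posterior draws (chains x draws x ...), diagnostics, point estimates."""

    draws: dict[str, np.ndarray]
    log_lik: np.ndarray  # chains x draws x n
    spec: ModelSpec
    config: MCMCConfig
    divergences: int
    step_sizes: list[float]
    elapsed: float
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.log_lik.shape[0]

    @property
    def n_draws(self) -> int:
        return self.log_lik.shape[1]

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened into the first axis."""
        a = self.draws[name]
        return a.reshape(-1, *a.shape[2:])

    @property
    def log_lik_matrix(self) -> np.ndarray:
        """Pointwise log likelihood, (total draws) x n."""
        return self.log_lik.reshape(-1, self.log_lik.shape[-1])

    @property
    def point_estimates(self) -> dict[str, np.ndarray | float]:
        out: dict[str, np.ndarray | float] = {}
        for name, a in self.draws.items():
            mean = a.mean(axis=(0, 1))
            out[name] = float(mean) if np.ndim(mean) == 0 else mean
        return out


# ---------------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------------

def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction for one scalar parameter.

    ``x`` is chains x draws; each chain is split in half, so a single
    chain still yields a meaningful statistic.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    d = x.shape[1] // 2
    if d < 2:
        return float("nan")
    halves = np.concatenate([x[:, :d], x[:, d : 2 * d]], axis=0)
    chain_means = halves.mean(axis=1)
    chain_vars = halves.var(axis=1, ddof=1)
    w = chain_vars.mean()
    b = d * chain_means.var(ddof=1)
    if w <= 0:
        return float("nan") if b > 0 else 1.0
    var_plus = (d - 1) / d * w + b / d
    return float(math.sqrt(var_plus / w))


def ess_bulk(x: np.ndarray) -> float:
    """Effective sample size from pairwise-summed autocorrelations (Geyer)."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    c, d = x.shape
    if d < 4:
        return float("nan")
    acov = np.empty((c, d))
    for k in range(c):
        y = x[k] - x[k].mean()
        nfft = int(2 ** math.ceil(math.log2(2 * d)))
        f = np.fft.rfft(y, nfft)
        ac = np.fft.irfft(f * np.conjugate(f), nfft)[:d].real
        acov[k] = ac / d
    var_within = acov[:, 0].mean() * d / (d - 1.0)
    if c > 1:
        var_plus = var_within * (d - 1.0) / d + x.mean(axis=1).var(ddof=1)
    else:
        var_plus = var_within
    if var_plus <= 0:
        return float("nan")
    rho = 1.0 - (var_within - acov.mean(axis=0)) / var_plus
    # Geyer initial monotone positive sequence on paired sums
    t = 1
    s = 0.0
    prev = float("inf")
    while t + 1 < d:
        pair = rho[t] + rho[t + 1]
        if pair < 0:
            break
        pair = min(pair, prev)
        s += pair
        prev = pair
        t += 2
    ess = c * d / (1.0 + 2.0 * s)
    return float(min(ess, c * d))


# ---------------------------------------------------------------------------
# NUTS internals
# ---------------------------------------------------------------------------

class _DiagMetric:
    """Diagonal mass matrix: inv holds the per-coordinate inverse mass."""

    def __init__(self, dim: int):
        self.dim = dim
        self.inv = np.ones(dim)
        self._sqrt_mass = np.ones(dim)

    def update(self, cov: np.ndarray) -> None:
        var = np.diag(cov) if cov.ndim == 2 else cov
        self.inv = var
        self._sqrt_mass = 1.0 / np.sqrt(var)

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal(self.dim) * self._sqrt_mass

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv * p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.dot(p, self.inv * p))


class _DenseMetric:
    """Dense mass matrix: inv is the posterior covariance estimate.

    Handles stiff directions that are not axis-aligned (e.g. the soft
    sum-to-zero constraint, near-collinear compositional predictors); only
    used for moderate dimensions where the O(dim^2) work is negligible.
    """

    def __init__(self, dim: int):
        self.dim = dim
        self.inv = np.eye(dim)
        self._chol = np.eye(dim)  # chol(inv), lower

    def update(self, cov: np.ndarray) -> None:
        if cov.ndim == 1:
            cov = np.diag(cov)
        for jitter in (0.0, 1e-8, 1e-6, 1e-4):
            try:
                chol = np.linalg.cholesky(cov + jitter * np.eye(self.dim))
                break
            except np.linalg.LinAlgError:
                continue
        else:  # pragma: no cover - extreme degeneracy
            return
        self.inv = cov + 0.0
        self._chol = chol

    def sample_momentum(self, rng: np.random.Generator) -> np.ndarray:
        # p ~ N(0, inv^{-1}); with inv = L L', p = L^{-T} z has cov L^{-T}L^{-1}
        z = rng.standard_normal(self.dim)
        return solve_triangular(self._chol, z, lower=True, trans="T")

    def velocity(self, p: np.ndarray) -> np.ndarray:
        return self.inv @ p

    def kinetic(self, p: np.ndarray) -> float:
        return 0.5 * float(np.dot(p, self.inv @ p))


def _make_metric(kind: str, dim: int):
    if kind == "dense" or (kind == "auto" and dim <= _DENSE_METRIC_MAX_DIM):
        return _DenseMetric(dim)
    return _DiagMetric(dim)


class _Tree:
    """State bundle for one NUTS trajectory subtree."""

    __slots__ = (
        "q_minus", "p_minus", "g_minus", "q_plus", "p_plus", "g_plus",
        "q_prop", "logp_prop", "log_sum_w", "sum_alpha", "n_alpha",
        "diverged", "turned",
    )


def _leapfrog(post, q, p, grad, eps, metric):
    p1 = p + 0.5 * eps * grad
    q1 = q + eps * metric.velocity(p1)
    logp1, grad1 = post.logp_grad(q1)
    p1 = p1 + 0.5 * eps * grad1
    return q1, p1, logp1, grad1


def _is_turning(q_minus, q_plus, p_minus, p_plus, metric) -> bool:
    dq = q_plus - q_minus
    return (np.dot(dq, metric.velocity(p_minus)) < 0.0) or (
        np.dot(dq, metric.velocity(p_plus)) < 0.0
    )


def _build_tree(post, q, p, grad, depth, direction, eps, h0, metric, rng) -> _Tree:
    t = _Tree()
    if depth == 0:
        q1, p1, logp1, grad1 = _leapfrog(post, q, p, grad, direction * eps, metric)
        h = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else float("inf")
        log_w = h0 - h
        t.q_minus = t.q_plus = t.q_prop = q1
        t.p_minus = t.p_plus = p1
        t.g_minus = t.g_plus = grad1
        t.logp_prop = logp1
        t.log_sum_w = log_w
        t.sum_alpha = min(1.0, math.exp(min(0.0, log_w)))
        t.n_alpha = 1
        t.diverged = (h - h0) > _DIVERGENCE_ENERGY or not np.isfinite(h)
        t.turned = False
        return t

    first = _build_tree(post, q, p, grad, depth - 1, direction, eps, h0, metric, rng)
    if first.diverged or first.turned:
        return first
    if direction == 1:
        second = _build_tree(
            post, first.q_plus, first.p_plus, first.g_plus, depth - 1, direction,
            eps, h0, metric, rng,
        )
        first.q_plus = second.q_plus
        first.p_plus = second.p_plus
        first.g_plus = second.g_plus
    else:
        second = _build_tree(
            post, first.q_minus, first.p_minus, first.g_minus, depth - 1, direction,
            eps, h0, metric, rng,
        )
        first.q_minus = second.q_minus
        first.p_minus = second.p_minus
        first.g_minus = second.g_minus

    total = np.logaddexp(first.log_sum_w, second.log_sum_w)
    if math.log(rng.random() + 1e-300) < second.log_sum_w - total:
        first.q_prop = second.q_prop
        first.logp_prop = second.logp_prop
    first.log_sum_w = total
    first.sum_alpha += second.sum_alpha
    first.n_alpha += second.n_alpha
    first.diverged = second.diverged
    first.turned = second.turned or _is_turning(
        first.q_minus, first.q_plus, first.p_minus, first.p_plus, metric
    )
    return first


def _nuts_step(post, q, logp, grad, eps, metric, max_depth, rng):
    p0 = metric.sample_momentum(rng)
    h0 = -logp + metric.kinetic(p0)
    q_minus = q_plus = q
    p_minus = p_plus = p0
    g_minus = g_plus = grad
    q_prop, logp_prop = q, logp
    log_sum_w = 0.0
    sum_alpha = 0.0
    n_alpha = 0
    diverged = False
    for depth in range(max_depth):
        direction = 1 if rng.random() < 0.5 else -1
        if direction == 1:
            sub = _build_tree(post, q_plus, p_plus, g_plus, depth, 1, eps, h0, metric, rng)
            q_plus, p_plus, g_plus = sub.q_plus, sub.p_plus, sub.g_plus
        else:
            sub = _build_tree(post, q_minus, p_minus, g_minus, depth, -1, eps, h0, metric, rng)
            q_minus, p_minus, g_minus = sub.q_minus, sub.p_minus, sub.g_minus
        sum_alpha += sub.sum_alpha
        n_alpha += sub.n_alpha
        if sub.diverged:
            diverged = True
            break
        if sub.turned:
            break
        # progressive multinomial sampling: accept subtree proposal
        if math.log(rng.random() + 1e-300) < sub.log_sum_w - log_sum_w:
            q_prop, logp_prop = sub.q_prop, sub.logp_prop
        log_sum_w = np.logaddexp(log_sum_w, sub.log_sum_w)
        if _is_turning(q_minus, q_plus, p_minus, p_plus, metric):
            break
    accept_stat = sum_alpha / max(n_alpha, 1)
    return q_prop, logp_prop, accept_stat, diverged


def _find_initial_step(post, q, logp, grad, metric, rng) -> float:
    eps = 1.0
    p0 = metric.sample_momentum(rng)
    h0 = -logp + metric.kinetic(p0)
    _, p1, logp1, _ = _leapfrog(post, q, p0, grad, eps, metric)
    h1 = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else float("inf")
    delta = h0 - h1
    direction = 1 if delta > math.log(0.5) else -1
    for _ in range(100):
        eps *= 2.0**direction
        _, p1, logp1, _ = _leapfrog(post, q, p0, grad, eps, metric)
        h1 = -logp1 + metric.kinetic(p1) if np.isfinite(logp1) else float("inf")
        delta = h0 - h1
        if (direction == 1 and delta <= math.log(0.5)) or (
            direction == -1 and delta >= math.log(0.5)
        ):
            break
    return max(eps, 1e-10)


def _warmup_windows(warmup: int) -> list[tuple[int, int]]:
    """(start, end) of the expanding covariance-estimation windows."""
    init = max(int(0.15 * warmup), 1)
    term = max(int(0.1 * warmup), 1)
    windows = []
    start = init
    size = 25
    while start < warmup - term:
        end = min(start + size, warmup - term)
        if (warmup - term - end) < size * 2:
            end = warmup - term
        windows.append((start, end))
        start = end
        size *= 2
    return windows


def _sample_chain(post, q0, mcmc: MCMCConfig, rng: np.random.Generator):
    dim = len(q0)
    metric = _make_metric(mcmc.metric, dim)
    dense = isinstance(metric, _DenseMetric)
    logp, grad = post.logp_grad(q0)
    if not np.isfinite(logp):
        raise ValueError("non-finite log posterior at the initial position")
    q = q0

    eps = _find_initial_step(post, q, logp, grad, metric, rng)
    mu = math.log(10.0 * eps)
    log_eps_bar = 0.0
    h_bar = 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    adapt_count = 0

    windows = _warmup_windows(mcmc.warmup)
    win_idx = 0
    welford_n = 0
    welford_mean = np.zeros(dim)
    welford_m2 = np.zeros((dim, dim)) if dense else np.zeros(dim)

    samples = np.empty((mcmc.draws, dim))
    divergences = 0

    for it in range(mcmc.warmup + mcmc.draws):
        warming = it < mcmc.warmup
        q, logp, accept_stat, diverged = _nuts_step(
            post, q, logp, grad, eps, metric, mcmc.max_treedepth, rng
        )
        logp, grad = post.logp_grad(q)
        if warming:
            adapt_count += 1
            frac = 1.0 / (adapt_count + t0)
            h_bar = (1.0 - frac) * h_bar + frac * (mcmc.target_accept - accept_stat)
            log_eps = mu - math.sqrt(adapt_count) / gamma * h_bar
            weight = adapt_count ** (-kappa)
            log_eps_bar = weight * log_eps + (1.0 - weight) * log_eps_bar
            eps = math.exp(log_eps)
            if win_idx < len(windows):
                start, end = windows[win_idx]
                if start <= it < end:
                    welford_n += 1
                    delta = q - welford_mean
                    welford_mean += delta / welford_n
                    if dense:
                        welford_m2 += np.outer(delta, q - welford_mean)
                    else:
                        welford_m2 += delta * (q - welford_mean)
                if it == end - 1:
                    if welford_n > 4:
                        cov = welford_m2 / (welford_n - 1)
                        shrink = welford_n / (welford_n + 5.0)
                        if dense:
                            # shrink off-diagonals toward the diagonal so that
                            # genuinely tiny-variance directions (the soft
                            # sum-to-zero constraint) stay tiny
                            diag = np.diag(cov).copy()
                            cov = shrink * cov
                            cov[np.diag_indices_from(cov)] = diag * (
                                shrink + (1.0 - shrink)
                            ) + 1e-10 * max(diag.mean(), 1e-8)
                        else:
                            cov = shrink * cov + 1e-3 * (5.0 / (welford_n + 5.0))
                        metric.update(cov)
                    welford_n = 0
                    welford_mean = np.zeros(dim)
                    welford_m2 = np.zeros((dim, dim)) if dense else np.zeros(dim)
                    win_idx += 1
                    # restart dual averaging around the current step size
                    mu = math.log(10.0 * eps)
                    log_eps_bar = math.log(eps)
                    h_bar = 0.0
                    adapt_count = 0
            if it == mcmc.warmup - 1:
                eps = math.exp(log_eps_bar)
        else:
            if diverged:
                divergences += 1
            samples[it - mcmc.warmup] = q
    return samples, divergences, eps


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def fit(spec: ModelSpec, data: ModelData, mcmc: MCMCConfig) -> PosteriorFit:
    """Sample the joint posterior by NUTS and collect draws and diagnostics."""
    post = UnconstrainedPosterior(data, spec)
    seeds = np.random.SeedSequence(mcmc.seed).spawn(mcmc.chains)
    t_start = time.perf_counter()
    all_samples = []
    total_div = 0
    step_sizes = []
    for c in range(mcmc.chains):
        rng = np.random.default_rng(seeds[c])
        q0 = post.initial_position(rng)
        samples, div, eps = _sample_chain(post, q0, mcmc, rng)
        all_samples.append(samples)
        total_div += div
        step_sizes.append(eps)
    elapsed = time.perf_counter() - t_start

    n, m = data.n, data.m
    C, S = mcmc.chains, mcmc.draws
    draws: dict[str, np.ndarray] = {
        "beta0": np.empty((C, S)),
        "beta_star": np.empty((C, S, m)),
        "tau": np.empty((C, S)),
        "lam": np.empty((C, S, m)),
        "c2": np.empty((C, S)),
    }
    if post.has_u:
        draws["u"] = np.empty((C, S, n))
        draws["re_variance"] = np.empty((C, S))
    if post.has_phi:
        draws["dispersion"] = np.empty((C, S))
    log_lik = np.empty((C, S, n))

    for c in range(C):
        for s in range(S):
            st = post.constrain(all_samples[c][s])
            draws["beta0"][c, s] = st.beta0
            draws["beta_star"][c, s] = st.beta_star
            draws["tau"][c, s] = st.tau
            draws["lam"][c, s] = st.lam
            draws["c2"][c, s] = st.c2
            if post.has_u:
                draws["u"][c, s] = st.u
                draws["re_variance"][c, s] = st.re_variance
            if post.has_phi:
                draws["dispersion"][c, s] = st.dispersion
            log_lik[c, s] = post.pointwise_loglik(all_samples[c][s])

    total_draws = C * S
    div_frac = total_div / total_draws
    if div_frac > 0.10:
        warnings.warn(
            f"{total_div}/{total_draws} divergent transitions ({div_frac:.0%}); "
            "consider half-t local/global priors (local_prior='half-t')",
            UserWarning,
            stacklevel=2,
        )

    scalars = {k: draws[k] for k in ("beta0", "tau", "c2") if k in draws}
    diagnostics = {
        "divergences": total_div,
        "divergence_fraction": div_frac,
        "step_sizes": list(map(float, step_sizes)),
        "rhat": {k: split_rhat(v) for k, v in scalars.items()},
        "ess": {k: ess_bulk(v) for k, v in scalars.items()},
        "seed": mcmc.seed,
    }
    diagnostics["max_rhat_scalar"] = max(diagnostics["rhat"].values())

    return PosteriorFit(
        draws=draws,
        log_lik=log_lik,
        spec=spec,
        config=mcmc,
        divergences=total_div,
        step_sizes=list(map(float, step_sizes)),
        elapsed=elapsed,
        diagnostics=diagnostics,
    )


def _flat_names(fitdraws: dict[str, np.ndarray]) -> list[tuple[str, str, tuple]]:
    out = []
    for name, a in fitdraws.items():
        if a.ndim == 2:
            out.append((name, name, ()))
        else:
            for k in range(a.shape[2]):
                out.append((f"{name}[{k + 1}]", name, (k,)))
    return out


def posterior_summary(fit: PosteriorFit) -> pd.DataFrame:
    """Per-parameter mean, sd, central 95% interval, split-Rhat and ESS."""
    rows = []
    for label, name, idx in _flat_names(fit.draws):
        a = fit.draws[name]
        x = a[(slice(None), slice(None)) + idx]
        flat = x.ravel()
        rows.append(
            {
                "parameter": label,
                "mean": float(flat.mean()),
                "sd": float(flat.std(ddof=1)) if flat.size > 1 else 0.0,
                "q2.5": float(np.quantile(flat, 0.025)),
                "q97.5": float(np.quantile(flat, 0.975)),
                "rhat": split_rhat(x),
                "ess": ess_bulk(x),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")


def predict(
    fit: PosteriorFit,
    Z_new: np.ndarray,
    include_u: bool = False,
    draws_mean: bool = True,
) -> np.ndarray:
    """Posterior-mean predictions g^{-1}(eta) for new (or training) samples.

    For new samples the random effect is set to its prior mean 0; pass
    ``include_u=True`` only for in-sample prediction with a BCGLMM fit.
    """
    Z_new = np.asarray(Z_new, dtype=float)
    beta0 = fit.stacked("beta0")  # (S,)
    beta = fit.stacked("beta_star")  # (S, m)
    if Z_new.shape[1] != beta.shape[1]:
        raise ValueError(
            f"taxon mismatch: model has {beta.shape[1]} taxa, input has {Z_new.shape[1]}"
        )
    eta = beta0[None, :] + Z_new @ beta.T  # (n_new, S)
    if include_u:
        if "u" not in fit.draws:
            raise ValueError("fit has no random effects; include_u is only valid for BCGLMM")
        u = fit.stacked("u")  # (S, n)
        if u.shape[1] != Z_new.shape[0]:
            raise ValueError("include_u requires Z_new to be the training design")
        eta = eta + u.T
    mu = eta if fit.spec.family == "gaussian" else expit(eta)
    return mu.mean(axis=1) if draws_mean else mu
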