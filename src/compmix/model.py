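"""Joint log posterior for the three model variants.

Variants
--------
``BGLM``
    log-contrast regression with a regularized-horseshoe prior and
    independent half-Cauchy (or half-t) local scales.
``BCGLM``
    the local scales are log-transformed (psi = log lambda) and given a
    pairwise-difference (intrinsic autoregressive) prior over a taxon
    similarity graph, so similar taxa share shrinkage.
``BCGLMM``
    additionally a per-sample random effect u ~ MVN(0, re_variance * K)
    with K a normalized sample kernel.

Priors (defaults): beta0 ~ t(3, 0, 10); tau ~ half-Cauchy(0, 1);
lambda_j ~ half-Cauchy(0, 1); c^2 ~ Inv-Gamma(slab_df/2,
slab_df*slab_scale2/2) with slab_df=4, slab_scale2=2; dispersion and the
random-effect variance ~ half-t(3, 0, 10).  The slope vector carries a
soft sum-to-zero constraint sum(beta*) ~ N(0, sd=0.001*m).  The improper
pairwise-difference prior is identified by the same soft-centering device
applied to sum(psi).

Half-t(3) replacements: for m >= 500 the heavy-tailed Cauchy local priors
cause divergent transitions and are swapped for half-t(3); for binomial
outcomes the global scale likewise (data-separation remedy).  See
:func:`default_spec`.

The sampler works on an unconstrained, non-centered parameterization
(:class:`UnconstrainedPosterior`) with analytic gradients;
:func:`joint_logpost` is the plain constrained-space density used for
testing and component attribution.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np
from scipy.special import expit, gammaln

from compmix.kernels import IARGraph, PSDKernel

__all__ = [
    "ModelSpec",
    "ModelData",
    "ParameterState",
    "UnconstrainedPosterior",
    "default_spec",
    "regularized_local_scale",
    "iar_logpdf",
    "soft_sum_to_zero_logpdf",
    "linear_predictor",
    "random_effect_draw",
    "joint_logpost",
]

_LOG_2PI = math.log(2.0 * math.pi)

FAMILIES = ("gaussian", "binomial")
VARIANTS = ("BGLM", "BCGLM", "BCGLMM")


@dataclass
class ModelSpec:
    """Model family, variant, and prior hyperparameters."""

    family: str = "gaussian"
    variant: str = "BCGLMM"
    slab_df: float = 4.0
    slab_scale2: float = 2.0
    global_scale: float = 1.0
    local_prior: str = "half-cauchy"  # "half-cauchy" | "half-t" (df 3)
    global_prior: str = "half-cauchy"
    sum_constraint_scale_coef: float = 0.001
    intercept_prior_scale: float = 10.0  # t(3, 0, scale)
    dispersion_prior_scale: float = 10.0  # half-t(3, 0, scale)
    re_variance_prior_scale: float = 10.0  # half-t(3, 0, scale)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")
        if self.slab_df <= 0 or self.slab_scale2 <= 0:
            raise ValueError("slab_df and slab_scale2 must be positive")
        for name in ("global_scale", "sum_constraint_scale_coef", "intercept_prior_scale",
                     "dispersion_prior_scale", "re_variance_prior_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.local_prior not in ("half-cauchy", "half-t"):
            raise ValueError("local_prior must be 'half-cauchy' or 'half-t'")
        if self.global_prior not in ("half-cauchy", "half-t"):
            raise ValueError("global_prior must be 'half-cauchy' or 'half-t'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


def default_spec(family: str, variant: str, m: int, **overrides) -> ModelSpec:
    """ModelSpec with the documented half-t replacement rules applied.

    Local scales switch to half-t(3) when ``m >= 500``; the global scale
    switches to half-t(3) for binomial outcomes.
    """
    kwargs = dict(family=family, variant=variant)
    if m >= 500:
        kwargs["local_prior"] = "half-t"
    if family == "binomial":
        kwargs["global_prior"] = "half-t"
    kwargs.update(overrides)
    return ModelSpec(**kwargs)


@dataclass
class ModelData:
    """Observed data plus the structures a variant requires."""

    y: np.ndarray
    Z: np.ndarray
    family: str = "gaussian"
    graph: Optional[IARGraph] = None
    kernel: Optional[PSDKernel] = None

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[0] != len(self.y):
            raise ValueError("Z must be n x m with n matching the outcome length")
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.family == "binomial" and not np.all(np.isin(self.y, (0.0, 1.0))):
            raise ValueError("binomial outcomes must be coded 0/1")
        if self.graph is not None and self.graph.n_nodes != self.Z.shape[1]:
            raise ValueError("IAR graph node count must equal the number of taxa")
        if self.kernel is not None and self.kernel.size != len(self.y):
            raise ValueError("sample kernel size must equal the number of samples")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.Z.shape[1]


@dataclass
class ParameterState:
    """One point in constrained parameter space."""

    beta0: float
    beta_star: np.ndarray
    tau: float
    lam: np.ndarray
    c2: float
    u: Optional[np.ndarray] = None
    re_variance: Optional[float] = None
    dispersion: Optional[float] = None

    def __post_init__(self) -> None:
        self.beta_star = np.asarray(self.beta_star, dtype=float)
        self.lam = np.asarray(self.lam, dtype=float)
        if np.any(self.lam <= 0) or self.tau <= 0 or self.c2 <= 0:
            raise ValueError("tau, lam, c2 must be positive")
        if self.u is not None:
            self.u = np.asarray(self.u, dtype=float)
        if self.re_variance is not None and self.re_variance <= 0:
            raise ValueError("re_variance must be positive")
        if self.dispersion is not None and self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    @property
    def psi(self) -> np.ndarray:
        return np.log(self.lam)

    @property
    def lam_tilde(self) -> np.ndarray:
        return regularized_local_scale(self.lam, self.tau, self.c2)


# ---------------------------------------------------------------------------
# closed-form components
# ---------------------------------------------------------------------------

def regularized_local_scale(lam: np.ndarray, tau: float, c2: float) -> np.ndarray:
    """lam_tilde_j = sqrt(c2 lam_j^2 / (c2 + tau^2 lam_j^2)).

    The prior sd of slope j is tau * lam_tilde_j: it behaves like the plain
    horseshoe (tau*lam small) but saturates at the slab scale sqrt(c2).
    """
    lam = np.asarray(lam, dtype=float)
    if np.any(lam <= 0) or tau <= 0 or c2 <= 0:
        raise ValueError("lam, tau, c2 must be positive")
    l2 = lam**2
    return np.sqrt(c2 * l2 / (c2 + tau**2 * l2))


def iar_logpdf(psi: np.ndarray, graph: IARGraph) -> float:
    """Pairwise-difference log density -1/2 sum_{i~j} w_ij (psi_i - psi_j)^2.

    Improper (shift invariant); identification via soft-centering of
    sum(psi) is added separately in the joint.
    """
    psi = np.asarray(psi, dtype=float)
    if len(psi) != graph.n_nodes:
        raise ValueError("psi length must match graph node count")
    if np.any(graph.w < 0):
        raise ValueError("IAR weights must be nonnegative")
    diff = psi[graph.i] - psi[graph.j]
    return float(-0.5 * np.sum(graph.w * diff**2))


def soft_sum_to_zero_logpdf(vec: np.ndarray, m: int | None = None, scale_coef: float = 0.001) -> float:
    """Log density of N(0, sd = scale_coef * m) evaluated at sum(vec)."""
    vec = np.asarray(vec, dtype=float)
    if m is None:
        m = len(vec)
    sd = scale_coef * m
    s = vec.sum()
    return float(-0.5 * _LOG_2PI - math.log(sd) - 0.5 * (s / sd) ** 2)


def linear_predictor(state: ParameterState, Z: np.ndarray, include_u: bool = True) -> np.ndarray:
    """eta = beta0 + Z beta* (+ u)."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != len(state.beta_star):
        raise ValueError("Z column count must match beta_star length")
    eta = state.beta0 + Z @ state.beta_star
    if include_u and state.u is not None:
        if len(state.u) != Z.shape[0]:
            raise ValueError("u length must match sample count")
        eta = eta + state.u
    return eta


def random_effect_draw(z_raw: np.ndarray, kernel_factor: np.ndarray, re_variance: float) -> np.ndarray:
    """Non-centered random effect u = sqrt(re_variance) * L @ z_raw."""
    z_raw = np.asarray(z_raw, dtype=float)
    if re_variance < 0:
        raise ValueError("re_variance must be nonnegative")
    if kernel_factor.shape[1] != len(z_raw):
        raise ValueError("kernel factor and z_raw are non-conformable")
    return math.sqrt(re_variance) * (kernel_factor @ z_raw)


# ---------------------------------------------------------------------------
# scalar prior densities (and their d/dx on the log scale where needed)
# ---------------------------------------------------------------------------

def _half_cauchy_logpdf(x: float | np.ndarray, scale: float) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.sum(math.log(2.0 / math.pi) - math.log(scale) - np.log1p((x / scale) ** 2)))


def _half_t3_logpdf(x: float | np.ndarray, scale: float) -> float:
    # half-t with 3 df: 2 * t_3(x | 0, scale) on x > 0
    x = np.asarray(x, dtype=float)
    const = (
        math.log(2.0)
        + gammaln(2.0)
        - gammaln(1.5)
        - 0.5 * math.log(3.0 * math.pi)
        - math.log(scale)
    )
    return float(np.sum(const - 2.0 * np.log1p((x / scale) ** 2 / 3.0)))


def _t3_logpdf(x: float, scale: float) -> float:
    const = gammaln(2.0) - gammaln(1.5) - 0.5 * math.log(3.0 * math.pi) - math.log(scale)
    return const - 2.0 * math.log1p((x / scale) ** 2 / 3.0)


def _invgamma_logpdf(x: float, a: float, b: float) -> float:
    return a * math.log(b) - gammaln(a) - (a + 1.0) * math.log(x) - b / x


def _gaussian_loglik(y: np.ndarray, eta: np.ndarray, phi: float) -> float:
    r = y - eta
    n = len(y)
    return float(-0.5 * n * _LOG_2PI - n * math.log(phi) - 0.5 * np.dot(r, r) / phi**2)


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # sum y*eta - log(1 + exp(eta)), stable
    return float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())


def pointwise_loglik(state: ParameterState, data: ModelData, include_u: bool = True) -> np.ndarray:
    """Per-observation log likelihood at a constrained state."""
    eta = linear_predictor(state, data.Z, include_u=include_u)
    if data.family == "gaussian":
        phi = state.dispersion if state.dispersion is not None else 1.0
        return -0.5 * _LOG_2PI - math.log(phi) - 0.5 * ((data.y - eta) / phi) ** 2
    return data.y * eta - np.logaddexp(0.0, eta)


def joint_logpost(state: ParameterState, data: ModelData, spec: ModelSpec) -> float:
    """Sum of likelihood and all prior components in constrained space.

    Raises a ValueError naming the offending component if any term is
    non-finite.
    """
    m = data.m
    parts: dict[str, float] = {}

    eta = linear_predictor(state, data.Z, include_u=spec.variant == "BCGLMM")
    if data.family == "gaussian":
        phi = state.dispersion if state.dispersion is not None else 1.0
        parts["likelihood"] = _gaussian_loglik(data.y, eta, phi)
        parts["dispersion_prior"] = _half_t3_logpdf(phi, spec.dispersion_prior_scale)
    else:
        parts["likelihood"] = _bernoulli_loglik(data.y, eta)

    parts["sum_to_zero"] = soft_sum_to_zero_logpdf(
        state.beta_star, m, spec.sum_constraint_scale_coef
    )
    parts["intercept_prior"] = _t3_logpdf(state.beta0, spec.intercept_prior_scale)

    sd_beta = state.tau * state.lam_tilde
    parts["beta_prior"] = float(
        np.sum(-0.5 * _LOG_2PI - np.log(sd_beta) - 0.5 * (state.beta_star / sd_beta) ** 2)
    )

    if spec.global_prior == "half-cauchy":
        parts["tau_prior"] = _half_cauchy_logpdf(state.tau, spec.global_scale)
    else:
        parts["tau_prior"] = _half_t3_logpdf(state.tau, spec.global_scale)

    if spec.variant == "BGLM":
        if spec.local_prior == "half-cauchy":
            parts["lambda_prior"] = _half_cauchy_logpdf(state.lam, 1.0)
        else:
            parts["lambda_prior"] = _half_t3_logpdf(state.lam, 1.0)
    else:
        if data.graph is None:
            raise ValueError(f"variant {spec.variant} requires an IAR graph")
        parts["lambda_prior"] = iar_logpdf(state.psi, data.graph) + soft_sum_to_zero_logpdf(
            state.psi, m, spec.sum_constraint_scale_coef
        )

    parts["slab_prior"] = _invgamma_logpdf(
        state.c2, spec.slab_df / 2.0, spec.slab_df * spec.slab_scale2 / 2.0
    )

    if spec.variant == "BCGLMM":
        if data.kernel is None:
            raise ValueError("variant BCGLMM requires a sample kernel")
        if state.u is None or state.re_variance is None:
            raise ValueError("BCGLMM state requires u and re_variance")
        K = data.kernel.normalized
        v = state.re_variance
        sol = np.linalg.solve(v * K, state.u)
        ld = data.kernel.logdet(v, normalized=True)
        parts["random_effect"] = float(
            -0.5 * data.n * _LOG_2PI - 0.5 * ld - 0.5 * np.dot(state.u, sol)
        )
        parts["re_variance_prior"] = _half_t3_logpdf(v, spec.re_variance_prior_scale)

    total = 0.0
    for name, value in parts.items():
        if not np.isfinite(value):
            raise ValueError(f"non-finite log-posterior component: {name} = {value}")
        total += value
    return total


# ---------------------------------------------------------------------------
# unconstrained, non-centered posterior with analytic gradients
# ---------------------------------------------------------------------------

@dataclass
class _Layout:
    """Index layout of the flat unconstrained vector."""

    m: int
    n: int
    has_u: bool
    has_phi: bool

    def __post_init__(self) -> None:
        m = self.m
        self.b0 = 0
        self.zb = slice(1, 1 + m)
        self.lt = 1 + m
        self.psi = slice(2 + m, 2 + 2 * m)
        self.lc = 2 + 2 * m
        pos = 3 + 2 * m
        if self.has_u:
            self.zu = slice(pos, pos + self.n)
            pos += self.n
            self.lv = pos
            pos += 1
        if self.has_phi:
            self.lphi = pos
            pos += 1
        self.dim = pos


class UnconstrainedPosterior:
    """Log posterior and gradient on the sampler's unconstrained scale.

    Parameterization: ``beta* = zb * tau * lam_tilde`` with ``zb``
    standard normal (non-centered), ``tau = exp(lt)``, ``lam = exp(psi)``,
    ``c2 = exp(lc)``, ``u = sqrt(v) L zu`` with ``v = exp(lv)`` and ``L``
    the (normalized) kernel factor, ``phi = exp(lphi)``.  All positivity
    Jacobians are included.
    """

    def __init__(self, data: ModelData, spec: ModelSpec):
        if spec.family != data.family:
            raise ValueError("spec and data families disagree")
        self.data = data
        self.spec = spec
        self.has_u = spec.variant == "BCGLMM"
        self.has_phi = data.family == "gaussian"
        self.layout = _Layout(data.m, data.n, self.has_u, self.has_phi)
        self.use_iar = spec.variant in ("BCGLM", "BCGLMM")
        if self.use_iar:
            if data.graph is None:
                raise ValueError(f"variant {spec.variant} requires an IAR graph")
            self._lap = data.graph.laplacian()
        if self.has_u:
            if data.kernel is None:
                raise ValueError("variant BCGLMM requires a sample kernel")
            self._L = data.kernel.normalized_factor  # symmetric: L.T == L
        sig_b = spec.sum_constraint_scale_coef * data.m
        self._sum_var = sig_b**2
        self._slab_a = spec.slab_df / 2.0
        self._slab_b = spec.slab_df * spec.slab_scale2 / 2.0
        # hot-loop constants and contiguous transposes
        self._ZT = np.ascontiguousarray(data.Z.T)
        self._Z = np.ascontiguousarray(data.Z)
        self._ht3_const = (
            math.log(2.0) + float(gammaln(2.0) - gammaln(1.5)) - 0.5 * math.log(3.0 * math.pi)
        )
        self._slab_const = self._slab_a * math.log(self._slab_b) - float(gammaln(self._slab_a))
        self._empty = np.zeros((0, 0))
        try:
            from compmix._fastgrad import NUMBA_AVAILABLE

            self._use_fast = NUMBA_AVAILABLE
        except Exception:  # pragma: no cover
            self._use_fast = False

    @property
    def dim(self) -> int:
        return self.layout.dim

    # -- state transforms ----------------------------------------------------

    def constrain(self, q: np.ndarray) -> ParameterState:
        lay = self.layout
        tau = math.exp(q[lay.lt])
        lam = np.exp(q[lay.psi])
        c2 = math.exp(q[lay.lc])
        lam_t = regularized_local_scale(lam, tau, c2)
        beta_star = q[lay.zb] * tau * lam_t
        u = None
        v = None
        phi = None
        if self.has_u:
            v = math.exp(q[lay.lv])
            u = random_effect_draw(q[lay.zu], self._L, v)
        if self.has_phi:
            phi = math.exp(q[lay.lphi])
        return ParameterState(
            beta0=float(q[lay.b0]),
            beta_star=beta_star,
            tau=tau,
            lam=lam,
            c2=c2,
            u=u,
            re_variance=v,
            dispersion=phi,
        )

    def initial_position(self, rng: np.random.Generator, damp: float = 0.1) -> np.ndarray:
        """Prior-flavored initialization with scales damped toward zero."""
        lay = self.layout
        y = self.data.y
        q = np.empty(lay.dim)
        q[lay.zb] = damp * rng.standard_normal(lay.m)
        q[lay.lt] = math.log(damp) + 0.5 * rng.standard_normal()
        q[lay.psi] = damp * rng.standard_normal(lay.m)
        q[lay.lc] = math.log(self.spec.slab_scale2) + damp * rng.standard_normal()
        if self.has_u:
            q[lay.zu] = damp * rng.standard_normal(lay.n)
            q[lay.lv] = math.log(damp) + 0.5 * rng.standard_normal()
        if self.has_phi:
            # moment-matched start keeps the first leapfrogs sane whatever
            # the scale of y
            q[lay.b0] = float(y.mean()) + damp * rng.standard_normal()
            sd_y = float(y.std())
            q[lay.lphi] = math.log(max(sd_y, 1e-3)) + damp * rng.standard_normal()
        else:
            p_bar = min(max(float(y.mean()), 0.05), 0.95)
            q[lay.b0] = math.log(p_bar / (1.0 - p_bar)) + damp * rng.standard_normal()
        return q

    # -- density -------------------------------------------------------------

    def logp_grad(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        # guard: reject positions where the exp-transforms would overflow;
        # the sampler treats -inf as a divergence
        if not np.all(np.isfinite(q)) or np.max(np.abs(q)) > 200.0:
            return -math.inf, np.zeros(self.layout.dim)
        if self._use_fast:
            logp, grad = self._fast_args_call(q)
        else:
            with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
                logp, grad = self._logp_grad_inner(q)
        if not (np.isfinite(logp) and np.all(np.isfinite(grad))):
            return -math.inf, np.zeros(self.layout.dim)
        return logp, grad

    def _fast_args_call(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        from compmix._fastgrad import _logp_grad_jit

        spec = self.spec
        empty = self._empty
        return _logp_grad_jit(
            np.ascontiguousarray(q),
            self.data.y,
            self._Z,
            self._ZT,
            self._lap if self.use_iar else empty,
            self._L if self.has_u else empty,
            self.use_iar,
            self.has_u,
            self.has_phi,
            spec.local_prior == "half-t",
            spec.global_prior == "half-t",
            self._sum_var,
            self._slab_a,
            self._slab_b,
            self._slab_const,
            self._ht3_const,
            spec.global_scale,
            spec.intercept_prior_scale,
            spec.dispersion_prior_scale,
            spec.re_variance_prior_scale,
        )

    def _logp_grad_inner(self, q: np.ndarray) -> tuple[float, np.ndarray]:
        data, spec, lay = self.data, self.spec, self.layout
        y, Z = data.y, data.Z
        n, m = data.n, data.m

        b0 = q[lay.b0]
        zb = q[lay.zb]
        lt = q[lay.lt]
        psi = q[lay.psi]
        lc = q[lay.lc]

        tau2 = math.exp(2.0 * lt)
        c2 = math.exp(lc)
        l2 = np.exp(2.0 * psi)
        A = tau2 * l2
        denom = c2 + A
        s2 = c2 * A / denom  # (tau * lam_tilde)^2
        s = np.sqrt(s2)
        r = c2 / denom  # in (0, 1); ds/dpsi = s*r, ds/dlt = s*r, ds/dlc = s*(1-r)/2

        beta = zb * s
        eta = b0 + Z @ beta
        u = None
        if self.has_u:
            zu = q[lay.zu]
            v = math.exp(q[lay.lv])
            Lzu = self._L @ zu
            u = math.sqrt(v) * Lzu
            eta = eta + u

        grad = np.zeros(lay.dim)
        logp = 0.0

        # likelihood
        if data.family == "gaussian":
            phi = math.exp(q[lay.lphi])
            resid = y - eta
            rss = float(np.dot(resid, resid))
            logp += -0.5 * n * _LOG_2PI - n * q[lay.lphi] - 0.5 * rss / phi**2
            g_eta = resid / phi**2
            # d/dlphi of likelihood + half-t(3, scale) prior on phi + Jacobian
            ps2 = 3.0 * self.spec.dispersion_prior_scale ** 2
            logp += (self._ht3_const - math.log(spec.dispersion_prior_scale)
                     - 2.0 * math.log1p(phi**2 / ps2) + q[lay.lphi])
            grad[lay.lphi] = -n + rss / phi**2 - 4.0 * phi**2 / (ps2 + phi**2) + 1.0
        else:
            logp += float(np.dot(y, eta) - np.logaddexp(0.0, eta).sum())
            g_eta = y - expit(eta)

        # soft sum-to-zero on beta*
        S = float(beta.sum())
        logp += -0.5 * _LOG_2PI - 0.5 * math.log(self._sum_var) - 0.5 * S**2 / self._sum_var
        gS = -S / self._sum_var

        # combined gradient wrt beta*
        gbeta = self._ZT @ g_eta + gS

        # intercept t(3, 0, scale)
        is2 = 3.0 * spec.intercept_prior_scale ** 2
        logp += (self._ht3_const - math.log(2.0) - math.log(spec.intercept_prior_scale)
                 - 2.0 * math.log1p(b0**2 / is2))
        grad[lay.b0] = float(g_eta.sum()) - 4.0 * b0 / (is2 + b0**2)

        # zb ~ N(0, 1)
        logp += -0.5 * m * _LOG_2PI - 0.5 * float(np.dot(zb, zb))
        grad[lay.zb] = gbeta * s - zb

        gbz = gbeta * zb  # shared chain-rule factor
        gbzs = gbz * s

        # tau prior (+ Jacobian)
        gs2 = spec.global_scale ** 2
        if spec.global_prior == "half-cauchy":
            logp += (math.log(2.0 / math.pi) - math.log(spec.global_scale)
                     - math.log1p(tau2 / gs2) + lt)
            gtau = -2.0 * tau2 / (gs2 + tau2) + 1.0
        else:
            logp += (self._ht3_const - math.log(spec.global_scale)
                     - 2.0 * math.log1p(tau2 / (3.0 * gs2)) + lt)
            gtau = -4.0 * tau2 / (3.0 * gs2 + tau2) + 1.0
        grad[lay.lt] = float(np.dot(gbzs, r)) + gtau

        # local scales
        if self.use_iar:
            lap_psi = self._lap @ psi
            Sp = float(psi.sum())
            logp += -0.5 * float(np.dot(psi, lap_psi))
            logp += -0.5 * _LOG_2PI - 0.5 * math.log(self._sum_var) - 0.5 * Sp**2 / self._sum_var
            grad[lay.psi] = gbzs * r - lap_psi - Sp / self._sum_var
        else:
            if spec.local_prior == "half-cauchy":
                logp += float(np.sum(math.log(2.0 / math.pi) - np.log1p(l2))) + float(psi.sum())
                gpsi_prior = -2.0 * l2 / (1.0 + l2) + 1.0
            else:
                logp += float(
                    np.sum(self._ht3_const - 2.0 * np.log1p(l2 / 3.0))
                ) + float(psi.sum())
                gpsi_prior = -4.0 * l2 / (3.0 + l2) + 1.0
            grad[lay.psi] = gbzs * r + gpsi_prior

        # slab c2 ~ Inv-Gamma(a, b) (+ Jacobian)
        a, bb = self._slab_a, self._slab_b
        logp += self._slab_const - (a + 1.0) * lc - bb / c2 + lc
        grad[lay.lc] = 0.5 * float(np.dot(gbzs, 1.0 - r)) - a + bb / c2

        # random effect
        if self.has_u:
            logp += -0.5 * n * _LOG_2PI - 0.5 * float(np.dot(zu, zu))
            grad[lay.zu] = math.sqrt(v) * (self._L @ g_eta) - zu  # L symmetric
            vs2 = 3.0 * spec.re_variance_prior_scale ** 2
            logp += (self._ht3_const - math.log(spec.re_variance_prior_scale)
                     - 2.0 * math.log1p(v**2 / vs2) + q[lay.lv])
            grad[lay.lv] = 0.5 * float(np.dot(g_eta, u)) - 4.0 * v**2 / (vs2 + v**2) + 1.0

        return logp, grad

    def logp(self, q: np.ndarray) -> float:
        return self.logp_grad(q)[0]

    def pointwise_loglik(self, q: np.ndarray) -> np.ndarray:
        return pointwise_loglik(self.constrain(q), self.data, include_u=self.has_u)
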