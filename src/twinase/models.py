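"""Bayesian comparison of binomial-logit twin mixed models for ASE.

For one SNP-transcript pair the alternative-allele read proportion ``p_is``
of twin pair ``i`` and disease status ``s`` (affected s=1, unaffected s=0)
is modelled on the logit scale::

    M1: logit(p_is) = beta0 + beta_s * s + gamma_i
    M0: logit(p_is) = beta0 + gamma_i

with a shared per-pair random intercept gamma_i ~ Normal(0, sigma_gamma^2).
The evidence for a phenotype-linked allelic switch is the Bayes factor
BF = m1 / m0, where each m is the marginal likelihood with the fixed
effects, the random intercepts and sigma_gamma all integrated out under
weakly-informative priors (Normal(0, beta_sd^2) on fixed effects,
half-Normal(sigma_gamma_prior) on sigma_gamma). BF > 5 is the stringent
call threshold; BF > 3 already favours M1.

Counts are binomial by default; a beta-binomial with intra-class
correlation ``rho`` (variance inflation ~ 1+(n-1)rho) accommodates
overdispersed allelic counts.

Marginal likelihoods are computed by

* ``laplace`` — a joint Laplace approximation over (beta, gamma, log sigma);
* ``laplace_aghq`` (default) — the per-pair gamma integrals are done by
  adaptive Gauss-Hermite quadrature around each conditional mode, and the
  remaining low-dimensional (beta, log sigma) integral by Laplace;
* ``brute_force_log_marginal`` — a dense tensor-grid quadrature oracle for
  instances with at most 3 pairs, used to validate the fast paths;
* ``bic`` — a Schwarz approximation, provided for comparison only.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .types import AllelicCountRecord

M1 = "M1"
M0 = "M0"

_LOG2PI = math.log(2.0 * math.pi)
_TAU_MIN = math.log(1e-3)  # lower bound on log sigma_gamma in MAP fits
_GH_NODES = 15
_GH_X, _GH_W = np.polynomial.hermite.hermgauss(_GH_NODES)
_GH_LOGW = np.log(_GH_W)
# outer quadrature over (fixed effects, log sigma_gamma)
_OUTER_GH_X, _OUTER_GH_W = np.polynomial.hermite.hermgauss(7)
_OUTER_GH_LOGW = np.log(_OUTER_GH_W)


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PriorSpec:
    """Priors of the Bayesian model comparison.

    beta_sd
        SD of the Normal(0, beta_sd^2) prior on each fixed effect. The BF is
        prior-sensitive, so this is deliberately explicit (default 3.0).
    sigma_gamma_prior
        Scale of the half-Normal prior on the random-intercept SD.
    rho_mode
        "fixed_zero" (binomial likelihood), "fixed_value" (beta-binomial at
        ``rho_value``) or "profile" (rho chosen on a small grid by the M0
        marginal likelihood and shared by both models).
    """

    beta_sd: float = 3.0
    sigma_gamma_prior: float = 1.0
    rho_mode: str = "fixed_zero"
    rho_value: Optional[float] = None

    def __post_init__(self) -> None:
        if self.beta_sd <= 0 or self.sigma_gamma_prior <= 0:
            raise ValueError("prior scales must be positive")
        if self.rho_mode not in ("fixed_zero", "fixed_value", "profile"):
            raise ValueError(f"unknown rho_mode {self.rho_mode!r}")
        if self.rho_mode == "fixed_value":
            if self.rho_value is None or not (0.0 <= self.rho_value < 1.0):
                raise ValueError("fixed_value rho_mode needs rho_value in [0, 1)")


_PROFILE_RHO_GRID = (0.0, 0.005, 0.02, 0.05, 0.1, 0.2)


@dataclass(frozen=True)
class ASEParams:
    """One point in parameter space of the logit mixed model."""

    beta0: float
    betas: float
    gamma: np.ndarray
    rho: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must be in [0, 1)")


@dataclass
class ModelFit:
    model: str
    mode: np.ndarray  # (beta0[, betas], gamma_1..k, sigma_gamma)
    hessian: Optional[np.ndarray]
    log_marginal: float
    method: str
    converged: bool
    pair_ids: tuple = ()
    rho: float = 0.0


@dataclass
class BFRecord:
    """Bayes-factor verdict for one SNP-transcript pair."""

    snp_id: str
    transcript_id: str
    logml_m1: float
    logml_m0: float
    bf: float
    n_informative_pairs: int
    call: bool
    converged: bool = True

    @property
    def log_bf(self) -> float:
        return self.logml_m1 - self.logml_m0


# --------------------------------------------------------------------------
# internal count layout


class _PairedCounts:
    """Counts of one SNP-transcript pair flattened to numpy arrays."""

    __slots__ = ("alt", "tot", "s", "pair_idx", "n_pairs", "pair_ids", "logC", "rho")

    def __init__(self, alt, tot, s, pair_idx, n_pairs, pair_ids, rho):
        self.alt = alt
        self.tot = tot
        self.s = s
        self.pair_idx = pair_idx
        self.n_pairs = n_pairs
        self.pair_ids = pair_ids
        self.rho = rho
        self.logC = (
            special.gammaln(tot + 1)
            - special.gammaln(alt + 1)
            - special.gammaln(tot - alt + 1)
        )

    @classmethod
    def from_records(
        cls, records: Sequence[AllelicCountRecord], rho: float = 0.0
    ) -> "_PairedCounts":
        records = list(records)
        if not records:
            raise ValueError("no count records supplied")
        for r in records:
            if r.alt_count < 0 or r.ref_count < 0:
                raise ValueError(f"negative counts in record {r}")
        kept = [r for r in records if r.depth > 0]
        if not kept:
            raise ValueError("all records have zero total depth")
        if len(kept) < len(records):
            warnings.warn(
                f"dropped {len(records) - len(kept)} zero-depth record(s)",
                stacklevel=3,
            )
        pair_ids = tuple(sorted({r.pair_id for r in kept}))
        index = {p: i for i, p in enumerate(pair_ids)}
        alt = np.array([r.alt_count for r in kept], dtype=float)
        tot = np.array([r.depth for r in kept], dtype=float)
        s = np.array([1.0 if r.member == "affected" else 0.0 for r in kept])
        pidx = np.array([index[r.pair_id] for r in kept], dtype=np.intp)
        return cls(alt, tot, s, pidx, len(pair_ids), pair_ids, float(rho))

    def swapped(self) -> "_PairedCounts":
        return _PairedCounts(
            self.tot - self.alt, self.tot, self.s, self.pair_idx,
            self.n_pairs, self.pair_ids, self.rho,
        )

    def canonical(self) -> tuple["_PairedCounts", bool]:
        """Orientation-normalized copy (allele swap leaves the marginal
        likelihood invariant under the symmetric priors; normalizing makes
        that invariance hold exactly in floating point)."""
        key_alt = (self.alt.sum(), tuple(self.alt))
        key_ref = ((self.tot - self.alt).sum(), tuple(self.tot - self.alt))
        if key_alt > key_ref:
            return self.swapped(), True
        return self, False


def _record_loglik(pc: _PairedCounts, eta: np.ndarray) -> np.ndarray:
    """Per-record log-pmf at linear predictor eta; eta's first axis is records."""
    eta = np.asarray(eta, dtype=float)
    if eta.ndim > 1:
        sh = (pc.alt.size,) + (1,) * (eta.ndim - 1)
        alt, tot, logC = pc.alt.reshape(sh), pc.tot.reshape(sh), pc.logC.reshape(sh)
    else:
        alt, tot, logC = pc.alt, pc.tot, pc.logC
    if pc.rho == 0.0:
        return logC + alt * special.log_expit(eta) + (tot - alt) * special.log_expit(-eta)
    p = np.clip(special.expit(eta), 1e-12, 1.0 - 1e-12)
    a = p * (1.0 - pc.rho) / pc.rho
    b = (1.0 - p) * (1.0 - pc.rho) / pc.rho
    return stats.betabinom.logpmf(alt, tot, a, b)


def _resolve_rho(priors: PriorSpec) -> float:
    if priors.rho_mode == "fixed_value":
        return float(priors.rho_value)
    return 0.0  # fixed_zero; "profile" is resolved in bayes_factor


# --------------------------------------------------------------------------
# likelihood (public)


def loglik(
    records: Sequence[AllelicCountRecord],
    params: ASEParams,
    model: str = M1,
) -> float:
    """Log-likelihood of one SNP-transcript pair's counts at fixed parameters.

    Binomial (or beta-binomial when ``params.rho > 0``) log-pmf of the
    alternative-allele count out of total depth, with
    p = logistic(beta0 + betas*s + gamma_i). Under M0 the betas term is
    ignored (fixed at 0).
    """
    if model not in (M1, M0):
        raise ValueError(f"model must be {M1!r} or {M0!r}")
    pc = _PairedCounts.from_records(records, rho=params.rho)
    gamma = np.asarray(params.gamma, dtype=float)
    if gamma.shape != (pc.n_pairs,):
        raise ValueError(
            f"gamma has length {gamma.size} but records span {pc.n_pairs} pair(s) "
            f"({', '.join(pc.pair_ids)})"
        )
    betas = params.betas if model == M1 else 0.0
    eta = params.beta0 + betas * pc.s + gamma[pc.pair_idx]
    return float(np.sum(_record_loglik(pc, eta)))


# --------------------------------------------------------------------------
# joint posterior in unconstrained coordinates z = (beta..., gamma..., tau)


def _unpack(z: np.ndarray, pc: _PairedCounts, model: str):
    nb = 2 if model == M1 else 1
    beta0 = z[0]
    betas = z[1] if nb == 2 else 0.0
    gamma = z[nb : nb + pc.n_pairs]
    tau = z[-1]
    return nb, beta0, betas, gamma, tau


def _logpost(z: np.ndarray, pc: _PairedCounts, model: str, priors: PriorSpec) -> float:
    nb, beta0, betas, gamma, tau = _unpack(z, pc, model)
    sigma = math.exp(tau)
    eta = beta0 + betas * pc.s + gamma[pc.pair_idx]
    lp = float(np.sum(_record_loglik(pc, eta)))
    lp += -0.5 * float(np.sum((z[:nb] / priors.beta_sd) ** 2)) - nb * (
        math.log(priors.beta_sd) + 0.5 * _LOG2PI
    )
    lp += -0.5 * float(np.sum((gamma / sigma) ** 2)) - pc.n_pairs * (tau + 0.5 * _LOG2PI)
    sg = priors.sigma_gamma_prior
    # half-Normal(sg) density of sigma plus the log-Jacobian of sigma = e^tau
    lp += 0.5 * math.log(2.0 / math.pi) - math.log(sg) - sigma**2 / (2.0 * sg**2) + tau
    return lp


def _logpost_grad(z, pc: _PairedCounts, model: str, priors: PriorSpec) -> np.ndarray:
    """Analytic gradient (binomial likelihood); numeric fallback otherwise."""
    if pc.rho != 0.0:
        return optimize.approx_fprime(z, _logpost, 1e-7, pc, model, priors)
    nb, beta0, betas, gamma, tau = _unpack(z, pc, model)
    sigma = math.exp(tau)
    eta = beta0 + betas * pc.s + gamma[pc.pair_idx]
    resid = pc.alt - pc.tot * special.expit(eta)
    g = np.empty_like(z)
    g[0] = resid.sum() - beta0 / priors.beta_sd**2
    if nb == 2:
        g[1] = float(np.sum(resid * pc.s)) - betas / priors.beta_sd**2
    g[nb : nb + pc.n_pairs] = (
        np.bincount(pc.pair_idx, weights=resid, minlength=pc.n_pairs) - gamma / sigma**2
    )
    sg = priors.sigma_gamma_prior
    g[-1] = float(np.sum(gamma**2)) / sigma**2 - pc.n_pairs - sigma**2 / sg**2 + 1.0
    return g


def _numeric_hessian(f, x: np.ndarray, step: float = 1e-4) -> np.ndarray:
    d = x.size
    h = np.full(d, step) * np.maximum(1.0, np.abs(x))
    hess = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d)
        ei[i] = h[i]
        hess[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d)
            ej[j] = h[j]
            hess[i, j] = hess[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4.0 * h[i] * h[j])
    return hess


def _fit_mode_pc(
    pc: _PairedCounts, model: str, priors: PriorSpec, grad_tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """MAP in z-space; returns (z_hat, hessian, logpost, converged)."""
    nb = 2 if model == M1 else 1
    d = nb + pc.n_pairs + 1
    frac = np.clip(pc.alt.sum() / pc.tot.sum(), 1e-3, 1.0 - 1e-3)
    b0_start = special.logit(frac)
    best = None
    for tau0 in (math.log(0.15), math.log(0.6)):
        z0 = np.zeros(d)
        z0[0] = b0_start
        z0[-1] = tau0
        res = optimize.minimize(
            lambda z: -_logpost(z, pc, model, priors),
            z0,
            jac=lambda z: -_logpost_grad(z, pc, model, priors),
            method="L-BFGS-B",
            bounds=[(-40, 40)] * (d - 1) + [(_TAU_MIN, 3.0)],
            options={"maxiter": 300, "ftol": 1e-13, "gtol": 1e-9},
        )
        if best is None or -res.fun > best[1]:
            best = (res.x.copy(), -res.fun)
    z = best[0]

    def proj_grad_norm(zz):
        # sigma_gamma is bounded below (the unbounded density spike at
        # sigma -> 0 with gamma = 0 is not a usable mode); the tau
        # component is projected out when tau sits on that bound and the
        # gradient points further down
        g = _logpost_grad(zz, pc, model, priors)
        if zz[-1] <= _TAU_MIN + 1e-9 and g[-1] < 0:
            g = g.copy()
            g[-1] = 0.0
        return np.linalg.norm(g)

    # Newton polish to drive the (projected) gradient norm below tolerance;
    # when tau sits on its bound the polish acts on the free subspace only
    for _ in range(12):
        if proj_grad_norm(z) <= grad_tol:
            break
        g = _logpost_grad(z, pc, model, priors)
        hess = _numeric_hessian(lambda x: _logpost(x, pc, model, priors), z)
        free = np.ones(d, dtype=bool)
        if z[-1] <= _TAU_MIN + 1e-9 and g[-1] < 0:
            free[-1] = False
        try:
            step_free = np.linalg.solve(hess[np.ix_(free, free)], -g[free])
        except np.linalg.LinAlgError:
            break
        step = np.zeros(d)
        step[free] = np.clip(step_free, -2.0, 2.0)
        z_new = z + step
        z_new[-1] = max(z_new[-1], _TAU_MIN)
        if _logpost(z_new, pc, model, priors) < _logpost(z, pc, model, priors) - 1e-9:
            z_new = z + 0.25 * step  # damped retry
            z_new[-1] = max(z_new[-1], _TAU_MIN)
            if _logpost(z_new, pc, model, priors) < _logpost(z, pc, model, priors):
                break
        z = z_new
    converged = proj_grad_norm(z) <= grad_tol
    hess = _numeric_hessian(lambda x: _logpost(x, pc, model, priors), z)
    return z, hess, _logpost(z, pc, model, priors), bool(converged)


def _mode_vector(z: np.ndarray, flipped: bool = False) -> np.ndarray:
    """z -> user-facing (beta..., gamma..., sigma_gamma), undoing allele swap."""
    out = z.copy()
    out[-1] = math.exp(z[-1])
    if flipped:
        out[:-1] = -out[:-1]
    return out


def fit_mode(
    records: Sequence[AllelicCountRecord],
    model: str = M1,
    priors: PriorSpec = PriorSpec(),
) -> ModelFit:
    """Posterior mode of (beta0[, betas], gamma_1..k, sigma_gamma).

    Quasi-Newton (L-BFGS-B with analytic gradient for the binomial case)
    followed by Newton polishing; ``converged`` reflects a gradient-norm
    tolerance of 1e-6. sigma_gamma is optimized on the log scale from two
    starting scales to sidestep local ridges.
    """
    if model not in (M1, M0):
        raise ValueError(f"model must be {M1!r} or {M0!r}")
    pc = _PairedCounts.from_records(records, rho=_resolve_rho(priors))
    z, hess, _, converged = _fit_mode_pc(pc, model, priors)
    return ModelFit(
        model=model,
        mode=_mode_vector(z),
        hessian=hess,
        log_marginal=float("nan"),
        method="mode",
        converged=converged,
        pair_ids=pc.pair_ids,
        rho=pc.rho,
    )


# --------------------------------------------------------------------------
# adaptive Gauss-Hermite machinery


def _pair_indicator(pc: _PairedCounts) -> np.ndarray:
    P = np.zeros((pc.n_pairs, pc.alt.size))
    P[pc.pair_idx, np.arange(pc.alt.size)] = 1.0
    return P


def _pair_integrals_batch(
    pc: _PairedCounts,
    beta0: np.ndarray,
    betas: np.ndarray,
    sigma: np.ndarray,
    inner: str = "aghq",
) -> tuple[np.ndarray, np.ndarray]:
    """log integral over gamma_i of lik_i * Normal(gamma; 0, sigma^2), per
    pair, for a batch of (beta0, betas, sigma) parameter points.

    ``inner="aghq"``: Newton for each conditional mode, then 15 Hermite
    nodes scaled by the conditional curvature. ``inner="laplace"``: the
    one-term Laplace value at the conditional mode. Returns
    (logI (k, B), gamma_hat (k, B)).
    """
    beta0 = np.atleast_1d(np.asarray(beta0, dtype=float))
    betas = np.atleast_1d(np.asarray(betas, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    B = beta0.size
    k = pc.n_pairs
    m = pc.alt.size
    P = _pair_indicator(pc)
    base = beta0[None, :] + betas[None, :] * pc.s[:, None]  # (m, B)
    g = np.zeros((k, B))
    inv_s2 = 1.0 / sigma[None, :] ** 2  # (1, B)
    if pc.rho == 0.0:
        alt = pc.alt[:, None]
        tot = pc.tot[:, None]
        for _ in range(60):
            eta = base + g[pc.pair_idx, :]
            p = special.expit(eta)
            grad = P @ (alt - tot * p) - g * inv_s2
            curv = P @ (tot * p * (1.0 - p)) + inv_s2
            step = np.clip(grad / curv, -3.0, 3.0)
            g += step
            if np.max(np.abs(step)) < 1e-11:
                break
        p = special.expit(base + g[pc.pair_idx, :])
        curv = P @ (tot * p * (1.0 - p)) + inv_s2
    else:
        h = 1e-4
        for _ in range(80):
            f0 = P @ _record_loglik(pc, base + g[pc.pair_idx, :])
            fp = P @ _record_loglik(pc, base + (g + h)[pc.pair_idx, :])
            fm = P @ _record_loglik(pc, base + (g - h)[pc.pair_idx, :])
            grad = (fp - fm) / (2 * h) - g * inv_s2
            curv = np.maximum(-((fp - 2 * f0 + fm) / h**2) + inv_s2, 1e-6)
            step = np.clip(grad / curv, -1.0, 1.0)
            g += step
            if np.max(np.abs(step)) < 1e-9:
                break
    shat = 1.0 / np.sqrt(curv)  # (k, B)
    log_sigma = np.log(sigma)[None, :]
    if inner == "laplace":
        f_mode = P @ _record_loglik(pc, base + g[pc.pair_idx, :])
        f_mode += -0.5 * (g / sigma[None, :]) ** 2 - log_sigma - 0.5 * _LOG2PI
        return f_mode + 0.5 * _LOG2PI + np.log(shat), g
    nodes = g[:, :, None] + math.sqrt(2.0) * shat[:, :, None] * _GH_X[None, None, :]
    eta_nodes = base[:, :, None] + nodes[pc.pair_idx, :, :]  # (m, B, J)
    ll = _record_loglik(pc, eta_nodes)
    f = (P @ ll.reshape(m, B * _GH_NODES)).reshape(k, B, _GH_NODES)
    f += -0.5 * (nodes / sigma[None, :, None]) ** 2 - log_sigma[:, :, None] - 0.5 * _LOG2PI
    logI = (
        0.5 * math.log(2.0)
        + np.log(shat)
        + special.logsumexp(_GH_LOGW[None, None, :] + _GH_X[None, None, :] ** 2 + f, axis=2)
    )
    return logI, g


def _pair_integrals(
    pc: _PairedCounts, beta0: float, betas: float, sigma: float,
    inner: str = "aghq",
) -> tuple[np.ndarray, np.ndarray]:
    logI, g = _pair_integrals_batch(
        pc, np.array([beta0]), np.array([betas]), np.array([sigma]), inner
    )
    return logI[:, 0], g[:, 0]


def _h_theta(
    theta: np.ndarray, pc: _PairedCounts, model: str, priors: PriorSpec,
    inner: str = "aghq",
) -> float:
    """Integrated log-posterior over theta = (beta0[, betas], tau)."""
    nb = 2 if model == M1 else 1
    beta0 = theta[0]
    betas = theta[1] if nb == 2 else 0.0
    tau = theta[-1]
    sigma = math.exp(tau)
    logI, _ = _pair_integrals(pc, beta0, betas, sigma, inner=inner)
    val = float(np.sum(logI))
    val += -0.5 * float(np.sum((theta[:nb] / priors.beta_sd) ** 2)) - nb * (
        math.log(priors.beta_sd) + 0.5 * _LOG2PI
    )
    sg = priors.sigma_gamma_prior
    val += 0.5 * math.log(2.0 / math.pi) - math.log(sg) - sigma**2 / (2.0 * sg**2) + tau
    return val


def _h_theta_batch(
    th: np.ndarray, pc: _PairedCounts, model: str, priors: PriorSpec, inner: str
) -> np.ndarray:
    """Vectorized ``_h_theta`` over a (B, d) batch of theta points."""
    nb = 2 if model == M1 else 1
    beta0 = th[:, 0]
    betas = th[:, 1] if nb == 2 else np.zeros(th.shape[0])
    tau = th[:, -1]
    sigma = np.exp(tau)
    logI, _ = _pair_integrals_batch(pc, beta0, betas, sigma, inner)
    val = logI.sum(axis=0)
    val += -0.5 * np.sum((th[:, :nb] / priors.beta_sd) ** 2, axis=1) - nb * (
        math.log(priors.beta_sd) + 0.5 * _LOG2PI
    )
    sg = priors.sigma_gamma_prior
    val += 0.5 * math.log(2.0 / math.pi) - math.log(sg) - sigma**2 / (2.0 * sg**2) + tau
    return val


def _conditional_beta_modes(
    pc: _PairedCounts,
    model: str,
    priors: PriorSpec,
    inner: str,
    taus: np.ndarray,
    beta_init: np.ndarray,
) -> np.ndarray:
    """Per-tau conditional modes (and curvatures) of h over the fixed
    effects.

    Damped Newton with finite-difference derivatives, batched across the
    tau grid; h is log-concave in beta at fixed tau, so this is safe. The
    linear (Gaussian) centre shift supplies the starting values. Returns
    (modes (n_tau, nb), hessians (n_tau, nb, nb)); the per-tau curvature
    matters because the conditional beta scale is likelihood-limited at
    small sigma_gamma but prior-limited at large sigma_gamma.
    """
    n_tau = taus.size
    nb = beta_init.shape[1]
    beta = beta_init.copy()
    delta = 1e-4

    def h_at(b):
        th = np.concatenate([b, taus[:, None]], axis=1)
        return _h_theta_batch(th, pc, model, priors, inner)

    for _ in range(4):
        f0 = h_at(beta)
        grad = np.empty((n_tau, nb))
        hess = np.empty((n_tau, nb, nb))
        fp, fm = [], []
        for a in range(nb):
            e = np.zeros(nb)
            e[a] = delta
            fpa, fma = h_at(beta + e), h_at(beta - e)
            fp.append(fpa)
            fm.append(fma)
            grad[:, a] = (fpa - fma) / (2 * delta)
            hess[:, a, a] = (fpa - 2 * f0 + fma) / delta**2
        if nb == 2:
            e0 = np.array([delta, 0.0])
            e1 = np.array([0.0, delta])
            fpp = h_at(beta + e0 + e1)
            fpm = h_at(beta + e0 - e1)
            fmp = h_at(beta - e0 + e1)
            fmm = h_at(beta - e0 - e1)
            cross = (fpp - fpm - fmp + fmm) / (4 * delta**2)
            hess[:, 0, 1] = hess[:, 1, 0] = cross
        step = np.empty_like(beta)
        for t in range(n_tau):
            H = hess[t]
            try:
                step[t] = np.linalg.solve(H, -grad[t])
            except np.linalg.LinAlgError:
                step[t] = 0.0
        np.clip(step, -1.5, 1.5, out=step)
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            break
    return beta, hess


def _log_marginal_nested(
    pc: _PairedCounts, model: str, priors: PriorSpec,
    theta0: Optional[np.ndarray] = None, inner: str = "aghq",
) -> tuple[float, np.ndarray, np.ndarray, bool]:
    nb = 2 if model == M1 else 1
    d = nb + 1
    frac = np.clip(pc.alt.sum() / pc.tot.sum(), 1e-3, 1.0 - 1e-3)
    starts = []
    if theta0 is not None:
        starts.append(np.asarray(theta0, dtype=float))
    base = np.zeros(d)
    base[0] = special.logit(frac)
    for tau0 in (math.log(0.3), math.log(1.0)):
        t = base.copy()
        t[-1] = tau0
        starts.append(t)
    best = None
    neg = lambda t: -_h_theta(t, pc, model, priors, inner)
    for t0 in starts:
        res = optimize.minimize(
            neg,
            t0,
            method="L-BFGS-B",
            bounds=[(-30, 30)] * nb + [(-9.0, 2.0)],
            options={"maxiter": 200, "ftol": 1e-12},
        )
        if best is None or -res.fun > -best.fun:
            best = res
        if theta0 is not None:
            break  # warm start is trusted; saves half the work in screens
    theta = best.x
    h_val = -best.fun
    hess = _numeric_hessian(lambda t: _h_theta(t, pc, model, priors, inner), theta, step=3e-4)
    sign, logdet = np.linalg.slogdet(-hess)
    converged = bool(best.success or np.linalg.norm(best.jac) < 1e-3)
    if sign <= 0:
        hess = _numeric_hessian(
            lambda t: _h_theta(t, pc, model, priors, inner), theta, step=3e-3
        )
        sign, logdet = np.linalg.slogdet(-hess)
        if sign <= 0:
            return float("nan"), theta, hess, False
    if inner == "laplace":
        # plain nested Laplace: Gaussian approximation of the theta integral
        logml = h_val + 0.5 * d * _LOG2PI - 0.5 * logdet
        return float(logml), theta, hess, converged
    # refine the theta integral: exact trapezoid grid over tau = log
    # sigma_gamma (whose marginal has an exponential, distinctly
    # non-Gaussian tail), and adaptive Gauss-Hermite over the conditional
    # fixed-effect block, which is log-concave and close to Gaussian. The
    # conditional centre shifts linearly with tau (exact for a Gaussian).
    nb = d - 1
    cov = np.linalg.inv(-hess)
    cov = (cov + cov.T) / 2.0
    sd_tau = math.sqrt(cov[-1, -1])
    slope = cov[:-1, -1] / cov[-1, -1]  # d beta_c / d tau (Gaussian shift)
    cov_cond = cov[:-1, :-1] - np.outer(cov[:-1, -1], cov[:-1, -1]) / cov[-1, -1]
    A_mode = np.linalg.cholesky((cov_cond + cov_cond.T) / 2.0)
    half = max(5.0 * sd_tau, 4.0)
    lo = max(theta[-1] - half, -9.0)
    hi = min(theta[-1] + half, 2.5)
    n_tau = 25
    taus = np.linspace(lo, hi, n_tau)
    dtau = taus[1] - taus[0]
    mesh = np.meshgrid(*([_OUTER_GH_X] * nb), indexing="ij")
    X = np.stack([m_.ravel() for m_ in mesh], axis=1)  # (7^nb, nb)
    logW = sum(
        np.meshgrid(*([_OUTER_GH_LOGW] * nb), indexing="ij")[i].ravel()
        for i in range(nb)
    )
    n_x = X.shape[0]
    beta_init = theta[None, :-1] + slope[None, :] * (taus[:, None] - theta[-1])
    beta_centre, beta_hess = _conditional_beta_modes(
        pc, model, priors, inner, taus, beta_init
    )
    # per-tau Cholesky scaling from the conditional curvature
    A_t = np.empty((n_tau, nb, nb))
    logdet_A = np.empty(n_tau)
    for t in range(n_tau):
        try:
            cov_t = np.linalg.inv(-beta_hess[t])
            A_t[t] = np.linalg.cholesky((cov_t + cov_t.T) / 2.0)
        except np.linalg.LinAlgError:
            A_t[t] = A_mode
        logdet_A[t] = np.sum(np.log(np.diag(A_t[t])))
    th_nodes = np.empty((n_tau * n_x, d))
    shifted = beta_centre[:, None, :] + math.sqrt(2.0) * np.einsum(
        "xb,tab->txa", X, A_t
    )
    th_nodes[:, :-1] = shifted.reshape(n_tau * n_x, nb)
    th_nodes[:, -1] = np.repeat(taus, n_x)
    hv = _h_theta_batch(th_nodes, pc, model, priors, inner).reshape(n_tau, n_x)
    # per-tau adaptive GH integral over beta, then trapezoid over tau
    log_g = (
        0.5 * nb * math.log(2.0)
        + logdet_A
        + special.logsumexp(logW[None, :] + np.sum(X**2, axis=1)[None, :] + hv, axis=1)
    )
    w_tau = np.full(n_tau, dtau)
    w_tau[[0, -1]] = dtau / 2.0
    # below the grid the integrand decays as e^tau (prior Jacobian times a
    # plateauing likelihood), so the truncated lower tail integrates to
    # exactly the integrand value at the lowest grid point
    logml = special.logsumexp(np.append(log_g + np.log(w_tau), log_g[0]))
    return float(logml), theta, hess, converged


def log_marginal(
    records: Sequence[AllelicCountRecord],
    model: str = M1,
    priors: PriorSpec = PriorSpec(),
    method: str = "laplace_aghq",
) -> ModelFit:
    """Log marginal likelihood of M1 or M0 for one SNP-transcript pair.

    Both Laplace variants are nested: the per-pair random-intercept
    integrals are done first, then the low-dimensional (fixed effects,
    log sigma_gamma) integral by Laplace. ``laplace`` uses a one-term
    Laplace value for each inner integral; ``laplace_aghq`` (default, more
    accurate) refines them with 15-node adaptive Gauss-Hermite quadrature
    around each conditional mode. The nesting is essential, not cosmetic:
    the joint posterior density is unbounded as sigma_gamma -> 0 with all
    gamma at zero, so a single joint Laplace has no usable mode. ``bic``
    is a Schwarz approximation for comparison only. Records are
    orientation-normalized internally, which makes the result exactly
    invariant to a global alt/ref swap.
    """
    if method not in ("laplace", "laplace_aghq", "bic"):
        raise ValueError(f"unknown method {method!r}")
    pc = _PairedCounts.from_records(records, rho=_resolve_rho(priors))
    return _log_marginal_pc(pc, model, priors, method)


def _log_marginal_pc(
    pc: _PairedCounts, model: str, priors: PriorSpec, method: str,
    theta0: Optional[np.ndarray] = None,
) -> ModelFit:
    pc_c, flipped = pc.canonical()
    if method in ("laplace_aghq", "laplace"):
        inner = "aghq" if method == "laplace_aghq" else "laplace"
        logml, theta, hess, converged = _log_marginal_nested(
            pc_c, model, priors, theta0, inner
        )
        nb = 2 if model == M1 else 1
        sigma = math.exp(theta[-1])
        _, ghat = _pair_integrals(pc_c, theta[0], theta[1] if nb == 2 else 0.0, sigma)
        z = np.concatenate([theta[:nb], ghat, [theta[-1]]])
        return ModelFit(
            model=model,
            mode=_mode_vector(z, flipped),
            hessian=hess,
            log_marginal=logml,
            method=method,
            converged=converged,
            pair_ids=pc.pair_ids,
            rho=pc.rho,
        )
    # BIC / Schwarz: max log-likelihood penalized by (n_params/2) log(n_obs);
    # random intercepts counted as parameters. Comparison mode only.
    z, hess, _, converged = _fit_mode_pc(pc, model, priors)
    nb = 2 if model == M1 else 1
    gamma = z[nb : nb + pc.n_pairs]
    eta = z[0] + (z[1] if nb == 2 else 0.0) * pc.s + gamma[pc.pair_idx]
    llmax = float(np.sum(_record_loglik(pc, eta)))
    n_params = nb + pc.n_pairs + 1
    logml = llmax - 0.5 * n_params * math.log(pc.alt.size)
    return ModelFit(
        model=model,
        mode=_mode_vector(z),
        hessian=hess,
        log_marginal=float(logml),
        method=method,
        converged=converged,
        pair_ids=pc.pair_ids,
        rho=pc.rho,
    )


# --------------------------------------------------------------------------
# brute-force quadrature oracle


@dataclass(frozen=True)
class GridSpec:
    """Resolution of the brute-force tensor-grid marginal likelihood.

    The fixed-effect grid spacing is an exact multiple of the gamma grid
    spacing so that beta0 + gamma falls on a shared lattice, letting the
    per-record likelihood be evaluated once on that lattice and then
    gathered by stride tricks. sigma below ``sigma_low`` is handled by a
    Gauss-Hermite rule in the scaled variable u = gamma/sigma, where the
    trapezoid gamma grid would be under-resolved.
    """

    beta_half_range: float = 12.0
    n_beta: int = 201
    gamma_half_range: float = 12.0
    sigma_max: float = 3.5
    n_sigma: int = 40
    sigma_low: float = 0.05
    n_sigma_low: int = 8
    sigma_low_min: float = 0.004

    def refine(self, factor: int = 2) -> "GridSpec":
        return replace(
            self,
            n_beta=self.n_beta * factor - (factor - 1),
            n_sigma=self.n_sigma * factor,
            n_sigma_low=self.n_sigma_low * factor,
        )


def _trapz_logw(x: np.ndarray) -> np.ndarray:
    w = np.empty_like(x)
    w[1:-1] = (x[2:] - x[:-2]) / 2.0
    w[0] = (x[1] - x[0]) / 2.0
    w[-1] = (x[-1] - x[-2]) / 2.0
    return np.log(w)


def brute_force_log_marginal(
    records: Sequence[AllelicCountRecord],
    model: str = M1,
    priors: PriorSpec = PriorSpec(),
    grid: GridSpec = GridSpec(),
) -> float:
    """Dense-grid numerical integration of likelihood x priors (oracle).

    Integrates over (beta0[, betas], gamma_1..k, sigma_gamma) by nested
    quadrature with log-sum-exp accumulation, exploiting the per-pair
    factorization of the gamma integrals given the shared parameters.
    Refuses instances with more than 3 pairs (integration dimension > 6).
    Independent of the Laplace/AGHQ code paths.
    """
    if model not in (M1, M0):
        raise ValueError(f"model must be {M1!r} or {M0!r}")
    pc = _PairedCounts.from_records(records, rho=_resolve_rho(priors))
    if pc.n_pairs > 3:
        raise ValueError(
            f"brute-force oracle limited to <=3 pairs (got {pc.n_pairs}); "
            "integration dimension would exceed 6"
        )
    nb_dim = 2 if model == M1 else 1

    # shared lattice: gamma spacing hg, beta spacing 3*hg
    n_beta = grid.n_beta
    hb = 2.0 * grid.beta_half_range / (n_beta - 1)
    hg = hb / 3.0
    bgrid = np.linspace(-grid.beta_half_range, grid.beta_half_range, n_beta)
    t_lo = -grid.beta_half_range - grid.gamma_half_range
    n_t = 3 * (n_beta - 1) + int(round(2.0 * grid.gamma_half_range / hg)) + 1
    tgrid = t_lo + hg * np.arange(n_t)
    n_gamma = int(round(2.0 * grid.gamma_half_range / hg)) + 1

    sig_main = np.linspace(grid.sigma_low, grid.sigma_max, grid.n_sigma)
    sig_low = np.geomspace(grid.sigma_low_min, grid.sigma_low, grid.n_sigma_low, endpoint=False)
    sig_all = np.concatenate([sig_low, sig_main])

    ggrid = hg * (np.arange(n_gamma) - (n_gamma - 1) // 2)
    log_wg = math.log(hg)
    # Normal(0, sigma) density over the gamma grid, trapezoid-weighted
    phi = np.exp(
        -0.5 * (ggrid[:, None] / sig_main[None, :]) ** 2
        - np.log(sig_main)[None, :]
        - 0.5 * _LOG2PI
        + log_wg
    )

    gh_x, gh_w = np.polynomial.hermite.hermgauss(7)

    logI_pairs = []  # each (n_beta[, n_beta], n_sigma_all)
    for i in range(pc.n_pairs):
        mask = pc.pair_idx == i
        alt_i = pc.alt[mask]
        tot_i = pc.tot[mask]
        s_i = pc.s[mask]
        logC_i = pc.logC[mask]

        def rec_ll(eta, a, n, lc):
            if pc.rho == 0.0:
                return lc + a * special.log_expit(eta) + (n - a) * special.log_expit(-eta)
            p = np.clip(special.expit(eta), 1e-12, 1 - 1e-12)
            aa = p * (1 - pc.rho) / pc.rho
            bb = (1 - p) * (1 - pc.rho) / pc.rho
            return stats.betabinom.logpmf(a, n, aa, bb)

        if model == M1:
            # F(t, bs) = sum_records loglik(t + bs*s)
            F = np.zeros((n_beta, n_t))
            for a, n, s_r, lc in zip(alt_i, tot_i, s_i, logC_i):
                F += rec_ll(tgrid[None, :] + (bgrid * s_r)[:, None], a, n, lc)
            # view V[b0, bs, g] = F[bs, 3*b0 + g]
            sF = F.strides
            V = np.lib.stride_tricks.as_strided(
                F, shape=(n_beta, n_beta, n_gamma), strides=(3 * sF[1], sF[0], sF[1]),
                writeable=False,
            )
            rowmax = V.max(axis=2)
            Mexp = np.exp((V - rowmax[:, :, None]).astype(np.float32))
            prod = (Mexp.reshape(-1, n_gamma) @ phi.astype(np.float32)).astype(np.float64)
            logI_main = rowmax[:, :, None] + np.log(np.maximum(prod, 1e-300)).reshape(
                n_beta, n_beta, grid.n_sigma
            )
            # low-sigma block: Gauss-Hermite in u = gamma/sigma, lerp F along t
            logI_low = np.empty((n_beta, n_beta, sig_low.size))
            for si, sv in enumerate(sig_low):
                vals = np.full((n_beta, n_beta, gh_x.size), -np.inf)
                for j, (x, w) in enumerate(zip(gh_x, gh_w)):
                    gpt = math.sqrt(2.0) * sv * x
                    pos = (np.arange(n_beta) * 3) + ((n_gamma - 1) // 2) + gpt / hg
                    i0 = np.clip(np.floor(pos).astype(int), 0, n_t - 2)
                    frac = pos - i0
                    Fj = F[:, i0] * (1 - frac)[None, :] + F[:, i0 + 1] * frac[None, :]
                    vals[:, :, j] = Fj.T + math.log(w / math.sqrt(math.pi))
                logI_low[:, :, si] = special.logsumexp(vals, axis=2)
            logI_pairs.append(np.concatenate([logI_low, logI_main], axis=2))
        else:
            F = np.zeros(n_t)
            for a, n, lc in zip(alt_i, tot_i, logC_i):
                F += rec_ll(tgrid, a, n, lc)
            sF = F.strides
            V = np.lib.stride_tricks.as_strided(
                F, shape=(n_beta, n_gamma), strides=(3 * sF[0], sF[0]), writeable=False
            )
            rowmax = V.max(axis=1)
            Mexp = np.exp(V - rowmax[:, None])
            logI_main = rowmax[:, None] + np.log(np.maximum(Mexp @ phi, 1e-300))
            logI_low = np.empty((n_beta, sig_low.size))
            for si, sv in enumerate(sig_low):
                vals = np.full((n_beta, gh_x.size), -np.inf)
                for j, (x, w) in enumerate(zip(gh_x, gh_w)):
                    gpt = math.sqrt(2.0) * sv * x
                    pos = (np.arange(n_beta) * 3) + ((n_gamma - 1) // 2) + gpt / hg
                    i0 = np.clip(np.floor(pos).astype(int), 0, n_t - 2)
                    frac = pos - i0
                    vals[:, j] = F[i0] * (1 - frac) + F[i0 + 1] * frac + math.log(
                        w / math.sqrt(math.pi)
                    )
                logI_low[:, si] = special.logsumexp(vals, axis=1)
            logI_pairs.append(np.concatenate([logI_low, logI_main], axis=1))

    S = sum(logI_pairs)
    # priors and integration weights
    sg = priors.sigma_gamma_prior
    log_prior_sigma = (
        0.5 * math.log(2.0 / math.pi) - math.log(sg) - sig_all**2 / (2.0 * sg**2)
    )
    log_wsig = _trapz_logw(sig_all)
    log_prior_b = -0.5 * (bgrid / priors.beta_sd) ** 2 - math.log(priors.beta_sd) - 0.5 * _LOG2PI
    log_wb = math.log(hb)
    if model == M1:
        S = (
            S
            + log_prior_b[:, None, None]
            + log_prior_b[None, :, None]
            + (log_prior_sigma + log_wsig)[None, None, :]
            + 2.0 * log_wb
        )
    else:
        S = S + log_prior_b[:, None] + (log_prior_sigma + log_wsig)[None, :] + log_wb
    return float(special.logsumexp(S))


def importance_sample_log_marginal(
    records: Sequence[AllelicCountRecord],
    model: str = M1,
    priors: PriorSpec = PriorSpec(),
    n_draws: int = 1_000_000,
    seed: int = 0,
    scale: float = 1.6,
) -> float:
    """Monte-Carlo importance-sampling estimate of the log marginal likelihood.

    Second independent oracle: draws from a multivariate normal proposal at
    the joint posterior mode with covariance inflated by ``scale**2``, and
    averages importance weights in log space. Binomial likelihood only.
    """
    pc = _PairedCounts.from_records(records, rho=_resolve_rho(priors))
    if pc.rho != 0.0:
        raise ValueError("importance sampler supports the binomial likelihood only")
    # proposal centred at the nested-fit mode; the joint Hessian there can be
    # indefinite in the tau direction, so clip its spectrum to keep a proper
    # (and deliberately wide) Gaussian proposal
    _, theta, _, _ = _log_marginal_nested(pc, model, priors, inner="aghq")
    nb = 2 if model == M1 else 1
    _, ghat = _pair_integrals(
        pc, theta[0], theta[1] if nb == 2 else 0.0, math.exp(theta[-1])
    )
    z_hat = np.concatenate([theta[:nb], ghat, [theta[-1]]])
    hess = _numeric_hessian(lambda x: _logpost(x, pc, model, priors), z_hat)
    w, V = np.linalg.eigh(-(hess + hess.T) / 2.0)
    w = np.maximum(w, 0.2)
    cov = scale**2 * (V / w) @ V.T
    cov = (cov + cov.T) / 2.0
    rng = np.random.default_rng(seed)
    draws = rng.multivariate_normal(z_hat, cov, size=n_draws)
    nb = 2 if model == M1 else 1
    k = pc.n_pairs
    beta0 = draws[:, 0]
    betas = draws[:, 1] if nb == 2 else 0.0
    gamma = draws[:, nb : nb + k]
    tau = draws[:, -1]
    sigma = np.exp(tau)
    eta = beta0[:, None] + (betas[:, None] * pc.s[None, :] if nb == 2 else 0.0) + gamma[
        :, pc.pair_idx
    ]
    ll = np.sum(
        pc.logC[None, :]
        + pc.alt[None, :] * special.log_expit(eta)
        + (pc.tot - pc.alt)[None, :] * special.log_expit(-eta),
        axis=1,
    )
    lp = ll
    lp += -0.5 * np.sum((draws[:, :nb] / priors.beta_sd) ** 2, axis=1) - nb * (
        math.log(priors.beta_sd) + 0.5 * _LOG2PI
    )
    lp += -0.5 * np.sum((gamma / sigma[:, None]) ** 2, axis=1) - k * (tau + 0.5 * _LOG2PI)
    sg = priors.sigma_gamma_prior
    lp += 0.5 * math.log(2.0 / math.pi) - math.log(sg) - sigma**2 / (2.0 * sg**2) + tau
    logq = stats.multivariate_normal.logpdf(draws, mean=z_hat, cov=cov)
    return float(special.logsumexp(lp - logq) - math.log(n_draws))


# --------------------------------------------------------------------------
# Bayes factor


def bayes_factor(
    records: Sequence[AllelicCountRecord],
    priors: PriorSpec = PriorSpec(),
    threshold: float = 5.0,
    method: str = "laplace_aghq",
    snp_id: str = "",
    transcript_id: str = "",
) -> BFRecord:
    """Bayes factor M1 vs M0 for one SNP-transcript pair's counts.

    BF = exp(logml_M1 - logml_M0); a call is made when both model fits
    converged and BF exceeds ``threshold`` (default 5, the stringent cut;
    BF > 3 already favours the phenotype model).
    """
    records = list(records)
    if priors.rho_mode == "profile":
        # choose rho on a small grid by the M0 marginal likelihood, then
        # hold it fixed for both models so the BF compares like with like
        best_rho, best_ml = 0.0, -np.inf
        for rho in _PROFILE_RHO_GRID:
            pc = _PairedCounts.from_records(records, rho=rho)
            fit = _log_marginal_pc(pc, M0, priors, method)
            if fit.converged and fit.log_marginal > best_ml:
                best_rho, best_ml = rho, fit.log_marginal
        rho = best_rho
    else:
        rho = _resolve_rho(priors)
    pc = _PairedCounts.from_records(records, rho=rho)
    fit0 = _log_marginal_pc(pc, M0, priors, method)
    warm = None
    if method == "laplace_aghq" and fit0.converged:
        # warm-start M1 at the canonical-orientation M0 solution with betas=0
        pc_c, _ = pc.canonical()
        frac = np.clip(pc_c.alt.sum() / pc_c.tot.sum(), 1e-3, 1 - 1e-3)
        warm = np.array(
            [special.logit(frac), 0.0, math.log(max(fit0.mode[-1], 1e-3))]
        )
    fit1 = (
        _log_marginal_pc(pc, M1, priors, method, theta0=warm)
        if method == "laplace_aghq"
        else _log_marginal_pc(pc, M1, priors, method)
    )
    converged = bool(fit0.converged and fit1.converged)
    log_bf = fit1.log_marginal - fit0.log_marginal
    with np.errstate(over="ignore"):
        bf = float(np.exp(log_bf)) if np.isfinite(log_bf) else float("nan")
    call = bool(converged and np.isfinite(log_bf) and bf > threshold)
    return BFRecord(
        snp_id=snp_id,
        transcript_id=transcript_id,
        logml_m1=float(fit1.log_marginal),
        logml_m0=float(fit0.log_marginal),
        bf=bf,
        n_informative_pairs=pc.n_pairs,
        call=call,
        converged=converged,
    )
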