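"""Variational Bayes fitting of the switching AR factor-analysis model.

Structured mean field ``q(z) q(x) q(theta)``: the discrete state chain
``q(z)`` is smoothed exactly by forward-backward under expected
log-densities, the latent trajectory ``q(x)`` is a Gaussian chain smoothed
exactly under responsibility-collapsed dynamics, and all parameter factors
are conjugate (Dirichlet for pi and rows of A; Gaussian for loading rows,
means and AR coefficients; Gamma for noise precisions and the ARD
precisions nu that switch off unused latent dimensions).

Every update is an exact coordinate-ascent step on one evidence lower
bound, so the recorded ELBO trace is non-decreasing; this is asserted by
the test suite on every dataset it fits.

Group-level fitting shares q(theta) across subjects; subject-level refits
reuse the group posterior as the subject's prior (`fit_subject`), which
preserves state identities across the two levels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.special import digamma, gammaln

from ._kernels import chain_smoother_core, forward_backward_core
from .model import (
    ARDPrecisions,
    ARParams,
    FAParams,
    HMMParams,
    ModelError,
    StateParameters,
    TimeSeriesDataset,
)

__all__ = [
    "StatePosterior",
    "LatentTrajectoryPosterior",
    "FitResult",
    "forward_backward",
    "estep_states",
    "estep_latents",
    "mstep",
    "fit_group",
    "fit_subject",
    "posterior_state_parameters",
]

_TAU_MU = 1.0          # prior precision on observation means mu_kd
_GAMMA_A0 = 1e-3       # Gamma(a0, b0) prior on noise and ARD precisions
_GAMMA_B0 = 1e-3
_INIT_VAR = 10.0       # fixed state-independent prior variance of x_1


# ---------------------------------------------------------------------------
# Posterior containers


@dataclass
class StatePosterior:
    """Smoothed discrete-state posterior of one subject."""

    gamma: np.ndarray          # (T, K) responsibilities
    xi: np.ndarray             # (T-1, K, K) pairwise marginals
    loglik_contrib: np.ndarray  # (T, K) expected per-frame emission scores
    logZ: float = 0.0


@dataclass
class LatentTrajectoryPosterior:
    """Gaussian posterior over the latent trajectory of one subject."""

    mean: np.ndarray       # (T, P)
    cov: np.ndarray        # (T, P, P)
    lag_cov: np.ndarray    # (T-1, P, P), Cov(x_t, x_{t+1})
    logdet_prec: float = 0.0


@dataclass
class QTheta:
    """All conjugate parameter factors of the variational posterior."""

    alpha_pi: np.ndarray   # (K,) Dirichlet
    alpha_A: np.ndarray    # (K, K) Dirichlet rows
    m_w: np.ndarray        # (K, D, P+1) Gaussian means of (loadings row, mu)
    S_w: np.ndarray        # (K, D, P+1, P+1)
    a_psi: np.ndarray      # (K,) Gamma shape of observation precisions
    b_psi: np.ndarray      # (K, D) Gamma rates
    m_g: np.ndarray        # (K, P, 2) Gaussian means of (v, m)
    S_g: np.ndarray        # (K, P, 2, 2)
    a_sig: np.ndarray      # (K,) Gamma shape of innovation precisions
    b_sig: np.ndarray      # (K, P)
    a_nu: float            # ARD Gamma shape (group level only)
    b_nu: np.ndarray       # (K, P)

    @property
    def K(self) -> int:
        return self.alpha_pi.size

    @property
    def D(self) -> int:
        return self.m_w.shape[1]

    @property
    def P(self) -> int:
        return self.m_g.shape[1]

    def restrict(self, keep: np.ndarray) -> "QTheta":
        """Drop pruned states, keeping the Dirichlet mass of survivors."""
        return QTheta(
            alpha_pi=self.alpha_pi[keep].copy(),
            alpha_A=self.alpha_A[np.ix_(keep, keep)].copy(),
            m_w=self.m_w[keep].copy(),
            S_w=self.S_w[keep].copy(),
            a_psi=self.a_psi[keep].copy(),
            b_psi=self.b_psi[keep].copy(),
            m_g=self.m_g[keep].copy(),
            S_g=self.S_g[keep].copy(),
            a_sig=self.a_sig[keep].copy(),
            b_sig=self.b_sig[keep].copy(),
            a_nu=self.a_nu,
            b_nu=self.b_nu[keep].copy(),
        )


@dataclass
class Priors:
    """Natural-parameter priors; group defaults or an informed carry-over."""

    alpha0_pi: np.ndarray
    alpha0_A: np.ndarray
    P0_w: np.ndarray | None    # (K, D, P+1, P+1) precision; None = ARD-driven
    r0_w: np.ndarray           # (K, D, P+1) precision * mean
    a0_psi: np.ndarray         # (K,)
    b0_psi: np.ndarray         # (K, D)
    P0_g: np.ndarray           # (K, P, 2, 2)
    r0_g: np.ndarray           # (K, P, 2)
    a0_sig: np.ndarray
    b0_sig: np.ndarray         # (K, P)
    use_ard: bool = True

    @classmethod
    def default(cls, K: int, D: int, P: int, sticky_kappa: float = 10.0) -> "Priors":
        alpha0_A = np.ones((K, K)) + sticky_kappa * np.eye(K)
        return cls(
            alpha0_pi=np.ones(K),
            alpha0_A=alpha0_A,
            P0_w=None,
            r0_w=np.zeros((K, D, P + 1)),
            a0_psi=np.full(K, _GAMMA_A0),
            b0_psi=np.full((K, D), _GAMMA_B0),
            P0_g=np.broadcast_to(np.eye(2), (K, P, 2, 2)).copy(),
            r0_g=np.zeros((K, P, 2)),
            a0_sig=np.full(K, _GAMMA_A0),
            b0_sig=np.full((K, P), _GAMMA_B0),
            use_ard=True,
        )

    @classmethod
    def from_posterior(cls, q: QTheta) -> "Priors":
        """Use a fitted posterior as the prior of an informed refit."""
        K, D, P = q.K, q.D, q.P
        P0_w = np.linalg.inv(q.S_w)
        r0_w = np.einsum("kdab,kdb->kda", P0_w, q.m_w)
        P0_g = np.linalg.inv(q.S_g)
        r0_g = np.einsum("kpab,kpb->kpa", P0_g, q.m_g)
        return cls(
            alpha0_pi=q.alpha_pi.copy(),
            alpha0_A=q.alpha_A.copy(),
            P0_w=P0_w,
            r0_w=r0_w,
            a0_psi=q.a_psi.copy(),
            b0_psi=q.b_psi.copy(),
            P0_g=P0_g,
            r0_g=r0_g,
            a0_sig=q.a_sig.copy(),
            b0_sig=q.b_sig.copy(),
            use_ard=False,
        )


@dataclass
class FitResult:
    """Output of a group- or subject-level VB fit."""

    params: StateParameters
    qtheta: QTheta
    state_posteriors: dict[str, StatePosterior]
    latent_posteriors: dict[str, LatentTrajectoryPosterior]
    elbo_trace: np.ndarray
    K_effective: int
    effective_P: np.ndarray    # per-state count of surviving latent dims
    config: dict = field(default_factory=dict)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.config.get("channel_names", ()))


# ---------------------------------------------------------------------------
# Expectations of q(theta) (or a point parameterization) used by the E-steps


@dataclass
class Expectations:
    Elogpi: np.ndarray         # (K,)
    ElogA: np.ndarray          # (K, K)
    Epsiinv: np.ndarray        # (K, D)
    Elogpsiinv: np.ndarray     # (K, D)
    Ew: np.ndarray             # (K, D, P+1)
    Eww: np.ndarray            # (K, D, P+1, P+1)
    Esiginv: np.ndarray        # (K, P)
    Elogsiginv: np.ndarray     # (K, P)
    Eg: np.ndarray             # (K, P, 2)
    Egg: np.ndarray            # (K, P, 2, 2)

    @classmethod
    def from_qtheta(cls, q: QTheta) -> "Expectations":
        Elogpi = digamma(q.alpha_pi) - digamma(q.alpha_pi.sum())
        ElogA = digamma(q.alpha_A) - digamma(q.alpha_A.sum(axis=1, keepdims=True))
        Epsiinv = q.a_psi[:, None] / q.b_psi
        Elogpsiinv = digamma(q.a_psi)[:, None] - np.log(q.b_psi)
        Eww = q.S_w + np.einsum("kda,kdb->kdab", q.m_w, q.m_w)
        Esiginv = q.a_sig[:, None] / q.b_sig
        Elogsiginv = digamma(q.a_sig)[:, None] - np.log(q.b_sig)
        Egg = q.S_g + np.einsum("kpa,kpb->kpab", q.m_g, q.m_g)
        return cls(Elogpi, ElogA, Epsiinv, Elogpsiinv, q.m_w, Eww, Esiginv,
                   Elogsiginv, q.m_g, Egg)

    @classmethod
    def from_point(cls, params: StateParameters) -> "Expectations":
        """Delta expectations at fixed parameters (plug-in use and oracles)."""
        K, D = params.K, params.D
        P = params.fa[0].P
        with np.errstate(divide="ignore"):
            Elogpi = np.log(params.hmm.pi)
            ElogA = np.log(params.hmm.A)
        Epsiinv = np.stack([1.0 / f.psi for f in params.fa])
        Ew = np.stack([np.hstack([f.U, f.mu[:, None]]) for f in params.fa])
        Eww = np.einsum("kda,kdb->kdab", Ew, Ew)
        Esiginv = np.stack([1.0 / a.sigma for a in params.ar])
        Eg = np.stack([np.stack([a.V[0], a.m], axis=1) for a in params.ar])
        Egg = np.einsum("kpa,kpb->kpab", Eg, Eg)
        return cls(Elogpi, ElogA, Epsiinv, np.log(Epsiinv), Ew, Eww, Esiginv,
                   np.log(Esiginv), Eg, Egg)


# ---------------------------------------------------------------------------
# E-step over discrete states


def forward_backward(
    log_b: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Exact smoothed HMM marginals under per-frame log scores."""
    log_b = np.ascontiguousarray(log_b, dtype=float)
    gamma, xi, logZ, status = forward_backward_core(
        log_b, np.asarray(log_pi, dtype=float), np.asarray(log_A, dtype=float)
    )
    if status >= 0:
        raise ModelError(
            f"all state scores vanished at frame {status}; emissions are "
            "degenerate (-inf or overflowing) there"
        )
    return gamma, xi, logZ


def estep_states(
    emission_logliks: np.ndarray, log_pi: np.ndarray, log_A: np.ndarray
) -> StatePosterior:
    """Smoothed state posterior for given (expected) emission scores."""
    L = np.asarray(emission_logliks, dtype=float)
    if not np.all(np.isfinite(L) | (L == -np.inf)):
        raise ModelError("emission scores contain NaN/inf")
    gamma, xi, logZ = forward_backward(L, log_pi, log_A)
    return StatePosterior(gamma=gamma, xi=xi, loglik_contrib=L, logZ=logZ)


# ---------------------------------------------------------------------------
# E-step over latent trajectories


def _chain_potentials(
    y: np.ndarray, gamma: np.ndarray, exp: Expectations, init_var: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Natural parameters of the collapsed Gaussian chain over x."""
    T, D = y.shape
    K = gamma.shape[1]
    P = exp.Esiginv.shape[1]

    Uw = exp.Ew[:, :, :P]                       # (K, D, P)
    Lam = np.einsum("kd,kdab->kab", exp.Epsiinv, exp.Eww[:, :, :P, :P])
    c = np.einsum("kd,kdp->kp", exp.Epsiinv, exp.Eww[:, :, :P, P])
    Wpsi = exp.Epsiinv[:, :, None] * Uw         # (K, D, P)

    Ev = exp.Eg[:, :, 0]
    Em = exp.Eg[:, :, 1]
    Evv = exp.Egg[:, :, 0, 0]
    Evm = exp.Egg[:, :, 0, 1]
    a = exp.Esiginv                              # (K, P)

    J_diag = np.einsum("tk,kab->tab", gamma, Lam)
    diag_add = np.zeros((T, P))
    diag_add[1:] += gamma[1:] @ a
    diag_add[:-1] += gamma[1:] @ (a * Evv)
    diag_add[0] += 1.0 / init_var
    idx = np.arange(P)
    J_diag[:, idx, idx] += diag_add

    J_off = np.zeros((T - 1, P, P))
    off = -(gamma[1:] @ (a * Ev))
    J_off[:, idx, idx] = off

    h = np.zeros((T, P))
    for k in range(K):
        h += gamma[:, [k]] * (y @ Wpsi[k] - c[k])
    h[1:] += gamma[1:] @ (a * Em)
    h[:-1] -= gamma[1:] @ (a * Evm)
    return np.ascontiguousarray(J_diag), np.ascontiguousarray(J_off), h


def _smooth_chain(J_diag, J_off, h) -> LatentTrajectoryPosterior:
    mean, cov, lag, logdet = chain_smoother_core(J_diag, J_off, h)
    return LatentTrajectoryPosterior(mean=mean, cov=cov, lag_cov=lag, logdet_prec=logdet)


def estep_latents(
    y: np.ndarray,
    gamma: np.ndarray,
    params: StateParameters | Expectations,
    init_var: float = _INIT_VAR,
) -> LatentTrajectoryPosterior:
    """Gaussian posterior over x under responsibility-collapsed dynamics.

    Exact for the γ-weighted linear-Gaussian chain; when ``gamma`` is
    one-hot this is a single linear-Gaussian smoother.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    gamma = np.asarray(gamma, dtype=float)
    if not (np.all(np.isfinite(y)) and np.all(np.isfinite(gamma))):
        raise ModelError("non-finite inputs to the latent E-step")
    exp = params if isinstance(params, Expectations) else Expectations.from_point(params)
    return _smooth_chain(*_chain_potentials(y, gamma, exp, init_var))


# ---------------------------------------------------------------------------
# Expected per-frame scores for q(z)


def _xtilde_moments(xpost: LatentTrajectoryPosterior) -> tuple[np.ndarray, np.ndarray]:
    T, P = xpost.mean.shape
    xt = np.concatenate([xpost.mean, np.ones((T, 1))], axis=1)
    Xtt = np.einsum("ta,tb->tab", xt, xt)
    Xtt[:, :P, :P] += xpost.cov
    return xt, Xtt


def expected_scores(
    y: np.ndarray, xpost: LatentTrajectoryPosterior, exp: Expectations
) -> np.ndarray:
    """Expected emission + dynamics log-density, per frame and state."""
    T, D = y.shape
    K, P = exp.Esiginv.shape
    xt, Xtt = _xtilde_moments(xpost)

    A2 = np.einsum("kd,kdab->kab", exp.Epsiinv, exp.Eww)
    term1 = (y**2) @ exp.Epsiinv.T                      # (T, K)
    term3 = np.einsum("kab,tab->tk", A2, Xtt)
    term2 = np.empty((T, K))
    for k in range(K):
        B = exp.Epsiinv[k][:, None] * exp.Ew[k]          # (D, P+1)
        term2[:, k] = np.einsum("td,td->t", y, xt @ B.T)
    L = 0.5 * exp.Elogpsiinv.sum(axis=1)[None, :] - 0.5 * D * np.log(2 * np.pi) \
        - 0.5 * (term1 - 2.0 * term2 + term3)

    # dynamics terms for t >= 1
    mu = xpost.mean
    Ex2 = mu**2 + np.einsum("tpp->tp", xpost.cov)
    lagE = np.einsum("tpp->tp", xpost.lag_cov) + mu[:-1] * mu[1:]
    Ev, Em = exp.Eg[:, :, 0], exp.Eg[:, :, 1]
    quad = (
        np.einsum("tp,kp->tk", Ex2[1:], exp.Esiginv)
        - 2.0 * np.einsum("tp,kp->tk", lagE, exp.Esiginv * Ev)
        - 2.0 * np.einsum("tp,kp->tk", mu[1:], exp.Esiginv * Em)
        + np.einsum("tp,kp->tk", Ex2[:-1], exp.Esiginv * exp.Egg[:, :, 0, 0])
        + 2.0 * np.einsum("tp,kp->tk", mu[:-1], exp.Esiginv * exp.Egg[:, :, 0, 1])
        + np.einsum("kp->k", exp.Esiginv * exp.Egg[:, :, 1, 1])[None, :]
    )
    L[1:] += 0.5 * exp.Elogsiginv.sum(axis=1)[None, :] - 0.5 * P * np.log(2 * np.pi) \
        - 0.5 * quad
    return L


# ---------------------------------------------------------------------------
# Sufficient statistics and M-step


@dataclass
class SuffStats:
    z1: np.ndarray      # (K,)
    trans: np.ndarray   # (K, K)
    N: np.ndarray       # (K,)
    N1: np.ndarray      # (K,)
    Sxx: np.ndarray     # (K, P+1, P+1)
    Syx: np.ndarray     # (K, D, P+1)
    Syy: np.ndarray     # (K, D)
    S2: np.ndarray      # (K, P, 2, 2)
    r: np.ndarray       # (K, P, 2)
    q2: np.ndarray      # (K, P)

    @classmethod
    def zeros(cls, K: int, D: int, P: int) -> "SuffStats":
        return cls(
            np.zeros(K), np.zeros((K, K)), np.zeros(K), np.zeros(K),
            np.zeros((K, P + 1, P + 1)), np.zeros((K, D, P + 1)),
            np.zeros((K, D)), np.zeros((K, P, 2, 2)), np.zeros((K, P, 2)),
            np.zeros((K, P)),
        )

    def accumulate(
        self, y: np.ndarray, zpost: StatePosterior, xpost: LatentTrajectoryPosterior
    ) -> None:
        gamma, xi = zpost.gamma, zpost.xi
        xt, Xtt = _xtilde_moments(xpost)
        mu = xpost.mean
        Ex2 = mu**2 + np.einsum("tpp->tp", xpost.cov)
        lagE = np.einsum("tpp->tp", xpost.lag_cov) + mu[:-1] * mu[1:]

        self.z1 += gamma[0]
        self.trans += xi.sum(axis=0)
        self.N += gamma.sum(axis=0)
        g1 = gamma[1:]
        self.N1 += g1.sum(axis=0)
        self.Sxx += np.einsum("tk,tab->kab", gamma, Xtt)
        self.Syx += np.einsum("tk,td,ta->kda", gamma, y, xt)
        self.Syy += np.einsum("tk,td->kd", gamma, y**2)

        self.S2[:, :, 0, 0] += np.einsum("tk,tp->kp", g1, Ex2[:-1])
        s10 = np.einsum("tk,tp->kp", g1, mu[:-1])
        self.S2[:, :, 0, 1] += s10
        self.S2[:, :, 1, 0] += s10
        self.S2[:, :, 1, 1] += g1.sum(axis=0)[:, None]
        self.r[:, :, 0] += np.einsum("tk,tp->kp", g1, lagE)
        self.r[:, :, 1] += np.einsum("tk,tp->kp", g1, mu[1:])
        self.q2 += np.einsum("tk,tp->kp", g1, Ex2[1:])


def mstep(stats: SuffStats, priors: Priors, q: QTheta) -> QTheta:
    """Conjugate coordinate updates of every parameter factor.

    With empty-state statistics (all-zero rows) each update reduces to the
    prior; no special-casing is needed.
    """
    K, D = stats.Syy.shape
    P = stats.q2.shape[1]

    alpha_pi = priors.alpha0_pi + stats.z1
    alpha_A = priors.alpha0_A + stats.trans

    Epsiinv = q.a_psi[:, None] / q.b_psi
    Enu = q.a_nu / q.b_nu
    m_w = np.empty_like(q.m_w)
    S_w = np.empty_like(q.S_w)
    for k in range(K):
        for d in range(D):
            if priors.P0_w is None:
                P0 = np.diag(np.concatenate([Enu[k], [_TAU_MU]]))
                r0 = np.zeros(P + 1)
            else:
                P0 = priors.P0_w[k, d]
                r0 = priors.r0_w[k, d]
            prec = P0 + Epsiinv[k, d] * stats.Sxx[k]
            S = np.linalg.inv(prec)
            S_w[k, d] = 0.5 * (S + S.T)
            m_w[k, d] = S @ (r0 + Epsiinv[k, d] * stats.Syx[k, d])

    Eww = S_w + np.einsum("kda,kdb->kdab", m_w, m_w)
    resid = (
        stats.Syy
        - 2.0 * np.einsum("kda,kda->kd", m_w, stats.Syx)
        + np.einsum("kdab,kab->kd", Eww, stats.Sxx)
    )
    a_psi = priors.a0_psi + 0.5 * stats.N
    b_psi = priors.b0_psi + 0.5 * np.clip(resid, 0.0, None)

    if priors.use_ard:
        a_nu = _GAMMA_A0 + 0.5 * D
        b_nu = _GAMMA_B0 + 0.5 * np.einsum("kdpp->kp", Eww[:, :, :P, :P])
    else:
        a_nu, b_nu = q.a_nu, q.b_nu.copy()

    Esiginv = q.a_sig[:, None] / q.b_sig
    m_g = np.empty_like(q.m_g)
    S_g = np.empty_like(q.S_g)
    for k in range(K):
        for p in range(P):
            prec = priors.P0_g[k, p] + Esiginv[k, p] * stats.S2[k, p]
            S = np.linalg.inv(prec)
            S_g[k, p] = 0.5 * (S + S.T)
            m_g[k, p] = S @ (priors.r0_g[k, p] + Esiginv[k, p] * stats.r[k, p])

    Egg = S_g + np.einsum("kpa,kpb->kpab", m_g, m_g)
    resid_g = (
        stats.q2
        - 2.0 * np.einsum("kpa,kpa->kp", m_g, stats.r)
        + np.einsum("kpab,kpab->kp", Egg, stats.S2)
    )
    a_sig = priors.a0_sig + 0.5 * stats.N1
    b_sig = priors.b0_sig + 0.5 * np.clip(resid_g, 0.0, None)

    return QTheta(alpha_pi, alpha_A, m_w, S_w, a_psi, b_psi, m_g, S_g,
                  a_sig, b_sig, a_nu, b_nu)


# ---------------------------------------------------------------------------
# ELBO


def _dirichlet_contrib(alpha_hat: np.ndarray, alpha0: np.ndarray) -> float:
    """E_q[log p] - E_q[log q] for one Dirichlet factor."""
    Elog = digamma(alpha_hat) - digamma(alpha_hat.sum())
    logp = gammaln(alpha0.sum()) - gammaln(alpha0).sum() + ((alpha0 - 1) * Elog).sum()
    logq = gammaln(alpha_hat.sum()) - gammaln(alpha_hat).sum() + ((alpha_hat - 1) * Elog).sum()
    return float(logp - logq)


def _gamma_contrib(a_hat, b_hat, a0, b0) -> float:
    a_hat = np.broadcast_to(np.asarray(a_hat, dtype=float), np.shape(b_hat))
    a0 = np.broadcast_to(np.asarray(a0, dtype=float), np.shape(b_hat))
    b0 = np.broadcast_to(np.asarray(b0, dtype=float), np.shape(b_hat))
    Elog = digamma(a_hat) - np.log(b_hat)
    E = a_hat / b_hat
    logp = a0 * np.log(b0) - gammaln(a0) + (a0 - 1) * Elog - b0 * E
    logq = a_hat * np.log(b_hat) - gammaln(a_hat) + (a_hat - 1) * Elog - a_hat
    return float(np.sum(logp - logq))


def _gaussian_contrib(m, S, P0, r0) -> float:
    """E_q[log p] - E_q[log q] (= -KL) for Gaussian q with a fixed Gaussian
    prior given in natural form (precision P0, linear r0 = P0 mu0)."""
    dim = m.shape[-1]
    if np.any(r0):
        mu0 = np.linalg.solve(P0, r0[..., None])[..., 0]
    else:
        mu0 = np.zeros_like(m)
    diff = m - mu0
    _, logdetP0 = np.linalg.slogdet(P0)
    _, logdetS = np.linalg.slogdet(S)
    quad = np.einsum("...a,...ab,...b->...", diff, P0, diff)
    tr = np.einsum("...ab,...ba->...", P0, S)
    kl = 0.5 * (tr + quad - dim - (logdetP0 + logdetS))
    return float(-np.sum(kl))


def _w_ard_contrib(q: QTheta) -> float:
    """E[log p(w | nu)] + H(q(w)) for the group-level ARD prior."""
    K, D, P1 = q.m_w.shape
    P = P1 - 1
    Enu = q.a_nu / q.b_nu                     # (K, P)
    Elognu = digamma(q.a_nu) - np.log(q.b_nu)
    Eww_diag = np.einsum("kdaa->kda", q.S_w + np.einsum("kda,kdb->kdab", q.m_w, q.m_w))
    total = 0.0
    for k in range(K):
        logp = (
            -0.5 * D * P1 * np.log(2 * np.pi)
            + 0.5 * D * (Elognu[k].sum() + np.log(_TAU_MU))
            - 0.5 * np.sum(Enu[k][None, :] * Eww_diag[k, :, :P])
            - 0.5 * _TAU_MU * np.sum(Eww_diag[k, :, P])
        )
        sign, logdetS = np.linalg.slogdet(q.S_w[k])
        H = 0.5 * np.sum(logdetS) + 0.5 * D * P1 * (1 + np.log(2 * np.pi))
        total += logp + H
    return float(total)


def parameter_elbo_terms(q: QTheta, priors: Priors) -> float:
    """Sum over parameter factors of E[log p] - E[log q] (= -KL)."""
    total = _dirichlet_contrib(q.alpha_pi, priors.alpha0_pi)
    for j in range(q.K):
        total += _dirichlet_contrib(q.alpha_A[j], priors.alpha0_A[j])
    if priors.use_ard:
        total += _w_ard_contrib(q)
        total += _gamma_contrib(q.a_nu, q.b_nu, _GAMMA_A0, _GAMMA_B0)
    else:
        total += _gaussian_contrib(q.m_w, q.S_w, priors.P0_w, priors.r0_w)
    total += _gamma_contrib(q.a_psi[:, None], q.b_psi, priors.a0_psi[:, None], priors.b0_psi)
    total += _gaussian_contrib(q.m_g, q.S_g, priors.P0_g, priors.r0_g)
    total += _gamma_contrib(q.a_sig[:, None], q.b_sig, priors.a0_sig[:, None], priors.b0_sig)
    return total


def _chain_elbo_terms(xpost: LatentTrajectoryPosterior, init_var: float) -> float:
    """log N(x_1; 0, s0 I) expectation plus the entropy of q(x)."""
    T, P = xpost.mean.shape
    e_init = -0.5 * P * np.log(2 * np.pi * init_var) - 0.5 * (
        np.trace(xpost.cov[0]) + xpost.mean[0] @ xpost.mean[0]
    ) / init_var
    H = 0.5 * T * P * (1 + np.log(2 * np.pi)) - 0.5 * xpost.logdet_prec
    return float(e_init + H)


# ---------------------------------------------------------------------------
# Initialization


def _sliding_cov_features(y: np.ndarray, window: int) -> np.ndarray:
    """Per-frame vectorized covariance of a centered sliding window."""
    T, D = y.shape
    window = min(window, T)
    iu = np.triu_indices(D)
    feats = np.empty((T, iu[0].size))
    half = window // 2
    for t in range(T):
        a = max(0, t - half)
        b = min(T, a + window)
        a = max(0, b - window)
        seg = y[a:b]
        C = np.cov(seg.T, bias=True)
        feats[t] = np.atleast_2d(C)[iu]
    return feats


def _kmeans_gamma(
    data: TimeSeriesDataset, K: int, seed: int, window: int = 15, soft: float = 0.9
) -> dict[str, np.ndarray]:
    from sklearn.cluster import KMeans

    feats = [_sliding_cov_features(y, window) for y in data.subjects.values()]
    X = np.vstack(feats)
    km = KMeans(n_clusters=K, n_init=10, random_state=seed).fit(X)
    labels = km.labels_
    gammas = {}
    start = 0
    for sid, y in data.subjects.items():
        T = y.shape[0]
        lab = labels[start : start + T]
        start += T
        g = np.full((T, K), (1.0 - soft) / K)
        g[np.arange(T), lab] += soft
        gammas[sid] = g
    return gammas


def _random_gamma(data: TimeSeriesDataset, K: int, rng: np.random.Generator):
    return {
        sid: rng.dirichlet(np.ones(K), size=y.shape[0])
        for sid, y in data.subjects.items()
    }


def _init_latents(y: np.ndarray, P: int) -> LatentTrajectoryPosterior:
    T, D = y.shape
    yc = y - y.mean(axis=0)
    _, s, Vt = np.linalg.svd(yc, full_matrices=False)
    comp = Vt[:P]
    scores = yc @ comp.T
    sd = scores.std(axis=0)
    sd[sd == 0] = 1.0
    mean = scores / sd
    if P > comp.shape[0]:  # degenerate, pad
        mean = np.pad(mean, ((0, 0), (0, P - comp.shape[0])))
    cov = np.broadcast_to(np.eye(P), (T, P, P)).copy()
    lag = np.zeros((T - 1, P, P))
    return LatentTrajectoryPosterior(mean=mean, cov=cov, lag_cov=lag, logdet_prec=0.0)


# ---------------------------------------------------------------------------
# Main VB loop


def _validate_dataset(data: TimeSeriesDataset, R: int = 1) -> None:
    for sid, y in data.subjects.items():
        if y.shape[0] < R + 2:
            raise ModelError(f"subject {sid!r} has T={y.shape[0]} < R+2")
        sd = y.std(axis=0)
        for d in np.where(sd == 0)[0]:
            name = data.channel_names[d]
            raise ModelError(f"channel {name!r} is constant for subject {sid!r}")


def _vb_run(
    data: TimeSeriesDataset,
    priors: Priors,
    gammas: dict[str, np.ndarray],
    P: int,
    max_iter: int,
    tol: float,
    inner_sweeps: int,
    init_var: float,
) -> tuple[QTheta, dict, dict, np.ndarray]:
    K = priors.alpha0_pi.size
    D = data.D
    ys = data.subjects
    xposts = {sid: _init_latents(y, P) for sid, y in ys.items()}
    zposts = {
        sid: StatePosterior(
            gamma=gammas[sid],
            xi=np.broadcast_to(
                np.full((K, K), 1.0 / K**2), (ys[sid].shape[0] - 1, K, K)
            ).copy(),
            loglik_contrib=np.zeros((ys[sid].shape[0], K)),
        )
        for sid in ys
    }
    q = _initial_qtheta(K, D, P)
    elbos: list[float] = []
    for it in range(max_iter):
        stats = SuffStats.zeros(K, D, P)
        for sid, y in ys.items():
            stats.accumulate(y, zposts[sid], xposts[sid])
        q = mstep(stats, priors, q)
        exp = Expectations.from_qtheta(q)
        chain_term = 0.0
        logZ_total = 0.0
        for sid, y in ys.items():
            for _ in range(inner_sweeps):
                xposts[sid] = estep_latents(y, zposts[sid].gamma, exp, init_var)
                L = expected_scores(y, xposts[sid], exp)
                zposts[sid] = estep_states(L, exp.Elogpi, exp.ElogA)
            chain_term += _chain_elbo_terms(xposts[sid], init_var)
            logZ_total += zposts[sid].logZ
        elbo = logZ_total + chain_term + parameter_elbo_terms(q, priors)
        elbos.append(elbo)
        if it >= 1:
            prev = elbos[-2]
            if abs(elbo - prev) < tol * abs(elbo):
                break
    return q, zposts, xposts, np.array(elbos)


def _initial_qtheta(K: int, D: int, P: int) -> QTheta:
    eye_w = np.broadcast_to(np.eye(P + 1), (K, D, P + 1, P + 1)).copy()
    eye_g = np.broadcast_to(np.eye(2), (K, P, 2, 2)).copy()
    return QTheta(
        alpha_pi=np.ones(K),
        alpha_A=np.ones((K, K)),
        m_w=np.zeros((K, D, P + 1)),
        S_w=eye_w,
        a_psi=np.ones(K),
        b_psi=np.ones((K, D)),
        m_g=np.zeros((K, P, 2)),
        S_g=eye_g,
        a_sig=np.ones(K),
        b_sig=np.ones((K, P)),
        a_nu=1.0,
        b_nu=np.ones((K, P)),
    )


def posterior_state_parameters(q: QTheta) -> StateParameters:
    """Posterior-mean plug-in :class:`StateParameters` from a fitted q."""
    K, D, P1 = q.m_w.shape
    P = P1 - 1
    pi = q.alpha_pi / q.alpha_pi.sum()
    A = q.alpha_A / q.alpha_A.sum(axis=1, keepdims=True)
    fa, ar = [], []
    v_all = q.m_g[:, :, 0]
    if np.any(np.abs(v_all) >= 1):
        warnings.warn(
            "posterior mean AR coefficients outside the stationary region; "
            "clipped for plug-in use", RuntimeWarning, stacklevel=2
        )
    for k in range(K):
        U = q.m_w[k, :, :P]
        mu = q.m_w[k, :, P]
        psi = q.b_psi[k] / q.a_psi[k]        # 1 / E[psi^-1]
        fa.append(FAParams(U=U, mu=mu, psi=psi))
        v = np.clip(q.m_g[k, :, 0], -1 + 1e-6, 1 - 1e-6)
        m = q.m_g[k, :, 1]
        sigma = q.b_sig[k] / q.a_sig[k]
        ar.append(ARParams(V=v[None, :], m=m, sigma=sigma))
    return StateParameters(
        hmm=HMMParams(pi=pi, A=A),
        fa=tuple(fa),
        ar=tuple(ar),
        ard=ARDPrecisions(q.a_nu / q.b_nu),
    )


def effective_latent_dims(q: QTheta, ratio: float = 1e3) -> np.ndarray:
    """Per-state count of latent dimensions the ARD has not switched off."""
    Enu = q.a_nu / q.b_nu
    med = np.median(Enu, axis=1, keepdims=True)
    return (Enu <= ratio * med).sum(axis=1)


def fit_group(
    data: TimeSeriesDataset,
    K_max: int = 10,
    P_max: int | None = None,
    n_restarts: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
    sticky_kappa: float = 10.0,
    inner_sweeps: int = 2,
    prune: bool = True,
    elbo_eliminate_below: float = 0.05,
    init_var: float = _INIT_VAR,
) -> FitResult:
    """Group-level VB fit on all subjects with automatic state pruning.

    Restart 0 initializes responsibilities from k-means on sliding-window
    covariance features; the remaining restarts are random.  The restart
    with the best final ELBO wins.  After convergence, states whose
    fractional occupancy falls below ``max(1e-3, 2 / total_frames)`` are
    removed and the model re-smoothed.  Remaining low-occupancy states
    (below ``elbo_eliminate_below``) are then subjected to an ELBO
    cross-check: the model is refit without the state and the reduced
    model replaces it only when its bound is higher (backward elimination
    guided by the ELBO; set ``elbo_eliminate_below=0`` to disable).  The
    surviving count is ``K_effective``.
    """
    if K_max < 1:
        raise ModelError("K_max must be >= 1")
    _validate_dataset(data)
    D = data.D
    P = P_max if P_max is not None else max(D - 1, 1)
    if P > D:
        raise ModelError(f"P_max={P} must not exceed D={D}")
    priors = Priors.default(K_max, D, P, sticky_kappa=sticky_kappa)
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(max(n_restarts, 1))

    best = None
    for r in range(max(n_restarts, 1)):
        rseed = int(children[r].generate_state(1)[0] % (2**31 - 1))
        if r == 0:
            gammas = _kmeans_gamma(data, K_max, seed=rseed)
        else:
            gammas = _random_gamma(data, K_max, np.random.default_rng(children[r]))
        run = _vb_run(data, priors, gammas, P, max_iter, tol, inner_sweeps, init_var)
        if best is None or run[3][-1] > best[3][-1]:
            best = run
    q, zposts, xposts, elbos = best

    total_T = sum(y.shape[0] for y in data.subjects.values())
    occ = sum(zp.gamma.sum(axis=0) for zp in zposts.values()) / total_T
    keep = occ >= max(1e-3, 2.0 / total_T) if prune else np.ones(K_max, bool)
    if prune and keep.sum() == 0:
        keep[np.argmax(occ)] = True
    if keep.sum() < K_max:
        q = q.restrict(keep)
        exp = Expectations.from_qtheta(q)
        for sid, y in data.subjects.items():
            xposts[sid] = estep_latents(y, _renorm(zposts[sid].gamma[:, keep]), exp, init_var)
            L = expected_scores(y, xposts[sid], exp)
            zposts[sid] = estep_states(L, exp.Elogpi, exp.ElogA)

    # ELBO cross-check: backward elimination of remaining small states.
    # Low-occupancy states are often local-optimum artifacts (e.g. a state
    # specialized on a handful of switch frames); refitting without the
    # state and comparing bounds decides whether the data support it.
    if prune and elbo_eliminate_below > 0:
        while q.K > 1:
            occ = sum(zp.gamma.sum(axis=0) for zp in zposts.values()) / total_T
            order = np.argsort(occ)
            cand = [int(k) for k in order if occ[k] < elbo_eliminate_below]
            accepted = False
            for k in cand:
                keep_k = np.ones(q.K, dtype=bool)
                keep_k[k] = False
                gammas_red = {
                    sid: _renorm(zp.gamma[:, keep_k])
                    for sid, zp in zposts.items()
                }
                priors_red = Priors.default(
                    int(keep_k.sum()), D, P, sticky_kappa=sticky_kappa
                )
                run = _vb_run(data, priors_red, gammas_red, P, max_iter, tol,
                              inner_sweeps, init_var)
                if run[3][-1] > elbos[-1]:
                    q, zposts, xposts, elbos = run
                    accepted = True
                    break
            if not accepted:
                break

    params = posterior_state_parameters(q)
    config = dict(
        K_max=K_max, P_max=P, n_restarts=n_restarts, seed=seed, tol=tol,
        max_iter=max_iter, sticky_kappa=sticky_kappa, inner_sweeps=inner_sweeps,
        init_var=init_var, tr=data.tr, channel_names=tuple(data.channel_names),
        level="group",
    )
    return FitResult(
        params=params,
        qtheta=q,
        state_posteriors=zposts,
        latent_posteriors=xposts,
        elbo_trace=elbos,
        K_effective=q.K,
        effective_P=effective_latent_dims(q),
        config=config,
    )


def _renorm(g: np.ndarray) -> np.ndarray:
    s = g.sum(axis=1, keepdims=True)
    s[s == 0] = 1.0
    return g / s


def fit_subject(
    group: FitResult,
    subject_data: TimeSeriesDataset,
    tol: float = 1e-6,
    max_iter: int = 200,
    inner_sweeps: int = 2,
) -> FitResult:
    """Subject-level informed refit: the group posterior becomes the prior.

    State identities are preserved (no pruning, no relabeling); the same
    coordinate-ascent loop runs on the single subject's data.
    """
    _validate_dataset(subject_data)
    if subject_data.D != group.params.D:
        raise ModelError(
            f"subject has D={subject_data.D}, group model has D={group.params.D}"
        )
    if group.channel_names and tuple(subject_data.channel_names) != group.channel_names:
        raise ModelError(
            "subject channel names/order differ from the group model: "
            f"{tuple(subject_data.channel_names)} vs {group.channel_names}"
        )
    priors = Priors.from_posterior(group.qtheta)
    P = group.qtheta.P
    init_var = group.config.get("init_var", _INIT_VAR)
    # initialize responsibilities by smoothing under the group model
    exp = Expectations.from_qtheta(group.qtheta)
    gammas = {}
    for sid, y in subject_data.subjects.items():
        xp = _init_latents(y, P)
        for _ in range(2):
            L = expected_scores(y, xp, exp)
            zp = estep_states(L, exp.Elogpi, exp.ElogA)
            xp = estep_latents(y, zp.gamma, exp, init_var)
        gammas[sid] = zp.gamma
    q, zposts, xposts, elbos = _vb_run(
        subject_data, priors, gammas, P, max_iter, tol, inner_sweeps, init_var
    )
    params = posterior_state_parameters(q)
    config = dict(group.config)
    config.update(level="subject", tr=subject_data.tr)
    return FitResult(
        params=params,
        qtheta=q,
        state_posteriors=zposts,
        latent_posteriors=xposts,
        elbo_trace=elbos,
        K_effective=group.K_effective,
        effective_P=effective_latent_dims(q),
        config=config,
    )
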