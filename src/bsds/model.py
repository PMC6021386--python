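"""Generative model of the switching dynamical system.

Each latent brain state ``k`` is a linear-Gaussian regime

.. math::

    y_t = U_k x_t + \\mu_k + e_{kt}, \\qquad e_{kt} \\sim N(0, \\Psi_k)

    x_t = V_k \\odot x_{t-1} + \\epsilon_{kt}, \\qquad
    \\epsilon_{kt} \\sim N(m_k, \\Sigma_k)

with a D×P loading matrix ``U_k``, diagonal observation noise ``Psi_k``,
per-dimension AR(1) coefficients ``V_k`` and diagonal innovation covariance
``Sigma_k``.  The discrete state index follows a first-order Markov chain
with initial probabilities ``pi`` and row-stochastic transition matrix
``A`` (``A[j, k] = P(z_t = k | z_{t-1} = j)``).

Connectivity is always reported through the implied stationary observed
covariance ``C_k = U_k Gamma_k U_k^T + Psi_k`` (``Gamma_k`` the stationary
latent covariance), never through ``U_k`` itself: the factor space is only
identified up to rotation when ``Gamma_k`` is isotropic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "HMMParams",
    "FAParams",
    "ARParams",
    "ARDPrecisions",
    "StateParameters",
    "TimeSeriesDataset",
    "NonStationaryError",
    "state_stationary_latent_cov",
    "state_observed_cov",
    "marginal_emission_loglik",
    "cov_to_corr",
]

_JITTER = 1e-8


class ModelError(ValueError):
    pass


class NonStationaryError(ModelError):
    """AR coefficient with modulus >= 1: no stationary distribution."""


def _as_prob_vector(p, name: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ModelError(f"{name} must be a probability vector, got {p!r}")
    return np.clip(p, 0.0, None) / p.sum()


@dataclass(frozen=True)
class HMMParams:
    """Initial distribution ``pi`` and transition matrix ``A`` of the chain."""

    pi: np.ndarray
    A: np.ndarray

    def __post_init__(self):
        pi = _as_prob_vector(self.pi, "pi")
        A = np.asarray(self.A, dtype=float)
        if A.shape != (pi.size, pi.size):
            raise ModelError(f"A must be K x K with K={pi.size}, got {A.shape}")
        A = np.vstack([_as_prob_vector(row, f"A[{j}]") for j, row in enumerate(A)])
        object.__setattr__(self, "pi", pi)
        object.__setattr__(self, "A", A)

    @property
    def K(self) -> int:
        return self.pi.size

    def stationary(self) -> np.ndarray:
        """Stationary distribution of ``A`` (left Perron eigenvector)."""
        w, v = np.linalg.eig(self.A.T)
        i = int(np.argmin(np.abs(w - 1.0)))
        p = np.abs(np.real(v[:, i]))
        return p / p.sum()


@dataclass(frozen=True)
class FAParams:
    """Factor-analysis observation parameters of one state."""

    U: np.ndarray        # (D, P) loadings
    mu: np.ndarray       # (D,) observation mean offset
    psi: np.ndarray      # (D,) diagonal observation noise variances

    def __post_init__(self):
        U = np.atleast_2d(np.asarray(self.U, dtype=float))
        mu = np.asarray(self.mu, dtype=float).ravel()
        psi = np.asarray(self.psi, dtype=float).ravel()
        if U.shape[0] != mu.size or psi.size != mu.size:
            raise ModelError(
                f"inconsistent FA dims: U {U.shape}, mu {mu.size}, psi {psi.size}"
            )
        if U.shape[1] > U.shape[0]:
            raise ModelError(f"latent dim P={U.shape[1]} exceeds D={U.shape[0]}")
        if np.any(psi <= 0):
            raise ModelError("psi entries must be strictly positive")
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "psi", psi)

    @property
    def D(self) -> int:
        return self.U.shape[0]

    @property
    def P(self) -> int:
        return self.U.shape[1]


@dataclass(frozen=True)
class ARParams:
    """Per-dimension AR(R) latent dynamics of one state.

    ``V`` holds one coefficient per latent dimension and lag, shape (R, P);
    innovation mean ``m`` and diagonal covariance ``sigma`` (variances).
    """

    V: np.ndarray
    m: np.ndarray
    sigma: np.ndarray
    R: int = 1

    def __post_init__(self):
        V = np.atleast_2d(np.asarray(self.V, dtype=float))
        m = np.asarray(self.m, dtype=float).ravel()
        sigma = np.asarray(self.sigma, dtype=float).ravel()
        if V.shape != (self.R, m.size):
            raise ModelError(f"V must have shape (R={self.R}, P={m.size}), got {V.shape}")
        if sigma.size != m.size or np.any(sigma <= 0):
            raise ModelError("sigma must be length P with positive entries")
        object.__setattr__(self, "V", V)
        object.__setattr__(self, "m", m)
        object.__setattr__(self, "sigma", sigma)

    @property
    def P(self) -> int:
        return self.m.size


@dataclass(frozen=True)
class ARDPrecisions:
    """Automatic-relevance precisions, one per state and latent dimension."""

    nu: np.ndarray  # (K, P) or list of per-state vectors

    def __post_init__(self):
        nu = np.asarray(self.nu, dtype=float)
        if np.any(nu <= 0):
            raise ModelError("ARD precisions must be positive")
        object.__setattr__(self, "nu", nu)


@dataclass(frozen=True)
class StateParameters:
    """Full parameter set of a K-state switching AR factor-analysis model."""

    hmm: HMMParams
    fa: tuple[FAParams, ...]
    ar: tuple[ARParams, ...]
    ard: ARDPrecisions | None = None

    def __post_init__(self):
        fa = tuple(self.fa)
        ar = tuple(self.ar)
        K = self.hmm.K
        if len(fa) != K or len(ar) != K:
            raise ModelError(f"need {K} FA and AR parameter sets, got {len(fa)}/{len(ar)}")
        D = fa[0].D
        for f, a in zip(fa, ar):
            if f.D != D:
                raise ModelError("all states must share the observation dimension D")
            if f.P != a.P:
                raise ModelError("FA and AR latent dimensions disagree within a state")
        object.__setattr__(self, "fa", fa)
        object.__setattr__(self, "ar", ar)

    @property
    def K(self) -> int:
        return self.hmm.K

    @property
    def D(self) -> int:
        return self.fa[0].D


@dataclass
class TimeSeriesDataset:
    """Subject-indexed multivariate time series with a fixed TR.

    ``subjects`` maps subject id to a (T_s, D) float array; all subjects
    share the channel count D.  No missing values are allowed.
    """

    subjects: dict[str, np.ndarray]
    tr: float
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self):
        if self.tr <= 0:
            raise ModelError(f"tr must be positive, got {self.tr}")
        subs = {}
        D = None
        for sid, y in self.subjects.items():
            y = np.atleast_2d(np.asarray(y, dtype=float))
            if not np.all(np.isfinite(y)):
                t, d = map(int, np.argwhere(~np.isfinite(y))[0])
                raise ModelError(f"non-finite value for subject {sid!r} at frame {t}, channel {d}")
            if D is None:
                D = y.shape[1]
            elif y.shape[1] != D:
                raise ModelError(f"subject {sid!r} has D={y.shape[1]}, expected {D}")
            subs[str(sid)] = y
        self.subjects = subs
        if not self.channel_names:
            self.channel_names = tuple(f"ch{d}" for d in range(D or 0))
        elif D is not None and len(self.channel_names) != D:
            raise ModelError("channel_names length does not match D")

    @property
    def D(self) -> int:
        return next(iter(self.subjects.values())).shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def subject_ids(self) -> list[str]:
        return list(self.subjects)

    def concat(self) -> np.ndarray:
        """All subjects stacked along time (for group-level statistics)."""
        return np.vstack(list(self.subjects.values()))


# ---------------------------------------------------------------------------
# Deterministic model math


def state_stationary_latent_cov(ar_k: ARParams) -> tuple[np.ndarray, np.ndarray]:
    """Stationary covariance and mean of a state's AR(1) latent process.

    For per-dimension AR(1), ``Gamma_pp = sigma_p / (1 - v_p^2)`` and the
    stationary mean is ``m_p / (1 - v_p)``.  Raises
    :class:`NonStationaryError` when any ``|v_p| >= 1``.
    """
    if ar_k.R != 1:
        raise ModelError("stationary covariance implemented for R=1 only")
    v = ar_k.V[0]
    if np.any(np.abs(v) >= 1):
        raise NonStationaryError(f"AR coefficients not stationary: {v}")
    gamma = np.diag(ar_k.sigma / (1.0 - v**2))
    mean = ar_k.m / (1.0 - v)
    return gamma, mean


def state_observed_cov(fa_k: FAParams, ar_k: ARParams) -> np.ndarray:
    """Stationary observed covariance ``C_k = U Gamma U^T + Psi`` of a state."""
    gamma, _ = state_stationary_latent_cov(ar_k)
    C = fa_k.U @ gamma @ fa_k.U.T + np.diag(fa_k.psi)
    return 0.5 * (C + C.T)


def _stable_cholesky(C: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(C)
    except np.linalg.LinAlgError:
        jitter = _JITTER * float(np.mean(np.diag(C)))
        try:
            return np.linalg.cholesky(C + jitter * np.eye(C.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ModelError("covariance not positive definite after jitter") from exc


def marginal_emission_loglik(y: np.ndarray, k: int, params: StateParameters) -> np.ndarray:
    """Plug-in stationary emission log-density of state ``k``.

    Evaluates ``log N(y; mu_k + U_k m*_k, C_k)`` with ``m*_k`` the
    stationary latent mean, for a single frame (D,) or a batch (T, D).
    Used by Viterbi decoding and plug-in posterior time courses; the VB fit
    itself uses expected log-densities instead.
    """
    fa, ar = params.fa[k], params.ar[k]
    _, mstar = state_stationary_latent_cov(ar)
    C = state_observed_cov(fa, ar)
    mean = fa.mu + fa.U @ mstar
    L = _stable_cholesky(C)
    y2 = np.atleast_2d(np.asarray(y, dtype=float)) - mean
    sol = np.linalg.solve(L, y2.T)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    ll = -0.5 * (fa.D * np.log(2 * np.pi) + logdet + np.sum(sol**2, axis=0))
    return ll[0] if np.asarray(y).ndim == 1 else ll


def cov_to_corr(C: np.ndarray) -> np.ndarray:
    """Covariance to correlation; requires a strictly positive diagonal."""
    C = np.asarray(C, dtype=float)
    d = np.diag(C)
    if np.any(d <= 0):
        raise ModelError("covariance has non-positive diagonal entries")
    s = 1.0 / np.sqrt(d)
    R = C * np.outer(s, s)
    np.fill_diagonal(R, 1.0)
    return np.clip(R, -1.0, 1.0)
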