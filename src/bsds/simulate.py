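"""Synthetic regime-switching time series with known ground truth.

Emulates the validation paradigms used to benchmark the switching model:
block-designed ON/OFF regimes whose states differ in covariance structure
(a three-node network with five 60 s ON/OFF cycles; a seven-node circuit
with 20 alternating ON trials over 1200 s; an HCP-like three-condition
working-memory design).  The series are drawn exactly from the generative
model: per-state factor loadings map AR(1) latent trajectories to observed
channels with diagonal noise.

The generator does not attempt scanner physics; an optional canonical
double-gamma HRF convolution is provided to emulate hemodynamic sluggishness
and is OFF by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .designs import BlockDesign
from .model import (
    ARParams,
    FAParams,
    HMMParams,
    ModelError,
    NonStationaryError,
    StateParameters,
    TimeSeriesDataset,
    state_stationary_latent_cov,
)

__all__ = [
    "GroundTruth",
    "simulate_switching_series",
    "hrf_convolve",
    "hrf_kernel",
    "default_state_parameters",
]


@dataclass(frozen=True)
class GroundTruth:
    """Per-subject generating state sequences (1-based labels) and parameters."""

    state_sequence: dict[str, np.ndarray]
    generating_params: StateParameters
    condition_to_state: dict[str, int] | None = None


def _draw_state_sequence(hmm: HMMParams, T: int, rng: np.random.Generator) -> np.ndarray:
    z = np.empty(T, dtype=np.int64)
    z[0] = rng.choice(hmm.K, p=hmm.pi)
    for t in range(1, T):
        z[t] = rng.choice(hmm.K, p=hmm.A[z[t - 1]])
    return z


def _design_state_sequence(
    design: BlockDesign, condition_to_state: dict[str, int]
) -> np.ndarray:
    labels = design.frame_labels()
    try:
        return np.array([condition_to_state[c] for c in labels], dtype=np.int64)
    except KeyError as exc:
        raise ModelError(f"design condition {exc} has no mapped state") from None


def _simulate_one(
    params: StateParameters,
    z: np.ndarray,
    rng: np.random.Generator,
    mean_offset: np.ndarray | None,
    latent_reinit: str = "switch",
) -> np.ndarray:
    T = z.size
    D = params.D
    P = params.fa[0].P
    for ar in params.ar:
        if np.any(np.abs(ar.V) >= 1):
            raise NonStationaryError("simulation requires |V| < 1 in every state")
        if ar.P != P:
            raise ModelError("simulation requires a shared latent dimension P")
    if latent_reinit not in ("switch", "start"):
        raise ModelError("latent_reinit must be 'switch' or 'start'")
    R = params.ar[0].R

    def _stationary_draw(k: int) -> np.ndarray:
        gam, mstar = state_stationary_latent_cov_general(params.ar[k])
        return np.tile(mstar, (R, 1)) + rng.standard_normal((R, P)) * np.sqrt(
            np.diag(gam)
        )

    y = np.empty((T, D))
    x_hist = _stationary_draw(z[0])
    x = x_hist[-1]
    for t in range(T):
        k = z[t]
        ar, fa = params.ar[k], params.fa[k]
        if t > 0:
            if latent_reinit == "switch" and k != z[t - 1]:
                # fresh draw from the entering state's stationary law, so
                # each regime expresses its covariance from its first frame
                x_hist = _stationary_draw(k)
                x = x_hist[-1]
            else:
                drive = np.einsum("rp,rp->p", ar.V, x_hist[::-1])
                x = drive + ar.m + rng.standard_normal(P) * np.sqrt(ar.sigma)
                x_hist = np.vstack([x_hist[1:], x]) if R > 1 else x[None, :]
        y[t] = fa.U @ x + fa.mu + rng.standard_normal(D) * np.sqrt(fa.psi)
    if mean_offset is not None:
        y += mean_offset
    return y


def state_stationary_latent_cov_general(ar: ARParams) -> tuple[np.ndarray, np.ndarray]:
    """Stationary latent covariance/mean; closed form for R=1, Yule-Walker else."""
    if ar.R == 1:
        return state_stationary_latent_cov(ar)
    # per-dimension AR(R): solve for stationary variance via the companion form
    P = ar.P
    var = np.empty(P)
    mean = np.empty(P)
    for p in range(P):
        coeffs = ar.V[:, p]
        comp = np.zeros((ar.R, ar.R))
        comp[0, :] = coeffs
        if ar.R > 1:
            comp[1:, :-1] = np.eye(ar.R - 1)
        if np.max(np.abs(np.linalg.eigvals(comp))) >= 1:
            raise NonStationaryError(f"latent dimension {p} not stationary")
        # vec(Gamma) = (I - comp (x) comp)^{-1} vec(Q)
        Q = np.zeros((ar.R, ar.R))
        Q[0, 0] = ar.sigma[p]
        vecG = np.linalg.solve(
            np.eye(ar.R**2) - np.kron(comp, comp), Q.ravel()
        )
        var[p] = vecG.reshape(ar.R, ar.R)[0, 0]
        mean[p] = ar.m[p] / (1.0 - coeffs.sum())
    return np.diag(var), mean


def simulate_switching_series(
    params: StateParameters,
    design_or_chain: BlockDesign | np.ndarray | None,
    n_subjects: int = 1,
    n_frames: int | None = None,
    tr: float | None = None,
    condition_to_state: dict[str, int] | None = None,
    subject_offset_sd: float = 0.0,
    hrf: bool = False,
    latent_reinit: str = "switch",
    seed: int = 0,
) -> tuple[TimeSeriesDataset, GroundTruth]:
    """Draw subject time series from the switching generative model.

    Parameters
    ----------
    params
        Generating :class:`~bsds.model.StateParameters`.
    design_or_chain
        Either a :class:`~bsds.designs.BlockDesign` (state at frame t is the
        design's condition mapped through ``condition_to_state``), or
        ``None`` to draw state paths from the model's own Markov chain
        (``n_frames`` and ``tr`` then required).
    condition_to_state
        Condition label -> 0-based state index.  Defaults to enumerating
        the design's conditions in order of first appearance, rest first.
    subject_offset_sd
        Standard deviation of a per-subject constant channel offset
        (subject heterogeneity); 0 disables it.
    latent_reinit
        ``"switch"`` (default) redraws the latent trajectory from the
        entering state's stationary law at every state change, so each
        regime expresses its stationary covariance from its first frame;
        ``"start"`` draws only at t=1 and lets latents evolve continuously
        across switches (brief cross-regime transients).
    hrf
        Convolve each channel with the canonical HRF (default off: the
        model's own inputs are already BOLD-like).
    seed
        Master seed; subjects use independently spawned streams.
    """
    rng_master = np.random.SeedSequence(seed)
    if isinstance(design_or_chain, BlockDesign):
        design = design_or_chain
        if condition_to_state is None:
            conds = [design.rest_label] + [
                c for c in design.conditions if c != design.rest_label
            ]
            condition_to_state = {c: i for i, c in enumerate(conds)}
        bad = set(condition_to_state.values()) - set(range(params.K))
        if bad:
            raise ModelError(f"condition_to_state maps to unknown states {bad}")
        z_template = _design_state_sequence(design, condition_to_state)
        tr = design.tr
        chain_driven = False
    elif design_or_chain is None:
        if n_frames is None or tr is None:
            raise ModelError("chain-driven simulation requires n_frames and tr")
        chain_driven = True
        z_template = None
    else:
        # explicit transition matrix: replace the model's chain
        A = np.asarray(design_or_chain, dtype=float)
        params = StateParameters(
            hmm=HMMParams(pi=params.hmm.pi, A=A), fa=params.fa, ar=params.ar, ard=params.ard
        )
        if n_frames is None or tr is None:
            raise ModelError("chain-driven simulation requires n_frames and tr")
        chain_driven = True
        z_template = None

    subjects: dict[str, np.ndarray] = {}
    sequences: dict[str, np.ndarray] = {}
    for s, child in enumerate(rng_master.spawn(n_subjects)):
        rng = np.random.default_rng(child)
        z = _draw_state_sequence(params.hmm, n_frames, rng) if chain_driven else z_template
        offset = (
            rng.standard_normal(params.D) * subject_offset_sd
            if subject_offset_sd > 0
            else None
        )
        y = _simulate_one(params, z, rng, offset, latent_reinit=latent_reinit)
        if hrf:
            y = hrf_convolve(y, tr)
        sid = f"sub-{s + 1:02d}"
        subjects[sid] = y
        sequences[sid] = z + 1  # 1-based labels on the outside
    data = TimeSeriesDataset(subjects=subjects, tr=float(tr))
    truth = GroundTruth(
        state_sequence=sequences,
        generating_params=params,
        condition_to_state=condition_to_state if not chain_driven else None,
    )
    return data, truth


# ---------------------------------------------------------------------------
# Hemodynamic response


def hrf_kernel(tr: float, duration_s: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at ``tr`` (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), normalized to unit peak."""
    from scipy.stats import gamma as gamma_dist

    if tr <= 0:
        raise ModelError(f"tr must be positive, got {tr}")
    t = np.arange(0, duration_s, tr)
    # shape/scale chosen so the modes sit at 6 s and 16 s (scale 1 s)
    peak = gamma_dist.pdf(t, a=6.0, scale=1.0)
    undershoot = gamma_dist.pdf(t, a=16.0, scale=1.0)
    h = peak - undershoot / 6.0
    return h / h.max()


def hrf_convolve(series_or_mask: np.ndarray, tr: float) -> np.ndarray:
    """Convolve signal(s) with the canonical HRF, truncated to input length.

    Accepts a 1-D signal or a (T, D) matrix (each column convolved).
    """
    x = np.asarray(series_or_mask, dtype=float)
    h = hrf_kernel(tr)
    if x.ndim == 1:
        return np.convolve(x, h)[: x.size]
    if x.ndim != 2:
        raise ModelError("expected a 1-D signal or a T x D matrix")
    out = np.empty_like(x)
    for d in range(x.shape[1]):
        out[:, d] = np.convolve(x[:, d], h)[: x.shape[0]]
    return out


# ---------------------------------------------------------------------------
# Preset generating parameters for the validation designs


def default_state_parameters(
    K: int,
    D: int,
    P: int = 2,
    loading_scale: float = 1.5,
    noise_var: float = 0.2,
    ar_coef: float = 0.5,
    self_prob: float = 0.95,
    seed: int = 0,
) -> StateParameters:
    """Well-separated generating parameters: states share means but differ
    in covariance structure through distinct loading subspaces.

    Loadings are drawn once from a seeded stream and orthonormalized per
    state before scaling, so every pair of states differs strongly in its
    stationary covariance; means are zero so regimes are distinguishable by
    second-order structure only.  The Markov chain is sticky with
    ``self_prob`` on the diagonal.
    """
    if P > D:
        raise ModelError(f"P={P} must not exceed D={D}")
    rng = np.random.default_rng(seed)
    fa, ar = [], []
    for _ in range(K):
        raw = rng.standard_normal((D, P))
        q, _ = np.linalg.qr(raw)
        U = q[:, :P] * loading_scale
        fa.append(FAParams(U=U, mu=np.zeros(D), psi=np.full(D, noise_var)))
        ar.append(
            ARParams(
                V=np.full((1, P), ar_coef),
                m=np.zeros(P),
                sigma=np.full(P, 1.0 - ar_coef**2),  # unit stationary variance
            )
        )
    off = (1.0 - self_prob) / max(K - 1, 1)
    A = np.full((K, K), off)
    np.fill_diagonal(A, self_prob if K > 1 else 1.0)
    hmm = HMMParams(pi=np.full(K, 1.0 / K), A=A)
    from .model import ARDPrecisions

    return StateParameters(hmm=hmm, fa=tuple(fa), ar=tuple(ar), ard=ARDPrecisions(np.ones((K, P))))
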