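"""State sequences and their dynamics statistics.

Everything downstream of the fitted model that concerns the *temporal*
behavior of latent brain states: Viterbi decoding, posterior time courses,
occupancy rates, mean lifetimes, empirical transition matrices, run-level
switch paths, onset-locked occupancy and cross-fit state matching.

Conventions (documented once, used everywhere):

* state labels are 1-based in :class:`StateSequence`;
* transitions are counted from frame ``t`` to frame ``t + 1``;
* runs truncated by a condition-mask boundary still count as observed runs
  in lifetime statistics (excluding them would bias against long dominant
  states); pass ``split_runs_at_mask=False`` to change that.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .designs import BlockDesign
from .inference import Expectations, FitResult, estep_states
from .model import ModelError, StateParameters, marginal_emission_loglik
from ._kernels import viterbi_core

__all__ = [
    "StateSequence",
    "StateMetrics",
    "viterbi_decode",
    "posterior_timecourse",
    "occupancy_rate",
    "mean_lifetime",
    "empirical_transition_matrix",
    "switch_paths",
    "onset_transition_occupancy",
    "match_states",
    "run_length_encode",
]


@dataclass(frozen=True)
class StateSequence:
    """Frame-indexed decoded states (labels in 1..K) of one subject."""

    labels: np.ndarray
    tr: float
    subject_id: str = ""
    K: int | None = None

    def __post_init__(self):
        labels = np.asarray(self.labels, dtype=np.int64)
        if labels.size < 1:
            raise ModelError("state sequence must have length >= 1")
        if labels.min() < 1:
            raise ModelError("state labels are 1-based")
        K = self.K if self.K is not None else int(labels.max())
        if labels.max() > K:
            raise ModelError(f"label {labels.max()} exceeds K={K}")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "K", K)

    def __len__(self) -> int:
        return self.labels.size


@dataclass
class StateMetrics:
    """Bundle of per-state dynamics statistics for one conditioning set."""

    occupancy: np.ndarray          # (K,) fractions, sums to 1
    mean_lifetime_s: np.ndarray    # (K,) seconds, NaN where state absent
    empirical_A: np.ndarray        # (K, K) row-stochastic, NaN rows undefined
    n_frames: int


def run_length_encode(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(run_values, run_lengths) of a label sequence."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return np.array([], dtype=labels.dtype), np.array([], dtype=np.int64)
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return labels[starts], ends - starts


def _plugin_scores(params: StateParameters, y: np.ndarray) -> np.ndarray:
    y = np.atleast_2d(np.asarray(y, dtype=float))
    return np.stack(
        [marginal_emission_loglik(y, k, params) for k in range(params.K)], axis=1
    )


def viterbi_decode(
    params: StateParameters, y: np.ndarray, tr: float | None = None,
    subject_id: str = "",
) -> StateSequence:
    """Exact MAP state sequence under the plug-in stationary emissions.

    Log-space dynamic programming; ties break toward the lower state index.
    """
    L = _plugin_scores(params, y)
    with np.errstate(divide="ignore"):
        log_pi = np.log(params.hmm.pi)
        log_A = np.log(params.hmm.A)
    path = viterbi_core(np.ascontiguousarray(L), log_pi, log_A)
    return StateSequence(labels=path + 1, tr=tr or 1.0, subject_id=subject_id,
                         K=params.K)


def posterior_timecourse(params: StateParameters, y: np.ndarray) -> np.ndarray:
    """Smoothed per-frame state probabilities under plug-in emissions."""
    L = _plugin_scores(params, y)
    with np.errstate(divide="ignore"):
        zp = estep_states(L, np.log(params.hmm.pi), np.log(params.hmm.A))
    return zp.gamma


def _masked_labels(seq: StateSequence, mask: np.ndarray | None) -> np.ndarray:
    if mask is None:
        return seq.labels
    mask = np.asarray(mask)
    if mask.dtype == bool:
        if mask.size != len(seq):
            raise ModelError("mask length does not match the sequence")
        return seq.labels[mask]
    if mask.size and (mask.min() < 0 or mask.max() >= len(seq)):
        raise ModelError("mask frame indices out of range")
    return seq.labels[mask]


def occupancy_rate(seq: StateSequence, mask: np.ndarray | None = None) -> np.ndarray:
    """Fraction of (masked) frames spent in each state; sums to 1."""
    lab = _masked_labels(seq, mask)
    if lab.size == 0:
        raise ModelError("empty mask: occupancy undefined")
    counts = np.bincount(lab - 1, minlength=seq.K).astype(float)
    return counts / counts.sum()


def _mask_segments(mask: np.ndarray | None, T: int) -> list[slice]:
    if mask is None:
        return [slice(0, T)]
    mask = np.asarray(mask)
    if mask.dtype != bool:
        b = np.zeros(T, dtype=bool)
        b[mask] = True
        mask = b
    vals, lens = run_length_encode(mask)
    out, pos = [], 0
    for v, n in zip(vals, lens):
        if v:
            out.append(slice(pos, pos + n))
        pos += n
    return out


def mean_lifetime(
    seq: StateSequence, mask: np.ndarray | None = None,
    split_runs_at_mask: bool = True,
) -> np.ndarray:
    """Mean contiguous run length per state, in seconds.

    States absent from the (masked) sequence are reported as NaN, not zero.
    Runs cut by a mask boundary count as observed runs.
    """
    runs: dict[int, list[int]] = {}
    if split_runs_at_mask:
        segments = [seq.labels[seg] for seg in _mask_segments(mask, len(seq))]
    else:
        segments = [_masked_labels(seq, mask)]
    for lab in segments:
        vals, lens = run_length_encode(lab)
        for v, n in zip(vals, lens):
            runs.setdefault(int(v), []).append(int(n))
    out = np.full(seq.K, np.nan)
    for k in range(1, seq.K + 1):
        if k in runs:
            out[k - 1] = float(np.mean(runs[k])) * seq.tr
    return out


def empirical_transition_matrix(
    seqs: StateSequence | list[StateSequence], mask: np.ndarray | None = None
) -> np.ndarray:
    """Row-normalized pooled bigram counts over consecutive frame pairs.

    Transitions are counted from frame t to t+1 and never across subjects
    or mask-segment boundaries.  Rows without any observed transition are
    NaN (undefined), not zero.
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    K = max(s.K for s in seqs)
    counts = np.zeros((K, K))
    n_pairs = 0
    for seq in seqs:
        for seg in _mask_segments(mask, len(seq)):
            lab = seq.labels[seg]
            if lab.size < 2:
                continue
            np.add.at(counts, (lab[:-1] - 1, lab[1:] - 1), 1)
            n_pairs += lab.size - 1
    if n_pairs == 0:
        raise ModelError("no transitions observed")
    rows = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        A = counts / rows
    A[rows[:, 0] == 0] = np.nan
    return A


def switch_paths(
    seqs: StateSequence | list[StateSequence], a: int, b: int
) -> dict:
    """Direct and mediated run-level paths from state ``a`` to state ``b``.

    Sequences are collapsed to their run-level form (consecutive duplicates
    merged); ``direct`` counts run bigrams (a, b) and ``via`` counts run
    trigrams (a, v, b) for every mediator v not in {a, b}.
    """
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    direct = 0
    via: dict[int, int] = {}
    for seq in seqs:
        vals, _ = run_length_encode(seq.labels)
        for i in range(len(vals) - 1):
            if vals[i] == a and vals[i + 1] == b:
                direct += 1
        for i in range(len(vals) - 2):
            v = int(vals[i + 1])
            if vals[i] == a and vals[i + 2] == b and v not in (a, b):
                via[v] = via.get(v, 0) + 1
    return {"direct": direct, "via": via}


def onset_transition_occupancy(
    seqs: StateSequence | list[StateSequence],
    design: BlockDesign,
    state: int,
    window_s: float = 5.0,
    conditions: list[str] | None = None,
) -> float:
    """Fraction of frames in ``state`` within ``[onset, onset + window_s)``
    pooled over all block onsets (optionally restricted to conditions)."""
    if window_s <= 0:
        raise ModelError("window_s must be positive")
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    tr = design.tr
    w = int(np.ceil(window_s / tr))
    hits = total = 0
    for seq in seqs:
        for onset, _, cond in design.intervals:
            if conditions is not None and cond not in conditions:
                continue
            a = int(np.floor(onset / tr))
            bnd = a + w
            if bnd > len(seq):
                warnings.warn(
                    f"onset window at {onset:.1f}s truncated by series end",
                    RuntimeWarning, stacklevel=2,
                )
                bnd = len(seq)
            seg = seq.labels[a:bnd]
            hits += int((seg == state).sum())
            total += seg.size
    return hits / total if total else 0.0


def compute_state_metrics(
    seqs: StateSequence | list[StateSequence], mask: np.ndarray | None = None
) -> StateMetrics:
    """Occupancy, lifetimes and empirical transitions in one bundle."""
    if isinstance(seqs, StateSequence):
        seqs = [seqs]
    K = max(s.K for s in seqs)
    counts = np.zeros(K)
    lifetimes: list[np.ndarray] = []
    for s in seqs:
        lab = _masked_labels(s, mask)
        counts += np.bincount(lab - 1, minlength=K)
        lifetimes.append(mean_lifetime(s, mask))
    occ = counts / counts.sum()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mlt = np.nanmean(np.vstack(lifetimes), axis=0)
    A = empirical_transition_matrix(seqs, mask)
    return StateMetrics(occupancy=occ, mean_lifetime_s=mlt, empirical_A=A,
                        n_frames=int(counts.sum()))


def match_states(
    fitA: FitResult,
    fitB: FitResult,
    data=None,
) -> tuple[dict[int, int], np.ndarray]:
    """One-to-one state matching between two fits via posterior correlation.

    Both models' posterior time courses are computed on the *same* data;
    the exclusive assignment maximizing total Pearson correlation between
    matched time courses is returned as ``{state_in_A: state_in_B}``
    (1-based) together with the per-pair correlations.  When the state
    counts differ, only ``min(K_A, K_B)`` states are matched.
    """
    from scipy.optimize import linear_sum_assignment

    ys = _match_data_arrays(fitA, data)
    gA = np.vstack([posterior_timecourse(fitA.params, y) for y in ys])
    gB = np.vstack([posterior_timecourse(fitB.params, y) for y in ys])
    KA, KB = gA.shape[1], gB.shape[1]
    C = np.empty((KA, KB))
    for i in range(KA):
        for j in range(KB):
            C[i, j] = _safe_corr(gA[:, i], gB[:, j])
    row, col = linear_sum_assignment(-C)
    mapping = {int(i) + 1: int(j) + 1 for i, j in zip(row, col)}
    corrs = C[row, col]
    return mapping, corrs


def _match_data_arrays(fit: FitResult, data) -> list[np.ndarray]:
    if data is None:
        raise ModelError("match_states needs the data to evaluate both fits on")
    if hasattr(data, "subjects"):
        return [np.asarray(y, dtype=float) for y in data.subjects.values()]
    return [np.atleast_2d(np.asarray(data, dtype=float))]


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
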