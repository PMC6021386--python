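"""Secondary analyses on fitted states.

Condition prediction from posterior time courses (linear multiclass
classifier, leave-one-subject-out, permutation test), link-wise
connectivity contrasts with Benjamini-Hochberg FDR, graph metrics on
top-proportion-thresholded state networks, behavior regression with
leave-one-out cross-validation, and the sliding-window + k-means baseline
that the switching model is compared against.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import ModelError, cov_to_corr

__all__ = [
    "ConnectivityFeature",
    "connectivity_features",
    "classify_conditions",
    "linkwise_tests",
    "binarize_top_edges",
    "node_degree",
    "betweenness",
    "behavior_regression",
    "sliding_window_clustering",
]


@dataclass
class ConnectivityFeature:
    """Fisher-z link values per (subject, state).

    ``values[subject][state]`` is the z-transformed lower triangle of the
    state's correlation matrix, indexed row-major, 0-based
    (``(1,0), (2,0), (2,1), ...``).
    """

    values: dict[str, dict[int, np.ndarray]]
    D: int

    @staticmethod
    def link_index(D: int) -> tuple[np.ndarray, np.ndarray]:
        return np.tril_indices(D, k=-1)


def connectivity_features(
    covariances: dict[str, dict[int, np.ndarray]]
) -> ConnectivityFeature:
    """Fisher-z transformed lower-triangle correlations per subject/state."""
    out: dict[str, dict[int, np.ndarray]] = {}
    D = None
    for sid, per_state in covariances.items():
        out[sid] = {}
        for k, C in per_state.items():
            R = cov_to_corr(np.asarray(C, dtype=float))
            D = R.shape[0]
            il = np.tril_indices(D, k=-1)
            out[sid][k] = np.arctanh(np.clip(R[il], -1 + 1e-12, 1 - 1e-12))
    return ConnectivityFeature(values=out, D=D or 0)


# ---------------------------------------------------------------------------
# Condition prediction


def classify_conditions(
    posteriors: dict[str, np.ndarray],
    labels: dict[str, np.ndarray],
    scheme: str = "loso",
    n_perm: int = 500,
    seed: int = 0,
    C: float = 1.0,
) -> tuple[float, float]:
    """Predict the per-frame task condition from state posteriors.

    A linear multiclass (one-vs-rest logistic) classifier is trained on the
    training folds' frames and scored on held-out frames; accuracy is the
    frame-weighted mean over folds.  ``scheme`` is ``"loso"``
    (leave-one-subject-out) or ``"split-half"`` (train first half of
    subjects, test the rest; the cross-session analogue).  The permutation
    p-value shuffles condition labels within subject:
    ``p = (1 + #{perm >= obs}) / (1 + n_perm)``.
    """
    from sklearn.linear_model import LogisticRegression

    sids = list(posteriors)
    if len(sids) < 2 and scheme == "loso":
        raise ModelError("leave-one-subject-out needs at least 2 subjects")
    all_labels = np.concatenate([np.asarray(labels[s]) for s in sids])
    if np.unique(all_labels).size < 2:
        raise ModelError("need at least two distinct conditions")

    def _folds():
        if scheme == "loso":
            for s in sids:
                yield [t for t in sids if t != s], [s]
        elif scheme == "split-half":
            h = len(sids) // 2
            yield sids[:h], sids[h:]
            yield sids[h:], sids[:h]
        else:
            raise ModelError(f"unknown scheme {scheme!r}")

    def _accuracy(lab: dict[str, np.ndarray]) -> float:
        hits = total = 0
        for train, test in _folds():
            Xtr = np.vstack([posteriors[s] for s in train])
            ytr = np.concatenate([lab[s] for s in train])
            clf = LogisticRegression(max_iter=2000, C=C)
            clf.fit(Xtr, ytr)
            for s in test:
                pred = clf.predict(posteriors[s])
                hits += int((pred == np.asarray(lab[s])).sum())
                total += len(pred)
        return hits / total

    obs = _accuracy({s: np.asarray(labels[s]) for s in sids})
    if n_perm <= 0:
        return obs, float("nan")
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        perm = {s: rng.permutation(np.asarray(labels[s])) for s in sids}
        if _accuracy(perm) >= obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return obs, p


# ---------------------------------------------------------------------------
# Link-wise tests


def linkwise_tests(
    features: ConnectivityFeature, stateA: int, stateB: int, q: float = 0.05
) -> dict:
    """Paired two-tailed t-test per link between two states, BH-corrected.

    Subjects contribute both states, so the test is paired across subjects.
    Zero-variance links get p = 1 and are flagged.
    """
    from statsmodels.stats.multitest import multipletests

    sids = [s for s in features.values if stateA in features.values[s]
            and stateB in features.values[s]]
    if len(sids) < 3:
        raise ModelError("link-wise tests need at least 3 subjects with both states")
    A = np.vstack([features.values[s][stateA] for s in sids])
    B = np.vstack([features.values[s][stateB] for s in sids])
    diff = A - B
    m = A.shape[1]
    tvals = np.zeros(m)
    pvals = np.ones(m)
    degenerate = np.zeros(m, dtype=bool)
    for i in range(m):
        if np.allclose(diff[:, i].std(ddof=1), 0.0):
            degenerate[i] = True
            continue
        t, p = sps.ttest_rel(A[:, i], B[:, i])
        tvals[i], pvals[i] = t, p
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return {"t": tvals, "p": pvals, "p_adj": p_adj, "reject": reject,
            "degenerate": degenerate, "subjects": sids}


# ---------------------------------------------------------------------------
# Graph metrics


def binarize_top_edges(C_or_R: np.ndarray, proportion: float) -> np.ndarray:
    """Keep the ceil(proportion * E) largest off-diagonal weights as edges.

    Ties at the cutoff break toward the lower (row, col) index, so the
    adjacency is reproducible for equal-weight inputs.
    """
    if not 0 < proportion <= 1:
        raise ModelError("proportion must be in (0, 1]")
    W = np.asarray(C_or_R, dtype=float)
    D = W.shape[0]
    il = np.tril_indices(D, k=-1)
    w = W[il]
    E = w.size
    keep = int(np.ceil(proportion * E))
    # sort by (-weight, row, col): stable tie-break toward lower indices
    order = np.lexsort((il[1], il[0], -w))
    adj = np.zeros((D, D), dtype=int)
    sel = order[:keep]
    adj[il[0][sel], il[1][sel]] = 1
    adj |= adj.T
    return adj


def node_degree(adj: np.ndarray) -> np.ndarray:
    """Row sums of a symmetric 0/1 adjacency."""
    adj = _check_adj(adj)
    return adj.sum(axis=1)


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness centrality on an unweighted graph.

    Sum over unordered node pairs (s, t) of the fraction of shortest s-t
    paths passing through the node; disconnected pairs contribute 0.
    """
    import networkx as nx

    adj = _check_adj(adj)
    G = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(G, normalized=False)
    return np.array([bc[i] for i in range(adj.shape[0])])


def _check_adj(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ModelError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ModelError("adjacency must be symmetric")
    if not np.isin(adj, [0, 1]).all():
        raise ModelError("adjacency must be 0/1")
    return adj.astype(int)


# ---------------------------------------------------------------------------
# Behavior regression


def behavior_regression(
    features: np.ndarray, y: np.ndarray, scheme: str = "loo"
) -> tuple[np.ndarray, float, float]:
    """Leave-one-out OLS prediction of a per-subject score.

    Returns pooled out-of-fold predictions, the Pearson correlation between
    predicted and observed scores, and its two-tailed p-value.  Collinear
    feature matrices fall back to a tiny ridge (lambda = 1e-6) with a
    warning.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n, f = X.shape
    if n != y.size:
        raise ModelError("features and scores disagree in subject count")
    if n <= f + 1:
        raise ModelError(f"need more subjects ({n}) than features + 1 ({f + 1})")
    if scheme != "loo":
        raise ModelError(f"unknown scheme {scheme!r}")
    Xd = np.column_stack([X, np.ones(n)])
    preds = np.empty(n)
    warned = False
    for i in range(n):
        idx = np.arange(n) != i
        A = Xd[idx]
        b = y[idx]
        gram = A.T @ A
        if np.linalg.cond(gram) > 1e12:
            if not warned:
                warnings.warn("collinear features: ridge fallback (lambda=1e-6)",
                              RuntimeWarning, stacklevel=2)
                warned = True
            gram = gram + 1e-6 * np.eye(gram.shape[0])
        beta = np.linalg.solve(gram, A.T @ b)
        preds[i] = Xd[i] @ beta
    r, p = sps.pearsonr(preds, y)
    return preds, float(r), float(p)


# ---------------------------------------------------------------------------
# Sliding-window clustering baseline


def sliding_window_clustering(
    y: np.ndarray,
    window_frames: int,
    stride: int = 1,
    k_range: range | list[int] = range(2, 7),
    seed: int = 0,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Sliding-window covariance + k-means baseline.

    Per-window covariances (Ledoit-Wolf shrinkage when the window is
    shorter than the channel count) are vectorized (lower triangle incl.
    diagonal) and clustered with k-means for each k in ``k_range``; k is
    chosen by silhouette, first k wins ties.  Returns (per-window labels
    for the chosen k, chosen k, window start frames).
    """
    from sklearn.cluster import KMeans
    from sklearn.covariance import LedoitWolf
    from sklearn.metrics import silhouette_score

    y = np.atleast_2d(np.asarray(y, dtype=float))
    T, D = y.shape
    if window_frames >= T:
        raise ModelError("window must be shorter than the series")
    starts = np.arange(0, T - window_frames + 1, stride)
    if starts.size < 2:
        raise ModelError("series too short: fewer than 2 windows")
    il = np.tril_indices(D)
    feats = np.empty((starts.size, il[0].size))
    shrink = window_frames < D + 2
    for i, a in enumerate(starts):
        seg = y[a : a + window_frames]
        if shrink:
            C = LedoitWolf().fit(seg).covariance_
        else:
            C = np.cov(seg.T, bias=True)
        feats[i] = np.atleast_2d(C)[il]
    ks = [k for k in k_range if 2 <= k < starts.size]
    if not ks:
        raise ModelError("no feasible k in k_range for this window count")
    best_k, best_sil, best_labels = None, -np.inf, None
    for k in ks:
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(feats)
        sil = silhouette_score(feats, km.labels_) if np.unique(km.labels_).size > 1 else -1.0
        if sil > best_sil:  # strict: argmax-first tie rule
            best_k, best_sil, best_labels = k, sil, km.labels_
    return best_labels, int(best_k), starts
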