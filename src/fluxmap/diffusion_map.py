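"""Asymmetric diffusion kernel and row-stochastic transition matrix.

The transition probability out of state ``t`` is a Gaussian kernel
centered on the *next observed* point ``D_{t+1}``::

    k(D_t, D_j) = exp(-||D_{t+1} - D_j||^2 / (2 sigma^2))

evaluated over the ``k_neighbors`` points nearest to ``D_{t+1}``
(including ``D_{t+1}`` itself) and then row-normalized.  Centering the
kernel forward in time is what makes the matrix asymmetric and lets its
complex spectrum expose cyclic fluxes; with the neighborhood shrunk to
the single next point the matrix degenerates to the observed sequence
itself (ones on the superdiagonal).

The bandwidth ``sigma^2`` is the product of the local temporal standard
deviations at ``t`` and ``t+1``, scaled by the mean kernel value over
the neighborhood.  That definition is self-referential; ``two_pass``
(default) resolves it with one provisional kernel pass, ``fixed_point``
iterates to convergence.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.neighbors import NearestNeighbors

from .datatypes import EmbeddedSeries, KernelConfig, TransitionMatrix

__all__ = [
    "knn",
    "local_std",
    "build_transition_matrix",
    "simulate_states",
]

_BRUTE_LIMIT = 4000  # full pairwise distances below this size


def _as_points(points) -> np.ndarray:
    if isinstance(points, EmbeddedSeries):
        return points.points
    return np.asarray(points, dtype=float)


def knn(points, k: int) -> np.ndarray:
    """Euclidean k-nearest-neighbor indices of every point.

    The point itself is excluded; exact distance ties are broken toward
    the lower index.  Returns an (n, k) integer array.
    """
    x = _as_points(points)
    n = x.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n_points={n}")
    if n <= _BRUTE_LIMIT:
        d2 = _sq_dists(x, x)
        np.fill_diagonal(d2, np.inf)
        order = np.lexsort((np.broadcast_to(np.arange(n), (n, n)), d2), axis=1)
        return order[:, :k]
    # larger clouds: tree/brute query with a margin, then a stable
    # re-sort by (distance, index) to make tie-breaks deterministic
    m = min(n - 1, k + 8)
    nn = NearestNeighbors(n_neighbors=m + 1).fit(x)
    dist, idx = nn.kneighbors(x)
    out = np.empty((n, k), dtype=int)
    for i in range(n):
        cand_d, cand_i = dist[i], idx[i]
        keep = cand_i != i
        cand_d, cand_i = cand_d[keep][:m], cand_i[keep][:m]
        order = np.lexsort((cand_i, cand_d))
        out[i] = cand_i[order[:k]]
    return out


def _sq_dists(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    d2 = (
        (a * a).sum(axis=1)[:, None]
        + (b * b).sum(axis=1)[None, :]
        - 2.0 * (a @ b.T)
    )
    np.maximum(d2, 0.0, out=d2)
    return d2


def local_std(points, t: int, window: int) -> float:
    """Pooled SD of coordinates in a temporal window centered at ``t``.

    The window covers frames ``[t - window//2, t + window//2)``,
    truncated at the series ends; the SD pools all coordinates of the
    points inside it (population convention, divide by n).
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    x = _as_points(points)
    lo = max(0, t - window // 2)
    hi = min(x.shape[0], t + (window + 1) // 2)
    return float(x[lo:hi].std())


def _local_std_all(x: np.ndarray, window: int) -> np.ndarray:
    n = x.shape[0]
    return np.array(
        [
            x[max(0, t - window // 2) : min(n, t + (window + 1) // 2)].std()
            for t in range(n)
        ]
    )


def _row_sigma2(d2: np.ndarray, sigma0_sq: float, mode: str) -> float:
    """Resolve the self-referential bandwidth for one row.

    ``d2`` are squared distances from D_{t+1} to its neighborhood
    (first entry 0 for D_{t+1} itself).
    """
    if sigma0_sq <= 0:
        return 0.0
    k0 = np.exp(-d2 / (2.0 * sigma0_sq))
    s2 = sigma0_sq * float(k0.mean())
    if mode == "fixed_point":
        for _ in range(50):
            k1 = np.exp(-d2 / (2.0 * max(s2, 1e-300)))
            s2_new = sigma0_sq * float(k1.mean())
            if abs(s2_new - s2) <= 1e-6 * max(s2, 1e-12):
                s2 = s2_new
                break
            s2 = s2_new
    return s2


def build_transition_matrix(
    emb: EmbeddedSeries, cfg: KernelConfig | None = None
) -> TransitionMatrix:
    """Build the asymmetric row-stochastic transition matrix.

    States are embedded points with a successor in the same recording
    (the final point of each recording is dropped from the state set).
    Row ``t`` places kernel mass on the ``k_neighbors`` states nearest
    to ``D_{t+1}``, always including ``D_{t+1}`` itself when it is a
    state; when the successor is a dropped recording-final point its
    mass is redirected to the nearest retained states.  Rows are
    normalized to sum to 1.  A degenerate bandwidth (locally constant
    data) falls back to putting all mass on the successor, with a
    warning.
    """
    if cfg is None:
        cfg = KernelConfig()
    x = emb.points
    n = x.shape[0]
    has_succ = np.empty(n, dtype=bool)
    has_succ[:-1] = emb.rec_ids[:-1] == emb.rec_ids[1:]
    has_succ[-1] = False
    states = np.flatnonzero(has_succ)
    n_states = states.size
    if n_states < 2:
        raise ValueError("need at least 2 states (points with successors)")
    global_to_state = -np.ones(n, dtype=int)
    global_to_state[states] = np.arange(n_states)

    k = cfg.k_neighbors
    # neighbors of each successor point among all points (self excluded);
    # extra margin so dropped points can be filtered out
    margin = min(n - 1, k + 4)
    nbrs = knn(x, margin) if margin >= 1 else np.empty((n, 0), dtype=int)
    sig_l = _local_std_all(x, cfg.local_window)

    rows, cols, vals = [], [], []
    warned = False
    for si, t in enumerate(states):
        succ = t + 1
        # neighborhood: successor first (distance 0), then its nearest
        # state neighbors up to k members total
        hood = [succ] if has_succ[succ] else []
        for j in nbrs[succ]:
            if len(hood) >= k:
                break
            if has_succ[j] and j != succ:
                hood.append(int(j))
        if not hood:
            hood = [int(j) for j in nbrs[succ] if has_succ[j]][:1]
        hood = np.asarray(hood, dtype=int)
        diff = x[hood] - x[succ]
        d2 = np.einsum("ij,ij->i", diff, diff)
        sigma0_sq = sig_l[succ] * sig_l[t]
        s2 = _row_sigma2(d2, sigma0_sq, cfg.sigma_mode)
        if s2 <= 0:
            if not warned:
                warnings.warn(
                    "degenerate kernel bandwidth (locally constant data); "
                    "assigning all mass to the next observed point",
                    stacklevel=2,
                )
                warned = True
            w = np.zeros(d2.size)
            w[int(np.argmin(d2))] = 1.0
        else:
            w = np.exp(-d2 / (2.0 * s2))
            total = w.sum()
            if total <= 0:
                w = np.zeros(d2.size)
                w[int(np.argmin(d2))] = 1.0
            else:
                w = w / total
        keep = w > 0
        rows.append(np.full(int(keep.sum()), si))
        cols.append(global_to_state[hood[keep]])
        vals.append(w[keep])

    probs = sp.csr_matrix(
        (
            np.concatenate(vals),
            (np.concatenate(rows), np.concatenate(cols)),
        ),
        shape=(n_states, n_states),
    )
    return TransitionMatrix(
        probs=probs,
        state_index=states,
        rec_ids=emb.rec_ids[states],
    )


def simulate_states(M: TransitionMatrix, x0, t: int) -> np.ndarray:
    """Propagate a distribution over states ``t`` steps: x_t = x_0 M^t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    x = np.asarray(x0, dtype=float)
    if not np.isclose(x.sum(), 1.0):
        raise ValueError("x0 must sum to 1")
    P = M.probs if isinstance(M, TransitionMatrix) else M
    for _ in range(t):
        x = x @ P
        x = np.asarray(x).ravel()
    return x
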