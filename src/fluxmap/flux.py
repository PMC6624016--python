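"""Cyclic-flux extraction: spectral phase and trajectory clustering.

The dominant cyclic flux of the asymmetric transition matrix is the
complex eigenvalue of largest modulus; the componentwise argument of
the associated eigenvector assigns each state a phase ``theta`` along
the flux.  When several disjoint fluxes coexist, states are first
grouped into fluxes by (1) densifying the matrix (powering it until
rows are no longer sparse), (2) computing the maximum time-lagged
correlation between rows, and (3) maximum-modularity (Louvain)
clustering of the resulting similarity graph.  Each flux then gets its
own coherent phase from the leading cyclic mode of its sub-matrix.
"""

from __future__ import annotations

import warnings

import numpy as np
import networkx as nx
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .datatypes import FluxDecomposition, TransitionMatrix

__all__ = [
    "leading_cyclic_mode",
    "assign_phase",
    "densify",
    "lagged_row_correlation",
    "cluster_fluxes",
    "decompose_fluxes",
]

_IM_TOL = 1e-8
_DENSE_LIMIT = 600


class NoCyclicModeError(RuntimeError):
    """Raised when the transition matrix has a purely real spectrum."""


def _get_probs(M) -> sp.csr_matrix:
    if isinstance(M, TransitionMatrix):
        return M.probs
    if sp.issparse(M):
        return M.tocsr()
    return sp.csr_matrix(np.asarray(M, dtype=float))


def _participation_ratio(v: np.ndarray) -> float:
    p = np.abs(v) ** 2
    return float(p.sum() ** 2 / (p**2).sum())


def leading_cyclic_mode(M, n_eigs: int = 40) -> tuple[complex, np.ndarray]:
    """Dominant complex eigenpair of the transition matrix.

    Returns the dominant complex eigenpair (conjugate-pair convention:
    positive imaginary part).  Selection proceeds in three steps over
    eigenvalues with ``|Im| > 1e-8``:

    1. candidates are the near-dominant complex modes, within 10% of
       the largest complex modulus;
    2. localized candidates -- participation ratio below half the
       candidates' maximum -- are discarded (they reflect slow
       oscillations of small state subsets, not the global flux);
    3. among the rest, the mode of smallest rotation rate ``|arg λ|``
       is returned: that is the fundamental of the cycle.  Harmonics
       rotate at integer multiples of the fundamental frequency and
       their moduli approach the fundamental's as noise vanishes, so a
       pure largest-modulus rule degenerates to an arbitrary pick among
       harmonics in the low-noise limit.  Modes slower than two full
       cycles per recording are skipped as unresolvable when a faster
       candidate exists.

    Raises :class:`NoCyclicModeError` when the spectrum is purely real
    (symmetric dynamics have no cyclic flux).
    """
    P = _get_probs(M)
    n = P.shape[0]
    if n <= _DENSE_LIMIT:
        vals, vecs = np.linalg.eig(P.toarray())
    else:
        k = min(n_eigs, n - 2)
        # fixed start vector: ARPACK is otherwise randomly initialized,
        # which would make fitted phases run-to-run nondeterministic
        v0 = np.full(n, 1.0 / n)
        vals, vecs = spla.eigs(P.astype(float), k=k, which="LM", v0=v0)
    cyc = np.flatnonzero(np.abs(vals.imag) > _IM_TOL)
    if cyc.size == 0:
        raise NoCyclicModeError(
            "no cyclic mode: all eigenvalues are real"
        )
    mods = np.abs(vals[cyc])
    near = cyc[mods >= 0.9 * mods.max()]
    if near.size > 1:
        prs = np.array([_participation_ratio(vecs[:, i]) for i in near])
        near = near[prs >= 0.5 * prs.max()]
    rates = np.abs(np.angle(vals[near]))
    resolvable = rates >= 4.0 * np.pi / n
    if resolvable.any():
        near = near[resolvable]
        rates = rates[resolvable]
    best = near[np.argmin(rates)]
    lam, vec = vals[best], vecs[:, best]
    if lam.imag < 0:
        lam, vec = np.conj(lam), np.conj(vec)
    return complex(lam), vec


def assign_phase(v: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Phase per state from the leading complex eigenvector.

    ``theta[t] = atan2(Im v_t, Re v_t)``; the global rotation is
    arbitrary.  Orientation is fixed so that the median per-step
    circular phase increment (states in frame order) is positive, which
    makes the flux run forward in time regardless of which member of
    the conjugate eigenpair was supplied.  Components with
    ``|v_t| < 1e-12`` have undefined phase and are flagged False in the
    returned mask.
    """
    v = np.asarray(v)
    theta = np.angle(v)
    defined = np.abs(v) >= 1e-12
    if defined.sum() >= 2:
        th = theta[defined]
        dth = np.angle(np.exp(1j * np.diff(th)))
        if np.median(dth) < 0:
            theta = np.angle(np.conj(v))
    return theta, defined


def densify(
    M, min_frac: float = 0.25, cap: int = 64
) -> tuple[np.ndarray, int]:
    """Power the matrix until every row is at least ``min_frac`` dense.

    Returns ``(M^N, N)`` for the smallest ``N >= 1`` such that every
    row of ``M^N`` has at least ``min_frac * n`` nonzero entries.  The
    exponent is capped at ``cap`` (with a warning) -- expected for
    reducible matrices such as permutation cycles or fully disjoint
    fluxes, whose powers can never reach the target fill.
    """
    if not (0 < min_frac <= 1):
        raise ValueError("min_frac must be in (0, 1]")
    P = _get_probs(M)
    n = P.shape[0]
    target = min_frac * n
    Pk = P.copy()
    exponent = 1
    while exponent < cap:
        nnz_rows = np.diff(Pk.tocsr().indptr)
        if nnz_rows.min() >= target:
            break
        Pk = Pk @ P
        Pk.data[np.abs(Pk.data) < 1e-300] = 0.0
        Pk.eliminate_zeros()
        exponent += 1
    else:
        nnz_rows = np.diff(Pk.tocsr().indptr)
        if nnz_rows.min() < target:
            warnings.warn(
                f"densification capped at N={cap} before reaching "
                f"{min_frac:.0%} row fill (reducible dynamics?)",
                stacklevel=2,
            )
    return np.asarray(Pk.todense()), exponent


def lagged_row_correlation(Md: np.ndarray) -> np.ndarray:
    """Maximum circular time-lagged Pearson correlation between rows.

    ``C[i, j] = max_t corr(row_i, roll(row_j, t))`` with the shift
    circular over state indices (states are in frame order, so shifting
    aligns trajectories traversed at different times).  The matrix is
    symmetrized as ``max(C_ij, C_ji)`` with unit diagonal; rows with
    zero variance correlate 0 with everything.

    All shifts are evaluated at once per pair through the cross-power
    spectrum (FFT), blocked over rows to bound memory.
    """
    Md = np.asarray(Md, dtype=float)
    if Md.ndim != 2:
        raise ValueError("expected a 2-D row matrix")
    n, m = Md.shape
    mu = Md.mean(axis=1, keepdims=True)
    sd = Md.std(axis=1, keepdims=True)
    ok = sd.ravel() > 0
    Z = np.where(sd > 0, (Md - mu) / np.where(sd > 0, sd, 1.0), 0.0)
    F = np.fft.rfft(Z, axis=1)
    C = np.empty((n, n))
    block = max(1, int(2e7 // max(1, n * (m // 2 + 1))))
    for s in range(0, n, block):
        e = min(n, s + block)
        cross = F[s:e, None, :] * np.conj(F)[None, :, :]
        cc = np.fft.irfft(cross, n=m, axis=2) / m
        C[s:e] = cc.max(axis=2)
    C[~ok, :] = 0.0
    C[:, ~ok] = 0.0
    C = np.maximum(C, C.T)
    np.fill_diagonal(C, 1.0)
    return C


def cluster_fluxes(
    C: np.ndarray, seed: int = 0, n_restarts: int = 10
) -> np.ndarray:
    """Maximum-modularity clustering of the similarity graph.

    Negative similarities are clipped to zero and the diagonal is
    ignored.  Greedy modularity optimization (Leiden refinement of the
    Louvain scheme, via ``leidenalg``) is run ``n_restarts`` times with
    consecutive seeds and the highest-modularity partition is kept;
    labels are contiguous integers ordered by each cluster's smallest
    state index.  Falls back to networkx's pure-Python Louvain when
    igraph/leidenalg are unavailable.
    """
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    W = np.clip(C, 0.0, None)
    np.fill_diagonal(W, 0.0)
    if W.sum() == 0:
        return np.zeros(n, dtype=int)
    try:
        import igraph as ig
        import leidenalg
    except ImportError:  # pragma: no cover - slow fallback
        return _cluster_fluxes_nx(W, seed, n_restarts)
    r_idx, c_idx = np.nonzero(np.triu(W, k=1))
    g = ig.Graph(
        n=n, edges=list(zip(r_idx.tolist(), c_idx.tolist())), directed=False
    )
    weights = W[r_idx, c_idx].tolist()
    best_labels, best_q = None, -np.inf
    for r in range(n_restarts):
        part = leidenalg.find_partition(
            g,
            leidenalg.ModularityVertexPartition,
            weights=weights,
            seed=seed + r,
        )
        q = part.quality()
        if q > best_q:
            best_q, best_labels = q, np.asarray(part.membership)
    best_labels = _merge_connected_clusters(W, best_labels)
    return _relabel_by_first(best_labels)


def _merge_connected_clusters(
    W: np.ndarray, labels: np.ndarray, merge_ratio: float = 0.8
) -> np.ndarray:
    """Merge cluster pairs that are not close to disjoint.

    Distinct fluxes are disjoint loops, so their states' (densified)
    transition rows have nearly orthogonal supports and near-zero
    lagged correlation; modularity optimization, by contrast, happily
    splits a single loop into phase arcs whose mutual similarity stays
    high.  Cluster pairs whose mean between-similarity exceeds
    ``merge_ratio`` times the mean within-similarity are therefore
    merged (greedily, highest ratio first) until all remaining pairs
    are genuinely weakly connected.
    """
    labels = labels.copy()
    while True:
        groups = [np.flatnonzero(labels == k) for k in np.unique(labels)]
        if len(groups) < 2:
            break
        within = []
        for idx in groups:
            block = W[np.ix_(idx, idx)]
            if idx.size > 1:
                within.append(block.sum() / (idx.size * (idx.size - 1)))
        within_mean = np.mean(within) if within else 0.0
        if within_mean <= 0:
            break
        best = (None, 0.0)
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                between = W[np.ix_(groups[a], groups[b])].mean()
                ratio = between / within_mean
                if ratio > best[1]:
                    best = ((a, b), ratio)
        if best[0] is None or best[1] < merge_ratio:
            break
        a, b = best[0]
        labels[groups[b]] = labels[groups[a]][0]
    return labels


def _cluster_fluxes_nx(W: np.ndarray, seed: int, n_restarts: int) -> np.ndarray:
    G = nx.from_numpy_array(W)
    best_parts, best_q = None, -np.inf
    for r in range(n_restarts):
        parts = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, parts, weight="weight")
        if q > best_q:
            best_q, best_parts = q, parts
    labels = np.empty(W.shape[0], dtype=int)
    for lbl, part in enumerate(sorted(best_parts, key=min)):
        for node in part:
            labels[node] = lbl
    return _relabel_by_first(_merge_connected_clusters(W, labels))


def _relabel_by_first(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    remap = {}
    out = np.empty_like(labels)
    for i, lab in enumerate(labels):
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


def _per_flux_phase(
    P: sp.csr_matrix, alpha: np.ndarray, theta_global: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Recompute a coherent phase within each flux's sub-matrix."""
    theta = theta_global.copy()
    defined = np.ones(theta.size, dtype=bool)
    for a in np.unique(alpha):
        idx = np.flatnonzero(alpha == a)
        if idx.size < 3:
            continue
        sub = P[idx][:, idx].toarray()
        row_sums = sub.sum(axis=1)
        empty = row_sums <= 0
        sub[empty] = 0.0
        sub[empty, np.arange(sub.shape[0])[empty]] = 1.0
        row_sums[empty] = 1.0
        sub = sub / row_sums[:, None]
        try:
            _, vec = leading_cyclic_mode(sub)
        except NoCyclicModeError:
            continue  # keep the global phase for this flux
        th, ok = assign_phase(vec)
        theta[idx] = th
        defined[idx] = ok
    return theta, defined


def decompose_fluxes(
    M: TransitionMatrix,
    min_frac: float = 0.25,
    seed: int = 0,
    cluster: bool = True,
    max_cluster_states: int = 600,
    points: np.ndarray | None = None,
    per_flux_phase: bool = True,
) -> FluxDecomposition:
    """Full flux decomposition: phase theta and flux label alpha per state.

    When ``cluster`` is False all states share flux 0 and only the
    global leading cyclic mode is used.  For matrices larger than
    ``max_cluster_states`` the all-pairs lagged row correlation is
    computed on an evenly strided subset of states and the labels of
    the remaining states are filled in from their nearest clustered
    state in the embedded space (``points``; falls back to nearest
    state index when absent).
    """
    P = _get_probs(M)
    n = P.shape[0]
    lam, vec = leading_cyclic_mode(M)
    theta, defined = assign_phase(vec)
    exponent = 1

    if cluster and n >= 3:
        if n > max_cluster_states:
            stride = int(np.ceil(n / max_cluster_states))
            sample = np.arange(0, n, stride)
        else:
            sample = np.arange(n)
        Md, exponent = densify(P, min_frac=min_frac)
        C = lagged_row_correlation(Md[np.ix_(sample, sample)])
        sub_labels = cluster_fluxes(C, seed=seed)
        alpha = np.empty(n, dtype=int)
        alpha[sample] = sub_labels
        rest = np.setdiff1d(np.arange(n), sample)
        if rest.size:
            if points is not None:
                x = np.asarray(points, dtype=float)
                d2 = (
                    (x[rest] ** 2).sum(1)[:, None]
                    + (x[sample] ** 2).sum(1)[None, :]
                    - 2.0 * x[rest] @ x[sample].T
                )
                alpha[rest] = sub_labels[np.argmin(d2, axis=1)]
            else:
                nearest = np.clip(
                    np.searchsorted(sample, rest), 0, sample.size - 1
                )
                alpha[rest] = sub_labels[nearest]
    else:
        alpha = np.zeros(n, dtype=int)

    # relabel contiguous from 0, ordered by first occurrence
    _, first = np.unique(alpha, return_index=True)
    remap = {
        old: new
        for new, old in enumerate(alpha[np.sort(first)])
    }
    alpha = np.array([remap[a] for a in alpha], dtype=int)

    if per_flux_phase and alpha.max() >= 0:
        theta, defined = _per_flux_phase(P, alpha, theta)

    return FluxDecomposition(
        theta=theta,
        alpha=alpha,
        lead_eigenvalue=lam,
        lead_eigenvector=vec,
        densify_exponent=exponent,
        theta_defined=defined,
    )
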