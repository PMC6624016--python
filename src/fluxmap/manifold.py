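"""The (theta, alpha) manifold: phase bins, summaries, projection.

Each flux's phase axis is divided into Gaussian bins of width
``delta_theta`` (radians); every observed state is assigned to the bin
of maximal circular Gaussian likelihood.  Bins carry the mean embedded
activity of their member states, a snapshot of raw (lag-0) neuronal
activity, the empirical distribution of behavior labels, an occupancy
count, and an empirical bin-level transition matrix.  The manifold can
decode behavior for new recordings -- including recordings missing some
of the model's neurons, in which case distances to bin centroids are
computed over the shared coordinates only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import gaussian_filter1d
from sklearn.decomposition import PCA

from .datatypes import EmbedConfig, EmbeddedSeries, FluxDecomposition, Recording
from .embedding import delay_embed
from .preprocess import derivative, gaussian_smooth, zscore

__all__ = [
    "BinSet",
    "ManifoldModel",
    "make_bins",
    "assign_bin",
    "assign_bins",
    "summarize_bins",
    "bin_transition_matrix",
    "build_manifold",
    "project",
    "dpca_coordinates",
]


@dataclass
class BinSet:
    """Phase-bin definitions: per-bin flux label, center, Gaussian SD."""

    alpha: np.ndarray
    center: np.ndarray
    sd: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.alpha.size


@dataclass
class ManifoldModel:
    """A fitted (theta, alpha) manifold with per-bin summaries.

    ``mean_activity`` holds raw-neuron (lag-0, z-scored) snapshots for
    *all* recorded neurons, including any excluded from distance
    computation; ``model_neurons`` are the names actually used for
    embedding and distances.
    """

    bins: BinSet
    mean_embedded: np.ndarray
    mean_activity: np.ndarray
    behavior_dist: np.ndarray
    behavior_vocab: list
    occupancy: np.ndarray
    flagged: np.ndarray
    bin_transitions: np.ndarray
    visited: np.ndarray
    model_neurons: list
    all_neurons: list
    embed_config: EmbedConfig
    smooth_sigma: float = 1.0
    min_count: int = 5
    theta: Optional[np.ndarray] = None
    alpha: Optional[np.ndarray] = None
    assignments: Optional[np.ndarray] = None
    state_rec_ids: Optional[np.ndarray] = None
    config: dict = field(default_factory=dict)

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    @property
    def n_occupied_bins(self) -> int:
        return int((self.occupancy > 0).sum())

    def modal_behavior(self, bin_idx: int) -> str:
        """Most prevalent behavior of a bin; 'unassigned' when flagged."""
        if self.flagged[bin_idx] or self.behavior_dist.shape[1] == 0:
            return "unassigned"
        return self.behavior_vocab[int(np.argmax(self.behavior_dist[bin_idx]))]


def make_bins(
    decomp: FluxDecomposition | np.ndarray, delta_theta: float = 0.05
) -> BinSet:
    """Uniform circular phase bins per flux.

    Centers are spaced ``2*pi / ceil(2*pi / delta_theta)`` apart over
    (-pi, pi] for every flux label, each bin a circular Gaussian of SD
    ``delta_theta``.  Empty bins are kept (they are flagged later, at
    summary time).
    """
    if delta_theta <= 0:
        raise ValueError("delta_theta must be > 0")
    if isinstance(decomp, FluxDecomposition):
        fluxes = np.unique(decomp.alpha)
    else:
        fluxes = np.unique(np.asarray(decomp, dtype=int))
    m = int(np.ceil(2.0 * np.pi / delta_theta))
    spacing = 2.0 * np.pi / m
    centers = -np.pi + spacing * (np.arange(m) + 1.0)  # (-pi, pi]
    alpha = np.repeat(fluxes, m)
    center = np.tile(centers, fluxes.size)
    sd = np.full(alpha.size, float(delta_theta))
    return BinSet(alpha=alpha, center=center, sd=sd)


def _circ_dist(a, b):
    return np.angle(np.exp(1j * (np.asarray(a) - np.asarray(b))))


def assign_bin(theta: float, alpha: int, bins: BinSet) -> int:
    """Most likely bin for one state (circular Gaussian likelihood).

    Ties break toward the lower bin index.
    """
    mask = bins.alpha == alpha
    if not mask.any():
        raise ValueError(f"no bins defined for flux {alpha}")
    idx = np.flatnonzero(mask)
    d = np.abs(_circ_dist(theta, bins.center[idx]))
    loglik = -0.5 * (d / bins.sd[idx]) ** 2
    return int(idx[np.argmax(loglik)])


def assign_bins(
    theta: np.ndarray, alpha: np.ndarray, bins: BinSet
) -> np.ndarray:
    """Vectorized :func:`assign_bin` over all states."""
    out = np.empty(theta.size, dtype=int)
    for a in np.unique(alpha):
        mask_b = np.flatnonzero(bins.alpha == a)
        if mask_b.size == 0:
            raise ValueError(f"no bins defined for flux {a}")
        sel = np.flatnonzero(alpha == a)
        d = np.abs(_circ_dist(theta[sel][:, None], bins.center[mask_b][None, :]))
        loglik = -0.5 * (d / bins.sd[mask_b][None, :]) ** 2
        out[sel] = mask_b[np.argmax(loglik, axis=1)]
    return out


def summarize_bins(
    bins: BinSet,
    assignments: np.ndarray,
    embedded: np.ndarray,
    activity: Optional[np.ndarray] = None,
    behaviors: Optional[np.ndarray] = None,
    min_count: int = 5,
):
    """Per-bin means, behavior distributions, occupancy, and flags.

    ``activity`` is the raw-neuron (lag-0) snapshot per state, which
    may cover more neurons than the embedding used.  Bins with fewer
    than ``min_count`` member states are flagged (their behavior is
    reported as 'unassigned'); bins with zero occupancy get no
    summaries.
    """
    nb = bins.n_bins
    embedded = np.asarray(embedded, dtype=float)
    occupancy = np.bincount(assignments, minlength=nb)
    mean_embedded = np.zeros((nb, embedded.shape[1]))
    n_act = 0 if activity is None else activity.shape[1]
    mean_activity = np.zeros((nb, n_act))
    vocab = []
    if behaviors is not None:
        vocab = sorted(set(np.asarray(behaviors).tolist()))
    behavior_dist = np.zeros((nb, len(vocab)))
    vocab_index = {v: i for i, v in enumerate(vocab)}
    for b in range(nb):
        members = np.flatnonzero(assignments == b)
        if members.size == 0:
            continue
        mean_embedded[b] = embedded[members].mean(axis=0)
        if activity is not None:
            mean_activity[b] = activity[members].mean(axis=0)
        if behaviors is not None:
            counts = np.bincount(
                [vocab_index[v] for v in behaviors[members]],
                minlength=len(vocab),
            )
            behavior_dist[b] = counts / counts.sum()
    flagged = occupancy < min_count
    return mean_embedded, mean_activity, behavior_dist, vocab, occupancy, flagged


def bin_transition_matrix(
    bin_seq: np.ndarray,
    rec_ids: Optional[np.ndarray] = None,
    n_bins: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical row-stochastic transition matrix over bins.

    Counts transitions between consecutive assignments in frame order,
    never across recording boundaries, and row-normalizes.  Returns
    ``(matrix, visited)`` where rows of never-departed bins are zero
    and flagged False in ``visited``.
    """
    bin_seq = np.asarray(bin_seq, dtype=int)
    if n_bins is None:
        n_bins = int(bin_seq.max()) + 1
    if rec_ids is None:
        rec_ids = np.zeros(bin_seq.size, dtype=int)
    counts = np.zeros((n_bins, n_bins))
    same = rec_ids[:-1] == rec_ids[1:]
    np.add.at(counts, (bin_seq[:-1][same], bin_seq[1:][same]), 1.0)
    row_sums = counts.sum(axis=1)
    visited = row_sums > 0
    probs = np.zeros_like(counts)
    probs[visited] = counts[visited] / row_sums[visited, None]
    return probs, visited


def build_manifold(
    emb: EmbeddedSeries,
    decomp: FluxDecomposition,
    M_states: np.ndarray,
    activity: Optional[np.ndarray] = None,
    behaviors: Optional[np.ndarray] = None,
    delta_theta: float = 0.05,
    min_count: int = 5,
    all_neurons: Optional[Sequence[str]] = None,
    smooth_sigma: float = 1.0,
    config: Optional[dict] = None,
) -> ManifoldModel:
    """Assemble a :class:`ManifoldModel` from a flux decomposition.

    ``M_states`` indexes the embedded points that are states of the
    transition matrix (see
    :func:`fluxmap.diffusion_map.build_transition_matrix`);
    ``activity``/``behaviors`` are per-state raw activity snapshots and
    behavior labels aligned to those states.
    """
    bins = make_bins(decomp, delta_theta)
    assignments = assign_bins(decomp.theta, decomp.alpha, bins)
    state_points = emb.points[M_states]
    (
        mean_embedded,
        mean_activity,
        behavior_dist,
        vocab,
        occupancy,
        flagged,
    ) = summarize_bins(
        bins, assignments, state_points, activity, behaviors, min_count
    )
    rec_ids = emb.rec_ids[M_states]
    transitions, visited = bin_transition_matrix(
        assignments, rec_ids, n_bins=bins.n_bins
    )
    return ManifoldModel(
        bins=bins,
        mean_embedded=mean_embedded,
        mean_activity=mean_activity,
        behavior_dist=behavior_dist,
        behavior_vocab=vocab,
        occupancy=occupancy,
        flagged=flagged,
        bin_transitions=transitions,
        visited=visited,
        model_neurons=list(emb.neuron_names),
        all_neurons=list(all_neurons) if all_neurons is not None else list(emb.neuron_names),
        embed_config=EmbedConfig(tau=emb.tau, n_delays=emb.n_delays),
        smooth_sigma=smooth_sigma,
        min_count=min_count,
        theta=decomp.theta,
        alpha=decomp.alpha,
        assignments=assignments,
        state_rec_ids=rec_ids,
        config=config or {},
    )


def _coord_mask(model: ManifoldModel, available: Sequence[str]) -> np.ndarray:
    """Boolean mask over embedded coordinates for a neuron subset."""
    n = len(model.model_neurons)
    keep = np.array([name in set(available) for name in model.model_neurons])
    n_slices = 2 * (model.embed_config.n_delays + 1)
    return np.tile(keep, n_slices)


def project(
    model: ManifoldModel,
    new_rec: Recording,
    available_neurons: Optional[Sequence[str]] = None,
) -> np.ndarray:
    """Assign every frame of a new recording to its nearest phase bin.

    The recording is preprocessed and delay-embedded with the model's
    configuration using only ``available_neurons`` (default: all model
    neurons present in the recording); each embedded point goes to the
    bin whose mean embedded activity is nearest in Euclidean distance
    restricted to the shared coordinates.  Flagged (under-occupied)
    bins are excluded as targets: their few-point centroids are
    unreliable landmarks and they carry no behavior distribution.
    """
    if available_neurons is None:
        available_neurons = [
            n for n in model.model_neurons if n in new_rec.neuron_names
        ]
    available = [n for n in available_neurons if n in model.model_neurons]
    if not available:
        raise ValueError("no shared neurons between model and recording")
    # keep the model's neuron order
    available = [n for n in model.model_neurons if n in available]
    sub = new_rec.subset(available)
    norm = zscore(gaussian_smooth(sub, model.smooth_sigma))
    emb = delay_embed(norm, derivative(norm), model.embed_config)
    mask = _coord_mask(model, available)
    centers = model.mean_embedded[:, mask]
    usable = np.flatnonzero((model.occupancy > 0) & ~model.flagged)
    if usable.size == 0:
        usable = np.flatnonzero(model.occupancy > 0)
    d2 = (
        (emb.points**2).sum(1)[:, None]
        + (centers[usable] ** 2).sum(1)[None, :]
        - 2.0 * emb.points @ centers[usable].T
    )
    return usable[np.argmin(d2, axis=1)]


def dpca_coordinates(model: ManifoldModel, n_components: int = 3) -> np.ndarray:
    """Principal-axes coordinates of the theta-ordered bin activity.

    Per-bin mean activity is ordered by (alpha, theta), smoothed with a
    circular Gaussian of SD two bins along theta within each flux, and
    projected onto its first three principal axes.  Export only; plays
    no role in the dynamics.
    """
    if model.n_bins < n_components:
        raise ValueError(f"need at least {n_components} bins")
    acts = model.mean_activity.copy()
    for a in np.unique(model.bins.alpha):
        idx = np.flatnonzero(model.bins.alpha == a)
        order = idx[np.argsort(model.bins.center[idx])]
        acts[order] = gaussian_filter1d(
            acts[order], sigma=2.0, axis=0, mode="wrap"
        )
    pca = PCA(n_components=n_components, svd_solver="full")
    return pca.fit_transform(acts)
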