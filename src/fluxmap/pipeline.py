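"""End-to-end orchestration and scikit-learn style estimators.

The full chain -- preprocess, delay-embed, asymmetric diffusion map,
flux decomposition, manifold binning -- is exposed both as the
:func:`fit_pipeline` function and as the :class:`CyclicFluxManifold`
estimator (``fit`` on recordings, ``transform`` to phase bins,
``predict`` behavior labels).  The smaller stages are available as
composable estimators too (:class:`TracePreprocessor`,
:class:`DelayEmbedder`, :class:`AsymmetricDiffusionMap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import EmbedConfig, KernelConfig, Recording
from .diffusion_map import build_transition_matrix
from .embedding import delay_embed, embed_recordings
from .flux import decompose_fluxes
from .manifold import ManifoldModel, build_manifold, project
from .preprocess import derivative, gaussian_smooth, preprocess_chain, zscore

__all__ = [
    "PipelineConfig",
    "fit_pipeline",
    "TracePreprocessor",
    "DelayEmbedder",
    "AsymmetricDiffusionMap",
    "CyclicFluxManifold",
]


@dataclass
class PipelineConfig:
    """Every tunable hyperparameter of the fitting pipeline.

    Defaults are the reference configuration for ~3 Hz worm whole-brain
    recordings: 1-frame smoothing, tau = 10 frames with five delays,
    12-neighbor kernel with a 12-frame local-SD window, densification
    to 25% row fill, phase bins of width 0.05 rad.
    """

    smooth_sigma: float = 1.0
    tau: int = 10
    n_delays: int = 5
    k_neighbors: int = 12
    local_window: int = 12
    sigma_mode: str = "two_pass"
    densify_min_frac: float = 0.25
    delta_theta: float = 0.05
    min_bin_count: int = 5
    median_window: int = 11
    bout_gap: int = 30
    kl_bin_range: tuple = (40, 200)
    tolerance_frames: int = 10
    ava_threshold_z: float = 0.0
    seed: int = 0
    cluster: bool = True
    per_flux_phase: bool = True
    max_cluster_states: int = 600

    def __post_init__(self) -> None:
        for name in ("tau", "n_delays", "k_neighbors", "local_window",
                     "min_bin_count", "median_window", "bout_gap"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not (0 < self.densify_min_frac <= 1):
            raise ValueError("densify_min_frac must be in (0, 1]")


def _shared_neurons(recordings: Sequence[Recording]) -> list:
    shared = [n for n in recordings[0].neuron_names]
    for rec in recordings[1:]:
        present = set(rec.neuron_names)
        shared = [n for n in shared if n in present]
    return shared


def fit_pipeline(
    recordings: Sequence[Recording],
    config: Optional[PipelineConfig] = None,
    exclude_neurons: Sequence[str] = (),
) -> ManifoldModel:
    """Fit the full manifold model on one or more recordings.

    Neurons shared by all recordings form the basis; ``exclude_neurons``
    are removed from embedding and distance computation but retained in
    the per-bin mean-activity reconstruction, so their expected
    activity can still be read off the fitted manifold.
    """
    if config is None:
        config = PipelineConfig()
    if not recordings:
        raise ValueError("need at least one recording")
    shared = _shared_neurons(recordings)
    if not shared:
        raise ValueError("recordings share no neurons")
    model_neurons = [n for n in shared if n not in set(exclude_neurons)]
    if not model_neurons:
        raise ValueError("all shared neurons were excluded")

    cfg_embed = EmbedConfig(tau=config.tau, n_delays=config.n_delays)
    model_recs = [rec.subset(model_neurons) for rec in recordings]
    emb = embed_recordings(model_recs, cfg_embed, config.smooth_sigma)

    # full-neuron z-scored lag-0 snapshots + behavior labels per point
    full_activity, behaviors = [], []
    have_behavior = all(rec.behavior is not None for rec in recordings)
    for rid, rec in enumerate(recordings):
        full = zscore(gaussian_smooth(rec.subset(shared), config.smooth_sigma))
        sel = emb.rec_ids == rid
        frames = emb.frame_index[sel]
        full_activity.append(full.activity[frames])
        if have_behavior:
            behaviors.append(np.asarray(rec.behavior)[frames])
    full_activity = np.concatenate(full_activity)
    behaviors = np.concatenate(behaviors) if have_behavior else None

    M = build_transition_matrix(
        emb,
        KernelConfig(
            k_neighbors=config.k_neighbors,
            local_window=config.local_window,
            sigma_mode=config.sigma_mode,
        ),
    )
    decomp = decompose_fluxes(
        M,
        min_frac=config.densify_min_frac,
        seed=config.seed,
        cluster=config.cluster,
        max_cluster_states=config.max_cluster_states,
        points=emb.points[M.state_index],
        per_flux_phase=config.per_flux_phase,
    )
    cfg_dict = asdict(config)
    cfg_dict["kl_bin_range"] = list(config.kl_bin_range)
    cfg_dict["exclude_neurons"] = list(exclude_neurons)
    model = build_manifold(
        emb,
        decomp,
        M.state_index,
        activity=full_activity[M.state_index],
        behaviors=None if behaviors is None else behaviors[M.state_index],
        delta_theta=config.delta_theta,
        min_count=config.min_bin_count,
        all_neurons=shared,
        smooth_sigma=config.smooth_sigma,
        config=cfg_dict,
    )
    return model


def _as_recording(X, neuron_names=None) -> Recording:
    if isinstance(X, Recording):
        return X
    X = np.asarray(X, dtype=float)
    if neuron_names is None:
        neuron_names = [f"n{i}" for i in range(X.shape[1])]
    return Recording(X, neuron_names)


class TracePreprocessor(TransformerMixin, BaseEstimator):
    """Gaussian smoothing plus per-channel z-scoring as a transformer."""

    def __init__(self, sigma_frames: float = 1.0):
        self.sigma_frames = sigma_frames

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        rec = _as_recording(X)
        return zscore(gaussian_smooth(rec, self.sigma_frames)).activity


class DelayEmbedder(TransformerMixin, BaseEstimator):
    """Delay embedding of traces and their derivative as a transformer.

    ``transform`` computes the derivative of the given (already
    normalized) traces internally and returns the embedded point
    matrix of dimension ``2 * n_features * (n_delays + 1)``; frames
    without full lag history are dropped.
    """

    def __init__(self, tau: int = 10, n_delays: int = 5):
        self.tau = tau
        self.n_delays = n_delays

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        rec = _as_recording(X)
        cfg = EmbedConfig(tau=self.tau, n_delays=self.n_delays)
        return delay_embed(rec, derivative(rec), cfg).points


class AsymmetricDiffusionMap(BaseEstimator):
    """Asymmetric diffusion kernel transition matrix as an estimator.

    ``fit`` expects delay-embedded points in temporal order and exposes
    the fitted row-stochastic matrix as ``transition_matrix_`` (a
    :class:`fluxmap.datatypes.TransitionMatrix`).
    """

    def __init__(
        self,
        k_neighbors: int = 12,
        local_window: int = 12,
        sigma_mode: str = "two_pass",
    ):
        self.k_neighbors = k_neighbors
        self.local_window = local_window
        self.sigma_mode = sigma_mode

    def fit(self, X, y=None):
        from .datatypes import EmbeddedSeries

        if isinstance(X, EmbeddedSeries):
            emb = X
        else:
            X = np.asarray(X, dtype=float)
            # wrap a bare point matrix: single pseudo-neuron layout
            d = X.shape[1]
            if d % 2:
                raise ValueError("embedded dimension must be even")
            emb = EmbeddedSeries(
                points=X,
                frame_index=np.arange(X.shape[0]),
                rec_ids=np.zeros(X.shape[0], dtype=int),
                tau=1,
                n_delays=0,
                neuron_names=[f"c{i}" for i in range(d // 2)],
            )
        self.transition_matrix_ = build_transition_matrix(
            emb,
            KernelConfig(
                k_neighbors=self.k_neighbors,
                local_window=self.local_window,
                sigma_mode=self.sigma_mode,
            ),
        )
        self.n_features_in_ = emb.dim
        return self


class CyclicFluxManifold(BaseEstimator):
    """Full cyclic-flux manifold model as a scikit-learn estimator.

    ``fit`` accepts a :class:`Recording`, a list of recordings, or a
    bare (frames x neurons) array with optional per-frame behavior
    labels ``y``.  Fitted attributes: ``model_`` (the
    :class:`~fluxmap.manifold.ManifoldModel`), ``theta_``, ``alpha_``,
    ``n_fluxes_``, ``bin_assignments_``.  ``transform`` maps a
    recording to per-frame phase-bin indices; ``predict`` decodes the
    per-frame modal behavior; ``score`` is decoding accuracy.
    """

    def __init__(
        self,
        smooth_sigma: float = 1.0,
        tau: int = 10,
        n_delays: int = 5,
        k_neighbors: int = 12,
        local_window: int = 12,
        sigma_mode: str = "two_pass",
        densify_min_frac: float = 0.25,
        delta_theta: float = 0.05,
        min_bin_count: int = 5,
        cluster: bool = True,
        per_flux_phase: bool = True,
        max_cluster_states: int = 600,
        exclude_neurons: tuple = (),
        seed: int = 0,
    ):
        self.smooth_sigma = smooth_sigma
        self.tau = tau
        self.n_delays = n_delays
        self.k_neighbors = k_neighbors
        self.local_window = local_window
        self.sigma_mode = sigma_mode
        self.densify_min_frac = densify_min_frac
        self.delta_theta = delta_theta
        self.min_bin_count = min_bin_count
        self.cluster = cluster
        self.per_flux_phase = per_flux_phase
        self.max_cluster_states = max_cluster_states
        self.exclude_neurons = exclude_neurons
        self.seed = seed

    def _config(self) -> PipelineConfig:
        return PipelineConfig(
            smooth_sigma=self.smooth_sigma,
            tau=self.tau,
            n_delays=self.n_delays,
            k_neighbors=self.k_neighbors,
            local_window=self.local_window,
            sigma_mode=self.sigma_mode,
            densify_min_frac=self.densify_min_frac,
            delta_theta=self.delta_theta,
            min_bin_count=self.min_bin_count,
            seed=self.seed,
            cluster=self.cluster,
            per_flux_phase=self.per_flux_phase,
            max_cluster_states=self.max_cluster_states,
        )

    @staticmethod
    def _as_recordings(X, y=None) -> list:
        if isinstance(X, Recording):
            recs = [X]
        elif isinstance(X, (list, tuple)) and X and isinstance(X[0], Recording):
            recs = list(X)
        else:
            recs = [_as_recording(X)]
        if y is not None:
            if len(recs) != 1:
                raise ValueError("per-frame labels y only apply to a single recording")
            rec = recs[0]
            recs = [
                Recording(
                    rec.activity,
                    rec.neuron_names,
                    rec.frame_rate,
                    np.asarray(y),
                    rec.animal_id,
                )
            ]
        return recs

    def fit(self, X, y=None):
        recs = self._as_recordings(X, y)
        self.model_ = fit_pipeline(
            recs, self._config(), exclude_neurons=tuple(self.exclude_neurons)
        )
        self.theta_ = self.model_.theta
        self.alpha_ = self.model_.alpha
        self.n_fluxes_ = int(self.alpha_.max()) + 1
        self.bin_assignments_ = self.model_.assignments
        self.n_features_in_ = len(self.model_.all_neurons)
        return self

    def transform(self, X) -> np.ndarray:
        recs = self._as_recordings(X)
        return np.concatenate(
            [project(self.model_, rec) for rec in recs]
        )

    def predict(self, X) -> np.ndarray:
        bins = self.transform(X)
        return np.asarray(
            [self.model_.modal_behavior(b) for b in bins], dtype=object
        ).astype(str)

    def score(self, X, y) -> float:
        """Decoding accuracy against true per-frame behavior labels.

        Labels are aligned to the embedded frames (the first
        ``n_delays * tau`` frames of each recording carry no embedded
        point and are skipped).
        """
        recs = self._as_recordings(X)
        history = self.model_.embed_config.n_delays * self.model_.embed_config.tau
        y = np.asarray(y)
        pred = self.predict(X)
        truth = np.concatenate(
            [y[history:]] if len(recs) == 1 else [
                np.asarray(r.behavior)[history:] for r in recs
            ]
        )
        return float((pred == truth).mean())
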