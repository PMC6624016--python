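"""Takens delay embedding of activity and its derivative.

Each embedded point concatenates activity snapshots at lags
``0, tau, ..., n_delays*tau`` followed by derivative snapshots at the
same lags, giving dimension ``2 * n_neurons * (n_delays + 1)`` (180 for
15 neurons with five delays).  Frames without a complete lag history
are dropped; recordings are embedded independently so no embedded pair
spans a recording boundary.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np

from .datatypes import EmbedConfig, EmbeddedSeries, Recording
from .preprocess import preprocess_chain

__all__ = ["estimate_delay", "delay_embed", "embed_recordings"]


def estimate_delay(trace, max_lag: int | None = None) -> int:
    """Estimate the embedding delay from the autocorrelation zero crossing.

    Returns the smallest lag at which the autocorrelation of ``trace``
    first drops to <= 0.  If no crossing occurs within ``max_lag``
    (default: a quarter of the trace length), that bound is returned
    with a warning.
    """
    x = np.asarray(trace, dtype=float).ravel()
    n = x.size
    if max_lag is None:
        max_lag = n // 4
    if n <= 4 * max_lag and max_lag > 1:
        max_lag = max(1, n // 4)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("constant trace has no autocorrelation structure")
    for lag in range(1, max_lag + 1):
        ac = float(x[:-lag] @ x[lag:]) / denom
        if ac <= 0:
            return lag
    warnings.warn(
        f"autocorrelation never crossed zero within {max_lag} lags; "
        "returning the bound",
        stacklevel=2,
    )
    return max_lag


def delay_embed(
    activity: Recording,
    deriv: Recording,
    cfg: EmbedConfig | None = None,
    rec_id: int = 0,
) -> EmbeddedSeries:
    """Delay-embed one recording given its activity and derivative.

    The point at frame ``t`` concatenates activity slices at frames
    ``t - k*tau`` for ``k = 0..n_delays`` followed by derivative slices
    at the same lags.  Frames ``t < n_delays*tau`` are dropped.
    """
    if cfg is None:
        cfg = EmbedConfig()
    if activity.activity.shape != deriv.activity.shape:
        raise ValueError("activity and derivative must share shape")
    n_frames, n_neurons = activity.activity.shape
    history = cfg.n_delays * cfg.tau
    if n_frames <= history:
        raise ValueError(
            f"recording of {n_frames} frames is too short for "
            f"n_delays={cfg.n_delays}, tau={cfg.tau} "
            f"(needs more than {history} frames)"
        )
    frames = np.arange(history, n_frames)
    slices = [activity.activity[frames - k * cfg.tau] for k in range(cfg.n_delays + 1)]
    slices += [deriv.activity[frames - k * cfg.tau] for k in range(cfg.n_delays + 1)]
    points = np.concatenate(slices, axis=1)
    return EmbeddedSeries(
        points=points,
        frame_index=frames,
        rec_ids=np.full(frames.size, rec_id, dtype=int),
        tau=cfg.tau,
        n_delays=cfg.n_delays,
        neuron_names=activity.neuron_names,
    )


def embed_recordings(
    recordings: Sequence[Recording],
    cfg: EmbedConfig | None = None,
    smooth_sigma: float = 1.0,
) -> EmbeddedSeries:
    """Preprocess and embed several recordings into one point cloud.

    Each recording is smoothed, z-scored, differentiated, and embedded
    independently; the embedded points are concatenated with per-point
    recording ids so downstream stages never link states across
    recording boundaries.  All recordings must share the neuron set and
    order.
    """
    if cfg is None:
        cfg = EmbedConfig()
    if not recordings:
        raise ValueError("need at least one recording")
    names = list(recordings[0].neuron_names)
    parts = []
    for rid, rec in enumerate(recordings):
        if list(rec.neuron_names) != names:
            raise ValueError("recordings must share the same neuron order")
        norm, deriv = preprocess_chain(rec, smooth_sigma)
        parts.append(delay_embed(norm, deriv, cfg, rec_id=rid))
    return EmbeddedSeries(
        points=np.concatenate([p.points for p in parts]),
        frame_index=np.concatenate([p.frame_index for p in parts]),
        rec_ids=np.concatenate([p.rec_ids for p in parts]),
        tau=cfg.tau,
        n_delays=cfg.n_delays,
        neuron_names=names,
    )
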