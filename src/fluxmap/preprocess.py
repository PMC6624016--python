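"""Trace normalization: Gaussian smoothing, z-scoring, differentiation.

The standard chain applied before embedding is smooth (sigma = 1
frame) -> z-score -> derivative of the z-scored signal.  The smoothing
SD is orders of magnitude below typical trace autocorrelation times, so
it suppresses frame noise without touching the dynamics.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .datatypes import Recording

__all__ = ["gaussian_smooth", "zscore", "derivative", "preprocess_chain"]


def gaussian_smooth(rec: Recording, sigma_frames: float = 1.0) -> Recording:
    """Convolve each neuron's trace with a unit-area Gaussian kernel.

    Boundaries use reflect padding (affects roughly the outermost
    3*sigma frames at each end).  Output length is unchanged.
    """
    if sigma_frames <= 0:
        raise ValueError("sigma_frames must be > 0")
    if rec.n_frames < 3:
        raise ValueError("need at least 3 frames to smooth")
    smoothed = gaussian_filter1d(
        rec.activity, sigma=sigma_frames, axis=0, mode="reflect"
    )
    out = rec.copy_with(smoothed)
    out.behavior = None if rec.behavior is None else rec.behavior.copy()
    return out


def zscore(rec: Recording) -> Recording:
    """Standardize each neuron's trace to mean 0, SD 1 (population SD)."""
    mean = rec.activity.mean(axis=0)
    sd = rec.activity.std(axis=0)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = [rec.neuron_names[i] for i in zero]
        raise ValueError(
            f"zero-variance neuron(s) cannot be z-scored: {names}"
        )
    out = rec.copy_with((rec.activity - mean) / sd)
    out.behavior = None if rec.behavior is None else rec.behavior.copy()
    return out


def derivative(rec: Recording, method: str = "central") -> Recording:
    """Per-frame time derivative of each trace.

    ``central`` (default) uses the symmetric difference
    (x[t+1] - x[t-1]) / 2 in the interior with one-sided differences at
    the boundaries; ``forward`` uses x[t+1] - x[t] with the last value
    repeated.  Units are activity per frame.
    """
    if rec.n_frames < 3:
        raise ValueError("need at least 3 frames to differentiate")
    if method == "central":
        deriv = np.gradient(rec.activity, axis=0)
    elif method == "forward":
        deriv = np.empty_like(rec.activity)
        deriv[:-1] = np.diff(rec.activity, axis=0)
        deriv[-1] = deriv[-2]
    else:
        raise ValueError("method must be 'central' or 'forward'")
    out = rec.copy_with(deriv)
    out.behavior = None if rec.behavior is None else rec.behavior.copy()
    return out


def preprocess_chain(
    rec: Recording, sigma_frames: float = 1.0
) -> tuple[Recording, Recording]:
    """Smooth, z-score, and differentiate; return (activity, derivative).

    The derivative is taken of the smoothed, z-scored signal, matching
    the order of the preprocessing chain.
    """
    norm = zscore(gaussian_smooth(rec, sigma_frames))
    return norm, derivative(norm)
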