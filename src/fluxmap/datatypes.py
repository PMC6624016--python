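"""Core in-memory containers shared across the pipeline.

All containers are plain dataclasses wrapping numpy arrays.  A
:class:`Recording` holds fluorescence traces (frames x neurons) together
with neuron identities and optional per-frame behavior labels; the
downstream stages attach their own containers (embedded point clouds,
transition matrices, flux decompositions, manifold models).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp

__all__ = [
    "Recording",
    "GroundTruth",
    "TwoNeuronParams",
    "EmbedConfig",
    "EmbeddedSeries",
    "KernelConfig",
    "TransitionMatrix",
    "FluxDecomposition",
]


@dataclass
class Recording:
    """A single imaging session: frames x neurons activity plus metadata.

    Parameters
    ----------
    activity : ndarray, shape (n_frames, n_neurons)
        dF/F traces (or any per-frame scalar activity proxy), one column
        per neuron.
    neuron_names : sequence of str
        Unique identifiers, one per column of ``activity``.
    frame_rate : float
        Acquisition rate in frames per second (~3 Hz for the worm
        whole-brain recordings this package targets).
    behavior : ndarray of str, optional
        Per-frame categorical behavior label, aligned to frames.
    animal_id : str
        Identifier of the animal the recording came from.
    """

    activity: np.ndarray
    neuron_names: Sequence[str]
    frame_rate: float = 3.0
    behavior: Optional[np.ndarray] = None
    animal_id: str = "animal0"

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float)
        if self.activity.ndim != 2:
            raise ValueError("activity must be a 2-D (frames x neurons) array")
        self.neuron_names = list(self.neuron_names)
        if len(self.neuron_names) != self.activity.shape[1]:
            raise ValueError(
                f"{len(self.neuron_names)} neuron names for "
                f"{self.activity.shape[1]} activity columns"
            )
        if len(set(self.neuron_names)) != len(self.neuron_names):
            raise ValueError("neuron names must be unique")
        if self.behavior is not None:
            self.behavior = np.asarray(self.behavior)
            if self.behavior.shape[0] != self.activity.shape[0]:
                raise ValueError("behavior labels must align with frames")

    @property
    def n_frames(self) -> int:
        return self.activity.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.activity.shape[1]

    def copy_with(self, activity: np.ndarray) -> "Recording":
        """Return a new recording sharing metadata but with new traces."""
        return Recording(
            activity=np.asarray(activity, dtype=float),
            neuron_names=list(self.neuron_names),
            frame_rate=self.frame_rate,
            behavior=None if self.behavior is None else self.behavior.copy(),
            animal_id=self.animal_id,
        )

    def subset(self, names: Sequence[str]) -> "Recording":
        """Return a recording restricted to the given neurons, in the
        order given."""
        idx = [self.neuron_names.index(n) for n in names]
        return Recording(
            activity=self.activity[:, idx],
            neuron_names=list(names),
            frame_rate=self.frame_rate,
            behavior=None if self.behavior is None else self.behavior.copy(),
            animal_id=self.animal_id,
        )


@dataclass
class GroundTruth:
    """Known latent state of a synthetic recording, for recovery tests.

    ``phase`` is the true latent angle per frame in (-pi, pi]; ``loop_id``
    the true loop membership; ``behavior`` the hidden categorical state;
    ``dwell_params`` per-state dwell distribution parameters; ``latent``
    the 2-D latent coordinates when the generator has them.
    """

    phase: Optional[np.ndarray] = None
    loop_id: Optional[np.ndarray] = None
    behavior: Optional[np.ndarray] = None
    dwell_params: dict = field(default_factory=dict)
    latent: Optional[np.ndarray] = None


@dataclass
class TwoNeuronParams:
    """Parameters of the two-neuron stochastic relaxation oscillator.

    The default weights and biases give a mutually coupled pair whose
    deterministic part has a single weakly unstable spiral fixed point;
    per-step Gaussian noise then sustains recurrent excursions
    (noise-driven relaxation oscillations).  ``tau_b`` is the slow
    timescale multiplier of the B neuron.  Noise is added once per Euler
    step without sqrt(dt) scaling, so its effective magnitude depends on
    ``dt``; ``noise_as_variance`` selects whether ``noise_sd`` is read as
    a standard deviation (default) or as a variance.
    """

    w_aa: float = 8.0
    w_ab: float = -6.0
    b_a: float = -0.34
    w_ba: float = 16.0
    w_bb: float = -2.0
    b_b: float = -2.5
    tau_b: float = 6.0
    noise_sd: float = 0.1
    noise_as_variance: bool = False
    dt: float = 0.01

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.tau_b <= 0:
            raise ValueError("tau_b must be > 0")

    @property
    def step_noise_sd(self) -> float:
        if self.noise_as_variance:
            return float(np.sqrt(self.noise_sd))
        return float(self.noise_sd)


@dataclass
class EmbedConfig:
    """Delay-embedding configuration.

    ``tau`` is the delay in frames (10 frames ~ 4 s at 3 Hz for the worm
    data) and ``n_delays`` the number of additional lags beyond lag 0,
    so each embedded point concatenates ``n_delays + 1`` activity slices
    and the same number of derivative slices.
    """

    tau: int = 10
    n_delays: int = 5

    def __post_init__(self) -> None:
        if self.tau < 1:
            raise ValueError("tau must be >= 1")
        if self.n_delays < 0:
            raise ValueError("n_delays must be >= 0")

    def dim(self, n_neurons: int) -> int:
        """Embedded dimensionality: 2 * n_neurons * (n_delays + 1)."""
        return 2 * n_neurons * (self.n_delays + 1)


@dataclass
class EmbeddedSeries:
    """Delay-embedded state vectors with their frame bookkeeping.

    ``points[i]`` is the embedded snapshot for original frame
    ``frame_index[i]`` of recording ``rec_ids[i]``.  The coordinate
    layout is: activity slices at lags ``0, tau, ..., n_delays*tau``
    (each slice one value per neuron), followed by derivative slices at
    the same lags.
    """

    points: np.ndarray
    frame_index: np.ndarray
    rec_ids: np.ndarray
    tau: int
    n_delays: int
    neuron_names: Sequence[str]

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.rec_ids = np.asarray(self.rec_ids, dtype=int)
        self.neuron_names = list(self.neuron_names)
        d_expected = 2 * len(self.neuron_names) * (self.n_delays + 1)
        if self.points.shape[1] != d_expected:
            raise ValueError(
                f"embedded dimension {self.points.shape[1]} != "
                f"2 * n_neurons * (n_delays + 1) = {d_expected}"
            )

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_names)

    def activity_slice(self, lag: int = 0) -> np.ndarray:
        """Un-embed one activity slice back to neuron space."""
        n = self.n_neurons
        return self.points[:, lag * n : (lag + 1) * n]


@dataclass
class KernelConfig:
    """Asymmetric diffusion kernel configuration.

    ``k_neighbors`` points (including the next observed point itself)
    receive kernel mass in each row; ``local_window`` frames define the
    temporal window of the local standard deviation entering the kernel
    bandwidth; ``sigma_mode`` resolves the self-referential bandwidth
    definition either with a deterministic two-pass scheme or by
    fixed-point iteration.
    """

    k_neighbors: int = 12
    local_window: int = 12
    sigma_mode: str = "two_pass"

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.local_window < 2:
            raise ValueError("local_window must be >= 2")
        if self.sigma_mode not in ("two_pass", "fixed_point"):
            raise ValueError("sigma_mode must be 'two_pass' or 'fixed_point'")


@dataclass
class TransitionMatrix:
    """Row-stochastic transition matrix over observed states.

    States are embedded points that have a successor within the same
    recording; ``state_index[i]`` maps state ``i`` back to its row in
    the embedded point cloud.
    """

    probs: sp.csr_matrix
    state_index: np.ndarray
    rec_ids: np.ndarray

    @property
    def n_states(self) -> int:
        return self.probs.shape[0]


@dataclass
class FluxDecomposition:
    """Per-state phase and flux identity from spectral analysis.

    ``theta[i]`` is the phase of state ``i`` along its cyclic flux, in
    (-pi, pi]; ``alpha[i]`` its integer flux label (contiguous from 0).
    ``lead_eigenvalue``/``lead_eigenvector`` are the dominant complex
    eigenpair of the full transition matrix; ``densify_exponent`` the
    power used to densify the matrix before trajectory clustering.
    """

    theta: np.ndarray
    alpha: np.ndarray
    lead_eigenvalue: complex
    lead_eigenvector: np.ndarray
    densify_exponent: int = 1
    theta_defined: Optional[np.ndarray] = None

    @property
    def n_fluxes(self) -> int:
        return int(self.alpha.max()) + 1 if self.alpha.size else 0
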