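"""Synthetic generators with known ground truth.

Three generators cover the fixtures the rest of the package is tested
against:

* :func:`simulate_two_neuron` -- a two-neuron stochastic relaxation
  oscillator (mutually coupled excitatory/inhibitory pair with logistic
  activation) integrated by forward Euler with per-step Gaussian noise.
* :func:`simulate_noisy_loops` -- one or more noisy limit cycles in a
  2-D latent plane, linearly mixed into an arbitrary number of observed
  channels, with known latent phase and loop identity and optional
  stochastic hops between loops at a junction phase.
* :func:`simulate_markov_switcher` -- a hidden Markov behavior switcher
  with per-state activity templates and geometric dwell times.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .datatypes import GroundTruth, Recording, TwoNeuronParams

__all__ = [
    "logistic",
    "simulate_two_neuron",
    "simulate_noisy_loops",
    "simulate_markov_switcher",
]


def logistic(x):
    """Logistic activation sigma(x) = 1 / (1 + exp(-x))."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def simulate_two_neuron(
    params: TwoNeuronParams | None = None,
    n_steps: int = 5000,
    init: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    burn_in: int = 1000,
) -> tuple[Recording, GroundTruth]:
    """Integrate the two-neuron relaxation oscillator.

    Forward-Euler updates with fresh Gaussian noise each step::

        A <- A + dt * (-A + sigma(w_aa*A + w_ab*B + b_a)) + eps
        B <- B + (dt / tau_b) * (-B + sigma(w_ba*A + w_bb*B + b_b)) + eps'

    The first ``burn_in`` steps are discarded.  Noise is applied once
    per step as written (no sqrt(dt) scaling), so its effective strength
    depends on ``dt``.

    Returns a two-neuron :class:`Recording` (neurons "A", "B") and a
    :class:`GroundTruth` whose ``phase`` is the latent angle of the
    state around the system's deterministic fixed point (a nominal
    phase; the toy system has no exact limit cycle).

    Raises
    ------
    FloatingPointError
        If the state overflows to a non-finite value.
    """
    if params is None:
        params = TwoNeuronParams()
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.default_rng(seed)
    total = burn_in + n_steps
    a = float(init[0])
    b = float(init[1])
    sd = params.step_noise_sd
    dt = params.dt
    out = np.empty((total, 2), dtype=float)
    for t in range(total):
        drive_a = logistic(params.w_aa * a + params.w_ab * b + params.b_a)
        drive_b = logistic(params.w_ba * a + params.w_bb * b + params.b_b)
        noise = rng.normal(0.0, sd, size=2) if sd > 0 else (0.0, 0.0)
        a = a + dt * (-a + drive_a) + noise[0]
        b = b + (dt / params.tau_b) * (-b + drive_b) + noise[1]
        if not (np.isfinite(a) and np.isfinite(b)):
            raise FloatingPointError(
                f"two-neuron state became non-finite at step {t} "
                f"(A={a}, B={b}); reduce dt or noise_sd"
            )
        out[t, 0] = a
        out[t, 1] = b
    traces = out[burn_in:]
    rec = Recording(traces, ["A", "B"], frame_rate=1.0 / dt, animal_id="toy")
    centered = traces - traces.mean(axis=0)
    phase = np.arctan2(centered[:, 1], centered[:, 0])
    truth = GroundTruth(phase=phase, latent=traces.copy())
    return rec, truth


def _loop_centers(n_loops: int, radius: float) -> np.ndarray:
    # disjoint centers along the x-axis, 3 radii apart
    return np.stack(
        [np.arange(n_loops) * 3.0 * radius, np.zeros(n_loops)], axis=1
    )


def simulate_noisy_loops(
    n_loops: int = 1,
    omega: float = 2.0 * np.pi / 100.0,
    radius: float = 1.0,
    noise_sd: float = 0.05,
    n_frames: int = 2000,
    n_neurons: int = 6,
    seed: int = 0,
    hop_prob: float = 0.3,
    phase_noise_sd: float = 0.0,
    n_behaviors: int = 0,
) -> tuple[Recording, GroundTruth]:
    """Noisy limit-cycle trajectories with known phase and loop identity.

    A latent 2-D point orbits one of ``n_loops`` circles (disjoint
    centers, 3 radii apart).  The latent angle advances by ``omega``
    radians per frame (a scalar shared by all loops, or one value per
    loop) plus optional phase diffusion
    (``phase_noise_sd``); isotropic Gaussian noise of SD ``noise_sd``
    is added to the latent position.  When ``n_loops > 1`` the
    trajectory may hop to the next loop with probability ``hop_prob``
    each time the phase wraps past +pi (the junction).  Latent
    positions are mixed into ``n_neurons`` observed channels through a
    fixed random linear map.

    If ``n_behaviors > 0``, each frame gets a behavior label
    ``"b0" ... "b{n_behaviors-1}"`` from the equal phase sector its true
    angle falls into (sector 0 starts at -pi).
    """
    if n_loops < 1:
        raise ValueError("n_loops must be >= 1")
    if n_neurons < 2:
        raise ValueError("mixing needs at least 2 observed channels")
    rng = np.random.default_rng(seed)
    mix = rng.normal(0.0, 1.0, size=(n_neurons, 2)) / np.sqrt(2.0)
    centers = _loop_centers(n_loops, radius)
    omega_per_loop = np.broadcast_to(
        np.asarray(omega, dtype=float), (n_loops,)
    )

    phase = np.empty(n_frames)
    loop_id = np.empty(n_frames, dtype=int)
    theta = -np.pi
    loop = 0
    for t in range(n_frames):
        phase[t] = theta
        loop_id[t] = loop
        step = omega_per_loop[loop]
        if phase_noise_sd > 0:
            step = step + rng.normal(0.0, phase_noise_sd)
        new = theta + step
        if new > np.pi:  # wrapped past the junction
            new -= 2.0 * np.pi
            if n_loops > 1 and rng.random() < hop_prob:
                loop = (loop + 1) % n_loops
        elif new <= -np.pi:
            new += 2.0 * np.pi
        theta = new

    latent = centers[loop_id] + radius * np.stack(
        [np.cos(phase), np.sin(phase)], axis=1
    )
    if noise_sd > 0:
        latent = latent + rng.normal(0.0, noise_sd, size=latent.shape)
    traces = latent @ mix.T

    behavior = None
    if n_behaviors > 0:
        sector = ((phase + np.pi) / (2.0 * np.pi) * n_behaviors).astype(int)
        sector = np.clip(sector, 0, n_behaviors - 1)
        behavior = np.array([f"b{s}" for s in sector])

    rec = Recording(
        traces,
        [f"n{i}" for i in range(n_neurons)],
        frame_rate=3.0,
        behavior=behavior,
        animal_id="loops",
    )
    truth = GroundTruth(
        phase=phase, loop_id=loop_id, behavior=behavior, latent=latent
    )
    return rec, truth


def simulate_markov_switcher(
    dwell_p,
    templates,
    noise_sd: float = 0.1,
    n_frames: int = 5000,
    seed: int = 0,
    state_names=None,
    routing: str = "uniform",
) -> tuple[Recording, GroundTruth]:
    """Hidden Markov behavior switcher with per-state activity templates.

    The hidden state stays put with probability ``dwell_p[s]``; on
    leaving, it jumps uniformly to one of the other states
    (``routing="uniform"``) or deterministically to the next state in
    a fixed cycle (``routing="cycle"``, giving the switcher a cyclic
    flux structure).  Either way the dwell time of state ``s`` is
    geometric with mean ``1 / (1 - dwell_p[s])``.  Emitted activity is
    ``templates[state] + N(0, noise_sd)``.
    """
    dwell_p = np.asarray(dwell_p, dtype=float)
    templates = np.atleast_2d(np.asarray(templates, dtype=float))
    n_states = dwell_p.shape[0]
    if np.any(dwell_p <= 0) or np.any(dwell_p >= 1):
        raise ValueError("dwell probabilities must lie strictly in (0, 1)")
    if templates.shape[0] != n_states:
        raise ValueError(
            f"{templates.shape[0]} templates for {n_states} states"
        )
    if state_names is None:
        state_names = [f"s{i}" for i in range(n_states)]
    if len(state_names) != n_states:
        raise ValueError("state_names must match the number of states")
    if routing not in ("uniform", "cycle"):
        raise ValueError("routing must be 'uniform' or 'cycle'")

    rng = np.random.default_rng(seed)
    states = np.empty(n_frames, dtype=int)
    s = 0
    for t in range(n_frames):
        states[t] = s
        if rng.random() >= dwell_p[s] and n_states > 1:
            if routing == "cycle":
                s = (s + 1) % n_states
            else:
                others = [j for j in range(n_states) if j != s]
                s = others[rng.integers(len(others))]
    traces = templates[states]
    if noise_sd > 0:
        traces = traces + rng.normal(0.0, noise_sd, size=traces.shape)

    behavior = np.asarray(state_names)[states]
    rec = Recording(
        traces,
        [f"n{i}" for i in range(templates.shape[1])],
        frame_rate=3.0,
        behavior=behavior,
        animal_id="switcher",
    )
    truth = GroundTruth(
        loop_id=states.copy(),
        behavior=behavior,
        dwell_params={
            name: {"p": float(p), "mean_dwell": float(1.0 / (1.0 - p))}
            for name, p in zip(state_names, dwell_p)
        },
    )
    return rec, truth
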