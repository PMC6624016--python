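import numpy as np
import pytest

from fluxmap import (
    EmbedConfig,
    Recording,
    simulate_markov_switcher,
    simulate_noisy_loops,
)
from fluxmap.datatypes import KernelConfig
from fluxmap.diffusion_map import build_transition_matrix
from fluxmap.embedding import embed_recordings

# embedding config suited to the ~100-frame-period loop fixtures:
# tau at a quarter period, two extra delays
LOOP_EMBED = EmbedConfig(tau=25, n_delays=2)


@pytest.fixture(scope="session")
def single_loop():
    """Noisy single-loop fixture with its embedding and transition matrix."""
    rec, truth = simulate_noisy_loops(
        n_loops=1,
        omega=2 * np.pi / 100,
        radius=1.0,
        noise_sd=0.1,
        n_frames=2000,
        n_neurons=6,
        seed=11,
    )
    emb = embed_recordings([rec], LOOP_EMBED)
    M = build_transition_matrix(emb, KernelConfig())
    return rec, truth, emb, M


@pytest.fixture(scope="session")
def switcher():
    """Two-state Markov switcher fixture (forward/backward labels)."""
    rng = np.random.default_rng(7)
    templates = rng.normal(0.0, 1.0, size=(2, 6))
    rec, truth = simulate_markov_switcher(
        [0.95, 0.9],
        templates,
        noise_sd=0.15,
        n_frames=6000,
        seed=7,
        state_names=["forward", "backward"],
    )
    return rec, truth, templates


@pytest.fixture()
def small_recording():
    rng = np.random.default_rng(0)
    return Recording(
        rng.normal(size=(200, 3)), ["a", "b", "c"], frame_rate=3.0
    )
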