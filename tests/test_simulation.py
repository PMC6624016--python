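"""Manifold simulation, dwell statistics, and transition forecasting."""

import numpy as np
import pytest

from fluxmap import (
    dwell_statistics,
    null_time_to_transition,
    path_to_activity,
    path_to_behavior,
    run_markov,
    time_to_transition,
)
from fluxmap.manifold import BinSet, ManifoldModel
from fluxmap.datatypes import EmbedConfig
from fluxmap.simulation import (
    SimulatedPath,
    dwell_r2,
    fill_unassigned,
    median_filter_labels,
)


def _toy_model(P, behavior_dist, vocab, occupancy=None):
    n = P.shape[0]
    occupancy = np.full(n, 10) if occupancy is None else np.asarray(occupancy)
    return ManifoldModel(
        bins=BinSet(
            alpha=np.zeros(n, dtype=int),
            center=np.linspace(-np.pi + 0.1, np.pi, n),
            sd=np.full(n, 0.05),
        ),
        mean_embedded=np.eye(n),
        mean_activity=np.arange(n, dtype=float)[:, None],
        behavior_dist=np.asarray(behavior_dist, dtype=float),
        behavior_vocab=list(vocab),
        occupancy=occupancy,
        flagged=occupancy < 1,
        bin_transitions=np.asarray(P, dtype=float),
        visited=np.asarray(P).sum(axis=1) > 0,
        model_neurons=["n0"],
        all_neurons=["n0"],
        embed_config=EmbedConfig(tau=1, n_delays=0),
    )


def _cycle_model(n=10, target_bin=7):
    P = np.zeros((n, n))
    P[np.arange(n), (np.arange(n) + 1) % n] = 1.0
    dist = np.zeros((n, 2))
    dist[:, 0] = 1.0
    dist[target_bin] = [0.0, 1.0]
    return _toy_model(P, dist, ["a", "b"])


class TestRunMarkov:
    def test_permutation_chain_cycles_deterministically(self):
        model = _cycle_model()
        path = run_markov(model, 0, 25, seed=0)
        assert np.array_equal(path.bin_sequence, np.arange(25) % 10)

    def test_same_seed_reproduces(self):
        rng = np.random.default_rng(0)
        P = rng.uniform(size=(5, 5))
        P /= P.sum(axis=1, keepdims=True)
        model = _toy_model(P, np.full((5, 2), 0.5), ["a", "b"])
        p1 = run_markov(model, 0, 500, seed=3)
        p2 = run_markov(model, 0, 500, seed=3)
        assert np.array_equal(p1.bin_sequence, p2.bin_sequence)

    def test_two_bin_switch_rate_matches(self):
        p = 0.2
        P = np.array([[1 - p, p], [p, 1 - p]])
        model = _toy_model(P, np.full((2, 2), 0.5), ["a", "b"])
        path = run_markov(model, 0, 100_000, seed=1)
        emp = np.mean(path.bin_sequence[:-1] != path.bin_sequence[1:])
        se = np.sqrt(p * (1 - p) / 100_000)
        assert abs(emp - p) < 3 * se

    def test_unoccupied_start_rejected(self):
        model = _cycle_model()
        model.occupancy[4] = 0
        with pytest.raises(ValueError):
            run_markov(model, 4, 10, seed=0)

    def test_absorbing_bin_terminates_early(self):
        P = np.array([[0.0, 1.0], [0.0, 0.0]])
        model = _toy_model(P, np.full((2, 2), 0.5), ["a", "b"])
        model.visited[:] = [True, False]
        path = run_markov(model, 0, 50, seed=0)
        assert path.terminated_early
        assert path.bin_sequence.size == 2


class TestPathMaps:
    def test_single_bin_path_gives_constant_trace(self):
        model = _cycle_model()
        path = SimulatedPath(bin_sequence=np.full(5, 3))
        act = path_to_activity(path, model)
        assert np.allclose(act, model.mean_activity[3])

    def test_modal_behavior_deterministic(self):
        model = _cycle_model()
        path = run_markov(model, 0, 20, seed=0)
        b1 = path_to_behavior(path, model, mode="modal")
        b2 = path_to_behavior(path, model, mode="modal")
        assert np.array_equal(b1, b2)
        assert b1[7 % 20] == "b" if len(b1) > 7 else True

    def test_sampled_behavior_matches_distribution(self):
        P = np.array([[1.0]])
        dist = np.array([[0.3, 0.7]])
        model = _toy_model(P, dist, ["a", "b"])
        path = SimulatedPath(bin_sequence=np.zeros(100_000, dtype=int), seed=5)
        beh = path_to_behavior(path, model, mode="sample", seed=5)
        frac_b = np.mean(beh == "b")
        se = np.sqrt(0.7 * 0.3 / 100_000)
        assert abs(frac_b - 0.7) < 3 * se

    def test_probability_one_bin_always_emits_its_label(self):
        model = _cycle_model()
        path = SimulatedPath(bin_sequence=np.full(50, 7), seed=0)
        beh = path_to_behavior(path, model, mode="sample", seed=1)
        assert set(beh.tolist()) == {"b"}

    def test_flagged_bin_emits_unassigned(self):
        model = _cycle_model()
        model.flagged[2] = True
        path = SimulatedPath(bin_sequence=np.array([2, 3]))
        beh = path_to_behavior(path, model, mode="modal")
        assert beh[0] == "unassigned"


class TestDwellStatistics:
    def test_simple_runs_counted_exactly(self):
        seq = ["forward"] * 50 + ["backward"] * 20 + ["forward"] * 50
        stats = dwell_statistics(seq, median_window=1)
        assert sorted(stats.forward.tolist()) == [50, 50]
        assert stats.backward.tolist() == [20]
        assert stats.bouts.tolist() == [20]

    def test_short_forward_gap_merges_backing_bout(self):
        seq = ["backward"] * 20 + ["forward"] * 10 + ["backward"] * 20
        stats = dwell_statistics(seq, median_window=1, bout_gap=30)
        assert stats.bouts.tolist() == [50]
        seq_wide = ["backward"] * 20 + ["forward"] * 40 + ["backward"] * 20
        stats = dwell_statistics(seq_wide, median_window=1, bout_gap=30)
        assert stats.bouts.tolist() == [20, 20]

    def test_median_filter_removes_glitch(self):
        seq = np.array(
            ["forward"] * 25 + ["backward"] * 3 + ["forward"] * 25
        )
        stats = dwell_statistics(seq, median_window=11)
        assert stats.forward.tolist() == [53]
        assert stats.backward.size == 0
        # brute-force median filter oracle on the coded sequence
        codes = (seq == "forward").astype(int)
        brute = np.array([
            int(np.median(codes[max(0, i - 5): i + 6]))
            for i in range(len(codes))
        ])
        filt = median_filter_labels(seq, 11)
        assert np.array_equal((filt == "forward").astype(int)[5:-5], brute[5:-5])

    def test_unassigned_frames_inherit_previous_label(self):
        seq = ["forward"] * 10 + ["unassigned"] * 3 + ["forward"] * 10
        out = fill_unassigned(np.array(seq))
        assert set(out.tolist()) == {"forward"}
        stats = dwell_statistics(seq, median_window=1)
        assert stats.forward.tolist() == [23]

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            dwell_statistics([])

    def test_r2_of_matching_samples_is_high(self):
        rng = np.random.default_rng(0)
        a = rng.gamma(5.0, 4.0, size=2000)
        b = rng.gamma(5.0, 4.0, size=2000)
        c = rng.gamma(2.0, 20.0, size=2000)
        assert dwell_r2(a, b) > dwell_r2(a, c)
        assert dwell_r2(a, b) > 0.95


class TestTimeToTransition:
    def test_deterministic_cycle_exact_steps(self):
        model = _cycle_model(n=10, target_bin=7)
        fc = time_to_transition(model, 2, "b", n_sims=20, max_steps=100, seed=0)
        assert fc.mean == 5.0
        assert np.all(fc.times == 5.0)

    def test_start_inside_target_is_zero(self):
        model = _cycle_model(n=10, target_bin=7)
        fc = time_to_transition(model, 7, "b", n_sims=5, max_steps=10, seed=0)
        assert fc.mean == 0.0

    def test_angular_speed_sets_forecast(self):
        """Deterministic phase oscillator: the forecast equals the
        phase distance over the angular speed (one bin per step)."""
        n = 60
        model = _cycle_model(n=n, target_bin=45)
        fc = time_to_transition(model, 5, "b", n_sims=10, max_steps=200, seed=0)
        assert fc.mean == pytest.approx(40.0, abs=1.0)

    def test_missing_target_rejected(self):
        model = _cycle_model()
        with pytest.raises(ValueError):
            time_to_transition(model, 0, "nope", n_sims=5, max_steps=10)


class TestNullModel:
    def test_exponential_memorylessness(self):
        rng = np.random.default_rng(0)
        r = 0.05
        dwells = rng.exponential(1.0 / r, size=100_000)
        for t_start in (0.0, 10.0, 30.0):
            mean, _ = null_time_to_transition(dwells, t_start)
            assert abs(mean - 1.0 / r) / (1.0 / r) < 0.05

    def test_degenerate_dwell_residual(self):
        mean, res = null_time_to_transition([10.0], 4.0)
        assert mean == 6.0
        assert res.tolist() == [6.0]

    def test_zero_start_gives_dwell_mean(self):
        dwells = np.array([3.0, 7.0, 20.0])
        mean, _ = null_time_to_transition(dwells, 0.0)
        assert mean == pytest.approx(10.0)

    def test_exceeding_all_dwells_flagged(self):
        with pytest.raises(ValueError):
            null_time_to_transition([5.0, 6.0], 10.0)
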