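"""Phase warping, consistency ANOVA, template decoding, relative information."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluxmap import (
    Recording,
    consistency_test,
    kl_divergence,
    min_binned_kl,
    optimize_threshold,
    phase_warp,
    relative_information,
    template_decode,
)
from fluxmap.behavior_stats import bootstrap_template_decode


class TestPhaseWarp:
    def test_output_is_centered_100_vector(self):
        trace = np.sin(np.linspace(0, 3, 500))
        w = phase_warp(trace, 100, 400)
        assert w.shape == (100,)
        assert abs(w.mean()) < 1e-9

    def test_linear_ramp_is_antisymmetric(self):
        w = phase_warp(np.arange(200.0), 20, 180)
        assert np.allclose(w, -w[::-1], atol=1e-9)
        assert abs(w[49] + w[50]) < 1e-9

    def test_duration_invariance(self):
        """Two instances of the same waveform at different durations
        warp to (almost) the same 100-sample vector."""
        t1 = np.linspace(0, 1, 61)
        t2 = np.linspace(0, 1, 241)
        w1 = phase_warp(np.sin(2 * np.pi * t1), 0, 60)
        w2 = phase_warp(np.sin(2 * np.pi * t2), 0, 240)
        assert np.max(np.abs(w1 - w2)) < 0.01

    def test_constant_trace_warps_to_zero(self):
        assert np.allclose(phase_warp(np.full(50, 3.0), 5, 45), 0.0)

    def test_too_short_interval_rejected(self):
        with pytest.raises(ValueError):
            phase_warp(np.arange(10.0), 5, 6)


class TestConsistencyTest:
    def test_shifted_animal_detected(self):
        rng = np.random.default_rng(0)
        base = np.sin(np.linspace(0, 2 * np.pi, 100))
        warped, ids = [], []
        for animal in range(4):
            shift = 3.0 if animal == 0 else 0.0
            for _ in range(6):
                w = base * (1 + shift) + rng.normal(0, 0.3, 100)
                warped.append(w - w.mean())
                ids.append(animal)
        p = consistency_test(np.array(warped), ids)
        assert p < 0.001

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError):
            consistency_test(np.zeros((4, 100)), [0, 0, 0, 0])

    def test_degenerate_identical_instances_flagged(self):
        warped = np.tile(np.sin(np.linspace(0, 1, 100)), (6, 1))
        warped = warped - warped.mean(axis=0)
        with pytest.raises(ValueError, match="degenerate"):
            consistency_test(warped, [0, 0, 0, 1, 1, 1])


class TestOptimizeThreshold:
    def test_perfect_separation_gives_probability_one(self):
        res = optimize_threshold([5.0, 6.0, 7.0], [1.0, 2.0])
        assert res.probability == 1.0
        assert res.threshold >= 3.0

    def test_identical_distributions_capped_near_half(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=500)
        res = optimize_threshold(s, rng.normal(size=500))
        assert res.probability <= 0.6

    @settings(max_examples=60, deadline=None)
    @given(
        data=st.data(),
        n_true=st.integers(1, 40),
        n_false=st.integers(1, 40),
    )
    def test_matches_exhaustive_scan(self, data, n_true, n_false):
        """The vectorized optimizer equals brute-force evaluation of the
        objective at every candidate threshold."""
        st_f = st.floats(-5, 5, allow_nan=False)
        true = np.array(data.draw(st.lists(st_f, min_size=n_true, max_size=n_true)))
        false = np.array(data.draw(st.lists(st_f, min_size=n_false, max_size=n_false)))
        res = optimize_threshold(true, false)
        best_p, best_x = -1.0, None
        for x in np.unique(np.concatenate([true, false])):
            p = (true >= x).sum() / (len(true) + (false >= x).sum())
            if p > best_p:
                best_p, best_x = p, x
        assert res.probability == pytest.approx(best_p, abs=1e-12)
        assert res.threshold == pytest.approx(best_x, abs=1e-12)


def _event_recording(onsets, template, n_frames, n_neurons, noise, seed):
    rng = np.random.default_rng(seed)
    act = rng.normal(0, noise, size=(n_frames, n_neurons))
    w = template.shape[0]
    for on in onsets:
        act[on - w + 1 : on + 1] += template
    return Recording(act, [f"n{i}" for i in range(n_neurons)])


class TestTemplateDecode:
    def test_noiseless_events_decoded_perfectly(self):
        rng = np.random.default_rng(2)
        template = rng.normal(0, 1, size=(10, 4)) * 3
        onsets = np.arange(30, 960, 60)
        rec = _event_recording(onsets, template, 1000, 4, 0.2, seed=3)
        p = template_decode([rec], [onsets], rec, onsets)
        assert p == 1.0

    def test_shuffled_training_events_decode_at_chance(self):
        """Training on random time points (kept clear of real events so
        the sham template carries no event signal) collapses decoding."""
        rng = np.random.default_rng(4)
        template = rng.normal(0, 1, size=(10, 4)) * 3
        onsets = np.arange(30, 1960, 60)
        rec = _event_recording(onsets, template, 2000, 4, 0.5, seed=5)
        random_onsets = onsets + 30  # mid-gap: >= 20 frames from any event
        p_true = template_decode([rec], [onsets], rec, onsets)
        p_shuf = template_decode([rec], [random_onsets], rec, onsets)
        assert p_true > 2 * p_shuf

    def test_bootstrap_split_decoding_beats_chance(self):
        from scipy.stats import binomtest

        rng = np.random.default_rng(6)
        template = rng.normal(0, 1, size=(10, 5)) * 2
        onsets = np.arange(40, 2960, 75)
        rec = _event_recording(onsets, template, 3000, 5, 0.5, seed=7)
        probs = bootstrap_template_decode(rec, onsets, n_boot=20, seed=8)
        assert np.median(probs) > 0.5

    def test_short_validation_rejected(self):
        rng = np.random.default_rng(8)
        template = rng.normal(size=(10, 3))
        onsets = [20, 50]
        rec = _event_recording(np.array(onsets), template, 100, 3, 0.1, seed=9)
        tiny = Recording(np.zeros((5, 3)), rec.neuron_names)
        with pytest.raises(ValueError):
            template_decode([rec], [onsets], tiny, [2])


class TestRelativeInformation:
    def test_kl_identities(self):
        p = np.array([0.2, 0.3, 0.5])
        assert kl_divergence(p, p) == pytest.approx(0.0, abs=1e-9)
        q = np.array([0.5, 0.25, 0.25])
        assert kl_divergence(p, q) > 0.0

    def test_worked_two_cell_example(self):
        """D(P||Q) for P=(.5,.5), Q=(.9,.1) is about 0.511 nats."""
        expected = 0.5 * np.log(0.5 / 0.9) + 0.5 * np.log(0.5 / 0.1)
        got = kl_divergence([0.5, 0.5], [0.9, 0.1])
        assert got == pytest.approx(expected, abs=1e-6)
        assert got == pytest.approx(0.511, abs=1e-3)

    def test_identical_samples_give_zero_information(self):
        rng = np.random.default_rng(0)
        s = rng.gamma(4, 10, size=3000)
        assert min_binned_kl(s, s) == pytest.approx(0.0, abs=1e-9)

    def test_relative_information_near_one_for_shared_generator(self):
        """Reference and modified simulations drawn from one generator
        carry the same information about the observations, so their
        ratio is ~1.  The observed distribution differs from the
        simulations so each divergence is resolvable above histogram
        sampling noise."""
        rng = np.random.default_rng(1)
        obs = {k: rng.gamma(4.0, 10.0, size=100_000) for k in ("fwd", "bwd", "bouts")}
        ref = {k: rng.gamma(4.6, 9.0, size=100_000) for k in ("fwd", "bwd", "bouts")}
        mod = {k: rng.gamma(4.6, 9.0, size=100_000) for k in ("fwd", "bwd", "bouts")}
        rel = relative_information(obs, ref, mod)
        assert rel.i_tot_reference > 0.005  # resolvable divergence
        assert 0.9 < rel.i_rel < 1.1

    def test_degenerate_distribution_rejected(self):
        with pytest.raises(ValueError):
            min_binned_kl(np.full(10, 3.0), np.full(10, 3.0))
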