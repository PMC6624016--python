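"""Simulation of the manifold and behavioral timing statistics.

The fitted manifold is a Markov chain over phase bins.  Simulating it
yields novel bin sequences that map back to neuronal activity (per-bin
mean snapshots, or samples) and behavior (per-bin modal label or draws
from the per-bin behavior distribution).  From simulated or observed
behavior sequences we compute dwell-time distributions (with the
median-filter / backing-bout conventions of the worm analyses) and
distributions of times until a target behavior starts, together with a
dwell-time-only null model for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.ndimage import median_filter
from scipy.stats import gaussian_kde

from .manifold import ManifoldModel

__all__ = [
    "SimulatedPath",
    "TransitionForecast",
    "DwellStats",
    "run_markov",
    "path_to_activity",
    "path_to_behavior",
    "simulate_path",
    "dwell_statistics",
    "smoothed_dwell_density",
    "dwell_r2",
    "time_to_transition",
    "null_time_to_transition",
]


@dataclass
class SimulatedPath:
    """A simulated trajectory through manifold bins."""

    bin_sequence: np.ndarray
    behavior: Optional[np.ndarray] = None
    activity: Optional[np.ndarray] = None
    seed: int = 0
    terminated_early: bool = False


@dataclass
class TransitionForecast:
    """Distribution of simulated times until a target behavior starts."""

    start_bin: int
    target_behavior: str
    times: np.ndarray
    censored: np.ndarray
    mean: float
    ci95: tuple

    @property
    def censored_fraction(self) -> float:
        return float(self.censored.mean()) if self.censored.size else 0.0


@dataclass
class DwellStats:
    """Dwell-time samples for forward/backward runs and backing bouts."""

    forward: np.ndarray
    backward: np.ndarray
    bouts: np.ndarray
    labels: dict = field(default_factory=dict)


def run_markov(
    model: ManifoldModel, start_bin: int, n_steps: int, seed: int = 0
) -> SimulatedPath:
    """Sample a bin sequence from the bin-level transition matrix.

    Terminates early (with a flag) if the chain reaches a bin with no
    outgoing transitions.
    """
    if model.occupancy[start_bin] == 0:
        raise ValueError(f"start bin {start_bin} was never occupied")
    rng = np.random.default_rng(seed)
    P = model.bin_transitions
    cum = np.cumsum(P, axis=1)
    seq = np.empty(n_steps, dtype=int)
    b = int(start_bin)
    terminated = False
    for t in range(n_steps):
        seq[t] = b
        if not model.visited[b]:
            terminated = True
            seq = seq[: t + 1]
            break
        b = int(np.searchsorted(cum[b], rng.random(), side="right"))
        b = min(b, P.shape[1] - 1)
    return SimulatedPath(bin_sequence=seq, seed=seed, terminated_early=terminated)


def path_to_activity(
    path: SimulatedPath,
    model: ManifoldModel,
    mode: str = "mean",
    seed: Optional[int] = None,
    member_activity: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Map a bin sequence back to neuronal activity snapshots.

    ``mean`` (default) emits each bin's mean raw-neuron snapshot;
    ``sample`` draws a random member state's snapshot per step, which
    requires the per-state ``member_activity`` the model was built
    from.
    """
    seq = path.bin_sequence
    if mode == "mean":
        return model.mean_activity[seq]
    if mode != "sample":
        raise ValueError("mode must be 'mean' or 'sample'")
    if member_activity is None or model.assignments is None:
        raise ValueError("sample mode needs per-state member activity")
    rng = np.random.default_rng(path.seed if seed is None else seed)
    out = np.empty((seq.size, member_activity.shape[1]))
    for i, b in enumerate(seq):
        members = np.flatnonzero(model.assignments == b)
        if members.size == 0:
            out[i] = model.mean_activity[b]
        else:
            out[i] = member_activity[members[rng.integers(members.size)]]
    return out


def path_to_behavior(
    path: SimulatedPath,
    model: ManifoldModel,
    mode: str = "modal",
    seed: Optional[int] = None,
) -> np.ndarray:
    """Map a bin sequence to behavior labels.

    ``modal`` takes each bin's most prevalent behavior (used for dwell
    statistics); ``sample`` draws from the per-bin behavior
    distribution.  Flagged (under-occupied) bins emit 'unassigned'.
    """
    seq = path.bin_sequence
    vocab = np.asarray(model.behavior_vocab, dtype=object)
    if vocab.size == 0:
        raise ValueError("model carries no behavior distributions")
    out = np.empty(seq.size, dtype=object)
    if mode == "modal":
        modal = np.asarray(
            [model.modal_behavior(b) for b in range(model.n_bins)], dtype=object
        )
        out[:] = modal[seq]
    elif mode == "sample":
        rng = np.random.default_rng(path.seed if seed is None else seed)
        cum = np.cumsum(model.behavior_dist, axis=1)
        for i, b in enumerate(seq):
            if model.flagged[b] or cum[b, -1] <= 0:
                out[i] = "unassigned"
            else:
                j = int(np.searchsorted(cum[b], rng.random(), side="right"))
                out[i] = vocab[min(j, vocab.size - 1)]
    else:
        raise ValueError("mode must be 'modal' or 'sample'")
    return out.astype(str)


def simulate_path(
    model: ManifoldModel,
    start_bin: int,
    n_steps: int,
    seed: int = 0,
    behavior_mode: str = "sample",
) -> SimulatedPath:
    """Simulate bins, then attach activity and behavior in one call."""
    path = run_markov(model, start_bin, n_steps, seed)
    path.activity = path_to_activity(path, model)
    path.behavior = path_to_behavior(path, model, mode=behavior_mode, seed=seed + 1)
    return path


def _runs(labels: np.ndarray):
    """(label, start, length) for each maximal run."""
    labels = np.asarray(labels)
    if labels.size == 0:
        return []
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [labels.size]])
    return [(labels[s], int(s), int(e - s)) for s, e in zip(starts, ends)]


def fill_unassigned(
    labels: np.ndarray, unassigned: str = "unassigned"
) -> np.ndarray:
    """Propagate the preceding behavior over 'unassigned' frames.

    Under-sampled (flagged) phase bins carry no behavior label; brief
    passages through them should not break a behavioral run, so each
    unassigned frame inherits the last assigned label (the first frames
    inherit the first assigned label).  A sequence with no assigned
    frame at all is returned unchanged.
    """
    labels = np.asarray(labels)
    mask = labels == unassigned
    if not mask.any() or mask.all():
        return labels.copy()
    out = labels.copy()
    idx = np.where(mask, 0, np.arange(labels.size))
    idx = np.maximum.accumulate(idx)
    # leading unassigned frames: inherit the first assigned label
    first = np.flatnonzero(~mask)[0]
    out[:first] = labels[first]
    sel = mask & (np.arange(labels.size) >= first)
    out[sel] = labels[idx[sel]]
    return out


def median_filter_labels(labels: np.ndarray, window: int) -> np.ndarray:
    """Median-filter a categorical sequence via its integer codes.

    With two labels this is a majority filter; with more, the median of
    the (sorted-vocabulary) codes is used, which is the direct
    analogue of median smoothing of a numeric state sequence.
    """
    labels = np.asarray(labels)
    if window <= 1:
        return labels.copy()
    vocab = sorted(set(labels.tolist()))
    codes = np.array([vocab.index(v) for v in labels])
    filt = median_filter(codes, size=window, mode="nearest")
    return np.asarray(vocab, dtype=object)[filt].astype(labels.dtype)


def dwell_statistics(
    behavior_seq,
    forward_label: str = "forward",
    backward_label: str = "backward",
    median_window: int = 11,
    bout_gap: int = 30,
) -> DwellStats:
    """Dwell-time samples for forward and backward runs plus backing bouts.

    The sequence is first median-filtered (``median_window`` steps) to
    remove decoder glitches, then contiguous runs of the two locomotor
    labels are tabulated.  A backing bout groups consecutive backward
    runs separated by forward runs of at most ``bout_gap`` frames; its
    duration spans from the first to the last backward frame of the
    group.
    """
    seq = np.asarray(behavior_seq)
    if seq.size == 0:
        raise ValueError("empty behavior sequence")
    seq = fill_unassigned(seq)
    filt = median_filter_labels(seq, median_window)
    runs = _runs(filt)
    forward = np.array(
        [ln for lbl, _, ln in runs if lbl == forward_label], dtype=float
    )
    backward_runs = [(s, ln) for lbl, s, ln in runs if lbl == backward_label]
    backward = np.array([ln for _, ln in backward_runs], dtype=float)

    bouts = []
    cur_start = cur_end = None
    for s, ln in backward_runs:
        if cur_start is None:
            cur_start, cur_end = s, s + ln
        elif s - cur_end <= bout_gap:
            cur_end = s + ln
        else:
            bouts.append(cur_end - cur_start)
            cur_start, cur_end = s, s + ln
    if cur_start is not None:
        bouts.append(cur_end - cur_start)
    return DwellStats(
        forward=forward,
        backward=backward,
        bouts=np.asarray(bouts, dtype=float),
        labels={"forward": forward_label, "backward": backward_label},
    )


def smoothed_dwell_density(sample, grid=None):
    """Gaussian kernel density of a dwell-time sample on a shared grid."""
    sample = np.asarray(sample, dtype=float)
    if sample.size < 2 or np.ptp(sample) == 0:
        raise ValueError("need a non-degenerate dwell sample")
    kde = gaussian_kde(sample)
    if grid is None:
        grid = np.linspace(sample.min(), sample.max(), 200)
    return grid, kde(grid)


def dwell_r2(obs, sim, n_grid: int = 200) -> float:
    """Squared Pearson correlation between two smoothed dwell densities."""
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    lo = min(obs.min(), sim.min())
    hi = max(obs.max(), sim.max())
    grid = np.linspace(lo, hi, n_grid)
    _, p = smoothed_dwell_density(obs, grid)
    _, q = smoothed_dwell_density(sim, grid)
    r = np.corrcoef(p, q)[0, 1]
    return float(r**2)


def time_to_transition(
    model: ManifoldModel,
    start_bin: int,
    target_behavior: str,
    n_sims: int = 200,
    max_steps: int = 2000,
    seed: int = 0,
    n_boot: int = 200,
) -> TransitionForecast:
    """Simulated distribution of steps until the target behavior starts.

    Each simulation runs the bin chain from ``start_bin`` until the
    per-bin modal behavior first equals ``target_behavior`` (0 when the
    start bin is already in the target).  Runs that never reach the
    target are censored at ``max_steps``; censored runs enter the mean
    only when they are fewer than 5% of all runs (as lower bounds).
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    modal = np.asarray(
        [model.modal_behavior(b) for b in range(model.n_bins)], dtype=object
    )
    if target_behavior not in set(modal.tolist()):
        raise ValueError(f"no bin has modal behavior {target_behavior!r}")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(model.bin_transitions, axis=1)
    times = np.empty(n_sims)
    censored = np.zeros(n_sims, dtype=bool)
    for i in range(n_sims):
        b = int(start_bin)
        t = 0
        while t < max_steps and modal[b] != target_behavior:
            if not model.visited[b]:
                break
            b = int(
                np.searchsorted(cum[b], rng.random(), side="right")
            )
            b = min(b, model.n_bins - 1)
            t += 1
        times[i] = t
        censored[i] = modal[b] != target_behavior
    frac = censored.mean()
    use = times if frac < 0.05 else times[~censored]
    if use.size == 0:
        mean = float("nan")
        ci = (float("nan"), float("nan"))
        warnings.warn("all simulations censored; forecast undefined", stacklevel=2)
    else:
        mean = float(use.mean())
        boot = rng.choice(use, size=(n_boot, use.size), replace=True).mean(axis=1)
        ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    return TransitionForecast(
        start_bin=int(start_bin),
        target_behavior=target_behavior,
        times=times,
        censored=censored,
        mean=mean,
        ci95=ci,
    )


def null_time_to_transition(dwells, t_start: float):
    """Dwell-time-only null forecast: expected residual time.

    Given an empirical dwell sample and the elapsed time since behavior
    onset, the null prediction is the mean of ``d - t_start`` over
    dwells ``d > t_start`` (the right tail of the dwell distribution).
    Returns ``(expected_residual, residual_sample)``; raises when no
    dwell exceeds ``t_start``.
    """
    dwells = np.asarray(dwells, dtype=float)
    if dwells.size == 0:
        raise ValueError("empty dwell sample")
    if t_start < 0:
        raise ValueError("t_start must be >= 0")
    residuals = dwells[dwells > t_start] - t_start
    if residuals.size == 0:
        raise ValueError(
            f"no observed dwell exceeds t_start={t_start}; null undefined"
        )
    return float(residuals.mean()), residuals
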