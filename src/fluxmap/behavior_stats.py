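"""Standalone behavioral statistics: phase warping, template decoding,
relative information.

Three analyses that operate directly on traces and behavior labels,
independently of the manifold:

* behavioral-phase warping of single-behavior activity snippets to a
  common 100-sample axis, with a PC1 / one-way-ANOVA test of
  inter-individual consistency;
* template-based decoding of behavioral event onsets with an optimal
  score threshold (maximizing the probability of correct
  identification) and bootstrap over data partitions;
* relative information between observed and simulated dwell-time
  distributions, as a ratio of summed minimal KL divergences.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import argrelextrema
from scipy.stats import f_oneway

from .datatypes import Recording

__all__ = [
    "phase_warp",
    "consistency_test",
    "ThresholdResult",
    "optimize_threshold",
    "template_decode",
    "bootstrap_template_decode",
    "kl_divergence",
    "min_binned_kl",
    "RelativeInformation",
    "relative_information",
]

N_PHASE_SAMPLES = 100


def phase_warp(trace, t_start: int, t_end: int, n_samples: int = N_PHASE_SAMPLES):
    """Warp one behavior instance onto the common behavioral-phase axis.

    Time is normalized to phase ``(t - t_start) / (t_end - t_start)``,
    the trace linearly resampled at ``n_samples`` equally spaced phases
    in [0, 1], and the mean over the instance subtracted so that
    differences between instances reflect temporal pattern rather than
    overall activity level.
    """
    trace = np.asarray(trace, dtype=float).ravel()
    if t_end <= t_start:
        raise ValueError("t_end must exceed t_start")
    if t_end - t_start < 2:
        raise ValueError("behavior instance must span at least 2 frames")
    seg_t = np.arange(t_start, t_end + 1)
    phases = np.linspace(0.0, 1.0, n_samples)
    warped = np.interp(
        t_start + phases * (t_end - t_start), seg_t, trace[t_start : t_end + 1]
    )
    return warped - warped.mean()


def consistency_test(warped: np.ndarray, animal_ids: Sequence) -> float:
    """One-way ANOVA p-value for inter-individual consistency.

    The warped instances (rows) are projected onto their first
    principal axis; the projections are compared across animals with a
    one-way ANOVA.  A small p-value means the temporal activity pattern
    differs consistently between individuals.  The caller is
    responsible for any multiple-comparison correction (the worm
    analyses use Bonferroni at alpha = 0.05).
    """
    warped = np.asarray(warped, dtype=float)
    ids = np.asarray(animal_ids)
    groups = np.unique(ids)
    if groups.size < 2:
        raise ValueError("need instances from at least 2 animals")
    for g in groups:
        if (ids == g).sum() < 2:
            raise ValueError(f"animal {g!r} has fewer than 2 instances")
    centered = warped - warped.mean(axis=0)
    # PC1 projection via SVD (deterministic up to sign, which ANOVA ignores)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    proj = centered @ vt[0]
    samples = [proj[ids == g] for g in groups]
    if all(np.ptp(s) == 0 for s in samples):
        raise ValueError("degenerate data: zero within-group variance")
    return float(f_oneway(*samples).pvalue)


@dataclass
class ThresholdResult:
    """Optimal decoding threshold and its correct-identification rate."""

    threshold: float
    probability: float


def optimize_threshold(scores_true, scores_false) -> ThresholdResult:
    """Threshold maximizing the probability of correct identification.

    For candidate threshold ``X`` the objective is::

        p(X) = |true >= X| / (|true| + |false >= X|)

    evaluated at every observed score; ties go to the lowest threshold.
    """
    st = np.sort(np.asarray(scores_true, dtype=float).ravel())
    sf = np.sort(np.asarray(scores_false, dtype=float).ravel())
    if st.size == 0 or sf.size == 0:
        raise ValueError("both score sets must be nonempty")
    candidates = np.unique(np.concatenate([st, sf]))
    n_true_ge = st.size - np.searchsorted(st, candidates, side="left")
    n_false_ge = sf.size - np.searchsorted(sf, candidates, side="left")
    p = n_true_ge / (st.size + n_false_ge)
    best = int(np.argmax(p))  # first maximum -> lowest threshold
    return ThresholdResult(float(candidates[best]), float(p[best]))


def _event_scores(activity: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Sliding inner product of a (window x neurons) template.

    ``score[t]`` matches the template against the window *ending* at
    frame ``t``; the first ``window - 1`` frames get -inf.
    """
    window, n_neurons = template.shape
    n = activity.shape[0]
    score = np.full(n, -np.inf)
    flat = template.ravel()
    for t in range(window - 1, n):
        score[t] = activity[t - window + 1 : t + 1].ravel() @ flat
    return score


def _score_peaks(score: np.ndarray) -> np.ndarray:
    peaks = argrelextrema(score, np.greater)[0]
    return peaks


def _label_peaks(peaks, onsets, tolerance):
    onsets = np.asarray(onsets)
    if onsets.size == 0 or len(peaks) == 0:
        return np.zeros(len(peaks), dtype=bool)
    return np.array(
        [np.min(np.abs(onsets - p)) <= tolerance for p in peaks], dtype=bool
    )


def _build_template(recs, onsets_per_rec, window):
    snippets = []
    for rec, onsets in zip(recs, onsets_per_rec):
        for on in onsets:
            if on - window + 1 < 0 or on >= rec.activity.shape[0]:
                continue
            snippets.append(rec.activity[on - window + 1 : on + 1])
    if not snippets:
        raise ValueError("no usable training events")
    return np.mean(snippets, axis=0)


def template_decode(
    train_recs: Sequence[Recording],
    train_onsets: Sequence[Sequence[int]],
    validate_rec: Recording,
    validate_onsets: Sequence[int],
    window: int = 10,
    tolerance_frames: int = 10,
    ignore_onsets: Optional[Sequence[int]] = None,
) -> float:
    """Template-matching decoding of behavioral event onsets.

    A per-neuron activity template is averaged over windows of
    ``window`` frames ending at each training onset.  The template's
    sliding inner product with the validation traces gives a similarity
    score; only local maxima of the score count as candidate
    detections.  The decoding threshold is optimized on the training
    scores, and a detection within ``tolerance_frames`` of a true
    validation onset is a hit.  Returns the probability of correct
    identification (hits over hits plus false alarms plus misses of
    the threshold criterion) on the validation data.
    """
    template = _build_template(train_recs, train_onsets, window)
    if validate_rec.activity.shape[0] < window:
        raise ValueError("validation recording shorter than the template")

    # threshold from the training data: one score per true event (the
    # best peak within tolerance of its onset); false scores are peaks
    # away from every onset
    true_scores, false_scores = [], []
    for rec, onsets in zip(train_recs, train_onsets):
        score = _event_scores(rec.activity, template)
        peaks = _score_peaks(score)
        if peaks.size == 0:
            continue
        is_true = _label_peaks(peaks, onsets, tolerance_frames)
        for on in onsets:
            near = peaks[np.abs(peaks - on) <= tolerance_frames]
            if near.size:
                true_scores.append(score[near].max())
        false_scores.extend(score[peaks[~is_true]])
    if not true_scores or not false_scores:
        raise ValueError("training data yields no separable score peaks")
    thr = optimize_threshold(true_scores, false_scores).threshold

    score = _event_scores(validate_rec.activity, template)
    peaks = _score_peaks(score)
    detections = peaks[score[peaks] >= thr]
    if ignore_onsets is not None and len(ignore_onsets):
        # detections at known non-validation events (e.g. the training
        # half of a within-recording split) are neither hits nor false
        near_ignored = _label_peaks(detections, ignore_onsets, tolerance_frames)
        detections = detections[~near_ignored]
    is_true = _label_peaks(detections, validate_onsets, tolerance_frames)
    n_events = len(validate_onsets)
    n_false = int((~is_true).sum())
    hit_onsets = {
        int(np.asarray(validate_onsets)[np.argmin(np.abs(np.asarray(validate_onsets) - d))])
        for d in detections[is_true]
    } if is_true.any() else set()
    n_hits = len(hit_onsets)
    denom = n_events + n_false
    return n_hits / denom if denom else 0.0


def bootstrap_template_decode(
    rec: Recording,
    onsets: Sequence[int],
    window: int = 10,
    tolerance_frames: int = 10,
    n_boot: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Within-recording bootstrap of template decoding.

    Each resample splits the events 50/50 into training and validation
    halves at random and decodes the full recording with a template
    built on the training half, scoring only the validation onsets.
    Returns the decoding probabilities across resamples.
    """
    onsets = np.asarray(onsets, dtype=int)
    if onsets.size < 2:
        raise ValueError("need at least 2 events to bootstrap")
    rng = np.random.default_rng(seed)
    probs = np.empty(n_boot)
    for i in range(n_boot):
        perm = rng.permutation(onsets.size)
        half = onsets.size // 2
        train, val = onsets[perm[:half]], onsets[perm[half:]]
        probs[i] = template_decode(
            [rec], [train], rec, val, window=window,
            tolerance_frames=tolerance_frames, ignore_onsets=train,
        )
    return probs


def kl_divergence(p, q, eps: float = 1e-12) -> float:
    """Discrete KL divergence D(p || q) in nats, with additive flooring."""
    p = np.asarray(p, dtype=float) + eps
    q = np.asarray(q, dtype=float) + eps
    p = p / p.sum()
    q = q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def min_binned_kl(
    obs, sim, bin_range: tuple = (40, 200), smooth_sigma: float = 1.0,
    eps: float = 1e-12,
) -> float:
    """Minimum KL divergence of observed vs simulated dwell samples.

    Both samples are histogrammed on shared edges spanning their union
    range; the histograms are smoothed with a Gaussian kernel
    (``smooth_sigma`` bins), floored by ``eps``, and normalized.
    Because binning strongly affects information-theoretic quantities,
    the divergence is scanned over bin counts in ``bin_range`` and the
    minimum is reported.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.size < 2 or sim.size < 2:
        raise ValueError("need at least 2 samples in each distribution")
    lo = min(obs.min(), sim.min())
    hi = max(obs.max(), sim.max())
    if hi == lo:
        raise ValueError("degenerate one-point distributions")
    best = np.inf
    for nb in range(bin_range[0], bin_range[1] + 1):
        edges = np.linspace(lo, hi, nb + 1)
        p = np.histogram(obs, bins=edges)[0].astype(float)
        q = np.histogram(sim, bins=edges)[0].astype(float)
        if smooth_sigma > 0:
            p = gaussian_filter1d(p, smooth_sigma)
            q = gaussian_filter1d(q, smooth_sigma)
        best = min(best, kl_divergence(p, q, eps=eps))
    return float(best)


@dataclass
class RelativeInformation:
    """Summed minimal KL divergences and their ratio."""

    i_tot_reference: float
    i_tot_modified: float
    i_rel: float
    per_distribution: dict


def relative_information(
    obs_dwells: dict,
    sim_dwells_reference: dict,
    sim_dwells_modified: dict,
    bin_range: tuple = (40, 200),
) -> RelativeInformation:
    """Relative information between a reference and a modified model.

    For each behavior distribution present in the observed dict
    (typically forward, backward, and backing bouts), the minimal
    binned KL divergence between observation and simulation is
    computed; divergences are summed into a total information for the
    reference and the modified simulation, and their ratio
    ``I_rel = I_tot(reference) / I_tot(modified)`` is returned.
    """
    per = {}
    i_ref = 0.0
    i_mod = 0.0
    for key, obs in obs_dwells.items():
        d_ref = min_binned_kl(obs, sim_dwells_reference[key], bin_range)
        d_mod = min_binned_kl(obs, sim_dwells_modified[key], bin_range)
        per[key] = {"reference": d_ref, "modified": d_mod}
        i_ref += d_ref
        i_mod += d_mod
    i_rel = i_ref / i_mod if i_mod > 0 else float("inf")
    return RelativeInformation(i_ref, i_mod, i_rel, per)
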