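# Methods

This note records the model, the numerical choices, and the reasoning
behind the design decisions in `fluxmap`, at the level of detail a user
needs to judge what the package's results do and do not show.

## Model and assumptions

The package models a noisy dynamical system observed through
multivariate time series (canonically ΔF/F calcium traces at ~3
frames/s).  The governing assumption is that the system is at steady
state over the recording and that its deterministic component is a
*cyclic flux*: a divergence-free flow forming closed loops in phase
space, with stochastic forces superimposed.  Under that assumption the
long-run state of the system is summarized by two macroscopic
variables: which loop it is on (flux label α) and where along the loop
it is (phase θ).

The phase space is reconstructed by delay embedding of the observed
activity and its time derivative (position and velocity of the
observable).  Transition probabilities between embedded states are
estimated with a Gaussian kernel *centered on the next observed state*,
so the row-stochastic transition matrix **M** preserves temporal order
and can carry complex spectrum; its dominant complex eigenmode defines
θ, and maximum-modularity clustering of time-lagged row correlations of
the densified matrix defines α.  The (θ, α) bins, with their empirical
bin-to-bin transition matrix, form the final model: a Markov chain over
phase bins whose simulation generates novel state sequences mapped back
to activity (per-bin mean snapshots) and behavior (per-bin label
distributions).

The Markov-chain reduction is an approximation: lumping states into
bins discards any history dependence finer than the bin partition.  Its
known failure mode, observed and characterized during development, is
memoryless "blob" dynamics whose transition corridors are shared by
both travel directions; there, label flicker around switches teaches
the lumped chain wrong-way edges and dwell times come out short.
Dynamics with genuinely directed cyclic structure (the method's target
domain) do not have this problem, because each corridor is traversed in
only one direction.

## Parameters

All defaults live in `fluxmap.PipelineConfig` and reflect the reference
configuration for worm whole-brain recordings:

| parameter | default | units | role |
|---|---|---|---|
| `smooth_sigma` | 1 | frames | Gaussian smoothing SD before z-scoring |
| `tau` | 10 | frames | embedding delay (~4 s at 3 Hz; autocorrelation zero-crossing) |
| `n_delays` | 5 | — | extra lags beyond lag 0 (dimension 2·n·(n_delays+1)) |
| `k_neighbors` | 12 | — | kernel neighborhood size, incl. the next observed point |
| `local_window` | 12 | frames | temporal window of the local SD in the bandwidth |
| `sigma_mode` | two_pass | — | resolution of the self-referential bandwidth |
| `densify_min_frac` | 0.25 | — | row fill target before trajectory clustering |
| `delta_theta` | 0.05 | rad | phase-bin width (126 bins per flux) |
| `min_bin_count` | 5 | states | occupancy below which a bin is 'unassigned' |
| `median_window` | 11 | frames | median filter before dwell statistics |
| `bout_gap` | 30 | frames | max forward run inside a backing bout |
| `kl_bin_range` | (40, 200) | — | bin-count scan for KL divergences |
| `tolerance_frames` | 10 | frames | event-matching tolerance in decoding |
| `ava_threshold_z` | 0.0 | z | threshold for reference-neuron behavior labels |

Bandwidth (`sigma_mode`): the bandwidth definition
σ² = σ_l(D_t) σ_l(D_(t+1)) ⟨k⟩ is self-referential (the mean kernel
value ⟨k⟩ depends on σ²).  `two_pass` (default) computes a provisional
kernel with σ₀² = σ_l(D_t)·σ_l(D_(t+1)), sets σ² = σ₀²·⟨k₀⟩, and
re-evaluates once; `fixed_point` iterates the same map to 1e-6 (50
iterations max).  Both agree in the small-bandwidth limit; two_pass is
deterministic and cheap.  When the local SD vanishes (locally constant
data) the row falls back to putting all mass on the next observed
point, with a warning.

Conventions: population SD (divide by n) throughout; phases live in
(−π, π] with circular distance everywhere; the local-SD window covers
frames [t − w/2, t + w/2), truncated at series ends; frames are
0-based; dwell times are reported in frames (seconds = frames /
`frame_rate`).

## Numerical choices

* **Kernel neighborhood.**  "The k nearest neighbors of D_(t+1)" is
  read as including D_(t+1) itself (its own nearest neighbor, at
  distance 0), so `k_neighbors=1` reproduces the deterministic limit
  exactly: ones on the superdiagonal, zeros elsewhere.  kNN ties break
  to the lower index; below 4,000 points neighbors come from exact
  pairwise distances, above from a tree query re-sorted stably by
  (distance, index).
* **State set.**  The final point of each recording has no successor
  and is dropped from the state set.  The one row whose kernel centers
  on such a dropped point redistributes that kernel over the nearest
  retained states; no transition ever links two recordings.
* **Mode selection.**  The dominant cyclic mode is the complex
  eigenvalue of largest modulus.  Among near-dominant complex modes
  (within 10% of the best modulus), eigenvectors localized on a small
  subset of states — participation ratio below half the candidates'
  maximum — are discarded first: such modes are slow oscillations of
  rare substructures, not the global flux.  Sparse eigensolves use a
  fixed ARPACK start vector so results are run-to-run deterministic.
* **Phase orientation.**  The eigenvector's componentwise argument
  gives θ up to global rotation and conjugation; orientation is fixed
  so the median per-step circular phase increment is positive (the flux
  runs forward in time).  Each flux's phase is re-derived from its own
  row-renormalized sub-matrix, because one global eigenmode cannot
  phase two disjoint loops coherently.
* **Trajectory clustering.**  Row correlations are maximized over all
  circular shifts via the cross-power spectrum (FFT), blocked to bound
  memory.  Modularity optimization uses seeded Leiden refinement
  (igraph/leidenalg), best of 10 restarts; above 600 states the
  correlation matrix is computed on an evenly strided subset and
  remaining states inherit the label of their nearest clustered
  neighbor in the embedded space.  Negative similarities are clipped to
  zero for the graph.
* **Binning.**  Bin centers are spaced 2π/⌈2π/Δθ⌉ per flux; assignment
  maximizes the circular Gaussian likelihood (ties to the lower index);
  unoccupied bins are kept but flagged.  Per-bin activity used for the
  3-D coordinate export is smoothed over θ with a circular Gaussian of
  two bins' SD (export only; plays no role in the dynamics).
* **Dwell statistics.**  'unassigned' frames (flagged bins) inherit the
  preceding label before run tabulation, so brief passages through
  under-sampled bins do not break behavioral runs; the median filter
  then removes isolated decoder glitches.  Backing bouts merge backward
  runs separated by forward runs of at most `bout_gap` frames and span
  first-to-last backward frame.
* **Forecasting.**  Transition forecasts use per-bin *modal* labels
  (sampling would add label noise to switch detection).  Runs censored
  at `max_steps` enter the mean only when under 5% of simulations.
  The dwell-time null is the mean of d − t_start over observed dwells
  d > t_start.
* **Information quantities.**  KL divergences are in nats, on shared
  histogram edges spanning the union range, Gaussian-smoothed (σ = 1
  bin), floored at 1e-12, and minimized over bin counts 40–200 because
  binning strongly affects information-theoretic values.

## The synthetic generators

The generators are first-class, tested code; they define the study
conditions for every quantitative check.

* `simulate_two_neuron` — a mutually coupled excitatory/inhibitory pair
  with logistic activation, forward-Euler integrated (dt = 0.01, noise
  SD 0.1 added once per step, without √dt scaling, so noise strength is
  dt-dependent; a variance reading of the noise parameter is available
  as an option).  Its deterministic part has a single weakly unstable
  spiral fixed point; noise sustains recurrent relaxation-like
  excursions.  Default initial condition (0.5, 0.5) with a 1,000-step
  burn-in.
* `simulate_noisy_loops` — one or more circular limit cycles in a 2-D
  latent plane (disjoint centers, 3 radii apart), each with its own
  angular speed, optional phase diffusion, isotropic latent noise, and
  stochastic hops to the next loop when the phase wraps (the junction);
  latent positions are mixed into the observed channels by a fixed
  random linear map.  Ground truth: phase, loop id, latent coordinates,
  and optional phase-sector behavior labels.
* `simulate_markov_switcher` — a hidden Markov chain with per-state
  templates and additive Gaussian noise; dwell times are geometric with
  mean 1/(1−p).  Routing is uniform (jump to any other state) or cyclic
  (always to the next state); the cyclic mode gives the switcher the
  directed-corridor structure the manifold method is built for.

What the generators do *not* emulate: slow indicator kinetics and
bleaching, non-stationarity (learning, state drift), recording
artifacts, inter-animal differences in dynamics (animals differ only by
noise realization and, where tested, by activation templates), and
realistic behavior-annotation uncertainty.  Tests passing on these
fixtures therefore demonstrate correctness of the algorithms under the
stated generative assumptions, not performance on real recordings.

## Scale of the validation runs

The quantitative checks run at sizes chosen to keep statistical error
meaningfully below the tested tolerances on a single CPU: recovery
tests use 1,500–5,000-frame recordings; the closed-loop dwell check
fits two 16,000-frame synthetic animals and simulates 100,000 steps
each (dwell-mean sampling error ~3%, against a 10% tolerance); the
forecasting check compares ~60–90 start bins against analytic expected
times.  Embedding windows are chosen per fixture — a quarter period
with two extra delays for smooth loops, lag-0-only for fixtures with
abrupt state jumps, where long windows would create hybrid states that
blur the manifold.

## Known limitations

* Dwell statistics of memoryless blob-switching dynamics with shared
  bidirectional corridors are systematically underestimated (see Model
  and assumptions); this is a property of the bin-chain reduction, not
  of the estimators.
* The relative-information ratio is unstable when both divergences are
  at histogram sampling-noise level (reference and modified simulations
  both nearly indistinguishable from the observations); it is
  meaningful only when the divergences are resolvable.
* Maximum-modularity clustering of the lagged-correlation graph is
  reliable for spatially disjoint loops; tangent or strongly
  overlapping loops may be merged or over-split, and the per-flux phase
  of a very small cluster falls back to the global phase.
* The mean-snapshot reconstruction of activity from bins removes
  within-bin variance; the sampling mode restores it at the cost of
  frame-to-frame discontinuity.
* In the exactly periodic (noise-free) limit, repeated traversals make
  the leading complex eigenvalue effectively degenerate (each cycle
  harmonic multiplies a near-unit spectrum of within-position mixing
  modes), and the phases of any one eigenvector from that space are
  arbitrary.  A small amount of observation noise lifts the degeneracy
  and stabilizes the phase; relatedly, as noise vanishes all harmonic
  moduli approach the fundamental's, which is why mode selection
  prefers the slowest near-dominant delocalized mode rather than the
  largest modulus alone.
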