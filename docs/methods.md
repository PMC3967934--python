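# Methods

## Model

The membrane potential obeys a fractional-order leaky-integrator equation

    C_m · dᵅV/dtᵅ = −g_L (V − V_L) + I(t),      0 < α ≤ 1,

with the Caputo definition of the fractional derivative, a hard threshold
V_th, reset to V_reset for an absolute refractory period τ_ref, and a
constant initial condition V_0. The Caputo derivative weights the entire
past of dV/dt with a power-law kernel, so the model is non-Markovian for
α < 1 and reduces exactly to the classical LIF at α = 1. The only
"adaptation mechanism" is this memory; there are no adaptation currents or
moving thresholds.

Units are fixed to {mV, ms, nA, nF, µS}, a self-consistent system
(nF·mV/ms = nA). The dimensional awkwardness of C_m multiplying a ms^−α
derivative is handled purely numerically in this unit system — the
discretized update below is what defines the model; no rescaling of C_m is
attempted. Default parameters: C_m = 0.5 nF, g_L = 0.025 µS (τ_m = 20 ms),
V_L = V_reset = V_0 = −70 mV, V_th = −50 mV, τ_ref = 5 ms, injected current
3 nA (`table1_params`). A second preset (`experiment_matched_params`,
g_L = 0.010 µS → τ_m = 50 ms, τ_ref = 1 ms) emulates the slower, less
refractory cells used for the oscillatory and pause protocols; its exact
values are a package choice (see Limitations).

## Discretization (L1 scheme)

On the uniform grid t_k = k·Δt, the Caputo derivative is approximated by
the L1 finite-difference form, and solving explicitly for V(t_N) gives

    V(t_N) = (Δtᵅ Γ(2−α)/C_m) · [−g_L(V_{N−1} − V_L) + I_{N−1}]
             + V(t_{N−1}) − Σ_{k=0}^{N−2} [V(t_{k+1}) − V(t_k)] · W_N(k),

    W_N(k) = (N−k)^{1−α} − (N−1−k)^{1−α}.

The first summand is the *Markov term* (instantaneous drive scaled by the
fractional coefficient Δtᵅ·Γ(2−α)); the sum is the *voltage-memory trace*.
The weights depend only on the lag N−k, are non-negative, grow toward the
present, increase pointwise as α decreases, and vanish identically at
α = 1 (the update then being one forward-Euler step of the classical LIF).
Implementation details:

- **Bootstrap.** The first step after the history origin is a single
  explicit-Euler classical-LIF step (the fractional sum needs two samples).
- **Spikes.** Threshold crossing is inclusive (candidate ≥ V_th). The spike
  sample records V_th (clipped); the following ⌈τ_ref/Δt⌉ samples record
  V_reset. All recorded samples — including spike and refractory samples —
  enter the memory sum; the reset step contributes a large negative
  increment, which produces the negative memory-trace transient after each
  spike and is essential for spike-to-spike adaptation. The neuron becomes
  eligible to fire again at the first grid point after the clamp.
- **Memory modes.** `full` (default) integrates the entire history exactly
  — O(N) per step, O(N²) per run, with the hot loop compiled (numba). No
  history truncation is applied by default because the long-memory effects
  (25-s recovery times) depend on the full trace. `reset_on_spike`
  truncates the history at each spike (the memory-reset variant); with
  constant current it must produce equal ISIs after the first, which is
  tested against the closed-form generator.
- **Time step.** Default Δt = 0.1 ms, exposed everywhere; long protocol
  sweeps use 0.5–1 ms (stated per protocol below). Convergence to the
  closed-form sub-threshold solution is asserted in the tests rather than
  assuming any particular step.
- **Determinism.** The integrator is exactly deterministic; all stochastic
  stimuli are driven by an explicit integer seed through
  `numpy.random.default_rng`.

## Closed-form reference (Mittag-Leffler)

For constant sub-threshold current the equation has the closed-form
solution

    V(t) = V_∞ + (V_0 − V_∞) · E_α(−tᵅ/τ_m),      V_∞ = V_L + I/g_L,

with E_α the one-parameter Mittag-Leffler function. The in-package
evaluator uses the power series Σ zᵏ/Γ(αk+1) for small |z| (switch-over at
|z| = min(5, 9ᵅ), keeping the worst intermediate term below ~e⁹ so
alternating-series cancellation stays under the 1e−10 default tolerance)
and, for large negative arguments, the completely monotone spectral
representation

    E_α(−x) = sin(απ)/(απ) · ∫₀^∞ exp(−(u·x)^{1/α}) / (u² + 2u·cos(απ) + 1) du

integrated adaptively (scipy.integrate.quad, with an explicit break point
at u = 1 where the integrand peaks as α → 1). Both branches are
cross-validated on their overlap band, against E_1 = exp, and against the
identity E_{1/2}(−x) = erfcx(x).

For small times E_α(−tᵅ/τ) ≈ exp(−tᵅ/(τ·Γ(1+α))) (stretched exponential),
which yields the closed-form charging time from reset to threshold

    T = [τ_m · Γ(1+α) · ln((V_∞ − V_reset)/(V_∞ − V_th))]^{1/α}

and the approximate rate 1000/(T + τ_ref) spikes/s; at α = 1 these are the
exact classical LIF formulas (T ≈ 3.65 ms, 115.7 spikes/s at 3 nA). The
full evaluator, not the approximation, is used for the memory-reset spike
generator (bisection on the monotone relaxation for each crossing time).

**Oracle use.** With Δt halving over {0.5, 0.25, 0.125, 0.0625} ms, the sup
error of the L1 trace against the closed form decreases monotonically for
α ∈ {0.3, 0.5, 0.8}. The comparison window is t ∈ [10, 2000] ms: the
pointwise error at t = Δt cannot converge in sup norm (the exact solution
rises like tᵅ while the Euler bootstrap rises linearly), and at Δt = 1 ms
the bootstrap error partially cancels the L1 truncation error for small α,
which is why the coarsest level is excluded from the monotonicity check.

## Stimulation protocols and quantification

- **Step / conditioning.** Constant steps; pre/post protocols concatenate a
  hyper- or depolarizing conditioning epoch with a test step. Epoch
  durations are rounded down to the grid (warning logged when not a
  multiple of Δt).
- **ZAP.** Sinusoid whose instantaneous frequency follows a logistic
  function of time from f_lo to f_hi (default 0→100 Hz in 10 s, endpoints
  within 1% of the band); the phase is the running integral of the
  frequency, so there are no phase jumps. The logistic steepness is
  exposed — only the monotone sweep matters for the impedance analysis.
  Impedance Z(f) = FFT(V)/FFT(I) on mean-subtracted signals, one
  non-windowed transform of the whole sub-threshold epoch, magnitude
  optionally smoothed with a 1-Hz boxcar (edge-preserving); phase negative
  when voltage lags current. Spiking epochs are refused.
- **Sine gain/phase.** Instantaneous rate = 1000/ISI at interval midpoints
  (the first-interval rate is exposed separately for the conditioning
  analysis). The rate is fitted by linear least squares with basis
  {1, log t, sin, cos} at the known period; the log term absorbs the slow
  power-law drift of the mean rate so it does not alias into the
  oscillation amplitude (disable with `detrend=None`). Gain is the rate
  amplitude over the current amplitude, (spikes/s)/nA; phase lead positive
  when the rate leads the current. Default drive 3.0 ± 0.5 nA, periods
  2–16 s, 5 cycles with the first discarded, Δt = 0.5 ms.
- **Square-wave adaptation.** Drive 3.4 ↔ 4.0 nA; a single exponential
  r_∞ + (r_0 − r_∞)e^{−t/τ} is fitted to the downward transient after each
  low→high switch and the upward transient after each high→low switch, in
  every period after the first (4 periods total), and τ is averaged across
  cycles — single-cycle fits of reciprocal-ISI rates are noisy.
- **Five-cycle gap protocol.** Five 2-s cycles of 4 nA separated by a
  swept silent gap (Δt = 0.5 ms; 1 ms for the 25-s gaps). Recovery metric:
  second-to-last ISI of Cycle 5 over that of Cycle 1; first-ISI comparison
  for the long-memory bound.
- **Pulse pause.** α = 0.1, `experiment_matched` preset, 4 nA baseline with
  a 20-s lead-in (first-spike latencies at α = 0.1 run to many seconds), a
  2-s pulse of 1–9 nA on top, 4-s tail. Pause = pulse offset to the next
  spike, excluding the offset sample itself (still driven by the last
  in-pulse current value under the explicit scheme); censored pauses are
  flagged.
- **Noise protocols.** Gaussian white noise generated per grid sample,
  scaled per epoch by a variance schedule, filtered with the causal alpha
  kernel (t/τ²)e^{−t/τ} (unit discrete DC gain, default τ = 2 ms), and
  added to the mean. The embedded-signal variant freezes one noise
  component across trials.
- **Reliability.** Trains binarized on the grid, smoothed with a Gaussian
  of σ = 3 ms (configurable), pairwise cosine similarity averaged over all
  pairs: R = 2/(N(N−1)) Σ_{i<j} s_i·s_j/(|s_i||s_j|) ∈ [0, 1]. Analysis
  epoch: last 5 s of 10-s simulations. The constant drive is calibrated per
  α (bisection on the noise-free rate) so ensembles are compared at a
  matched ~14 spikes/s; noise σ = 0.03 nA, alpha-filtered. Trains with no
  spikes in the epoch are excluded with a warning.
- **ISI power law.** Log-binned histogram (10 bins/decade), regression of
  log count on log ISI over occupied bins; an exponential alternative
  (log count vs linear ISI) is fitted on the same support so the two
  hypotheses can be compared by r².
- **Exponent fitting.** Grid search (default 0.05–1.00 step 0.01, finer
  than the coarse exploratory 0.5–1.0 step 0.1 preset because fitted
  exponents of adapting cells lie below 0.5); the protocol is re-simulated
  at every candidate α and the mean squared error against the reference
  curve minimized. The 95% CI walks the grid in both directions until the
  MSE exceeds the minimum by 5% — interpreted as *relative* change
  (configurable), since the rule's absolute/relative sense is ambiguous.
  An optional leading-ISI truncation mirrors fits that drop the first few
  model ISIs.

## Synthetic fixtures

`flif.fixtures.generate_fixtures` writes ISI-vs-index curves at known
α ∈ {0.15, 0.2, 0.4} (clean and with 5% multiplicative noise), a
rate-vs-time curve under 16-s square drive, and raster ensembles, each with
a JSON sidecar of generating parameters. They emulate digitized
experimental adaptation curves in shape and noise level, but not their
biological variability: cell-to-cell parameter scatter, slow
non-stationarities, measurement artifacts and spike-sorting errors are all
absent. Closed-loop tests passing on these fixtures therefore demonstrate
that the fitting machinery is consistent, not that real recordings are
fitted this well.

## Problem sizes

The default test and acceptance runs use 1–2-s simulations at Δt = 0.1 ms
for classical-limit and oracle checks, tens of seconds at Δt = 0.5–1 ms for
the oscillatory and history protocols, and 20-trial ensembles for
reliability — sizes chosen so the memory trace (O(N²) total work) stays
comfortable on a single core while every qualitative regime of the model is
exercised.

## Design choices made where the design was open

- The L1 weight indexing is fixed by two invariants: all past weights are
  exactly zero at α = 1, and weights increase pointwise as α decreases; the
  increment one step into the past carries weight 2^{1−α} − 1.
- The spike sample records V_th rather than the (overshooting) candidate;
  the recorded trace never exceeds threshold.
- With τ_ref = 0 a single reset sample is still recorded, so the post-spike
  state is always V_reset.
- The memory-reset variant restarts its history at the *last* refractory
  sample, so charging always begins from V_reset after the clamp — matching
  the closed-form generator's cycle structure (ISI = τ_ref + crossing time).
- Gain measurements detrend with a logarithmic baseline by default (see
  above); the plain sine fit remains available.

## Known limitations

- The exact parameter values of the slow-membrane preset and several
  protocol constants (cycle duration, pulse duration, baseline current,
  alpha-filter time constants) are package choices; quantitative outcomes
  that depend on them — most visibly the saturated post-pulse pause
  (measured ≈1.2 s here) and the gap needed for 5% ISI-ratio recovery
  (measured ≈10 s under these conditions) — shift substantially with those
  constants, while orderings and saturation behavior are robust.
- Under the default study conditions the measured log-log gain-vs-period
  slope at α = 0.2 is ≈ −0.12, not −α: the model's oscillatory rate
  response contains a non-vanishing adapted static gain alongside the
  fractional (period)^{−α} component, and over the 2–16-s band the mixture
  roughly halves the apparent slope. The slope deepens as α decreases and
  flattens toward 0 by α ≈ 0.4.
- No action-potential waveform, conductance-based adaptation, synaptic
  input, or multi-compartment/cable extension; current injection only.
- The full-memory integrator is exact but O(N²); multi-minute simulations
  at Δt = 0.1 ms are expensive by design (no truncation by default).
- The Mittag-Leffler evaluator covers real arguments with 0 < α ≤ 1 only.
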