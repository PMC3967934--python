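"""Fractional leaky integrate-and-fire (FLIF) state-update engine.

The membrane equation

    C_m * d^alpha V / dt^alpha = -g_L * (V - V_L) + I(t),   0 < alpha <= 1,

uses the Caputo fractional derivative, discretized with the L1 scheme on a
uniform grid t_k = k*dt.  Solving the explicit update for V(t_N) splits the
dynamics into a *Markov term* — the instantaneous leaky-integrator drive
scaled by the fractional coefficient dt**alpha * Gamma(2-alpha) — and a
*voltage-memory trace*, the weighted sum of all past voltage increments:

    V(t_N) = (dt**alpha * Gamma(2-alpha) / C_m) * (-g_L*(V_{N-1}-V_L) + I_{N-1})
             + V(t_{N-1}) - sum_{k=0}^{N-2} [V(t_{k+1})-V(t_k)] * W_N(k),

    W_N(k) = (N-k)**(1-alpha) - (N-1-k)**(1-alpha).

At alpha = 1 every past weight vanishes and the update reduces exactly to a
forward-Euler step of the classical leaky integrate-and-fire model.  Spiking
follows a fire-and-reset rule: when the candidate voltage reaches threshold
(inclusive) a spike is recorded, the spike sample is clipped to V_th, and the
voltage is clamped to V_reset for the refractory period.  All recorded
samples — spike and refractory samples included — enter the history summed
by the memory trace, which is what produces the negative memory transient
after each reset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .params import ModelParams, TimeGrid

__all__ = [
    "MemoryKernel",
    "NeuronState",
    "SimulationOptions",
    "SimulationResult",
    "advance_one_step",
    "gamma_coefficient",
    "memory_weights",
    "simulate",
    "voltage_memory_trace",
]

TRACE_COLUMNS = ["time_ms", "current_nA", "voltage_mV", "memory_trace_mV", "markov_term_mV"]


def _validate_alpha(alpha: float) -> None:
    if not (0.0 < alpha <= 1.0):
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")


def lag_weights(alpha: float, n_max: int) -> np.ndarray:
    """L1 weights indexed by lag j = N - k, for j = 0..n_max.

    ``w[j] = j**(1-alpha) - (j-1)**(1-alpha)``; ``w[0] = 0`` by convention and
    ``w[1] = 1`` is the coefficient of the most recent increment, absorbed into
    the explicit update.  Lags j >= 2 weight the memory trace.  At alpha = 1
    all lags j >= 2 carry exactly zero weight (no memory).
    """
    _validate_alpha(alpha)
    j = np.arange(n_max + 1, dtype=np.float64)
    w = np.empty(n_max + 1)
    w[0] = 0.0
    w[1:] = j[1:] ** (1.0 - alpha) - j[:-1] ** (1.0 - alpha)
    if alpha == 1.0:
        w[1:] = 0.0
        w[1] = 1.0
    return w


def memory_weights(alpha: float, N: int) -> np.ndarray:
    """Weights W_N(k) applying to past increments ΔV(t_k), k = 0..N-2.

    The most recent increment (k = N-1, unit weight) is part of the explicit
    update itself and is therefore excluded here.  Weights are non-negative,
    increase toward the present, and increase pointwise as alpha decreases.
    """
    _validate_alpha(alpha)
    if N < 2:
        raise ValueError(f"memory weights need a step index N >= 2, got {N}")
    w = lag_weights(alpha, N)
    # k = 0..N-2  <->  lag j = N-k = 2..N, oldest first
    return w[2 : N + 1][::-1].copy()


def gamma_coefficient(alpha: float, dt: float) -> float:
    """Fractional coefficient dt**alpha * Gamma(2 - alpha) of the Markov term."""
    _validate_alpha(alpha)
    if dt <= 0.0:
        raise ValueError(f"dt must be positive, got {dt}")
    return dt**alpha * math.gamma(2.0 - alpha)


@dataclass(frozen=True)
class MemoryKernel:
    """Precomputed L1 kernel for a given step index: past-increment weights
    plus the scalar fractional coefficient of the Markov term."""

    alpha: float
    weights: np.ndarray
    gamma_coeff: float

    @classmethod
    def build(cls, alpha: float, N: int, dt: float) -> "MemoryKernel":
        return cls(alpha=alpha, weights=memory_weights(alpha, N), gamma_coeff=gamma_coefficient(alpha, dt))


def voltage_memory_trace(history: np.ndarray, kernel: MemoryKernel) -> float:
    """Weighted sum of past voltage increments, sum_k ΔV(t_k)·W(k) (mV).

    ``history`` must contain the samples V(t_0..t_{N-1}) that precede the step
    being computed; the kernel must have been built for the same N.
    """
    history = np.asarray(history, dtype=np.float64)
    if history.ndim != 1 or history.size < 2:
        raise ValueError("history must be a 1-d array with at least 2 samples")
    n_incr = history.size - 1
    if kernel.weights.size != n_incr:
        raise ValueError(
            f"kernel built for {kernel.weights.size} increments, history has {n_incr}"
        )
    return float(np.dot(np.diff(history), kernel.weights))


@dataclass(frozen=True)
class SimulationOptions:
    """Integration options.

    memory_mode : 'full' integrates the entire voltage history; 'reset_on_spike'
        discards the history at every spike (the memory-reset variant), after
        which integration bootstraps again from the reset sample.
    dt : time step (ms).
    """

    memory_mode: str = "full"
    dt: float = 0.1

    def __post_init__(self) -> None:
        if self.memory_mode not in ("full", "reset_on_spike"):
            raise ValueError(f"unknown memory_mode {self.memory_mode!r}")
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")


def _n_ref_samples(tau_ref: float, dt: float) -> int:
    # at least one reset sample so the post-spike state is V_reset
    return max(int(math.ceil(tau_ref / dt - 1e-12)), 1)


@dataclass
class NeuronState:
    """Mutable single-neuron state for step-by-step integration.

    Holds the full voltage history (length N+1 after N steps), the refractory
    countdown in samples, accumulated spike times, and the history origin used
    by the memory-reset mode.
    """

    params: ModelParams
    options: SimulationOptions
    voltage: list = field(default_factory=list)
    spike_times: list = field(default_factory=list)
    refractory_left: int = 0
    origin: int = 0
    last_memory_trace: float = 0.0
    last_markov_term: float = 0.0

    def __post_init__(self) -> None:
        if not self.voltage:
            self.voltage = [self.params.V_0]

    @property
    def step_index(self) -> int:
        return len(self.voltage) - 1

    @property
    def time(self) -> float:
        return self.step_index * self.options.dt


def advance_one_step(state: NeuronState, I_now: float) -> NeuronState:
    """Advance the neuron by one grid step under instantaneous current ``I_now``.

    Reference (pure-Python) implementation of the L1 update; ``simulate`` runs
    the same recursion through a compiled kernel and is tested to agree with
    this one sample-for-sample.
    """
    p, opt = state.params, state.options
    dt = opt.dt
    N = state.step_index + 1  # index of the sample being computed
    V = state.voltage

    if state.refractory_left > 0:
        V.append(p.V_reset)
        state.refractory_left -= 1
        state.last_memory_trace = 0.0
        state.last_markov_term = 0.0
        return state

    M = N - state.origin  # steps since the history origin
    if M < 2:
        # bootstrap: one explicit-Euler classical LIF step
        markov = (dt / p.C_m) * (-p.g_L * (V[-1] - p.V_L) + I_now)
        trace = 0.0
    else:
        kernel = MemoryKernel.build(p.alpha, M, dt)
        trace = voltage_memory_trace(np.asarray(V[state.origin :]), kernel)
        markov = (kernel.gamma_coeff / p.C_m) * (-p.g_L * (V[-1] - p.V_L) + I_now)
    candidate = markov + V[-1] - trace
    if not math.isfinite(candidate):
        raise FloatingPointError(f"non-finite voltage candidate at step {N}")
    state.last_memory_trace = trace
    state.last_markov_term = markov

    if candidate >= p.V_th:
        V.append(p.V_th)  # clipped spike sample
        state.spike_times.append(N * dt)
        n_ref = _n_ref_samples(p.tau_ref, dt)
        state.refractory_left = n_ref
        if opt.memory_mode == "reset_on_spike":
            state.origin = N + n_ref  # restart history at the last reset sample
    else:
        V.append(candidate)
    return state


@dataclass(frozen=True)
class SimulationResult:
    """Full trajectory of one simulation on a uniform grid."""

    grid: TimeGrid
    voltage: np.ndarray
    spike_times: np.ndarray
    memory_trace: np.ndarray
    markov_term: np.ndarray
    stimulus: np.ndarray
    params: ModelParams
    options: SimulationOptions

    @property
    def times(self) -> np.ndarray:
        return self.grid.times

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def to_frame(self):
        """Trace as a pandas DataFrame with the canonical CSV columns."""
        import pandas as pd

        return pd.DataFrame(
            {
                "time_ms": self.times,
                "current_nA": self.stimulus,
                "voltage_mV": self.voltage,
                "memory_trace_mV": self.memory_trace,
                "markov_term_mV": self.markov_term,
            }
        )


@njit(cache=True)
def _l1_kernel(V, I, dV, trace_out, markov_out, spike_flags, w, kappa, dt,
               C_m, g_L, V_L, V_reset, V_th, n_ref, reset_on_spike):  # pragma: no cover
    n = V.shape[0]
    ref_left = 0
    origin = 0
    for N in range(1, n):
        if ref_left > 0:
            V[N] = V_reset
            ref_left -= 1
            dV[N - 1] = V[N] - V[N - 1]
            continue
        M = N - origin
        drive = -g_L * (V[N - 1] - V_L) + I[N - 1]
        if M < 2:
            markov = (dt / C_m) * drive
            trace = 0.0
        else:
            markov = (kappa / C_m) * drive
            trace = 0.0
            for j in range(2, M + 1):
                trace += w[j] * dV[N - j]
        cand = markov + V[N - 1] - trace
        trace_out[N] = trace
        markov_out[N] = markov
        if not np.isfinite(cand):
            return N
        if cand >= V_th:
            V[N] = V_th
            spike_flags[N] = True
            ref_left = n_ref
            if reset_on_spike:
                origin = N + n_ref
        else:
            V[N] = cand
        dV[N - 1] = V[N] - V[N - 1]
    return -1


def simulate(
    params: ModelParams,
    stimulus: np.ndarray,
    options: SimulationOptions | None = None,
) -> SimulationResult:
    """Run the FLIF model against a rendered current sequence.

    The stimulus supplies one current sample per grid sample (t_0 included);
    its length therefore fixes ``n_steps = len(stimulus) - 1``.  Deterministic:
    identical inputs give identical results.
    """
    if options is None:
        options = SimulationOptions()
    stimulus = np.ascontiguousarray(stimulus, dtype=np.float64)
    if stimulus.ndim != 1 or stimulus.size < 2:
        raise ValueError("stimulus must be 1-d with at least 2 samples")
    n = stimulus.size
    grid = TimeGrid(dt=options.dt, n_steps=n - 1)

    V = np.empty(n)
    V[0] = params.V_0
    dV = np.zeros(n - 1)
    trace_out = np.zeros(n)
    markov_out = np.zeros(n)
    spike_flags = np.zeros(n, dtype=np.bool_)
    w = lag_weights(params.alpha, n)
    kappa = gamma_coefficient(params.alpha, options.dt)
    n_ref = _n_ref_samples(params.tau_ref, options.dt)

    bad = _l1_kernel(
        V, stimulus, dV, trace_out, markov_out, spike_flags, w, kappa,
        options.dt, params.C_m, params.g_L, params.V_L, params.V_reset,
        params.V_th, n_ref, options.memory_mode == "reset_on_spike",
    )
    if bad >= 0:
        raise FloatingPointError(f"non-finite voltage candidate at step {bad}")

    spike_times = np.flatnonzero(spike_flags) * options.dt
    return SimulationResult(
        grid=grid,
        voltage=V,
        spike_times=spike_times,
        memory_trace=trace_out,
        markov_term=markov_out,
        stimulus=stimulus,
        params=params,
        options=options,
    )
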