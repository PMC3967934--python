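"""Named stimulation/quantification protocols.

Each function wires together a stimulus, the simulator and the relevant
quantification, with defaults reproducing the package's reference study
conditions (step response, conditioning, ZAP impedance, sine gain, square
adaptation, five-cycle gap recovery, post-pulse pause, variance-switching
noise, reliability ensembles, and the memory-reset comparison).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import analysis, stimuli
from .analytic import simulate_analytic_reset
from .core import SimulationOptions, SimulationResult, simulate
from .params import ModelParams, TimeGrid, experiment_matched_params, table1_params
from .analysis import (
    ISISeries,
    SpikeTrain,
    cycle_recovery_metric,
    extract_isis,
    fit_adaptation_tau,
    gain_phase_at_period,
    instantaneous_rate,
    mean_rate,
    pause_after_pulse,
    reliability,
)

__all__ = [
    "run_step",
    "run_prepost",
    "run_zap_impedance",
    "gain_vs_period",
    "loglog_gain_slope",
    "MemoryResetComparison",
    "adaptation_tau_vs_period",
    "run_cycle_train",
    "isis_by_cycle",
    "gap_recovery_ratio",
    "smallest_recovered_gap",
    "first_isi_by_cycle",
    "pause_vs_pulse_amplitude",
    "run_variance_switching",
    "calibrate_current_for_rate",
    "reliability_vs_alpha",
    "memory_reset_comparison",
]


def run_step(
    params: ModelParams,
    amplitude: float = 3.0,
    duration: float = 1000.0,
    dt: float = 0.1,
    memory_mode: str = "full",
) -> SimulationResult:
    """Constant step current from t=0 (the basic adaptation protocol)."""
    grid = TimeGrid.from_duration(duration, dt)
    spec = stimuli.StepCurrent(amplitude=amplitude)
    return simulate(params, stimuli.render(spec, grid), SimulationOptions(memory_mode=memory_mode, dt=dt))


def run_prepost(
    params: ModelParams,
    pre_amplitude: float,
    pre_duration: float,
    post_amplitude: float,
    post_duration: float,
    dt: float = 0.1,
) -> SimulationResult:
    """Conditioning current followed by a test step."""
    grid = TimeGrid.from_duration(pre_duration + post_duration, dt)
    spec = stimuli.PrePostCurrent(pre_amplitude=pre_amplitude, pre_duration=pre_duration,
                                  post_amplitude=post_amplitude)
    return simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))


def run_zap_impedance(
    params: ModelParams,
    amplitude: float = 0.1,
    f_hi: float = 100.0,
    sweep_duration: float = 10_000.0,
    dt: float = 0.1,
) -> tuple[SimulationResult, analysis.ImpedanceProfile]:
    """Sub-threshold ZAP protocol and its impedance profile."""
    grid = TimeGrid.from_duration(sweep_duration, dt)
    I = stimuli.zap_current(grid, amplitude, 0.0, f_hi, sweep_duration)
    result = simulate(params, I, SimulationOptions(dt=dt))
    profile = analysis.impedance_profile(result.voltage, I, grid, f_lo=0.0, f_hi=f_hi,
                                         v_th=params.V_th)
    return result, profile


def gain_vs_period(
    params: ModelParams | None = None,
    periods: tuple = (2000.0, 4000.0, 8000.0, 16000.0),
    offset: float = 3.0,
    amplitude: float = 0.5,
    n_cycles: int = 5,
    n_discard_cycles: int = 1,
    dt: float = 0.5,
) -> list[analysis.GainPhaseResult]:
    """Firing-rate gain and phase lead across sine periods (ms).

    Default drive (3.0 ± 0.5 nA around the standard injected current) keeps
    the model supra-threshold at every phase of the oscillation; gain falls
    and phase lead shrinks as the period grows.
    """
    if params is None:
        params = table1_params(alpha=0.2)
    out = []
    for period in periods:
        grid = TimeGrid.from_duration(n_cycles * period, dt)
        sine = stimuli.SineCurrent(offset=offset, amplitude=amplitude, period=period)
        result = simulate(params, stimuli.render(sine, grid), SimulationOptions(dt=dt))
        rate = instantaneous_rate(SpikeTrain.from_result(result))
        out.append(gain_phase_at_period(rate, sine, n_discard_cycles=n_discard_cycles))
    return out


def loglog_gain_slope(results: list[analysis.GainPhaseResult]) -> float:
    """Slope of log10(gain) against log10(period) by least squares."""
    x = np.log10([r.period for r in results])
    y = np.log10([r.gain for r in results])
    return float(np.polyfit(x, y, 1)[0])


def adaptation_tau_vs_period(
    params: ModelParams | None = None,
    periods: tuple = (4000.0, 8000.0, 16000.0),
    low: float = 3.4,
    high: float = 4.0,
    n_periods: int = 4,
    dt: float = 0.5,
) -> list[dict]:
    """Square-wave drive: single-exponential adaptation time constants.

    For each period the downward transient (after each low->high switch) and
    the upward transient (after each high->low switch) of the instantaneous
    rate is fitted in every period after the first, and the fitted time
    constants are averaged across cycles (single-cycle fits are noisy because
    the rate is a reciprocal-ISI estimate).
    """
    if params is None:
        params = table1_params(alpha=0.2)
    out = []
    for period in periods:
        grid = TimeGrid.from_duration(n_periods * period, dt)
        square = stimuli.SquareCurrent(low=low, high=high, period=period, start_high=True)
        result = simulate(params, stimuli.render(square, grid), SimulationOptions(dt=dt))
        rate = instantaneous_rate(SpikeTrain.from_result(result))
        downs, ups = [], []
        for k in range(1, n_periods):
            t0 = k * period
            downs.append(fit_adaptation_tau(rate, (t0, t0 + period / 2.0), "downward"))
            ups.append(fit_adaptation_tau(rate, (t0 + period / 2.0, t0 + period), "upward"))
        out.append({
            "period": period,
            "tau_down": float(np.mean([f.tau for f in downs])),
            "tau_up": float(np.mean([f.tau for f in ups])),
            "fits_down": downs,
            "fits_up": ups,
        })
    return out


def run_cycle_train(
    params: ModelParams,
    gap: float,
    amplitude: float = 4.0,
    cycle_duration: float = 2000.0,
    n_cycles: int = 5,
    dt: float = 0.5,
) -> tuple[SimulationResult, stimuli.CycleTrain]:
    """Five supra-threshold cycles separated by a silent gap (ms)."""
    spec = stimuli.CycleTrain(amplitude=amplitude, cycle_duration=cycle_duration,
                              gap=gap, n_cycles=n_cycles)
    duration = n_cycles * cycle_duration + (n_cycles - 1) * gap
    grid = TimeGrid.from_duration(duration, dt)
    result = simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))
    return result, spec


def isis_by_cycle(train: SpikeTrain, spec: stimuli.CycleTrain) -> list[ISISeries]:
    """Per-cycle ISI series (spikes assigned to the cycle they fall in)."""
    out = []
    for onset in spec.cycle_onsets():
        sub = train.restrict(onset, onset + spec.cycle_duration)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out.append(extract_isis(sub))
    return out


def gap_recovery_ratio(params: ModelParams, gap: float, **kwargs) -> float:
    """Second-to-last-ISI ratio Cycle5/Cycle1 for one gap value."""
    result, spec = run_cycle_train(params, gap, **kwargs)
    return cycle_recovery_metric(isis_by_cycle(SpikeTrain.from_result(result), spec))


def smallest_recovered_gap(
    params: ModelParams,
    gaps: np.ndarray,
    tolerance: float = 0.05,
    **kwargs,
) -> tuple[float | None, dict]:
    """Smallest gap (ms) whose recovery ratio is within ``tolerance`` of 1.

    Returns (gap or None, {gap: ratio}) over the swept gaps.
    """
    ratios = {}
    found = None
    for gap in gaps:
        r = gap_recovery_ratio(params, float(gap), **kwargs)
        ratios[float(gap)] = r
        if found is None and abs(r - 1.0) <= tolerance:
            found = float(gap)
    return found, ratios


def first_isi_by_cycle(train: SpikeTrain, spec: stimuli.CycleTrain) -> list[float]:
    """First inter-spike interval of each cycle (nan where < 2 spikes)."""
    out = []
    for s in isis_by_cycle(train, spec):
        out.append(float(s.isis[0]) if s.n else float("nan"))
    return out


def pause_vs_pulse_amplitude(
    params: ModelParams | None = None,
    amplitudes: tuple = (1.0, 2.0, 4.0, 6.0, 9.0),
    baseline: float = 4.0,
    pulse_onset: float = 20_000.0,
    pulse_duration: float = 2000.0,
    tail: float = 4000.0,
    dt: float = 0.5,
) -> dict:
    """Memory-induced pause after a strong pulse riding on a supra-threshold baseline.

    The long lead-in lets spiking establish on the baseline before the pulse
    (at alpha = 0.1 first-spike latencies run to many seconds).  Returns
    {pulse_amplitude: pause_ms}; pauses grow with amplitude and saturate
    because the firing rate during the pulse is bounded by the refractory
    period.
    """
    if params is None:
        params = experiment_matched_params(alpha=0.1)
    out = {}
    duration = pulse_onset + pulse_duration + tail
    grid = TimeGrid.from_duration(duration, dt)
    for amp in amplitudes:
        spec = stimuli.PulseOnBaseline(baseline=baseline, pulse_amplitude=amp,
                                       pulse_onset=pulse_onset, pulse_duration=pulse_duration)
        result = simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))
        res = pause_after_pulse(SpikeTrain.from_result(result), spec.pulse_end)
        out[float(amp)] = res.pause
    return out


def run_variance_switching(
    params: ModelParams | None = None,
    mean: float = 5.0,
    sigmas: tuple = (1.0, 4.0, 2.0, 1.0, 2.0, 1.0, 4.0, 2.0),
    epoch_duration: float = 4000.0,
    tau_filter: float = 2.0,
    seed: int = 0,
    dt: float = 0.5,
) -> SimulationResult:
    """Noisy current whose standard deviation switches between epochs."""
    if params is None:
        params = experiment_matched_params(alpha=0.2)
    schedule = tuple((epoch_duration, s) for s in sigmas)
    grid = TimeGrid.from_duration(epoch_duration * len(sigmas), dt)
    spec = stimuli.NoisyCurrent(mean=mean, tau_filter=tau_filter, seed=seed,
                                variance_schedule=schedule)
    return simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))


def calibrate_current_for_rate(
    params: ModelParams,
    target_rate: float = 14.0,
    duration: float = 10_000.0,
    epoch: tuple = (5000.0, 10_000.0),
    dt: float = 0.5,
    I_lo: float = 0.1,
    I_hi: float = 20.0,
    n_iter: int = 14,
) -> float:
    """Constant current giving approximately ``target_rate`` spikes/s.

    Bisection on the (monotone) rate-vs-current curve measured in the
    analysis epoch of a noise-free simulation.
    """

    def rate_at(I: float) -> float:
        result = run_step(params, amplitude=I, duration=duration, dt=dt)
        return mean_rate(SpikeTrain.from_result(result), *epoch)

    lo, hi = I_lo, I_hi
    if rate_at(hi) < target_rate:
        raise ValueError("upper current bound does not reach the target rate")
    for _ in range(n_iter):
        mid = 0.5 * (lo + hi)
        if rate_at(mid) < target_rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def reliability_vs_alpha(
    alphas: tuple = (1.0, 0.6, 0.2),
    n_trials: int = 20,
    sigma: float = 0.03,
    tau_filter: float = 2.0,
    target_rate: float = 14.0,
    duration: float = 10_000.0,
    epoch: tuple = (5000.0, 10_000.0),
    smoothing_sigma: float = 3.0,
    dt: float = 0.5,
    seed: int = 0,
    base_params: ModelParams | None = None,
) -> dict:
    """Spike-time reliability of noisy-input ensembles at matched mean rate.

    For each exponent the constant drive is first calibrated so the noise-free
    model fires near ``target_rate`` in the analysis epoch; ``n_trials``
    independent noise realizations are then simulated and the pairwise
    correlation reliability computed on the epoch.
    Returns {alpha: {'R': ..., 'I': ..., 'rate': ...}}.
    """
    if base_params is None:
        base_params = table1_params()
    grid = TimeGrid.from_duration(duration, dt)
    out = {}
    for ia, alpha in enumerate(alphas):
        params = base_params.with_alpha(alpha)
        I0 = calibrate_current_for_rate(params, target_rate, duration, epoch, dt)
        trains = []
        rates = []
        for trial in range(n_trials):
            spec = stimuli.NoisyCurrent(mean=I0, sigma=sigma, tau_filter=tau_filter,
                                        seed=seed + 1000 * ia + trial)
            result = simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))
            train = SpikeTrain.from_result(result)
            trains.append(train)
            rates.append(mean_rate(train, *epoch))
        rel = reliability(trains, smoothing_sigma=smoothing_sigma, epoch=epoch)
        out[float(alpha)] = {"R": rel.R, "I": I0, "rate": float(np.mean(rates))}
    return out


@dataclass(frozen=True)
class MemoryResetComparison:
    """Spike trains of the analytic-reset, L1-reset and full-memory models."""

    analytic_spikes: np.ndarray
    reset_spikes: np.ndarray
    full_spikes: np.ndarray


def memory_reset_comparison(
    params: ModelParams,
    amplitude: float,
    duration: float = 2000.0,
    dt: float = 0.1,
) -> MemoryResetComparison:
    """Run the three model variants under identical constant current."""
    ana = simulate_analytic_reset(params, amplitude, duration, dt)
    reset = run_step(params, amplitude, duration, dt, memory_mode="reset_on_spike")
    full = run_step(params, amplitude, duration, dt, memory_mode="full")
    return MemoryResetComparison(
        analytic_spikes=ana.spike_times,
        reset_spikes=reset.spike_times,
        full_spikes=full.spike_times,
    )
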