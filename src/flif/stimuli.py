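"""Declarative injected-current protocols rendered onto a time grid.

Every stimulus is a pure function of (spec, grid, seed): rendering the same
spec on the same grid always yields the same sample sequence, and stochastic
variants are reproducible from their integer seed.  Durations that are not
multiples of dt are rounded down to the nearest sample (a warning is logged).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .params import TimeGrid

__all__ = [
    "StimulusSpec",
    "StepCurrent",
    "PrePostCurrent",
    "ZapCurrent",
    "SineCurrent",
    "SquareCurrent",
    "NoisyCurrent",
    "EmbeddedSignalCurrent",
    "CycleTrain",
    "PulseOnBaseline",
    "render",
    "zap_current",
    "alpha_filter",
    "noisy_current",
    "spec_from_dict",
]

log = logging.getLogger(__name__)


def _n_samples_for(duration: float, dt: float) -> int:
    n = duration / dt
    n_floor = int(math.floor(n + 1e-9))
    if abs(n - round(n)) > 1e-9:
        log.warning("duration %.6g ms is not a multiple of dt=%.6g ms; rounding down", duration, dt)
    return n_floor


@dataclass(frozen=True)
class StimulusSpec:
    """Base class for declarative current protocols (amplitudes in nA, times in ms)."""

    variant = "base"

    def render(self, grid: TimeGrid) -> np.ndarray:
        raise NotImplementedError

    def to_dict(self) -> dict:
        d = asdict(self)
        d["variant"] = self.variant
        return d


@dataclass(frozen=True)
class StepCurrent(StimulusSpec):
    """Piecewise-constant step: ``baseline`` outside [onset, onset+duration), ``amplitude`` inside.

    ``duration=None`` extends the step to the end of the grid."""

    amplitude: float
    onset: float = 0.0
    duration: float | None = None
    baseline: float = 0.0
    variant = "step"

    def render(self, grid: TimeGrid) -> np.ndarray:
        I = np.full(grid.n_samples, self.baseline)
        i0 = _n_samples_for(self.onset, grid.dt)
        i1 = grid.n_samples if self.duration is None else i0 + _n_samples_for(self.duration, grid.dt)
        I[i0:i1] = self.amplitude
        return I


@dataclass(frozen=True)
class PrePostCurrent(StimulusSpec):
    """Conditioning epoch (hyper- or depolarizing) followed by a test epoch."""

    pre_amplitude: float
    pre_duration: float
    post_amplitude: float
    variant = "pre_post"

    def render(self, grid: TimeGrid) -> np.ndarray:
        i0 = _n_samples_for(self.pre_duration, grid.dt)
        I = np.full(grid.n_samples, self.post_amplitude)
        I[:i0] = self.pre_amplitude
        return I


@dataclass(frozen=True)
class ZapCurrent(StimulusSpec):
    """Frequency-swept sinusoid (ZAP): instantaneous frequency follows a
    logistic (sigmoidal) function of time from f_lo to f_hi over the sweep.

    The phase is the running integral of the instantaneous frequency, so the
    waveform has no phase jumps.  ``steepness`` is the normalized logistic
    rate; the default puts the endpoints within 1% of f_lo/f_hi.
    """

    amplitude: float
    f_lo: float = 0.0
    f_hi: float = 100.0
    sweep_duration: float = 10_000.0
    offset: float = 0.0
    steepness: float = 2.0 * math.log(99.0)
    variant = "zap"

    def __post_init__(self) -> None:
        if self.f_lo < 0 or self.f_hi < 0:
            raise ValueError("frequencies must be non-negative")
        if self.f_lo > self.f_hi:
            raise ValueError("f_lo must not exceed f_hi")
        if self.sweep_duration <= 0:
            raise ValueError("sweep_duration must be positive")

    def instantaneous_frequency(self, t_ms: np.ndarray) -> np.ndarray:
        if self.f_hi == self.f_lo:
            return np.full_like(np.asarray(t_ms, dtype=float), self.f_hi)
        x = self.steepness * (np.minimum(t_ms, self.sweep_duration) / self.sweep_duration - 0.5)
        return self.f_lo + (self.f_hi - self.f_lo) / (1.0 + np.exp(-x))

    def render(self, grid: TimeGrid) -> np.ndarray:
        t = grid.times
        f_hz = self.instantaneous_frequency(t)
        phase = 2.0 * math.pi * cumulative_trapezoid(f_hz, t / 1000.0, initial=0.0)
        return self.offset + self.amplitude * np.sin(phase)


@dataclass(frozen=True)
class SineCurrent(StimulusSpec):
    """Constant-frequency sinusoid: offset + amplitude*sin(2*pi*t/period)."""

    offset: float
    amplitude: float
    period: float  # ms
    variant = "sine"

    def render(self, grid: TimeGrid) -> np.ndarray:
        return self.offset + self.amplitude * np.sin(2.0 * math.pi * grid.times / self.period)


@dataclass(frozen=True)
class SquareCurrent(StimulusSpec):
    """Alternating square wave between ``low`` and ``high``, half-period each."""

    low: float
    high: float
    period: float  # ms
    start_high: bool = False
    variant = "square"

    def render(self, grid: TimeGrid) -> np.ndarray:
        phase = np.mod(grid.times, self.period) / self.period
        high_half = phase < 0.5 if self.start_high else phase >= 0.5
        return np.where(high_half, self.high, self.low)


@dataclass(frozen=True)
class NoisyCurrent(StimulusSpec):
    """Alpha-filtered Gaussian noise around a constant mean.

    White Gaussian samples (per-grid-sample, zero mean) are scaled per epoch
    by ``variance_schedule`` — a list of (duration_ms, sigma_nA) pairs tiling
    the grid — or by the single ``sigma``, filtered with the causal alpha
    kernel (t/tau**2)*exp(-t/tau), and added to ``mean``.
    """

    mean: float
    sigma: float = 0.0
    tau_filter: float = 2.0
    seed: int = 0
    variance_schedule: tuple = field(default=())
    variant = "noisy"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")

    def render(self, grid: TimeGrid) -> np.ndarray:
        rng = np.random.default_rng(self.seed)
        white = rng.standard_normal(grid.n_samples)
        if self.variance_schedule:
            sig = np.empty(grid.n_samples)
            i = 0
            for duration, s in self.variance_schedule:
                n = _n_samples_for(duration, grid.dt)
                sig[i : i + n] = s
                i += n
            if i < grid.n_samples - 1:
                raise ValueError("variance schedule does not cover the grid")
            if i < grid.n_samples:
                sig[i:] = self.variance_schedule[-1][1]  # closing fence sample
        else:
            sig = self.sigma
        noise = white * sig
        if np.any(np.asarray(sig) > 0):
            noise = alpha_filter(noise, self.tau_filter, grid)
        return self.mean + noise

    def to_dict(self) -> dict:
        d = super().to_dict()
        d["variance_schedule"] = [list(p) for p in self.variance_schedule]
        return d


@dataclass(frozen=True)
class EmbeddedSignalCurrent(StimulusSpec):
    """Frozen noisy signal embedded in trial-varying intrinsic noise.

    The embedded component (std ``sigma_embedded``, seed ``embedded_seed``) is
    identical across trials; the intrinsic component (std ``sigma``, seed
    ``seed``) varies trial to trial.  Both are alpha-filtered.
    """

    mean: float
    sigma: float
    sigma_embedded: float
    tau_filter: float = 2.0
    seed: int = 0
    embedded_seed: int = 12345
    variant = "embedded"

    def render(self, grid: TimeGrid) -> np.ndarray:
        intrinsic = NoisyCurrent(0.0, self.sigma, self.tau_filter, self.seed).render(grid)
        embedded = NoisyCurrent(0.0, self.sigma_embedded, self.tau_filter, self.embedded_seed).render(grid)
        return self.mean + intrinsic + embedded


@dataclass(frozen=True)
class CycleTrain(StimulusSpec):
    """n_cycles supra-threshold steps of ``amplitude`` and ``cycle_duration``,
    separated by ``gap`` at ``baseline`` (the five-cycle adaptation protocol)."""

    amplitude: float
    cycle_duration: float
    gap: float
    n_cycles: int = 5
    baseline: float = 0.0
    variant = "cycles"

    def cycle_onsets(self) -> np.ndarray:
        return np.arange(self.n_cycles) * (self.cycle_duration + self.gap)

    def render(self, grid: TimeGrid) -> np.ndarray:
        I = np.full(grid.n_samples, self.baseline)
        for onset in self.cycle_onsets():
            i0 = _n_samples_for(onset, grid.dt)
            i1 = i0 + _n_samples_for(self.cycle_duration, grid.dt)
            I[i0:i1] = self.amplitude
        return I


@dataclass(frozen=True)
class PulseOnBaseline(StimulusSpec):
    """Square pulse of extra current riding on a constant supra-threshold baseline."""

    baseline: float
    pulse_amplitude: float
    pulse_onset: float
    pulse_duration: float
    variant = "pulse"

    def render(self, grid: TimeGrid) -> np.ndarray:
        I = np.full(grid.n_samples, self.baseline)
        i0 = _n_samples_for(self.pulse_onset, grid.dt)
        i1 = i0 + _n_samples_for(self.pulse_duration, grid.dt)
        I[i0:i1] = self.baseline + self.pulse_amplitude
        return I

    @property
    def pulse_end(self) -> float:
        return self.pulse_onset + self.pulse_duration


_VARIANTS = {
    cls.variant: cls
    for cls in (
        StepCurrent,
        PrePostCurrent,
        ZapCurrent,
        SineCurrent,
        SquareCurrent,
        NoisyCurrent,
        EmbeddedSignalCurrent,
        CycleTrain,
        PulseOnBaseline,
    )
}


def spec_from_dict(d: dict) -> StimulusSpec:
    """Rebuild a stimulus spec from its serialized dictionary form."""
    d = dict(d)
    variant = d.pop("variant")
    if variant not in _VARIANTS:
        raise ValueError(f"unknown stimulus variant {variant!r}")
    if variant == "noisy" and "variance_schedule" in d:
        d["variance_schedule"] = tuple(tuple(p) for p in d["variance_schedule"])
    return _VARIANTS[variant](**d)


def render(spec: StimulusSpec, grid: TimeGrid) -> np.ndarray:
    """Render a stimulus spec to a current sample sequence (nA) on the grid."""
    I = spec.render(grid)
    if I.shape != (grid.n_samples,):
        raise ValueError("rendered stimulus does not match the grid length")
    if not np.all(np.isfinite(I)):
        raise FloatingPointError("rendered stimulus contains non-finite samples")
    return I


def zap_current(grid: TimeGrid, amplitude: float, f_lo: float = 0.0, f_hi: float = 100.0,
                sweep_duration: float = 10_000.0) -> np.ndarray:
    """ZAP current samples; see :class:`ZapCurrent`."""
    return ZapCurrent(amplitude=amplitude, f_lo=f_lo, f_hi=f_hi,
                      sweep_duration=sweep_duration).render(grid)


def alpha_filter(signal: np.ndarray, tau: float, grid: TimeGrid) -> np.ndarray:
    """Causal convolution with the normalized alpha kernel (t/tau**2)*exp(-t/tau).

    The discrete kernel is renormalized to unit sum so a constant input maps to
    a constant output of the same mean after the transient.  Output has the
    same length as the input; the kernel peaks at t = tau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    signal = np.asarray(signal, dtype=np.float64)
    t = np.arange(0.0, 10.0 * tau + grid.dt, grid.dt)
    kernel = (t / tau**2) * np.exp(-t / tau)
    s = kernel.sum()
    if s <= 0:
        raise ValueError("degenerate alpha kernel; tau too small for the grid step")
    kernel /= s
    return np.convolve(signal, kernel)[: signal.size]


def noisy_current(grid: TimeGrid, mean: float, sigma: float, tau_filter: float,
                  seed: int, variance_schedule=None) -> np.ndarray:
    """Alpha-filtered Gaussian noise current; see :class:`NoisyCurrent`."""
    sched = tuple(tuple(p) for p in variance_schedule) if variance_schedule else ()
    return NoisyCurrent(mean=mean, sigma=sigma, tau_filter=tau_filter, seed=seed,
                        variance_schedule=sched).render(grid)
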