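"""Quantification of simulated traces: spike statistics, adaptation fits,
impedance and phase, firing-rate gain, spike-time reliability, pause and
gap-recovery metrics.

All operators are pure functions of their inputs.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d, uniform_filter1d
from scipy.optimize import curve_fit

from .params import TimeGrid
from .stimuli import SineCurrent

__all__ = [
    "SpikeTrain",
    "ISISeries",
    "RateSeries",
    "ImpedanceProfile",
    "GainPhaseResult",
    "AdaptationFit",
    "ReliabilityResult",
    "PowerLawFit",
    "PauseResult",
    "extract_isis",
    "first_spike_latency",
    "instantaneous_rate",
    "mean_rate",
    "impedance_profile",
    "gain_phase_at_period",
    "fit_adaptation_tau",
    "isi_powerlaw_fit",
    "reliability",
    "pause_after_pulse",
    "cycle_recovery_metric",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times (ms) on their originating grid."""

    times: np.ndarray
    grid: TimeGrid

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", t)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("spike times must be strictly increasing")
        if t.size and (t[0] < 0 or t[-1] > self.grid.duration + 1e-9):
            raise ValueError("spike times must lie within the grid span")

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @classmethod
    def from_result(cls, result) -> "SpikeTrain":
        return cls(times=result.spike_times, grid=result.grid)

    def restrict(self, t0: float, t1: float) -> "SpikeTrain":
        m = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(times=self.times[m], grid=self.grid)


@dataclass(frozen=True)
class ISISeries:
    """Ordered inter-spike intervals (ms) with the index of each interval."""

    isis: np.ndarray
    index: np.ndarray

    @property
    def n(self) -> int:
        return int(self.isis.size)


@dataclass(frozen=True)
class RateSeries:
    """Instantaneous firing rate (spikes/s) at ISI midpoints."""

    times: np.ndarray
    rates: np.ndarray

    @property
    def first_interval_rate(self) -> float:
        """Rate computed from the first inter-spike interval."""
        if self.rates.size == 0:
            return float("nan")
        return float(self.rates[0])


def extract_isis(train: SpikeTrain) -> ISISeries:
    """Consecutive spike-time differences; empty (with a warning) for < 2 spikes."""
    if train.n_spikes < 2:
        warnings.warn("fewer than 2 spikes; returning empty ISI series", stacklevel=2)
        return ISISeries(isis=np.empty(0), index=np.empty(0, dtype=int))
    isis = np.diff(train.times)
    return ISISeries(isis=isis, index=np.arange(isis.size))


def first_spike_latency(train: SpikeTrain, stimulus_onset: float = 0.0) -> float | None:
    """Time from stimulus onset to the first subsequent spike; None if no spike."""
    after = train.times[train.times >= stimulus_onset]
    if after.size == 0:
        return None
    return float(after[0] - stimulus_onset)


def instantaneous_rate(train: SpikeTrain) -> RateSeries:
    """1000/ISI (spikes/s) assigned to each interval's midpoint."""
    series = extract_isis(train)
    if series.n == 0:
        return RateSeries(times=np.empty(0), rates=np.empty(0))
    mids = 0.5 * (train.times[1:] + train.times[:-1])
    return RateSeries(times=mids, rates=1000.0 / series.isis)


def mean_rate(train: SpikeTrain, window_start: float, window_end: float) -> float:
    """Spike count in [window_start, window_end) divided by the window length (spikes/s)."""
    if window_end <= window_start:
        raise ValueError("empty analysis window")
    n = int(np.count_nonzero((train.times >= window_start) & (train.times < window_end)))
    return 1000.0 * n / (window_end - window_start)


@dataclass(frozen=True)
class ImpedanceProfile:
    """Sub-threshold membrane impedance Z(f) = FFT(V)/FFT(I) on the swept band."""

    frequencies: np.ndarray  # Hz
    magnitude: np.ndarray  # MOhm (mV / nA)
    phase_deg: np.ndarray  # negative = voltage lags current
    resistance: np.ndarray  # Re Z, MOhm
    reactance: np.ndarray  # Im Z, MOhm


def impedance_profile(
    voltage: np.ndarray,
    current: np.ndarray,
    grid: TimeGrid,
    f_lo: float = 0.0,
    f_hi: float = 100.0,
    v_th: float | None = None,
    smooth_hz: float | None = 1.0,
) -> ImpedanceProfile:
    """Impedance magnitude and phase from one FFT of the whole (sub-threshold) epoch.

    Both signals are mean-subtracted; Z is evaluated on frequencies within
    [f_lo, f_hi] (the ZAP band), excluding DC.  ``smooth_hz`` applies a boxcar
    of that width to the magnitude (None disables).  If ``v_th`` is given and
    the voltage reaches it, the epoch contains spikes and the computation is
    refused: impedance is a sub-threshold quantity.
    """
    voltage = np.asarray(voltage, dtype=np.float64)
    current = np.asarray(current, dtype=np.float64)
    if voltage.shape != current.shape:
        raise ValueError("voltage and current must have equal length")
    if v_th is not None and np.any(voltage >= v_th):
        raise ValueError("spiking detected in epoch; impedance is defined sub-threshold only")

    n = voltage.size
    dt_s = grid.dt / 1000.0
    freqs = np.fft.rfftfreq(n, dt_s)
    Z = np.fft.rfft(voltage - voltage.mean()) / np.fft.rfft(current - current.mean())

    band = (freqs > max(f_lo, freqs[1] * 0.5)) & (freqs <= f_hi)
    freqs, Z = freqs[band], Z[band]
    mag = np.abs(Z)
    if smooth_hz:
        df = freqs[1] - freqs[0] if freqs.size > 1 else 1.0
        width = max(int(round(smooth_hz / df)), 1)
        if width > 1:
            mag = uniform_filter1d(mag, size=width, mode="nearest")
    phase = np.degrees(np.angle(Z))
    return ImpedanceProfile(
        frequencies=freqs,
        magnitude=mag,
        phase_deg=phase,
        resistance=Z.real,
        reactance=Z.imag,
    )


@dataclass(frozen=True)
class GainPhaseResult:
    """Sine fit of the instantaneous rate at a known stimulus period."""

    period: float  # ms
    gain: float  # (spikes/s) / nA
    phase_lead_deg: float  # positive = rate leads current
    rate_amplitude: float  # spikes/s
    rate_offset: float  # spikes/s
    residual: float  # RMS of the fit residuals


def gain_phase_at_period(
    rate: RateSeries,
    stimulus: SineCurrent,
    n_discard_cycles: int = 1,
    detrend: str | None = "log",
) -> GainPhaseResult:
    """Least-squares sine fit of the instantaneous rate at the stimulus period.

    Fits r(t) = r0 [+ c*log(t)] + a*sin(2*pi*t/P) + b*cos(2*pi*t/P) over the
    rate samples after discarding the first ``n_discard_cycles`` cycles; the
    gain is the fitted rate amplitude divided by the current amplitude, and
    the phase lead is the fitted rate phase relative to the (zero-phase)
    stimulus sine.  ``detrend='log'`` (default) absorbs the slow power-law
    adaptation drift of the mean rate into a logarithmic baseline term so it
    does not alias into the oscillation amplitude; ``detrend=None`` fits the
    plain sine.
    """
    P = stimulus.period
    t0 = n_discard_cycles * P
    m = rate.times >= t0
    t, r = rate.times[m], rate.rates[m]
    if t.size < 6 or (t[-1] - t[0]) < 2.5 * P:
        raise ValueError("need at least 3 analyzable cycles with several spikes per cycle")
    w = 2.0 * math.pi / P
    cols = [np.ones_like(t)]
    if detrend == "log":
        cols.append(np.log(t))
    elif detrend is not None:
        raise ValueError(f"unknown detrend mode {detrend!r}")
    cols += [np.sin(w * t), np.cos(w * t)]
    X = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(X, r, rcond=None)
    r0, a, b = coef[0], coef[-2], coef[-1]
    amp = math.hypot(a, b)
    phase = math.degrees(math.atan2(b, a))  # r = r0 + amp*sin(wt + phase)
    resid = float(np.sqrt(np.mean((X @ coef - r) ** 2)))
    return GainPhaseResult(
        period=P,
        gain=amp / abs(stimulus.amplitude),
        phase_lead_deg=phase,
        rate_amplitude=amp,
        rate_offset=float(r0),
        residual=resid,
    )


@dataclass(frozen=True)
class AdaptationFit:
    """Single-exponential fit r(t) = r_inf + (r_0 - r_inf)*exp(-(t-t0)/tau)."""

    direction: str  # 'upward' or 'downward'
    tau: float  # ms
    r0: float
    r_inf: float
    window: tuple
    residual: float


def fit_adaptation_tau(
    rate: RateSeries,
    window: tuple,
    direction: str,
) -> AdaptationFit:
    """Fit a single exponential to an upward or downward rate-adaptation transient.

    ``window`` is the (start, end) time interval (ms) containing the transient,
    typically one half-period of a square-wave drive.
    """
    if direction not in ("upward", "downward"):
        raise ValueError("direction must be 'upward' or 'downward'")
    t0, t1 = window
    m = (rate.times >= t0) & (rate.times < t1)
    t, r = rate.times[m] - t0, rate.rates[m]
    if t.size < 5:
        raise ValueError("too few rate samples in the adaptation window")

    r_inf0 = float(np.mean(r[-max(t.size // 4, 2) :]))
    r00 = float(r[0])
    tau0 = max((t1 - t0) / 5.0, 1.0)

    def model(tt, r_inf, dr, tau):
        return r_inf + dr * np.exp(-tt / tau)

    try:
        popt, _ = curve_fit(
            model, t, r, p0=[r_inf0, r00 - r_inf0, tau0],
            bounds=([0.0, -np.inf, 1e-6], [np.inf, np.inf, np.inf]), maxfev=20_000,
        )
    except RuntimeError as exc:  # pragma: no cover - diagnostic path
        raise RuntimeError(f"adaptation fit did not converge: {exc}") from exc
    r_inf, dr, tau = popt
    resid = float(np.sqrt(np.mean((model(t, *popt) - r) ** 2)))
    return AdaptationFit(
        direction=direction, tau=float(tau), r0=float(r_inf + dr),
        r_inf=float(r_inf), window=(t0, t1), residual=resid,
    )


@dataclass(frozen=True)
class PowerLawFit:
    """Log-log linear fit of an ISI histogram, with an exponential-model comparison."""

    slope: float
    intercept: float
    r_squared: float
    r_squared_exponential: float
    bin_centers: np.ndarray = field(repr=False)
    counts: np.ndarray = field(repr=False)


def _linfit_r2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ coef
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(coef[0]), float(coef[1]), r2


def isi_powerlaw_fit(isis: ISISeries, bins_per_decade: int = 10) -> PowerLawFit:
    """Regression of log10(count) on log10(ISI) over logarithmically binned ISIs.

    Also fits log10(count) against linear ISI (an exponential distribution
    model) on the same occupied bins, so the two hypotheses can be compared by
    their r-squared.
    """
    if isis.n < 20:
        raise ValueError("need at least 20 ISIs for a histogram fit")
    x = isis.isis
    lo, hi = x.min(), x.max()
    if not hi > lo:
        raise ValueError("degenerate ISI distribution: all intervals identical")
    edges = np.logspace(math.log10(lo), math.log10(hi), int(math.ceil(math.log10(hi / lo) * bins_per_decade)) + 2)
    counts, edges = np.histogram(x, bins=edges)
    centers = np.sqrt(edges[:-1] * edges[1:])
    occ = counts > 0
    if occ.sum() < 2:
        raise ValueError("fewer than 2 occupied histogram bins")
    logc = np.log10(counts[occ].astype(float))
    slope, intercept, r2 = _linfit_r2(np.log10(centers[occ]), logc)
    _, _, r2_exp = _linfit_r2(centers[occ], logc)
    return PowerLawFit(
        slope=slope, intercept=intercept, r_squared=r2,
        r_squared_exponential=r2_exp, bin_centers=centers[occ], counts=counts[occ],
    )


@dataclass(frozen=True)
class ReliabilityResult:
    """Pairwise correlation-based spike-time reliability, in [0, 1]."""

    n_trials: int
    smoothing_sigma: float  # ms
    R: float


def reliability(
    trains: list[SpikeTrain],
    smoothing_sigma: float = 3.0,
    epoch: tuple | None = None,
) -> ReliabilityResult:
    """Correlation-based reliability of an ensemble of spike trains.

    Each train is binarized on its grid, smoothed with a Gaussian kernel of
    standard deviation ``smoothing_sigma`` (ms), and the mean pairwise cosine
    similarity is returned:

        R = 2/(N(N-1)) * sum_{i<j} (s_i . s_j)/(|s_i| |s_j|).

    ``epoch`` restricts the analysis to a (start, end) window; trains with no
    spikes in the epoch are excluded with a warning.
    """
    if len(trains) < 2:
        raise ValueError("reliability needs at least 2 trains")
    grid = trains[0].grid
    if any(tr.grid.dt != grid.dt or tr.grid.n_steps != grid.n_steps for tr in trains):
        raise ValueError("all trains must share a common grid")
    t0, t1 = epoch if epoch is not None else (0.0, grid.duration)
    sigma_samples = smoothing_sigma / grid.dt

    vecs = []
    for tr in trains:
        times = tr.times[(tr.times >= t0) & (tr.times < t1)]
        if times.size == 0:
            warnings.warn("excluding a train with no spikes in the epoch", stacklevel=2)
            continue
        s = np.zeros(grid.n_samples)
        idx = np.clip(np.round(times / grid.dt).astype(int), 0, grid.n_samples - 1)
        np.add.at(s, idx, 1.0)
        vecs.append(gaussian_filter1d(s, sigma_samples))
    if len(vecs) < 2:
        raise ValueError("fewer than 2 trains with spikes in the epoch")

    N = len(vecs)
    total = 0.0
    for i in range(N):
        for j in range(i + 1, N):
            total += float(np.dot(vecs[i], vecs[j]) / (np.linalg.norm(vecs[i]) * np.linalg.norm(vecs[j])))
    R = 2.0 * total / (N * (N - 1))
    return ReliabilityResult(n_trials=N, smoothing_sigma=smoothing_sigma, R=R)


@dataclass(frozen=True)
class PauseResult:
    """Silent period after a pulse; censored=True if no spike followed."""

    pause: float  # ms
    censored: bool


def pause_after_pulse(train: SpikeTrain, pulse_end: float) -> PauseResult:
    """Time from pulse offset to the next spike.

    Requires spiking activity before the pulse end.  If no spike follows
    within the simulation, the span to the end of the grid is returned with a
    censoring flag.
    """
    if not np.any(train.times < pulse_end):
        raise ValueError("no spiking activity before the pulse end")
    # the sample at the offset itself is still driven by the last in-pulse
    # current value (explicit scheme), so the silent period starts one step later
    after = train.times[train.times > pulse_end + train.grid.dt + 1e-9]
    if after.size == 0:
        return PauseResult(pause=float(train.grid.duration - pulse_end), censored=True)
    return PauseResult(pause=float(after[0] - pulse_end), censored=False)


def cycle_recovery_metric(isis_by_cycle: list[ISISeries]) -> float:
    """Ratio of the second-to-last ISI of Cycle 5 to that of Cycle 1.

    Quantifies how completely the spike adaptation pattern recovers across a
    stimulation gap; identical cycles give 1.
    """
    if len(isis_by_cycle) < 5:
        raise ValueError("need at least 5 cycles")
    for i, s in enumerate((isis_by_cycle[0], isis_by_cycle[4])):
        if s.n < 3:
            raise ValueError(f"cycle {1 if i == 0 else 5} has fewer than 3 ISIs")
    return float(isis_by_cycle[4].isis[-2] / isis_by_cycle[0].isis[-2])
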