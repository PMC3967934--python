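"""Fitting the fractional exponent to a reference curve.

The exponent alpha is estimated by simulating a stimulation protocol across a
grid of candidate exponents, computing a scalar-valued curve for each
(ISI-vs-index, rate-vs-time, or gain-vs-period), and minimizing the mean
squared error against the reference.  A 95% confidence interval is assigned
by walking alpha away from the minimum in both directions until the MSE has
changed by more than 5% (relative to the minimum MSE; configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import SimulationOptions, simulate
from .params import ModelParams, TimeGrid
from .stimuli import SineCurrent, StimulusSpec, render
from .analysis import (
    SpikeTrain,
    extract_isis,
    gain_phase_at_period,
    instantaneous_rate,
)

__all__ = ["FitResult", "curve_mse", "fit_alpha", "default_alpha_grid", "coarse_alpha_grid"]


def default_alpha_grid() -> np.ndarray:
    """Fine default grid, 0.05..1.0 in steps of 0.01."""
    return np.round(np.arange(0.05, 1.0 + 1e-9, 0.01), 10)


def coarse_alpha_grid() -> np.ndarray:
    """Coarse exploratory grid, 0.5..1.0 in steps of 0.1."""
    return np.round(np.arange(0.5, 1.0 + 1e-9, 0.1), 10)


@dataclass(frozen=True)
class FitResult:
    """Best-fit exponent with its 5%-change confidence interval."""

    alpha_hat: float
    ci_lower: float
    ci_upper: float
    mse: float
    alpha_grid: np.ndarray = field(repr=False)
    mse_grid: np.ndarray = field(repr=False)
    metric: str = ""


def curve_mse(model_curve: np.ndarray, reference_curve: np.ndarray) -> float:
    """Mean of squared differences between two curves of equal length."""
    a = np.asarray(model_curve, dtype=np.float64)
    b = np.asarray(reference_curve, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"curve length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean((a - b) ** 2))


def _metric_curve(
    params: ModelParams,
    spec: StimulusSpec,
    metric: str,
    options: SimulationOptions,
    duration: float,
    ref_x: np.ndarray,
    skip_isis: int,
) -> np.ndarray | None:
    """Simulate the protocol and evaluate the named metric on the reference support."""
    grid = TimeGrid.from_duration(duration, options.dt)
    result = simulate(params, render(spec, grid), options)
    train = SpikeTrain.from_result(result)
    if metric == "isi_vs_index":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # sparse-spiking grid points are skipped below
            isis = extract_isis(train).isis
        if skip_isis:
            isis = isis[skip_isis:]
        if isis.size < ref_x.size:
            return None
        return isis[: ref_x.size]
    if metric == "rate_vs_time":
        rate = instantaneous_rate(train)
        if rate.times.size < 4:
            return None
        return np.interp(ref_x, rate.times, rate.rates)
    if metric == "gain_vs_period":
        if not isinstance(spec, SineCurrent):
            raise ValueError("gain_vs_period requires a sine stimulus template")
        gains = []
        for period in ref_x:
            g = TimeGrid.from_duration(4.0 * period, options.dt)
            sine = SineCurrent(offset=spec.offset, amplitude=spec.amplitude, period=float(period))
            res = simulate(params, render(sine, g), options)
            try:
                gp = gain_phase_at_period(instantaneous_rate(SpikeTrain.from_result(res)), sine)
            except ValueError:
                return None
            gains.append(gp.gain)
        return np.asarray(gains)
    raise ValueError(f"unknown metric {metric!r}")


def fit_alpha(
    reference_curve: np.ndarray,
    params: ModelParams,
    spec: StimulusSpec,
    metric: str = "isi_vs_index",
    alpha_grid: np.ndarray | None = None,
    options: SimulationOptions | None = None,
    duration: float | None = None,
    skip_isis: int = 0,
    ci_change: float = 0.05,
) -> FitResult:
    """Grid search for the fractional exponent minimizing the curve MSE.

    Parameters
    ----------
    reference_curve : (n, 2) array
        Two-column table (index-or-time, value).  For ``isi_vs_index`` the
        first column is the ISI index; for ``rate_vs_time`` it is time in ms;
        for ``gain_vs_period`` it is the stimulus period in ms.
    params : ModelParams
        Membrane parameters; its ``alpha`` field is overridden by the grid.
    spec : StimulusSpec
        Stimulation protocol (template for gain_vs_period).
    skip_isis : int
        Leading ISIs dropped from the model curve before comparison (the
        truncation option used when matching experimental ISI curves).
    ci_change : float
        Relative MSE change defining the 95% confidence bounds (default 5%).
    """
    ref = np.asarray(reference_curve, dtype=np.float64)
    if ref.ndim != 2 or ref.shape[1] != 2 or ref.shape[0] < 3:
        raise ValueError("reference curve must be an (n>=3, 2) table")
    ref_x, ref_y = ref[:, 0], ref[:, 1]

    if alpha_grid is None:
        alpha_grid = default_alpha_grid()
    alpha_grid = np.asarray(alpha_grid, dtype=np.float64)
    if options is None:
        options = SimulationOptions()
    if duration is None:
        duration = float(ref_x[-1] * 1.5) if metric == "rate_vs_time" else 2000.0

    mse_grid = np.full(alpha_grid.size, np.inf)
    for i, a in enumerate(alpha_grid):
        curve = _metric_curve(params.with_alpha(float(a)), spec, metric, options,
                              duration, ref_x, skip_isis)
        if curve is not None:
            mse_grid[i] = curve_mse(curve, ref_y)
    if not np.any(np.isfinite(mse_grid)):
        raise RuntimeError("no candidate exponent produced an analyzable simulation")

    i_min = int(np.nanargmin(np.where(np.isfinite(mse_grid), mse_grid, np.nan)))
    mse_min = float(mse_grid[i_min])
    threshold = mse_min * (1.0 + ci_change) if mse_min > 0 else ci_change

    i_lo = i_min
    while i_lo > 0 and np.isfinite(mse_grid[i_lo - 1]) and mse_grid[i_lo - 1] <= threshold:
        i_lo -= 1
    i_hi = i_min
    while i_hi < alpha_grid.size - 1 and np.isfinite(mse_grid[i_hi + 1]) and mse_grid[i_hi + 1] <= threshold:
        i_hi += 1

    return FitResult(
        alpha_hat=float(alpha_grid[i_min]),
        ci_lower=float(alpha_grid[i_lo]),
        ci_upper=float(alpha_grid[i_hi]),
        mse=mse_min,
        alpha_grid=alpha_grid,
        mse_grid=mse_grid,
        metric=metric,
    )
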