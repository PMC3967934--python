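"""Synthetic reference-curve generator.

Emits small CSV fixtures produced by the model itself at known exponents —
ISI-vs-index curves (clean and noisy), rate-vs-time curves under square-wave
drive, and raster ensembles for reliability analysis — each with a JSON
sidecar recording the generating parameters.  These stand in for digitized
experimental curves in closed-loop tests of the exponent-fitting machinery.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import protocols, stimuli
from .analysis import SpikeTrain, extract_isis, instantaneous_rate
from .core import SimulationOptions, simulate
from .io import write_json
from .params import TimeGrid, experiment_matched_params, table1_params

__all__ = ["generate_fixtures"]

FLOAT_FMT = "%.9g"


def _isi_fixture(out_dir: Path, alpha: float, seed: int, noise_frac: float,
                 amplitude: float, duration: float, dt: float) -> None:
    params = table1_params(alpha=alpha)
    result = protocols.run_step(params, amplitude=amplitude, duration=duration, dt=dt)
    isis = extract_isis(SpikeTrain.from_result(result)).isis
    rng = np.random.default_rng(seed)
    values = isis * (1.0 + noise_frac * rng.standard_normal(isis.size)) if noise_frac else isis
    tag = f"alpha{alpha:g}" + ("_noisy" if noise_frac else "")
    path = out_dir / f"isi_vs_index_{tag}.csv"
    pd.DataFrame({"isi_index": np.arange(isis.size), "isi_ms": values}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    write_json(
        {"alpha": alpha, "amplitude_nA": amplitude, "duration_ms": duration, "dt_ms": dt,
         "noise_frac": noise_frac, "seed": seed, "metric": "isi_vs_index",
         "preset": "table1"},
        path.with_suffix(".json"),
    )


def _rate_fixture(out_dir: Path, alpha: float, dt: float) -> None:
    params = experiment_matched_params(alpha=alpha)
    period = 16_000.0
    grid = TimeGrid.from_duration(2 * period, dt)
    spec = stimuli.SquareCurrent(low=3.4, high=4.0, period=period, start_high=True)
    result = simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))
    rate = instantaneous_rate(SpikeTrain.from_result(result))
    path = out_dir / f"rate_vs_time_square16s_alpha{alpha:g}.csv"
    pd.DataFrame({"time_ms": rate.times, "rate_sps": rate.rates}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    write_json(
        {"alpha": alpha, "low_nA": 3.4, "high_nA": 4.0, "period_ms": period, "dt_ms": dt,
         "metric": "rate_vs_time", "preset": "experiment_matched"},
        path.with_suffix(".json"),
    )


def _raster_fixture(out_dir: Path, alpha: float, seed: int, n_trials: int, dt: float) -> None:
    params = table1_params(alpha=alpha)
    I0 = protocols.calibrate_current_for_rate(params, dt=dt)
    grid = TimeGrid.from_duration(10_000.0, dt)
    rows = []
    for trial in range(n_trials):
        spec = stimuli.NoisyCurrent(mean=I0, sigma=0.03, tau_filter=2.0, seed=seed + trial)
        result = simulate(params, stimuli.render(spec, grid), SimulationOptions(dt=dt))
        for t in result.spike_times:
            rows.append((trial, t))
    path = out_dir / f"raster_alpha{alpha:g}.csv"
    pd.DataFrame(rows, columns=["trial", "spike_time_ms"]).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )
    write_json(
        {"alpha": alpha, "mean_nA": I0, "sigma_nA": 0.03, "tau_filter_ms": 2.0,
         "n_trials": n_trials, "duration_ms": 10_000.0, "dt_ms": dt, "seed": seed,
         "metric": "raster", "preset": "table1"},
        path.with_suffix(".json"),
    )


def generate_fixtures(
    seed: int,
    out_dir: str | Path,
    isi_alphas: tuple = (0.15, 0.2, 0.4),
    raster_alphas: tuple = (0.2, 1.0),
    n_trials: int = 10,
    dt: float = 0.5,
) -> list[Path]:
    """Write all fixture files under ``out_dir``; reproducible from ``seed``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for alpha in isi_alphas:
        _isi_fixture(out, alpha, seed, 0.0, amplitude=4.0, duration=2000.0, dt=dt)
        _isi_fixture(out, alpha, seed, 0.05, amplitude=4.0, duration=2000.0, dt=dt)
    _rate_fixture(out, 0.2, dt=dt)
    for alpha in raster_alphas:
        _raster_fixture(out, alpha, seed, n_trials, dt=dt)
    return sorted(out.glob("*.csv"))
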