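"""Configuration and serialization: YAML run configs, trace/spike CSV, JSON results.

Floating-point CSV output uses 9 significant digits so determinism checks on
re-runs are byte-meaningful.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import TRACE_COLUMNS, SimulationOptions, SimulationResult
from .params import ModelParams
from .stimuli import StimulusSpec, spec_from_dict

__all__ = [
    "RunConfig",
    "write_trace_csv",
    "read_trace_csv",
    "write_spikes_csv",
    "read_spikes_csv",
    "write_spikes_json",
    "write_json",
    "read_reference_curve",
]

FLOAT_FMT = "%.9g"


@dataclass(frozen=True)
class RunConfig:
    """One simulation run: parameters, stimulus, options, analyses, outputs."""

    params: ModelParams
    stimulus: StimulusSpec
    options: SimulationOptions = field(default_factory=SimulationOptions)
    duration: float = 1000.0  # ms
    analyses: tuple = ()  # subset of {'isis', 'rate', 'impedance'}
    out_dir: str = "."
    seed: int = 0
    label: str = "run"

    def to_dict(self) -> dict:
        return {
            "model": self.params.to_dict(),
            "stimulus": self.stimulus.to_dict(),
            "options": {"memory_mode": self.options.memory_mode, "dt": self.options.dt},
            "run": {
                "duration": self.duration,
                "analyses": list(self.analyses),
                "out_dir": self.out_dir,
                "seed": self.seed,
                "label": self.label,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        run = d.get("run", {})
        return cls(
            params=ModelParams.from_dict(d["model"]),
            stimulus=spec_from_dict(d["stimulus"]),
            options=SimulationOptions(**d.get("options", {})),
            duration=float(run.get("duration", 1000.0)),
            analyses=tuple(run.get("analyses", ())),
            out_dir=run.get("out_dir", "."),
            seed=int(run.get("seed", 0)),
            label=run.get("label", "run"),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def write_trace_csv(result: SimulationResult, path: str | Path) -> None:
    """Trace CSV with columns time_ms,current_nA,voltage_mV,memory_trace_mV,markov_term_mV."""
    result.to_frame().to_csv(path, index=False, float_format=FLOAT_FMT)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trace CSV missing columns: {sorted(missing)}")
    return df


def write_spikes_csv(spike_times: np.ndarray, path: str | Path) -> None:
    pd.DataFrame({"spike_time_ms": np.asarray(spike_times)}).to_csv(
        path, index=False, float_format=FLOAT_FMT
    )


def read_spikes_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path)["spike_time_ms"].to_numpy()


def write_spikes_json(spike_times: np.ndarray, path: str | Path) -> None:
    Path(path).write_text(json.dumps([float(f"{t:.9g}") for t in spike_times]))


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_json(record: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(record), indent=2, sort_keys=True))


def read_reference_curve(path: str | Path) -> np.ndarray:
    """Two-column (index_or_time, value) reference table as an (n, 2) array."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("reference curve must have two columns")
    return df.iloc[:, :2].to_numpy(dtype=float)
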