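"""Model parameters and the simulation time grid.

The internal unit system is fixed to {mV, ms, nA, nF, µS}, which is
self-consistent for the membrane equation (nF·mV/ms = nA) and keeps the
fractional coefficient dt**alpha dimensionally unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np

__all__ = ["ModelParams", "TimeGrid", "table1_params", "experiment_matched_params"]


@dataclass(frozen=True)
class ModelParams:
    """Membrane constants of the (fractional) leaky integrate-and-fire neuron.

    Attributes
    ----------
    C_m : float
        Membrane capacitance (nF).
    g_L : float
        Leak conductance (µS).  Note the unit: 25 nS is stored as 0.025.
    V_L : float
        Leak reversal potential (mV).
    V_reset : float
        Post-spike reset potential (mV).
    V_0 : float
        Initial membrane potential (mV).
    V_th : float
        Spike threshold (mV); threshold crossing is inclusive (V >= V_th).
    tau_ref : float
        Absolute refractory period (ms) during which the voltage is clamped
        to ``V_reset``.
    alpha : float
        Order of the fractional derivative, in (0, 1].  ``alpha = 1``
        recovers the classical (Markovian) leaky integrate-and-fire model.
    """

    C_m: float = 0.5
    g_L: float = 0.025
    V_L: float = -70.0
    V_reset: float = -70.0
    V_0: float = -70.0
    V_th: float = -50.0
    tau_ref: float = 5.0
    alpha: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ValueError(f"alpha must lie in (0, 1], got {self.alpha}")
        if self.C_m <= 0.0:
            raise ValueError(f"C_m must be positive, got {self.C_m}")
        if self.g_L <= 0.0:
            raise ValueError(f"g_L must be positive, got {self.g_L}")
        if self.tau_ref < 0.0:
            raise ValueError(f"tau_ref must be non-negative, got {self.tau_ref}")
        if not self.V_reset < self.V_th:
            raise ValueError("V_reset must be below V_th")
        if self.V_0 > self.V_th:
            raise ValueError("V_0 must not exceed V_th")

    @property
    def tau_m(self) -> float:
        """Passive membrane time constant C_m/g_L (ms); always derived."""
        return self.C_m / self.g_L

    @property
    def rheobase(self) -> float:
        """Classical threshold current g_L·(V_th − V_L) (nA)."""
        return self.g_L * (self.V_th - self.V_L)

    def with_alpha(self, alpha: float) -> "ModelParams":
        """Copy of the parameter set with a different fractional exponent."""
        return replace(self, alpha=alpha)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_m"] = self.tau_m
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        d = {k: v for k, v in d.items() if k != "tau_m"}
        return cls(**d)


@dataclass(frozen=True)
class TimeGrid:
    """Uniform time grid t_k = k·dt, k = 0..n_steps (ms)."""

    dt: float
    n_steps: int

    def __post_init__(self) -> None:
        if self.dt <= 0.0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")

    @property
    def n_samples(self) -> int:
        """Number of samples, n_steps + 1 (t_0 = 0 included)."""
        return self.n_steps + 1

    @property
    def duration(self) -> float:
        """Total span n_steps·dt (ms)."""
        return self.n_steps * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    @classmethod
    def from_duration(cls, duration: float, dt: float) -> "TimeGrid":
        """Grid covering ``duration`` ms; duration is rounded to a multiple of dt."""
        n = int(round(duration / dt))
        return cls(dt=dt, n_steps=max(n, 1))


def table1_params(alpha: float = 1.0) -> ModelParams:
    """Standard parameter set: C_m=0.5 nF, g_L=25 nS, V_L=V_reset=V_0=−70 mV,
    V_th=−50 mV, tau_ref=5 ms (tau_m = 20 ms)."""
    return ModelParams(alpha=alpha)


def experiment_matched_params(alpha: float = 0.2) -> ModelParams:
    """Slow-membrane preset used for the oscillatory/adaptation protocols:
    g_L lowered to 10 nS (tau_m = 50 ms) and tau_ref shortened to 1 ms."""
    return ModelParams(g_L=0.010, tau_ref=1.0, alpha=alpha)
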