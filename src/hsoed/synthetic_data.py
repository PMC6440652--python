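"""Noisy sampled GFP measurements — the in-silico stand-in for wet-lab data.

The measurement model is additive Gaussian noise on the deterministic ODE
output at the chosen time points,

    x_M(t_i) = x(p, t_i) + ε(t_i),     ε(t_i) ~ N(0, σ_i²),

with a heteroscedastic σ_i = max(sigma_rel·|y_i|, sigma_floor).  The default
levels (5% relative, 1e-3 μM floor) are repository choices; the noise
magnitudes used in the original study are not known.  Negative noisy values
are kept by default so the Gaussian assumption holds exactly for
goodness-of-fit calibration; a clipping option exists for realism.

The σ_i recorded in the :class:`MeasurementSet` are the single source of
truth reused downstream for wRSSE weighting and FIM construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circuits import CircuitModel, InputSignal, simulate_trajectory

__all__ = ["MeasurementSet", "generate_measurements"]


@dataclass
class MeasurementSet:
    """Sampled observable values with per-point standard deviations."""

    times: np.ndarray
    values: np.ndarray
    stds: np.ndarray
    observable: str = "G"
    input_descriptor: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if not (self.times.shape == self.values.shape == self.stds.shape):
            raise ValueError("times, values and stds must have equal shapes")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.stds < 0):
            raise ValueError("stds must be non-negative")

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time": self.times, "value": self.values, "std": self.stds}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, observable: str = "G") -> "MeasurementSet":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            times=df["time"].to_numpy(),
            values=df["value"].to_numpy(),
            stds=df["std"].to_numpy(),
            observable=observable,
        )


def generate_measurements(
    model: CircuitModel,
    input_signal: InputSignal,
    n_m: int,
    t_f: float = 3000.0,
    sigma_rel: float = 0.05,
    sigma_floor: float = 1e-3,
    seed: int | None = None,
    true_params: np.ndarray | None = None,
    clip_negative: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> MeasurementSet:
    """Simulate the circuit and sample its GFP output at ``n_m`` evenly
    spaced times in [0, t_f] with additive Gaussian noise.

    ``sigma_rel = sigma_floor = 0`` gives an exactly noiseless set.  The same
    seed always reproduces the same draw.
    """
    if n_m < 2:
        raise ValueError("need at least 2 measurement times")
    if sigma_rel < 0 or sigma_floor < 0:
        raise ValueError("noise parameters must be non-negative")
    times = np.linspace(0.0, t_f, n_m)
    traj = simulate_trajectory(model, input_signal, times, params=true_params,
                               rtol=rtol, atol=atol)
    y = traj.observable(model.observable)
    sig = np.maximum(sigma_rel * np.abs(y), sigma_floor)
    if np.all(sig == 0):
        values = y.copy()
    else:
        rng = np.random.default_rng(seed)
        values = y + rng.normal(0.0, 1.0, n_m) * sig
        if clip_negative:
            values = np.maximum(values, 0.0)
    return MeasurementSet(
        times=times,
        values=values,
        stds=sig,
        observable=model.state_names[model.observable],
        input_descriptor=f"{input_signal.kind}({input_signal.magnitude} μM)",
        seed=seed,
    )
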