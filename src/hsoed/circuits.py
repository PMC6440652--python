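"""Benchmark synthetic gene-circuit ODE models and input-signal generators.

Two doxorubicin (DOX)-inducible reporter circuits are modelled deterministically
in units of minutes and micromolar:

* **unbuffered** — DOX drives production of the transcription factor SKN7m
  (``X_m``), which binds the synthetic promoter P_TR-SSRE (complex ``C_m``) and
  activates GFP (``G``) through a Hill function.  3 states, 9 kinetic
  parameters.
* **buffered** — DOX drives a STAT5-HKRR fusion (``Z``) whose phosphate is
  relayed through YPD1 (``W``) to SKN7 (``X``); doubly phosphorylated SKN7
  (``X**``) activates GFP.  A load-insulating driver module with retroactivity
  constants ``r1, r2``.  10 states, 23 kinetic parameters.

The "true" kinetic values are not dictated by the biology alone; the defaults
shipped here (:data:`UNBUFFERED_DEFAULTS`, :data:`BUFFERED_DEFAULTS`) are
repository values chosen for realistic response timescales (hundreds of
minutes) and practical identifiability of the binding parameters, and every
function accepts overrides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "InputSignal",
    "make_input",
    "CircuitModel",
    "Trajectory",
    "make_circuit",
    "unbuffered_rhs",
    "buffered_rhs",
    "simulate_trajectory",
    "initial_state",
    "UNBUFFERED_KINETIC",
    "UNBUFFERED_FIXED",
    "BUFFERED_KINETIC",
    "BUFFERED_FIXED",
    "UNBUFFERED_DEFAULTS",
    "BUFFERED_DEFAULTS",
    "SimulationError",
]


class SimulationError(RuntimeError):
    """Raised when the ODE solver fails or the state becomes non-finite."""


# ---------------------------------------------------------------------------
# Input signals
# ---------------------------------------------------------------------------

_INPUT_KINDS = ("step", "double_step", "square", "constant")


@dataclass(frozen=True)
class InputSignal:
    """Deterministic scalar DOX input u(t) in μM.

    ``step``         0 before *onset*, *magnitude* after.
    ``double_step``  step to *magnitude* at *onset*, then to *second_magnitude*
                     at *second_onset*.
    ``square``       50% duty cycle, high phase first: *magnitude* on
                     [onset + kT, onset + kT + T/2), 0 otherwise.
    ``constant``     *magnitude* for all t ≥ 0.
    """

    kind: str
    magnitude: float
    onset: float = 0.0
    period: float | None = None
    second_onset: float | None = None
    second_magnitude: float | None = None

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        if self.kind == "constant":
            u = np.full_like(t, self.magnitude)
        elif self.kind == "step":
            u = np.where(t >= self.onset, self.magnitude, 0.0)
        elif self.kind == "double_step":
            u = np.where(t >= self.onset, self.magnitude, 0.0)
            u = np.where(t >= self.second_onset, self.second_magnitude, u)
        elif self.kind == "square":
            tau = t - self.onset
            phase = np.mod(tau, self.period)
            high = (tau >= 0) & (phase < self.period / 2.0)
            u = np.where(high, self.magnitude, 0.0)
        else:  # pragma: no cover - guarded by make_input
            raise ValueError(f"unknown input kind {self.kind!r}")
        return u if u.ndim else float(u)

    def switch_times(self, t_end: float) -> np.ndarray:
        """Discontinuity locations in (0, t_end), used to split integration."""
        pts: list[float] = []
        if self.kind in ("step", "double_step") and 0 < self.onset < t_end:
            pts.append(self.onset)
        if self.kind == "double_step" and 0 < self.second_onset < t_end:
            pts.append(self.second_onset)
        if self.kind == "square":
            half = self.period / 2.0
            k = self.onset
            while k < t_end:
                if k > 0:
                    pts.append(k)
                if 0 < k + half < t_end:
                    pts.append(k + half)
                k += self.period
        return np.unique(np.asarray(pts, dtype=float))


def make_input(
    kind: str,
    magnitude: float,
    onset: float = 0.0,
    period: float | None = None,
    second_onset: float | None = None,
    second_magnitude: float | None = None,
) -> InputSignal:
    """Validate and build an :class:`InputSignal`."""
    if kind not in _INPUT_KINDS:
        raise ValueError(f"kind must be one of {_INPUT_KINDS}, got {kind!r}")
    if magnitude < 0:
        raise ValueError("magnitude must be non-negative")
    if kind == "square":
        if period is None or period <= 0:
            raise ValueError("square input requires period > 0")
    if kind == "double_step":
        if second_onset is None:
            raise ValueError("double_step input requires second_onset")
        if second_magnitude is None:
            second_magnitude = magnitude
        if second_magnitude < 0:
            raise ValueError("second_magnitude must be non-negative")
    return InputSignal(
        kind=kind,
        magnitude=float(magnitude),
        onset=float(onset),
        period=None if period is None else float(period),
        second_onset=None if second_onset is None else float(second_onset),
        second_magnitude=None if second_magnitude is None else float(second_magnitude),
    )


# ---------------------------------------------------------------------------
# Parameter bookkeeping
# ---------------------------------------------------------------------------

UNBUFFERED_STATES = ("X_m", "C_m", "G")
#: 9 kinetic parameters of the unbuffered circuit (p_T included: the Hill and
#: half-saturation constants are the only quantities held fixed).
UNBUFFERED_KINETIC = (
    "k_m", "delta_M", "k_on", "k_off", "delta_c",
    "p_T", "k_sgfp", "k_g", "delta_G",
)
UNBUFFERED_FIXED = ("n1", "n2", "K_dox", "K_gfp")

BUFFERED_STATES = (
    "Z", "Zs", "W_T", "Ws", "X_T", "Xs", "Xss", "Cs", "Css", "G",
)
#: 23 kinetic parameters of the buffered circuit.
BUFFERED_KINETIC = (
    "k_m", "delta_Z", "k1", "k2", "k_p", "k_pp", "k_w", "delta_W",
    "k3", "k4", "k5", "k6", "k7", "k_x", "delta_X", "r1", "r2",
    "k_on", "k_off", "delta_C", "k_sgfp", "k_g", "delta_G",
)
BUFFERED_FIXED = ("n1", "n2", "K_dox", "K_gfp", "p_T")

# Repository default values (min, μM units).  Degradation/dilution rates of
# order 0.01/min give protein half-lives of ~70 min; binding constants for
# k1..k4 respect the 1-50 μM⁻¹ range and the k1 ≥ k3, k2 ≥ k4 ordering.
UNBUFFERED_DEFAULTS = {
    "k_m": 0.05,       # μM/min, max DOX-activated SKN7m production
    "delta_M": 0.01,   # 1/min
    "k_on": 0.02,      # 1/(μM·min); slow binding keeps k_on/k_off separately
    "k_off": 0.01,     # 1/min       identifiable (no quasi-equilibrium ridge)
    "delta_c": 0.005,  # 1/min
    "p_T": 5.0,        # μM total promoter binding sites
    "k_sgfp": 0.001,  # μM/min basal GFP synthesis
    "k_g": 0.2,       # μM/min max activated GFP synthesis
    "delta_G": 0.01,  # 1/min
    # fixed constants
    "n1": 2.0,
    "n2": 2.0,
    "K_dox": 10.0,
    "K_gfp": 10.0,
}

BUFFERED_DEFAULTS = {
    "k_m": 0.05,
    "delta_Z": 0.01,
    "k1": 10.0,
    "k2": 10.0,
    "k_p": 0.1,
    "k_pp": 0.1,
    "k_w": 0.02,
    "delta_W": 0.01,
    "k3": 5.0,
    "k4": 5.0,
    "k5": 0.05,
    "k6": 0.05,
    "k7": 0.01,
    "k_x": 0.02,
    "delta_X": 0.01,
    "r1": 0.001,
    "r2": 0.001,
    "k_on": 2.0,
    "k_off": 1.0,
    "delta_C": 0.01,
    "k_sgfp": 0.001,
    "k_g": 0.2,
    "delta_G": 0.01,
    # fixed constants
    "n1": 2.0,
    "n2": 2.0,
    "K_dox": 10.0,
    "K_gfp": 1.0,
    "p_T": 0.1,
}


@dataclass(frozen=True)
class CircuitModel:
    """One benchmark circuit: names, parameter values and RHS dispatch."""

    name: str
    state_names: tuple[str, ...]
    kinetic_names: tuple[str, ...]
    fixed_names: tuple[str, ...]
    kinetic_params: np.ndarray
    fixed_constants: np.ndarray
    load_factor: float = 1.0
    observable: int = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "observable", len(self.state_names) - 1)
        kp = np.asarray(self.kinetic_params, dtype=float)
        if kp.shape != (len(self.kinetic_names),):
            raise ValueError("kinetic parameter vector has wrong length")
        if not np.all(np.isfinite(kp)) or np.any(kp < 0):
            raise ValueError("kinetic parameters must be finite and non-negative")
        if self.name == "buffered":
            p = self.params_dict()
            for k in ("k1", "k2", "k3", "k4"):
                if not (1.0 <= p[k] <= 50.0):
                    raise ValueError(f"{k}={p[k]} outside the allowed [1, 50] μM⁻¹ range")
            if p["k1"] < p["k3"] or p["k2"] < p["k4"]:
                raise ValueError("phosphotransfer ordering requires k1 ≥ k3 and k2 ≥ k4")
        if self.load_factor <= 0:
            raise ValueError("load_factor must be positive")

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    @property
    def n_params(self) -> int:
        return len(self.kinetic_names)

    def params_dict(self) -> dict[str, float]:
        d = dict(zip(self.kinetic_names, self.kinetic_params))
        d.update(zip(self.fixed_names, self.fixed_constants))
        return d

    def with_params(self, values: np.ndarray) -> "CircuitModel":
        """Copy of the model with the kinetic vector replaced."""
        return replace(self, kinetic_params=np.asarray(values, dtype=float))

    def rhs(self, t, state, u_func):
        if self.name == "unbuffered":
            return unbuffered_rhs(state, t, self.kinetic_params,
                                  self.fixed_constants, u_func, self.load_factor)
        return buffered_rhs(state, t, self.kinetic_params,
                            self.fixed_constants, u_func, self.load_factor)


def make_circuit(
    name: str,
    params: dict[str, float] | None = None,
    load_factor: float = 1.0,
) -> CircuitModel:
    """Build a circuit model, merging ``params`` overrides into the defaults.

    ``load_factor`` ∈ {1, 2, 3} realizes the model+0x/+1x/+2x genetic-load
    conditions by multiplying the total promoter-site pool p_T.
    """
    if name == "unbuffered":
        defaults, states = UNBUFFERED_DEFAULTS, UNBUFFERED_STATES
        kin, fix = UNBUFFERED_KINETIC, UNBUFFERED_FIXED
    elif name == "buffered":
        defaults, states = BUFFERED_DEFAULTS, BUFFERED_STATES
        kin, fix = BUFFERED_KINETIC, BUFFERED_FIXED
    else:
        raise ValueError("name must be 'unbuffered' or 'buffered'")
    merged = dict(defaults)
    if params:
        unknown = set(params) - set(merged)
        if unknown:
            raise ValueError(f"unknown parameter(s): {sorted(unknown)}")
        merged.update(params)
    return CircuitModel(
        name=name,
        state_names=states,
        kinetic_names=kin,
        fixed_names=fix,
        kinetic_params=np.array([merged[k] for k in kin], dtype=float),
        fixed_constants=np.array([merged[k] for k in fix], dtype=float),
        load_factor=float(load_factor),
    )


# ---------------------------------------------------------------------------
# Right-hand sides
# ---------------------------------------------------------------------------

def _check_rhs_inputs(state, n, params):
    state = np.asarray(state, dtype=float)
    if state.shape != (n,):
        raise ValueError(f"state must have length {n}")
    if not np.all(np.isfinite(state)):
        raise ValueError("state contains non-finite values")
    params = np.asarray(params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(params < 0):
        raise ValueError("kinetic parameters must be finite and non-negative")
    return state, params


def unbuffered_rhs(state, t, kinetic_params, fixed_constants, u_func,
                   load_factor: float = 1.0):
    """Time derivatives (dX_m, dC_m, dG) of the unbuffered circuit."""
    state, kp = _check_rhs_inputs(state, 3, kinetic_params)
    X_m, C_m, G = state
    k_m, delta_M, k_on, k_off, delta_c, p_T, k_sgfp, k_g, delta_G = kp
    n1, n2, K_dox, K_gfp = np.asarray(fixed_constants, dtype=float)
    p_T = p_T * load_factor

    dox = float(u_func(t)) if callable(u_func) else float(u_func)
    act = k_m * dox ** n1 / (K_dox + dox ** n1)
    hill_g = X_m ** n2 / (K_gfp + X_m ** n2)

    dX = act - delta_M * X_m - k_on * X_m * (p_T - C_m) + k_off * C_m + delta_c * C_m
    dC = k_on * X_m * (p_T - C_m) - k_off * C_m - delta_c * C_m
    dG = k_sgfp + k_g * hill_g - delta_G * G
    return np.array([dX, dC, dG])


def buffered_rhs(state, t, kinetic_params, fixed_constants, u_func,
                 load_factor: float = 1.0):
    """Time derivatives of the 10-state buffered circuit.

    State order: Z, Z*, W_T, W*, X_T, X*, X**, C*, C**, G.
    """
    state, kp = _check_rhs_inputs(state, 10, kinetic_params)
    (Z, Zs, W_T, Ws, X_T, Xs, Xss, Cs, Css, G) = state
    (k_m, delta_Z, k1, k2, k_p, k_pp, k_w, delta_W,
     k3, k4, k5, k6, k7, k_x, delta_X, r1, r2,
     k_on, k_off, delta_C, k_sgfp, k_g, delta_G) = kp
    n1, n2, K_dox, K_gfp, p_T = np.asarray(fixed_constants, dtype=float)
    p_T = p_T * load_factor

    dox = float(u_func(t)) if callable(u_func) else float(u_func)
    act = k_m * dox ** n1 / (K_dox + dox ** n1)
    X_free = X_T - Xs - Xss - Cs - Css   # unphosphorylated, unbound SKN7
    W_free = W_T - Ws                    # unphosphorylated YPD1
    hill_g = Xss ** n2 / (K_gfp + Xss ** n2)

    dZ = act - delta_Z * Z - k2 * Ws * Z + k1 * Zs * W_free - k_p * Z + k_pp * Zs
    dZs = -k1 * Zs * W_free + k2 * Ws * Z + k_p * Z - k_pp * Zs - delta_Z * Zs
    dW_T = k_w - delta_W * W_T
    dWs = (k1 * Zs * W_free - k2 * Ws * Z
           - k3 * X_free * Ws + k4 * Xs * W_free
           - delta_W * Ws
           - k3 * Xs * Ws + k4 * Xss * W_free
           - k7 * Ws)
    dX_T = k_x - delta_X * X_T
    dXs = (k3 * X_free * Ws - k4 * Xs * W_free - delta_X * Xs
           - k3 * Xs * Ws + k4 * Xss * W_free
           - k5 * Xs + k6 * Xss + r1)
    dXss = k3 * Xs * Ws - k4 * Xss * W_free - k6 * Xss - delta_X * Xss + r2
    dCs = k_on * Xs * (p_T - Cs - Css) - k_off * Cs - delta_C * Cs
    dCss = k_on * Xss * (p_T - Cs - Css) - k_off * Css - delta_C * Css
    dG = k_sgfp + k_g * hill_g - delta_G * G
    return np.array([dZ, dZs, dW_T, dWs, dX_T, dXs, dXss, dCs, dCss, dG])


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    """ODE solution sampled on a time grid, with the input values alongside."""

    time_grid: np.ndarray
    states: np.ndarray          # (n_t, n_states)
    input_values: np.ndarray
    state_names: tuple[str, ...]

    def observable(self, index: int) -> np.ndarray:
        return self.states[:, index]

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.states, columns=list(self.state_names))
        df.insert(0, "time", self.time_grid)
        df["input"] = self.input_values
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.17g")


def initial_state(model: CircuitModel) -> np.ndarray:
    """Documented initial conditions: all states zero, except the buffered
    total pools W_T(0)=k_w/δ_W and X_T(0)=k_x/δ_X at their unforced steady
    states (avoids a production transient unrelated to the input)."""
    x0 = np.zeros(model.n_states)
    if model.name == "buffered":
        p = model.params_dict()
        x0[2] = p["k_w"] / p["delta_W"] if p["delta_W"] > 0 else 0.0
        x0[4] = p["k_x"] / p["delta_X"] if p["delta_X"] > 0 else 0.0
    return x0


# Output states in [-_CLIP_TOL, 0) are integrator round-off and clipped to 0;
# anything more negative is left visible to the caller.
_CLIP_TOL = 1e-7


def _integrate(model, input_signal, time_grid, x0, rtol, atol, rhs=None):
    """Piecewise integration across input discontinuities.

    ``rhs(t, y)`` defaults to the model's own right-hand side; the sensitivity
    module passes the augmented system through the same machinery.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if rhs is None:
        def rhs(t, y):
            return model.rhs(t, y, input_signal)
    t_end = float(time_grid[-1])
    breaks = input_signal.switch_times(t_end)
    edges = np.concatenate(([time_grid[0]], breaks, [t_end]))
    edges = np.unique(edges)

    out = np.empty((len(time_grid), len(x0)))
    out[0] = x0
    y = np.asarray(x0, dtype=float)
    for a, b in zip(edges[:-1], edges[1:]):
        mask = (time_grid > a) & (time_grid <= b)
        t_eval = np.unique(np.concatenate((time_grid[mask], [b])))
        sol = solve_ivp(rhs, (a, b), y, method="LSODA", t_eval=t_eval,
                        rtol=rtol, atol=atol)
        if not sol.success:
            raise SimulationError(
                f"ODE solver failed near t={sol.t[-1] if len(sol.t) else a:.3f} min: "
                f"{sol.message}")
        if not np.all(np.isfinite(sol.y)):
            raise SimulationError(f"non-finite state encountered in [{a}, {b}] min")
        interp = {t: sol.y[:, i] for i, t in enumerate(sol.t)}
        for idx in np.nonzero(mask)[0]:
            out[idx] = interp[time_grid[idx]]
        y = sol.y[:, -1]
    return out


def simulate_trajectory(
    model: CircuitModel,
    input_signal: InputSignal,
    time_grid,
    params: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Solve the circuit ODEs on ``time_grid`` (minutes, starting at 0).

    The integration is split at the input's discontinuities so step and
    square-wave edges are resolved exactly rather than smoothed over.
    """
    time_grid = np.asarray(time_grid, dtype=float)
    if time_grid.ndim != 1 or len(time_grid) < 2:
        raise ValueError("time_grid must be a 1-D array with at least 2 points")
    if time_grid[0] != 0:
        raise ValueError("time_grid must start at 0")
    if np.any(np.diff(time_grid) <= 0):
        raise ValueError("time_grid must be strictly increasing")
    if params is not None:
        model = model.with_params(params)
    x0 = initial_state(model)
    states = _integrate(model, input_signal, time_grid, x0, rtol, atol)
    states[(states < 0) & (states > -_CLIP_TOL)] = 0.0
    return Trajectory(
        time_grid=time_grid,
        states=states,
        input_values=np.asarray(input_signal(time_grid), dtype=float),
        state_names=model.state_names,
    )
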