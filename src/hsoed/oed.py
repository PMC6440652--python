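"""Two-stage nested harmony-search OED, sample-size selection and screening.

The outer loop searches the scalar DOX input level u within a feasible band
(default [1, 30] μM) to minimize cfun1, the modified-E criterion (condition
number) of the Fisher information matrix evaluated at the best available
parameter estimate.  For every candidate u the inner loop estimates the free
kinetic parameters by minimizing cfun2, the σ-weighted residual sum of
squares against measurements taken under that input.  Measurements for a
candidate u are regenerated from a seed derived deterministically from
(master seed, u), so the outer objective is a deterministic function of u and
memory comparisons are not noise-dominated.

Sample-size selection sweeps a grid of time-point counts n_m and minimizes
J(n_m) = RSS + λ(n_m − n_p)/n_m; the dose-response screen maps steady-state
GFP and circuit gain across input levels to locate the responsive band.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuits import (
    CircuitModel,
    InputSignal,
    SimulationError,
    make_input,
    simulate_trajectory,
)
from .fim import FIMResult, fisher_information
from .objectives import sample_size_cost, wrsse
from .optimizers import HSConfig, hs_minimize
from .sensitivity import forward_sensitivities
from .synthetic_data import MeasurementSet, generate_measurements

__all__ = [
    "DesignSpace",
    "OEDResult",
    "inner_estimate",
    "outer_design",
    "select_sample_size",
    "dose_response",
    "derive_seed",
]


def derive_seed(master: int | None, *keys) -> int:
    """Stable sub-seed below 2³¹ derived from a master seed and extra keys."""
    text = "|".join([str(master)] + [f"{k:.9e}" if isinstance(k, float) else str(k)
                                     for k in keys])
    h = hashlib.blake2b(text.encode(), digest_size=4)
    return int.from_bytes(h.digest(), "little") % (2**31)


@dataclass
class DesignSpace:
    """Feasible experiment designs: input family, level band, duration,
    sampling grid and cost coefficient λ."""

    input_kind: str = "step"
    u_bounds: tuple[float, float] = (1.0, 30.0)   # μM, feasible input band
    u_grid: np.ndarray | None = None              # optional discrete levels
    t_f: float = 3000.0                           # min, experiment duration
    n_m: int = 50                                 # time points per experiment
    n_m_grid: tuple[int, ...] = tuple(range(10, 101, 10))
    lam: float = 0.8                              # measurement-cost coefficient
    onset: float = 0.0
    period: float | None = None                   # square inputs only

    def __post_init__(self):
        if self.u_bounds[0] >= self.u_bounds[1]:
            raise ValueError("need u_lb < u_ub")
        if self.t_f <= 0:
            raise ValueError("t_f must be positive")
        if self.u_grid is not None:
            self.u_grid = np.sort(np.asarray(self.u_grid, dtype=float))

    def make_input(self, magnitude: float) -> InputSignal:
        return make_input(self.input_kind, magnitude, onset=self.onset,
                          period=self.period)


@dataclass
class OEDResult:
    """Everything the two-stage search produced."""

    u_star: float
    p_star: np.ndarray               # full kinetic vector with fitted values
    free_names: tuple[str, ...]
    cfun1_star: float
    outer_trace: np.ndarray          # incumbent cfun1 per outer iteration
    inner_trace: np.ndarray          # cfun2 trace of the winning inner fit
    fim_at_optimum: FIMResult | None
    evaluated: dict[float, float] = field(default_factory=dict)
    n_m_star: int | None = None
    cost_curve: pd.DataFrame | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "u_star": float(self.u_star),
            "p_star": self.p_star.tolist(),
            "free_names": list(self.free_names),
            "cfun1_star": float(self.cfun1_star),
            "outer_trace": self.outer_trace.tolist(),
            "evaluated": {f"{u:.6g}": float(v) for u, v in self.evaluated.items()},
            "n_m_star": self.n_m_star,
            "seed": self.seed,
            "fim": None if self.fim_at_optimum is None
            else self.fim_at_optimum.to_dict(),
        }


def _free_indices(model: CircuitModel, free_names) -> np.ndarray:
    idx = []
    for name in free_names:
        if name not in model.kinetic_names:
            raise ValueError(f"unknown kinetic parameter {name!r}")
        idx.append(model.kinetic_names.index(name))
    return np.asarray(idx, dtype=int)


def inner_estimate(
    model: CircuitModel,
    measurements: MeasurementSet,
    input_signal: InputSignal,
    free_names,
    lb,
    ub,
    hs_config: HSConfig | None = None,
    seed: int | None = None,
    max_iter: int = 2000,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Fit the free kinetic parameters to one measurement set (cfun2 = wRSSE).

    Returns ``(p_full, trace, best_wrsse)`` where ``p_full`` is the complete
    kinetic vector with the fitted entries substituted.  Candidates whose
    simulation fails evaluate to +∞ and are discarded by the search.
    """
    idx = _free_indices(model, free_names)
    ref = np.asarray(model.kinetic_params, dtype=float)

    def objective(theta):
        p = ref.copy()
        p[idx] = theta
        try:
            traj = simulate_trajectory(model, input_signal, measurements.times,
                                       params=p, rtol=rtol, atol=atol)
        except SimulationError:
            return np.inf
        yhat = traj.observable(model.observable)
        sig = np.where(measurements.stds > 0, measurements.stds, 1.0)
        return wrsse(measurements.values, yhat, sig)

    if hs_config is None:
        # Inner-loop refinement schedule: OED-context HMCR with a high pitch
        # rate and a wide-to-fine annealed bandwidth, so the search can both
        # traverse the correlated wRSSE valley and resolve its bottom.
        hs_config = HSConfig(lb=lb, ub=ub, max_iter=max_iter, seed=seed,
                             hmcr=0.8, par=0.9, hms=10,
                             bandwidth_frac=0.2, bandwidth_final_frac=5e-5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        result = hs_minimize(objective, hs_config, incumbent=ref[idx])
    p_full = ref.copy()
    p_full[idx] = result.best_vector
    return p_full, result.trace, result.best_fitness


def _cfun1(model, design, u, free_names, lb, ub, seed, inner_max_iter,
           sigma_rel, sigma_floor, combine_wrsse, inner_hmcr, rtol, atol):
    """Evaluate one candidate input level: generate → fit → FIM criterion."""
    input_signal = design.make_input(u)
    meas_seed = derive_seed(seed, float(u))
    # data generation stays at the simulator's full accuracy; only the
    # candidate fits inside the search use the relaxed rtol/atol
    measurements = generate_measurements(
        model, input_signal, design.n_m, t_f=design.t_f,
        sigma_rel=sigma_rel, sigma_floor=sigma_floor, seed=meas_seed)
    hs_cfg = HSConfig(lb=lb, ub=ub, max_iter=inner_max_iter,
                      hmcr=inner_hmcr, par=0.9, hms=10,
                      bandwidth_frac=0.2, bandwidth_final_frac=5e-5,
                      seed=derive_seed(seed, float(u), "inner"))
    p_hat, trace, phi = inner_estimate(
        model, measurements, input_signal, free_names, lb, ub,
        hs_config=hs_cfg, rtol=rtol, atol=atol)
    idx = _free_indices(model, free_names)
    try:
        S = forward_sensitivities(model, input_signal, measurements.times,
                                  params=p_hat, rtol=rtol, atol=atol)
    except SimulationError:
        return np.inf, p_hat, trace, None
    obs = S.observable_matrix(model.observable)[:, idx]
    sig = np.where(measurements.stds > 0, measurements.stds, 1.0)
    fim_res = fisher_information(obs, sig, param_names=tuple(free_names))
    value = fim_res.criteria["modE"]
    if combine_wrsse:
        value = value + phi
    return value, p_hat, trace, fim_res


def outer_design(
    model: CircuitModel,
    design: DesignSpace,
    free_names,
    lb,
    ub,
    seed: int | None = None,
    outer_iters: int = 10,
    inner_max_iter: int = 500,
    hms: int = 15,
    u0: float | None = None,
    sigma_rel: float = 0.05,
    sigma_floor: float = 1e-3,
    combine_wrsse: bool = False,
    inner_hmcr: float = 0.8,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> OEDResult:
    """Two-stage nested search for the optimal input level u*.

    Each outer iteration re-initializes a small harmony memory of input
    levels with row 1 holding the incumbent u*, evaluates cfun1 for every
    level and keeps the incumbent only on strict improvement, so the outer
    trace is monotone non-increasing.  cfun1 values are memoized per u, which
    is sound because each u deterministically fixes its measurement seed.
    """
    rng = np.random.default_rng(derive_seed(seed, "outer"))
    u_lb, u_ub = design.u_bounds
    lb = np.atleast_1d(np.asarray(lb, dtype=float))
    ub = np.atleast_1d(np.asarray(ub, dtype=float))

    cache: dict[float, tuple] = {}

    def evaluate(u) -> tuple:
        u = float(u)
        if u not in cache:
            cache[u] = _cfun1(model, design, u, free_names, lb, ub, seed,
                              inner_max_iter, sigma_rel, sigma_floor,
                              combine_wrsse, inner_hmcr, rtol, atol)
        return cache[u]

    def random_u() -> float:
        if design.u_grid is not None:
            return float(rng.choice(design.u_grid))
        return float(u_lb + (u_ub - u_lb) * rng.random())

    if u0 is None:
        u0 = (float(np.median(design.u_grid)) if design.u_grid is not None
              else 0.5 * (u_lb + u_ub))
    best_u = float(u0)
    best_val, best_p, best_trace, best_fim = evaluate(best_u)

    outer_trace = np.empty(outer_iters)
    for it in range(outer_iters):
        memory = [best_u] + [random_u() for _ in range(hms - 1)]
        for u in memory:
            val, p_hat, trace, fim_res = evaluate(u)
            if val < best_val:  # strict improvement keeps the earlier design
                best_u, best_val = float(u), float(val)
                best_p, best_trace, best_fim = p_hat, trace, fim_res
        outer_trace[it] = best_val

    if not np.isfinite(best_val):
        raise RuntimeError("all candidate input levels were infeasible")
    return OEDResult(
        u_star=best_u,
        p_star=best_p,
        free_names=tuple(free_names),
        cfun1_star=best_val,
        outer_trace=outer_trace,
        inner_trace=np.asarray(best_trace),
        fim_at_optimum=best_fim,
        evaluated={u: v[0] for u, v in cache.items()},
        seed=seed,
    )


def screen_inputs(
    model: CircuitModel,
    design: DesignSpace,
    u_values,
    free_names,
    lb,
    ub,
    seed: int | None = None,
    inner_max_iter: int = 500,
    sigma_rel: float = 0.05,
    sigma_floor: float = 1e-3,
    inner_hmcr: float = 0.8,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> pd.DataFrame:
    """Brute-force screening: evaluate cfun1 on a fixed list of input levels
    with the same per-u measurement seeds the nested search uses.

    Ties go to the lowest input level (first index)."""
    rows = []
    for u in np.asarray(u_values, dtype=float):
        val, _, _, _ = _cfun1(model, design, float(u), free_names,
                              np.atleast_1d(np.asarray(lb, dtype=float)),
                              np.atleast_1d(np.asarray(ub, dtype=float)),
                              seed, inner_max_iter, sigma_rel, sigma_floor,
                              False, inner_hmcr, rtol, atol)
        rows.append({"u": float(u), "cfun1": float(val)})
    return pd.DataFrame(rows)


def select_sample_size(
    model: CircuitModel,
    input_signal: InputSignal,
    n_m_grid=None,
    lam: float = 0.8,
    free_names=None,
    lb=None,
    ub=None,
    true_params: np.ndarray | None = None,
    refit: bool = True,
    sigma_rel: float = 0.05,
    sigma_floor: float = 1e-3,
    seed: int | None = None,
    t_f: float = 3000.0,
    inner_max_iter: int = 500,
    weighted: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-9,
):
    """Sweep the number of measured time points and minimize J(n_m).

    For each n_m on the grid: sample evenly over [0, t_f], generate
    measurements, (optionally) re-fit the free parameters, and evaluate the
    accuracy-plus-cost objective.  Returns ``(n_m_star, cost_curve)`` with the
    first grid index winning ties.
    """
    n_p = len(free_names) if free_names is not None else model.n_params
    if n_m_grid is None:
        n_m_grid = tuple(range(10, 101, 10))
    n_m_grid = tuple(int(n) for n in n_m_grid)
    if any(n <= n_p for n in n_m_grid):
        raise ValueError(f"every n_m must exceed the number of estimated "
                         f"parameters n_p={n_p}")

    rows = []
    for n_m in n_m_grid:
        meas = generate_measurements(
            model, input_signal, n_m, t_f=t_f, sigma_rel=sigma_rel,
            sigma_floor=sigma_floor, seed=derive_seed(seed, n_m),
            true_params=true_params)
        if refit:
            if free_names is None or lb is None or ub is None:
                raise ValueError("refit=True requires free_names, lb and ub")
            cfg = HSConfig(lb=lb, ub=ub, max_iter=inner_max_iter,
                           seed=derive_seed(seed, n_m, "fit"))
            p_fit, _, _ = inner_estimate(model, meas, input_signal,
                                         free_names, lb, ub, hs_config=cfg,
                                         rtol=rtol, atol=atol)
        else:
            p_fit = (np.asarray(true_params, dtype=float)
                     if true_params is not None else model.kinetic_params)
        # final prediction at full solver accuracy, matching data generation
        traj = simulate_trajectory(model, input_signal, meas.times,
                                   params=p_fit)
        residuals = meas.values - traj.observable(model.observable)
        cost = sample_size_cost(residuals, n_m, n_p, lam,
                                sigmas=np.where(meas.stds > 0, meas.stds, 1.0),
                                weighted=weighted)
        rows.append({"n_m": n_m, "J": cost.total, "accuracy": cost.accuracy,
                     "penalty": cost.penalty})
    curve = pd.DataFrame(rows)
    n_m_star = int(curve.loc[curve["J"].idxmin(), "n_m"])  # first index on ties
    return n_m_star, curve


def dose_response(
    model: CircuitModel,
    dox_levels,
    t_f: float = 3000.0,
    params: np.ndarray | None = None,
    steady_rtol: float = 1e-3,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> pd.DataFrame:
    """Steady-state GFP and circuit gain (GFP/DOX) per constant input level.

    The gain is undefined at zero input; the zero-input baseline GFP level is
    k_sgfp/δ_G and can be read off separately.  Rows whose trajectory has not
    settled by t_f are flagged ``steady=False``.
    """
    levels = np.asarray(dox_levels, dtype=float)
    if np.any(levels <= 0):
        raise ValueError("dose levels must be positive (gain undefined at 0)")
    grid = np.linspace(0.0, t_f, 61)
    rows = []
    for u in levels:
        traj = simulate_trajectory(model, make_input("constant", u), grid,
                                   params=params, rtol=rtol, atol=atol)
        g = traj.observable(model.observable)
        scale = max(abs(g[-1]), 1e-12)
        steady = abs(g[-1] - g[-4]) <= steady_rtol * scale
        if not steady:
            warnings.warn(f"trajectory at DOX={u} μM not steady by t_f={t_f}",
                          RuntimeWarning, stacklevel=2)
        rows.append({"dox": u, "steady_gfp": g[-1], "gain": g[-1] / u,
                     "steady": steady})
    return pd.DataFrame(rows)
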