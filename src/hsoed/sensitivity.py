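"""Local parameter sensitivities s(t) = ∂x(t)/∂p for the circuit models.

The primary route integrates the forward sensitivity equations

    dS/dt = J_x(t, p0) S + J_p(t, p0),   S(0) = 0,

as one augmented ODE system alongside the states, with the Jacobians taken in
closed form from the symbolic mirror of the right-hand sides.  A central
finite-difference fallback is provided both as an alternative method and as an
independent numerical oracle.

The initial state is treated as a fixed experimental condition: S(0) ≡ 0 even
for the buffered model, whose total-pool initial values are computed from the
reference parameters but are not differentiated (the finite-difference route
holds them at their reference values accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._symbolic import jacobian_functions
from .circuits import CircuitModel, InputSignal, _integrate, initial_state

__all__ = [
    "SensitivityTensor",
    "forward_sensitivities",
    "gauss_newton_hessian",
    "column_correlation",
]


@dataclass
class SensitivityTensor:
    """∂x_i(t_k)/∂p_j on a time grid; values shape (n_t, n_states, n_params)."""

    time_grid: np.ndarray
    values: np.ndarray
    state_names: tuple[str, ...]
    param_names: tuple[str, ...]
    reference_params: np.ndarray

    def observable_matrix(self, state_index: int) -> np.ndarray:
        """Sensitivity rows of one observed state, shape (n_t, n_params)."""
        return self.values[:, state_index, :]

    def to_long_frame(self):
        """Long-format table (time, state, parameter, value) for CSV export."""
        import pandas as pd

        n_t, n_x, n_p = self.values.shape
        t = np.repeat(self.time_grid, n_x * n_p)
        s = np.tile(np.repeat(np.array(self.state_names), n_p), n_t)
        p = np.tile(np.array(self.param_names), n_t * n_x)
        return pd.DataFrame(
            {"time": t, "state": s, "parameter": p, "value": self.values.ravel()}
        )


def forward_sensitivities(
    model: CircuitModel,
    input_signal: InputSignal,
    time_grid,
    params: np.ndarray | None = None,
    method: str = "forward_ode",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    fd_rel_step: float = 1e-5,
    fd_abs_floor: float = 1e-8,
) -> SensitivityTensor:
    """Compute the full-state sensitivity tensor on ``time_grid``."""
    time_grid = np.asarray(time_grid, dtype=float)
    if params is not None:
        model = model.with_params(params)
    p0 = np.asarray(model.kinetic_params, dtype=float)
    n_x, n_p = model.n_states, model.n_params
    x0 = initial_state(model)

    if method == "forward_ode":
        fixed = model.fixed_constants
        _, jx_fn, jp_fn = jacobian_functions(model.name,
                                             float(fixed[0]), float(fixed[1]))
        load = model.load_factor

        def rhs_aug(t, y):
            x = y[:n_x]
            S = y[n_x:].reshape(n_x, n_p)
            u = float(input_signal(t))
            f = model.rhs(t, x, input_signal)
            Jx = jx_fn(x, p0, fixed, u, load)
            Jp = jp_fn(x, p0, fixed, u, load)
            dS = Jx @ S + Jp
            return np.concatenate((f, dS.ravel()))

        y0 = np.concatenate((x0, np.zeros(n_x * n_p)))
        sol = _integrate(model, input_signal, time_grid, y0, rtol, atol, rhs=rhs_aug)
        values = sol[:, n_x:].reshape(len(time_grid), n_x, n_p)
    elif method == "finite_diff":
        values = np.empty((len(time_grid), n_x, n_p))
        for j in range(n_p):
            h = max(fd_rel_step * abs(p0[j]), fd_abs_floor)
            if h == 0:  # pragma: no cover - floor is positive
                raise ValueError("finite-difference step underflow")
            hi, lo = p0.copy(), p0.copy()
            hi[j] += h
            lo[j] = max(lo[j] - h, 0.0)
            denom = hi[j] - lo[j]
            m_hi, m_lo = model.with_params(hi), model.with_params(lo)
            # x0 held at the reference-parameter value: ICs are experimental
            # conditions, not functions of the estimated parameters.
            y_hi = _integrate(m_hi, input_signal, time_grid, x0, rtol, atol)
            y_lo = _integrate(m_lo, input_signal, time_grid, x0, rtol, atol)
            values[:, :, j] = (y_hi - y_lo) / denom
    else:
        raise ValueError("method must be 'forward_ode' or 'finite_diff'")

    values[0] = 0.0
    return SensitivityTensor(
        time_grid=time_grid,
        values=values,
        state_names=model.state_names,
        param_names=model.kinetic_names,
        reference_params=p0,
    )


def gauss_newton_hessian(S, observable: int | None = None) -> np.ndarray:
    """Gauss-Newton approximation H = SᵀS of the weighted-least-squares
    Hessian, built from the sensitivity rows of the observed state(s).

    ``S`` may be a :class:`SensitivityTensor` (with ``observable`` selecting a
    state, or None for all states stacked) or a plain 2-D design matrix.
    """
    if isinstance(S, SensitivityTensor):
        if observable is None:
            A = S.values.reshape(-1, S.values.shape[-1])
        else:
            A = S.observable_matrix(observable)
    else:
        A = np.asarray(S, dtype=float)
    if A.ndim != 2 or A.size == 0:
        raise ValueError("need a nonempty 2-D sensitivity matrix")
    return A.T @ A


def column_correlation(S) -> np.ndarray:
    """Pairwise correlations between sensitivity columns.

    |corr| = 1 between two columns flags linear dependence and hence practical
    non-identifiability of the corresponding parameter pair.  Zero-variance
    columns give NaN entries (undefined), with a warning, rather than a
    silent 0.
    """
    if isinstance(S, SensitivityTensor):
        A = S.values.reshape(-1, S.values.shape[-1])
    else:
        A = np.asarray(S, dtype=float)
    if A.ndim != 2 or A.shape[0] < 2:
        raise ValueError("need at least two observation rows")
    centered = A - A.mean(axis=0)
    sd = centered.std(axis=0, ddof=1)
    zero = sd == 0
    if np.any(zero):
        warnings.warn(
            "zero-variance sensitivity column(s): correlation undefined (NaN)",
            RuntimeWarning,
            stacklevel=2,
        )
    sd_safe = np.where(zero, np.nan, sd)
    cov = centered.T @ centered / (A.shape[0] - 1)
    corr = cov / np.outer(sd_safe, sd_safe)
    np.fill_diagonal(corr, np.where(zero, np.nan, 1.0))
    return np.clip(corr, -1.0, 1.0)
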