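"""Closed-form Jacobians of the circuit right-hand sides.

The state Jacobian J_x = ∂f/∂x and parameter Jacobian J_p = ∂f/∂p needed by
the forward sensitivity equations are derived symbolically (sympy) from a
mirror of the hand-coded right-hand sides and compiled to numpy callables
once per circuit.  Keeping a separate symbolic copy also gives the test suite
an independent route to cross-check the numeric RHS.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

from .circuits import (
    BUFFERED_FIXED,
    BUFFERED_KINETIC,
    BUFFERED_STATES,
    UNBUFFERED_FIXED,
    UNBUFFERED_KINETIC,
    UNBUFFERED_STATES,
)

__all__ = ["symbolic_rhs", "jacobian_functions"]


def _symbols(names):
    return sp.symbols([n.replace("*", "s") for n in names], real=True)


def symbolic_rhs(name: str):
    """Return (state_syms, param_syms, fixed_syms, u_sym, load_sym, f_exprs)."""
    u, load = sp.symbols("u load", positive=True)
    if name == "unbuffered":
        states = _symbols(UNBUFFERED_STATES)
        params = _symbols(UNBUFFERED_KINETIC)
        fixed = _symbols(UNBUFFERED_FIXED)
        X_m, C_m, G = states
        k_m, delta_M, k_on, k_off, delta_c, p_T, k_sgfp, k_g, delta_G = params
        n1, n2, K_dox, K_gfp = fixed
        pT = p_T * load
        act = k_m * u ** n1 / (K_dox + u ** n1)
        hill = X_m ** n2 / (K_gfp + X_m ** n2)
        f = [
            act - delta_M * X_m - k_on * X_m * (pT - C_m) + k_off * C_m + delta_c * C_m,
            k_on * X_m * (pT - C_m) - k_off * C_m - delta_c * C_m,
            k_sgfp + k_g * hill - delta_G * G,
        ]
    elif name == "buffered":
        states = _symbols(BUFFERED_STATES)
        params = _symbols(BUFFERED_KINETIC)
        fixed = _symbols(BUFFERED_FIXED)
        Z, Zs, W_T, Ws, X_T, Xs, Xss, Cs, Css, G = states
        (k_m, delta_Z, k1, k2, k_p, k_pp, k_w, delta_W,
         k3, k4, k5, k6, k7, k_x, delta_X, r1, r2,
         k_on, k_off, delta_C, k_sgfp, k_g, delta_G) = params
        n1, n2, K_dox, K_gfp, p_T = fixed
        pT = p_T * load
        act = k_m * u ** n1 / (K_dox + u ** n1)
        X_free = X_T - Xs - Xss - Cs - Css
        W_free = W_T - Ws
        hill = Xss ** n2 / (K_gfp + Xss ** n2)
        f = [
            act - delta_Z * Z - k2 * Ws * Z + k1 * Zs * W_free - k_p * Z + k_pp * Zs,
            -k1 * Zs * W_free + k2 * Ws * Z + k_p * Z - k_pp * Zs - delta_Z * Zs,
            k_w - delta_W * W_T,
            (k1 * Zs * W_free - k2 * Ws * Z
             - k3 * X_free * Ws + k4 * Xs * W_free
             - delta_W * Ws - k3 * Xs * Ws + k4 * Xss * W_free - k7 * Ws),
            k_x - delta_X * X_T,
            (k3 * X_free * Ws - k4 * Xs * W_free - delta_X * Xs
             - k3 * Xs * Ws + k4 * Xss * W_free - k5 * Xs + k6 * Xss + r1),
            k3 * Xs * Ws - k4 * Xss * W_free - k6 * Xss - delta_X * Xss + r2,
            k_on * Xs * (pT - Cs - Css) - k_off * Cs - delta_C * Cs,
            k_on * Xss * (pT - Cs - Css) - k_off * Css - delta_C * Css,
            k_sgfp + k_g * hill - delta_G * G,
        ]
    else:
        raise ValueError(name)
    return states, params, fixed, u, load, sp.Matrix(f)


@lru_cache(maxsize=None)
def jacobian_functions(name: str, n1: float = 2.0, n2: float = 2.0):
    """Compiled (rhs, J_x, J_p) callables with signature
    ``fn(state_vec, param_vec, fixed_vec, u_value, load_factor)``.

    The Hill coefficients are substituted numerically before differentiation:
    with a symbolic exponent the derivative of x**n carries a spurious 1/x
    that is singular at x = 0, while a numeric exponent gives the clean
    n·x**(n−1) form.
    """
    states, params, fixed, u, load, f = symbolic_rhs(name)
    f = f.subs({fixed[0]: sp.Float(n1), fixed[1]: sp.Float(n2)})
    Jx = f.jacobian(sp.Matrix(states))
    Jp = f.jacobian(sp.Matrix(params))
    args = (tuple(states), tuple(params), tuple(fixed), u, load)
    f_fn = sp.lambdify(args, f, modules="numpy")
    jx_fn = sp.lambdify(args, Jx, modules="numpy")
    jp_fn = sp.lambdify(args, Jp, modules="numpy")

    def wrap(fn, shape):
        def call(state, param_vec, fixed_vec, u_val, load_factor):
            out = np.asarray(
                fn(tuple(state), tuple(param_vec), tuple(fixed_vec),
                   u_val, load_factor),
                dtype=float,
            )
            return np.broadcast_to(out, shape).reshape(shape) if out.shape != shape else out
        return call

    n, p = len(states), len(params)
    return (
        wrap(f_fn, (n, 1)),
        wrap(jx_fn, (n, n)),
        wrap(jp_fn, (n, p)),
    )
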