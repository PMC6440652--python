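"""Fisher information, Crámer-Rao lower bounds and optimality criteria.

With Gaussian measurement noise of known per-time standard deviation σ_i on
the observed state(s), the Fisher information matrix at the reference
parameters is

    F = Σ_i S(t_i)ᵀ diag(1/σ_i²) S(t_i),

where S(t_i) holds the sensitivity rows of the observed states.  diag(F⁻¹)
gives the Crámer-Rao lower bounds on per-parameter estimator variances, and
scalar functionals of F define the classical design criteria:

    A = tr(F⁻¹)   D = det(F)   E = λ_min(F)   modE = λ_max(F)/λ_min(F).

The modified-E criterion (the condition number of F) is the quantity the
nested OED loop minimizes; modE = 1 describes perfectly balanced information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sensitivity import SensitivityTensor

__all__ = ["FIMResult", "fisher_information", "crlb", "scalar_criterion",
           "SINGULARITY_THRESHOLD"]

#: F is flagged singular when λ_min/λ_max falls below this ratio.
SINGULARITY_THRESHOLD = 1e-12

_CRITERIA = ("A", "D", "E", "modE")


@dataclass
class FIMResult:
    """Fisher matrix with its eigen-structure, criteria and CRLBs."""

    F: np.ndarray
    eigenvalues: np.ndarray          # descending
    crlb: np.ndarray                 # per-parameter variance lower bounds
    criteria: dict[str, float]
    singular: bool
    param_names: tuple[str, ...] | None = None

    @property
    def crlb_std(self) -> np.ndarray:
        """Standard-deviation view of the bounds (sqrt of the variances)."""
        return np.sqrt(self.crlb)

    def to_dict(self) -> dict:
        return {
            "F": self.F.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "crlb": self.crlb.tolist(),
            "criteria": {k: float(v) for k, v in self.criteria.items()},
            "singular": bool(self.singular),
            "param_names": list(self.param_names) if self.param_names else None,
        }


def _eig_sym(F):
    lam, V = np.linalg.eigh(F)
    return lam[::-1], V[:, ::-1]


def crlb(F: np.ndarray) -> np.ndarray:
    """Per-parameter Crámer-Rao variance bounds, diag(F⁻¹).

    A singular F (λ_min/λ_max below :data:`SINGULARITY_THRESHOLD`) yields
    infinite bounds for parameters with weight in the null space — small
    eigenvalues of F signal large uncertainty (non-identifiability).
    """
    F = np.asarray(F, dtype=float)
    lam, V = _eig_sym(F)
    lmax = lam[0] if lam[0] > 0 else 0.0
    null = lam <= lmax * SINGULARITY_THRESHOLD
    out = np.empty(F.shape[0])
    for j in range(F.shape[0]):
        w = V[j, :] ** 2
        if w[null].sum() > 1e-8:
            out[j] = np.inf
        else:
            out[j] = float(np.sum(w[~null] / lam[~null]))
    return out


def scalar_criterion(F: np.ndarray, kind: str) -> float:
    """A-, D-, E- or modified-E optimality functional of a symmetric FIM."""
    if kind not in _CRITERIA:
        raise ValueError(f"kind must be one of {_CRITERIA}")
    F = np.asarray(F, dtype=float)
    if not np.allclose(F, F.T, atol=1e-10):
        raise ValueError("F must be symmetric")
    lam, _ = _eig_sym(F)
    lmax, lmin = lam[0], lam[-1]
    singular = lmax <= 0 or lmin <= lmax * SINGULARITY_THRESHOLD
    if kind == "D":
        return float(np.prod(lam))
    if kind == "E":
        return float(lmin)
    if singular:
        return float("inf")
    if kind == "modE":
        return float(lmax / lmin)
    return float(np.sum(1.0 / lam))  # A


def fisher_information(
    S,
    sigmas,
    observable: int | None = None,
    param_names: tuple[str, ...] | None = None,
) -> FIMResult:
    """Assemble the FIM from sensitivities and measurement noise levels.

    Parameters
    ----------
    S
        :class:`SensitivityTensor` (with ``observable`` selecting the measured
        state; None stacks all states per time point) or a plain array of
        shape (n_t, n_p) / (n_t, n_obs, n_p).
    sigmas
        Per-time-point standard deviations, shape (n_t,) or (n_t, n_obs);
        all entries must be positive.
    """
    if isinstance(S, SensitivityTensor):
        if param_names is None:
            param_names = S.param_names
        blocks = (
            S.values if observable is None
            else S.values[:, observable:observable + 1, :]
        )
    else:
        blocks = np.asarray(S, dtype=float)
        if blocks.ndim == 2:
            blocks = blocks[:, None, :]
    n_t, n_obs, n_p = blocks.shape
    sig = np.asarray(sigmas, dtype=float)
    if sig.ndim == 1:
        sig = np.broadcast_to(sig[:, None], (n_t, n_obs))
    if sig.shape != (n_t, n_obs):
        raise ValueError("sigmas shape incompatible with sensitivities")
    if np.any(sig <= 0):
        raise ValueError("all measurement standard deviations must be positive")

    F = np.zeros((n_p, n_p))
    for i in range(n_t):
        Si = blocks[i]                       # (n_obs, n_p)
        F += Si.T @ (Si / sig[i][:, None] ** 2)
    F = 0.5 * (F + F.T)

    lam, _ = _eig_sym(F)
    lmax = lam[0] if lam[0] > 0 else 0.0
    singular = lmax <= 0 or lam[-1] <= lmax * SINGULARITY_THRESHOLD
    criteria = {k: scalar_criterion(F, k) for k in _CRITERIA}
    return FIMResult(
        F=F,
        eigenvalues=lam,
        crlb=crlb(F),
        criteria=criteria,
        singular=bool(singular),
        param_names=param_names,
    )
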