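"""Effort-minimizing force sharing across redundant muscles.

Distributes a demanded operational-space torque ``T`` over muscles with
torque transforms ``h_i`` so as to minimize the summed squared activations
subject to the torque balance and non-negativity.  The optimum has a closed
form: only muscles acting in the direction of ``T`` (the agonists) are
active, with activations proportional to their ``h``.  An independent
numerical solver (:func:`qp_oracle`) verifies the closed form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import ContractError, InfeasibleTorqueError, OracleError

__all__ = ["SharingProblem", "optimal_activations", "qp_oracle"]

log = logging.getLogger(__name__)


@dataclass
class SharingProblem:
    """A 1-DoF force-sharing instance: transforms ``h`` and demand ``T``."""

    h: np.ndarray
    T: float

    def __post_init__(self) -> None:
        self.h = np.atleast_1d(np.asarray(self.h, dtype=float))
        if self.h.ndim != 1 or self.h.size == 0:
            raise ContractError("h must be a non-empty vector")
        if not np.all(np.isfinite(self.h)) or not np.isfinite(self.T):
            raise ContractError("h and T must be finite")


def optimal_activations(problem: SharingProblem, warn_above: float = 1.0) -> np.ndarray:
    """Closed-form minimum-effort activations.

    Agonists (``sign(h_i) == sign(T)``) receive ``a_i = h_i T / sum_A h_j^2``
    with the sum over the agonist set; all other muscles are silent.  The
    torque constraint holds exactly and every activation is non-negative.
    No upper bound is imposed (sub-maximal regime); a warning is logged if
    any activation exceeds ``warn_above``.
    """
    h, T = problem.h, problem.T
    a = np.zeros_like(h)
    if T == 0:
        return a
    agonists = np.sign(h) == np.sign(T)
    if not np.any(agonists):
        raise InfeasibleTorqueError(
            f"demanded torque {T} but no muscle acts in that direction"
        )
    denom = np.sum(h[agonists] ** 2)
    a[agonists] = h[agonists] * T / denom
    if np.any(a > warn_above):
        log.warning(
            "sub-maximality violated: max activation %.3f for T=%.3g", a.max(), T
        )
    return a


def qp_oracle(problem: SharingProblem, penalty: float = 1e12) -> np.ndarray:
    """Independent numerical solution of the sharing problem.

    Minimizes ``sum a_i^2`` subject to ``h . a = T`` and ``a >= 0`` by
    recasting the equality constraint as a heavily weighted least-squares
    row and handing the whole system to an active-set non-negative
    least-squares solver.  This shares no structure with the sign-partition
    closed form; the constraint is enforced to better than 1e-9.
    """
    h, T = problem.h, problem.T
    m = h.size
    if T == 0:
        return np.zeros(m)
    rho = np.sqrt(penalty)
    M = np.vstack([rho * h[None, :], np.eye(m)])
    b = np.concatenate([[rho * T], np.zeros(m)])
    try:
        a, _ = optimize.nnls(M, b)
    except Exception as exc:
        raise OracleError(f"reference NNLS solve failed: {exc}") from exc
    if abs(h @ a - T) > 1e-9 * max(1.0, abs(T)):
        raise OracleError(
            f"reference solver constraint residual too large: {h @ a - T:.3g}"
        )
    return a
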