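"""Hill-type muscle force generation and the activation-to-torque transform.

A muscle is described phenomenologically: active force is the product of
activation, maximum isometric force, a force-length factor, a
force-velocity factor, and the cosine of the pennation angle.  The tendon
is rigid, so fiber kinematics follow directly from the musculotendon
length, which is stored as a polynomial in the operational angle ``theta``.
The moment arm is the negative derivative of that polynomial, which keeps
torque and length bookkeeping mutually consistent.

The central quantity for synergy construction is ``h``: the torque produced
in the operational space per unit activation at a given posture and
velocity.  Its sign encodes muscle function (positive for muscles whose
shortening increases ``theta``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractError, DomainError, RangeError

__all__ = [
    "MuscleParams",
    "MuscleState",
    "moment_arm",
    "musculotendon_length",
    "force_length",
    "force_velocity",
    "muscle_force",
    "h_analytic",
]

#: Default width of the Gaussian force-length curve.
DEFAULT_FL_WIDTH = 0.45
#: Default force-velocity curvature constant.
DEFAULT_FV_SHAPE = 0.25
#: Default eccentric (lengthening) force ceiling.
DEFAULT_FV_CEILING = 1.4
#: Activation at which velocity-scaling is frozen when computing ``h``.
DEFAULT_A_REF = 0.5


@dataclass
class MuscleParams:
    """Parameters of one Hill-type muscle acting on a 1-DoF joint.

    Parameters
    ----------
    name
        Human-readable muscle label.
    f0max
        Maximum isometric force, N.
    pennation
        Pennation angle, rad, in ``[0, pi/2)``.
    length_poly
        Ascending polynomial coefficients ``c0 + c1*theta + c2*theta**2 + ...``
        of musculotendon length (m) as a function of joint angle (rad).
    l_opt
        Optimal fiber length, m.
    l_slack
        Tendon slack length, m (tendon is rigid).
    v_max
        Maximum shortening velocity in optimal fiber lengths per second.
    fl_width
        Width of the Gaussian force-length relation (dimensionless).
    fv_shape
        Curvature constant of the force-velocity relation.
    fv_ceiling
        Eccentric force ceiling of the force-velocity relation.
    """

    name: str
    f0max: float
    pennation: float
    length_poly: np.ndarray
    l_opt: float
    l_slack: float
    v_max: float = 10.0
    fl_width: float = DEFAULT_FL_WIDTH
    fv_shape: float = DEFAULT_FV_SHAPE
    fv_ceiling: float = DEFAULT_FV_CEILING

    def __post_init__(self) -> None:
        self.length_poly = np.atleast_1d(np.asarray(self.length_poly, dtype=float))
        if self.f0max <= 0:
            raise ContractError(f"{self.name}: f0max must be positive")
        if self.l_opt <= 0:
            raise ContractError(f"{self.name}: l_opt must be positive")
        if self.v_max <= 0:
            raise ContractError(f"{self.name}: v_max must be positive")
        if not 0 <= self.pennation < np.pi / 2:
            raise ContractError(f"{self.name}: pennation must lie in [0, pi/2)")


@dataclass
class MuscleState:
    """Instantaneous kinematic state plus activation of a muscle's joint."""

    theta: float
    theta_dot: float = 0.0
    activation: float = 0.0

    def __post_init__(self) -> None:
        if self.activation < 0:
            raise ContractError("activation must be non-negative")


def _check_range(theta: float, theta_range) -> None:
    if theta_range is None:
        return
    lo, hi = theta_range
    if not lo <= theta <= hi:
        raise RangeError(f"theta={theta} outside configured range [{lo}, {hi}]")


def musculotendon_length(muscle: MuscleParams, theta, theta_range=None):
    """Musculotendon length (m) at angle ``theta``."""
    if np.ndim(theta):
        _check_range(float(np.min(theta)), theta_range)
        _check_range(float(np.max(theta)), theta_range)
    else:
        _check_range(theta, theta_range)
    return np.polynomial.polynomial.polyval(theta, muscle.length_poly)


def moment_arm(muscle: MuscleParams, theta, theta_range=None):
    """Moment arm r(theta) = -d(length)/d(theta), m.

    Positive for muscles whose shortening increases ``theta`` (flexors),
    negative for extensors.
    """
    if np.ndim(theta):
        _check_range(float(np.min(theta)), theta_range)
        _check_range(float(np.max(theta)), theta_range)
    else:
        _check_range(theta, theta_range)
    dcoef = np.polynomial.polynomial.polyder(muscle.length_poly)
    return -np.polynomial.polynomial.polyval(theta, dcoef)


def force_length(l_norm, width: float = DEFAULT_FL_WIDTH):
    """Gaussian active force-length factor, 1 at optimal fiber length."""
    l_norm = np.asarray(l_norm, dtype=float)
    if np.any(l_norm <= 0):
        raise DomainError("normalized fiber length must be positive")
    out = np.exp(-((l_norm - 1.0) ** 2) / width)
    return float(out) if out.ndim == 0 else out

def force_velocity(
    v_norm,
    a: float | None = None,
    shape: float = DEFAULT_FV_SHAPE,
    ceiling: float = DEFAULT_FV_CEILING,
    a_dependent: bool = False,
):
    """Force-velocity factor of fiber velocity normalized to ``v_max``.

    ``v_norm`` is negative for shortening.  Returns 1 at zero velocity, 0 at
    (and beyond) maximal shortening speed, and rises toward ``ceiling`` for
    lengthening.  When ``a_dependent`` is enabled, the effective maximum
    contraction velocity scales with activation as ``(0.25 + 0.75 a)``;
    by default this dependency is neglected.
    """
    v = np.asarray(v_norm, dtype=float)
    if a_dependent:
        if a is None:
            raise ContractError("activation required when a_dependent is enabled")
        if not 0 <= a <= 1:
            raise ContractError("activation must lie in [0, 1]")
        v = v / (0.25 + 0.75 * a)
    b = 2.0 + 2.0 / shape
    concentric = np.clip((1.0 + v) / (1.0 - np.minimum(v, 0.0) / shape), 0.0, None)
    eccentric = ((ceiling - 1.0) + b * ceiling * np.maximum(v, 0.0)) / (
        (ceiling - 1.0) + b * np.maximum(v, 0.0)
    )
    out = np.where(v < 0, concentric, eccentric)
    return float(out) if out.ndim == 0 else out


def _fiber_kinematics(muscle: MuscleParams, theta: float, theta_dot: float):
    """Normalized fiber length and velocity under the rigid-tendon assumption."""
    lmt = musculotendon_length(muscle, theta)
    l_norm = (lmt - muscle.l_slack) / muscle.l_opt
    # chain rule: d(lmt)/dt = d(lmt)/d(theta) * theta_dot = -r(theta) * theta_dot
    v_fiber = -moment_arm(muscle, theta) * theta_dot
    v_norm = v_fiber / (muscle.l_opt * muscle.v_max)
    return l_norm, v_norm


def muscle_force(
    muscle: MuscleParams,
    state: MuscleState,
    a_dependent: bool = False,
    theta_range=None,
) -> float:
    """Tendon-direction force (N) of one muscle in a given state."""
    _check_range(state.theta, theta_range)
    l_norm, v_norm = _fiber_kinematics(muscle, state.theta, state.theta_dot)
    fl = force_length(l_norm, muscle.fl_width)
    fv = force_velocity(
        v_norm,
        a=state.activation if a_dependent else None,
        shape=muscle.fv_shape,
        ceiling=muscle.fv_ceiling,
        a_dependent=a_dependent,
    )
    return state.activation * muscle.f0max * fl * fv * np.cos(muscle.pennation)


def h_analytic(
    muscle: MuscleParams,
    theta: float,
    theta_dot: float = 0.0,
    a_ref: float = DEFAULT_A_REF,
    a_dependent: bool = False,
    theta_range=None,
) -> float:
    """Torque per unit activation (N*m) of one muscle at a given state.

    The activation-dependence of the force-velocity factor, when enabled,
    is frozen at ``a_ref`` so that ``h`` is a pure function of posture and
    velocity.  Sign follows the moment arm.
    """
    _check_range(theta, theta_range)
    l_norm, v_norm = _fiber_kinematics(muscle, theta, theta_dot)
    fl = force_length(l_norm, muscle.fl_width)
    fv = force_velocity(
        v_norm,
        a=a_ref if a_dependent else None,
        shape=muscle.fv_shape,
        ceiling=muscle.fv_ceiling,
        a_dependent=a_dependent,
    )
    r = moment_arm(muscle, theta)
    return muscle.f0max * fl * fv * np.cos(muscle.pennation) * r
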