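"""Forward dynamics of 1-DoF musculoskeletal plants.

Two plants are used throughout: an open-chain forearm (see
:mod:`myosyn.fixtures`) and a seeded, randomly generated closed-chain crank
whose defining property is that at least one muscle changes function
(torque direction) inside the working range while one muscle per direction
keeps a constant sign and can therefore serve as a representative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import ContractError, DomainError, GenerationError, NumericError
from .muscle_mechanics import MuscleParams, force_length, force_velocity

__all__ = [
    "OneDoFModel",
    "SimulationResult",
    "net_torque",
    "active_torque",
    "h_vector",
    "step",
    "make_crank_model",
]


@dataclass
class OneDoFModel:
    """A 1-DoF musculoskeletal plant in operational-space coordinates.

    ``inertia`` may be a constant (kg*m^2) or a callable of theta;
    ``gravity_torque`` is a callable of theta returning N*m, or None.
    """

    muscles: list[MuscleParams]
    inertia: float | Callable[[float], float]
    damping: float = 0.0
    gravity_torque: Callable[[float], float] | None = None
    theta_range: tuple[float, float] = (0.0, np.pi)
    name: str = "model"
    fv_activation_dependent: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.muscles:
            raise ContractError("model needs at least one muscle")
        lo, hi = self.theta_range
        if not lo < hi:
            raise ContractError("theta_range must be increasing")
        self._rebuild_cache()

    def _rebuild_cache(self) -> None:
        # stacked per-muscle arrays for the vectorized hot path
        deg = max(len(m.length_poly) for m in self.muscles)
        coef = np.zeros((deg, len(self.muscles)))
        for j, m in enumerate(self.muscles):
            coef[: len(m.length_poly), j] = m.length_poly
        self._coef = coef
        self._dcoef = np.polynomial.polynomial.polyder(coef, axis=0)
        self._f0 = np.array([m.f0max for m in self.muscles])
        self._cosa = np.cos([m.pennation for m in self.muscles])
        self._lopt = np.array([m.l_opt for m in self.muscles])
        self._lslack = np.array([m.l_slack for m in self.muscles])
        self._vmax = np.array([m.v_max for m in self.muscles])
        self._flw = np.array([m.fl_width for m in self.muscles])
        self._fvs = np.array([m.fv_shape for m in self.muscles])
        self._fvc = np.array([m.fv_ceiling for m in self.muscles])

    @property
    def n_muscles(self) -> int:
        return len(self.muscles)

    @property
    def muscle_names(self) -> list[str]:
        return [m.name for m in self.muscles]

    def inertia_at(self, theta: float) -> float:
        I = self.inertia(theta) if callable(self.inertia) else self.inertia
        if I <= 0:
            raise ContractError(f"inertia must be positive, got {I} at theta={theta}")
        return I

    def gravity_at(self, theta: float) -> float:
        return self.gravity_torque(theta) if self.gravity_torque is not None else 0.0

    def contains(self, theta: float) -> bool:
        lo, hi = self.theta_range
        return lo <= theta <= hi

    def moment_arms(self, theta: float) -> np.ndarray:
        return -np.polynomial.polynomial.polyval(theta, self._dcoef)

    def norm_fiber_lengths(self, theta: float) -> np.ndarray:
        lmt = np.polynomial.polynomial.polyval(theta, self._coef)
        return (lmt - self._lslack) / self._lopt


def _fl_fv(model: OneDoFModel, theta: float, theta_dot: float, activations=None):
    """Vectorized force-length and force-velocity factors for all muscles."""
    lnorm = model.norm_fiber_lengths(theta)
    if np.any(lnorm <= 0):
        bad = model.muscle_names[int(np.argmin(lnorm))]
        raise DomainError(f"non-positive fiber length for {bad} at theta={theta}")
    fl = np.exp(-((lnorm - 1.0) ** 2) / model._flw)
    r = model.moment_arms(theta)
    vnorm = (-r * theta_dot) / (model._lopt * model._vmax)
    if model.fv_activation_dependent and activations is not None:
        vnorm = vnorm / (0.25 + 0.75 * np.asarray(activations))
    b = 2.0 + 2.0 / model._fvs
    concentric = np.clip((1.0 + vnorm) / (1.0 - np.minimum(vnorm, 0.0) / model._fvs), 0.0, None)
    vpos = np.maximum(vnorm, 0.0)
    eccentric = ((model._fvc - 1.0) + b * model._fvc * vpos) / ((model._fvc - 1.0) + b * vpos)
    fv = np.where(vnorm < 0, concentric, eccentric)
    return fl, fv, r


def active_torque(model: OneDoFModel, theta: float, theta_dot: float, activations) -> float:
    """Torque produced by the muscles alone: sum of F_i * r_i."""
    a = np.asarray(activations, dtype=float)
    if a.shape != (model.n_muscles,):
        raise ContractError(f"expected {model.n_muscles} activations, got shape {a.shape}")
    if np.any(a < 0):
        raise ContractError("activations must be non-negative")
    fl, fv, r = _fl_fv(model, theta, theta_dot, a)
    forces = a * model._f0 * fl * fv * model._cosa
    return float(forces @ r)


def net_torque(model: OneDoFModel, theta: float, theta_dot: float, activations) -> float:
    """Operational-space torque balance: muscle + gravity - viscous damping."""
    return (
        active_torque(model, theta, theta_dot, activations)
        + model.gravity_at(theta)
        - model.damping * theta_dot
    )


def h_vector(
    model: OneDoFModel,
    theta: float,
    theta_dot: float = 0.0,
    a_ref: float = 0.5,
) -> np.ndarray:
    """Per-muscle torque per unit activation at a posture (vectorized).

    Activation-dependence of the force-velocity factor, if the model enables
    it, is frozen at ``a_ref``.
    """
    a = np.full(model.n_muscles, a_ref) if model.fv_activation_dependent else None
    fl, fv, r = _fl_fv(model, theta, theta_dot, a)
    return model._f0 * fl * fv * model._cosa * r


def step(
    model: OneDoFModel,
    theta: float,
    theta_dot: float,
    activations,
    dt: float,
) -> tuple[float, float]:
    """One fixed-step RK4 update of (theta, theta_dot).

    Activations are held constant across the step.  The angle is clipped to
    the joint range; at a hard stop the outward velocity is zeroed.
    """
    if dt <= 0:
        raise ContractError("dt must be positive")
    a = np.asarray(activations, dtype=float)

    def deriv(th: float, thd: float) -> tuple[float, float]:
        tau = net_torque(model, th, thd, a)
        return thd, tau / model.inertia_at(th)

    k1 = deriv(theta, theta_dot)
    k2 = deriv(theta + 0.5 * dt * k1[0], theta_dot + 0.5 * dt * k1[1])
    k3 = deriv(theta + 0.5 * dt * k2[0], theta_dot + 0.5 * dt * k2[1])
    k4 = deriv(theta + dt * k3[0], theta_dot + dt * k3[1])
    theta_new = theta + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
    thd_new = theta_dot + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])

    if not (np.isfinite(theta_new) and np.isfinite(thd_new)):
        raise NumericError("non-finite state after integration step")

    lo, hi = model.theta_range
    if theta_new < lo:
        theta_new, thd_new = lo, max(thd_new, 0.0)
    elif theta_new > hi:
        theta_new, thd_new = hi, min(thd_new, 0.0)
    return theta_new, thd_new


@dataclass
class SimulationResult:
    """Time series of a closed-loop (or open-loop) simulation run."""

    time: np.ndarray
    theta: np.ndarray
    theta_dot: np.ndarray
    activations: np.ndarray  # (n_muscles, n_steps)
    torque_demand: np.ndarray
    torque_produced: np.ndarray
    muscle_names: list[str]
    desired_theta: np.ndarray | None = None
    effort: float | None = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for arr in (self.theta, self.theta_dot, self.torque_demand, self.torque_produced):
            if len(arr) != n:
                raise ContractError("time series are not aligned")
        if self.activations.shape != (len(self.muscle_names), n):
            raise ContractError("activation matrix misaligned with time axis")
        if np.any(self.activations < 0):
            raise ContractError("negative activation in result")

    def to_frame(self):
        import pandas as pd

        data = {
            "time": self.time,
            "theta": self.theta,
            "theta_dot": self.theta_dot,
            "torque_demand": self.torque_demand,
            "torque_produced": self.torque_produced,
        }
        if self.desired_theta is not None:
            data["desired_theta"] = self.desired_theta
        for i, name in enumerate(self.muscle_names):
            data[f"a_{name}"] = self.activations[i]
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict:
        out = {"duration": float(self.time[-1] - self.time[0])}
        if self.effort is not None:
            out["effort"] = float(self.effort)
        if self.desired_theta is not None:
            err = self.theta - self.desired_theta
            out["rms_tracking_error"] = float(np.sqrt(np.mean(err**2)))
        out["max_activation"] = float(self.activations.max())
        return out

    def write_summary(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2, sort_keys=True)


# ---------------------------------------------------------------------------
# Seeded crank-model generator
# ---------------------------------------------------------------------------

_CRANK_RANGE = (-np.pi / 2, np.pi / 2)


def _length_poly_from_arm(r_coef: Sequence[float], l_ref: float) -> np.ndarray:
    """Build a length polynomial whose negative derivative is ``r_coef``.

    The constant term is chosen so the fiber sits at optimal length at
    theta = 0 (length = l_ref there).
    """
    r_coef = np.asarray(r_coef, dtype=float)
    # l'(theta) = -r(theta) -> integrate term by term
    dcoef = -r_coef
    lcoef = np.concatenate([[0.0], dcoef / np.arange(1, len(dcoef) + 1)])
    lcoef[0] = l_ref
    return lcoef


def make_crank_model(seed: int, n_muscles: int = 6, max_retries: int = 50) -> OneDoFModel:
    """Generate a 1-DoF crank plant with posture-switching muscle function.

    The generated model is guaranteed to contain, by construction,

    * one muscle with strictly positive torque transform everywhere
      (``meta["rep_pos"]``),
    * one with strictly negative transform everywhere (``meta["rep_neg"]``),
    * at least one whose transform crosses zero inside the range
      (``meta["switching"]``) and therefore changes function with posture.

    Identical seeds yield identical models.
    """
    if n_muscles < 4:
        raise ContractError("crank model needs at least 4 muscles")
    rng = np.random.default_rng(seed)
    lo, hi = _CRANK_RANGE

    for _ in range(max_retries):
        muscles: list[MuscleParams] = []
        roles: list[str] = []
        for i in range(n_muscles):
            if i == 0:
                role = "pos"
            elif i == 1:
                role = "neg"
            elif i == 2:
                role = "switch"
            else:
                role = rng.choice(["pos", "neg", "switch"])
            roles.append(role)

            if role in ("pos", "neg"):
                r0 = rng.uniform(0.020, 0.040)
                r1 = rng.uniform(-0.004, 0.004)
                r2 = rng.uniform(-0.004, 0.004)
                arm = np.array([r0, r1, r2])
                # keep a sign margin across the whole range
                grid = np.linspace(lo, hi, 64)
                vals = arm[0] + arm[1] * grid + arm[2] * grid**2
                if vals.min() < 0.005:
                    arm = np.array([r0, 0.0, 0.0])
                if role == "neg":
                    arm = -arm
            else:  # switching: linear arm crossing zero inside the range
                k = rng.uniform(0.02, 0.05) * rng.choice([-1.0, 1.0])
                theta0 = rng.uniform(lo + 0.35, hi - 0.35)
                arm = np.array([-k * theta0, k])

            l_opt = rng.uniform(0.10, 0.16)
            l_slack = rng.uniform(0.05, 0.20)
            muscles.append(
                MuscleParams(
                    name=f"crank_{role}_{i}",
                    f0max=rng.uniform(300.0, 900.0),
                    pennation=0.0,
                    length_poly=_length_poly_from_arm(arm, l_opt + l_slack),
                    l_opt=l_opt,
                    l_slack=l_slack,
                )
            )

        model = OneDoFModel(
            muscles=muscles,
            inertia=0.12,
            damping=0.3,
            gravity_torque=None,
            theta_range=_CRANK_RANGE,
            name=f"crank[seed={seed}]",
            meta={
                "seed": int(seed),
                "rep_pos": 0,
                "rep_neg": 1,
                "switching": [i for i, r in enumerate(roles) if r == "switch"],
            },
        )

        grid = np.linspace(lo, hi, 101)
        H = np.stack([h_vector(model, th) for th in grid], axis=1)
        ok_pos = np.all(H[0] > 0)
        ok_neg = np.all(H[1] < 0)
        switching = [
            i for i in range(n_muscles) if H[i].min() < 0 < H[i].max()
        ]
        if ok_pos and ok_neg and switching:
            model.meta["switching"] = switching
            return model
    raise GenerationError(f"could not generate a valid crank model with seed {seed}")
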