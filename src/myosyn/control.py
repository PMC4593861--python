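"""Feedback controllers, tracking experiments, and the effort metric.

Two controller families are compared on identical tracking tasks:

* a per-step optimizer (forward static optimization, FSO) that modulates
  every muscle individually by minimizing a weighted sum of effort and
  predicted tracking error, and
* a scalar PID whose signed-activation output drives the two synergies —
  the positive part scales the positive-torque synergy, the negative part
  the negative-torque one.

The physiological effort of a run is the time-averaged integral of the
summed squared activations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .errors import ContractError, ControllerError, DomainError
from .nnmf import StaticSynergies
from .plant import OneDoFModel, SimulationResult, active_torque, h_vector, step
from .synergy import SynergyTable, reconstruct_activations

__all__ = [
    "PIDConfig",
    "FSOConfig",
    "TrajectorySpec",
    "pid_step",
    "split_signed_activation",
    "fso_step",
    "effort",
    "rms_tracking_error",
    "FSOController",
    "SynergyPIDController",
    "StaticSynergyPIDController",
    "simulate_tracking",
    "run_comparison",
    "ComparisonReport",
]

log = logging.getLogger(__name__)

DEFAULT_DT = 1e-3


@dataclass
class PIDConfig:
    """Gains of the signed-activation PID (defaults for the forearm task)."""

    kp: float = 10.0
    ki: float = 10.0
    kd: float = 2.0
    output_limit: float = 1.0
    derivative_cutoff_hz: float = 50.0

    def __post_init__(self) -> None:
        if min(self.kp, self.ki, self.kd) < 0:
            raise ContractError("PID gains must be non-negative")


@dataclass
class FSOConfig:
    """Weights of the per-step effort/tracking objective."""

    w1: float = 1.0       # effort
    w2: float = 3.0e6     # angle error
    w3: float = 5.0e2     # velocity error

    def __post_init__(self) -> None:
        if self.w1 <= 0 or self.w2 < 0 or self.w3 < 0:
            raise ContractError("weights must be non-negative with w1 > 0")


@dataclass
class TrajectorySpec:
    """A seeded sum-of-sines reference in the operational space."""

    amplitudes: np.ndarray
    frequencies: np.ndarray  # Hz
    phases: np.ndarray
    offset: float
    duration: float

    @classmethod
    def sum_of_sines(
        cls,
        seed: int,
        theta_range: tuple[float, float],
        n_terms: int = 3,
        duration: float = 10.0,
        max_freq: float = 0.25,
        min_freq: float = 0.1,
        span_fraction: float = 0.7,
    ) -> "TrajectorySpec":
        """Draw a random trajectory guaranteed to stay inside ``theta_range``.

        Amplitudes are rescaled so the worst-case excursion covers at most
        ``span_fraction`` of the half-range around the mid-point.
        """
        rng = np.random.default_rng(seed)
        lo, hi = theta_range
        offset = 0.5 * (lo + hi)
        amps = rng.uniform(0.3, 1.0, n_terms)
        amps *= span_fraction * 0.5 * (hi - lo) / amps.sum()
        freqs = rng.uniform(min_freq, max_freq, n_terms)
        phases = rng.uniform(0.0, 2 * np.pi, n_terms)
        return cls(amps, freqs, phases, offset, duration)

    def _omega(self) -> np.ndarray:
        return 2 * np.pi * np.asarray(self.frequencies)

    def theta(self, t):
        w = self._omega()
        t = np.asarray(t, dtype=float)
        return self.offset + np.sum(
            self.amplitudes * np.sin(np.outer(t, w) + self.phases), axis=-1
        ).reshape(t.shape)

    def theta_dot(self, t):
        w = self._omega()
        t = np.asarray(t, dtype=float)
        return np.sum(
            self.amplitudes * w * np.cos(np.outer(t, w) + self.phases), axis=-1
        ).reshape(t.shape)

    def theta_ddot(self, t):
        w = self._omega()
        t = np.asarray(t, dtype=float)
        return np.sum(
            -self.amplitudes * w**2 * np.sin(np.outer(t, w) + self.phases), axis=-1
        ).reshape(t.shape)


def pid_step(
    config: PIDConfig,
    error: float,
    error_integral: float,
    error_derivative: float,
) -> float:
    """Pure PID law with output clamped to the signed-activation range."""
    u = config.kp * error + config.ki * error_integral + config.kd * error_derivative
    return float(np.clip(u, -config.output_limit, config.output_limit))


def split_signed_activation(u: float) -> tuple[float, float]:
    """Split a signed activation into its positive and negative portions."""
    return max(u, 0.0), max(-u, 0.0)


def fso_step(
    model: OneDoFModel,
    theta: float,
    theta_dot: float,
    theta_des: float,
    theta_dot_des: float,
    config: FSOConfig,
    dt: float,
) -> np.ndarray:
    """One forward-static-optimization solve.

    The plant is predicted one step ahead under candidate activations
    (muscle torque enters linearly once velocity effects are frozen at the
    current state), and ``w1*sum(a^2) + w2*e_theta^2 + w3*e_thetadot^2`` is
    minimized over ``a >= 0``.  The problem is a non-negative least-squares
    system and is solved exactly each step.
    """
    if dt <= 0:
        raise ContractError("dt must be positive")
    m = model.n_muscles
    I = model.inertia_at(theta)
    h = h_vector(model, theta, theta_dot)
    tau0 = model.gravity_at(theta) - model.damping * theta_dot
    # one-step prediction: thd+ = thd + dt*tau/I ; th+ = th + dt*thd + dt^2/2*tau/I
    q_vel = dt / I
    q_pos = 0.5 * dt * dt / I
    c_pos = theta + dt * theta_dot + q_pos * tau0 - theta_des
    c_vel = theta_dot + q_vel * tau0 - theta_dot_des
    M = np.vstack(
        [
            np.sqrt(config.w1) * np.eye(m),
            np.sqrt(config.w2) * q_pos * h[None, :],
            np.sqrt(config.w3) * q_vel * h[None, :],
        ]
    )
    b = np.concatenate([np.zeros(m), [-np.sqrt(config.w2) * c_pos, -np.sqrt(config.w3) * c_vel]])
    try:
        a, _ = nnls(M, b)
    except Exception as exc:  # pragma: no cover - nnls is very robust
        raise ControllerError(f"inner NNLS solve failed: {exc}") from exc
    return a


class _PIDLoop:
    """Stateful PID with anti-windup and filtered derivative."""

    def __init__(self, config: PIDConfig, dt: float):
        self.config = config
        self.dt = dt
        rc = 1.0 / (2 * np.pi * config.derivative_cutoff_hz)
        self.alpha = dt / (dt + rc)
        self.reset()

    def reset(self) -> None:
        self.integral = 0.0
        self.filtered = 0.0
        self.first = True

    def step(self, error: float) -> float:
        f_new = self.filtered + self.alpha * (error - self.filtered)
        deriv = 0.0 if self.first else (f_new - self.filtered) / self.dt
        self.filtered, self.first = f_new, False
        candidate = self.integral + error * self.dt
        u = pid_step(self.config, error, candidate, deriv)
        unsat = (
            self.config.kp * error + self.config.ki * candidate + self.config.kd * deriv
        )
        if abs(unsat) <= self.config.output_limit:
            self.integral = candidate  # integrate only while unsaturated
        else:
            u = pid_step(self.config, error, self.integral, deriv)
        return u


class FSOController:
    """Per-step optimizer modulating every muscle individually."""

    name = "fso"

    def __init__(self, model: OneDoFModel, trajectory: TrajectorySpec,
                 config: FSOConfig | None = None, dt: float = DEFAULT_DT):
        self.model = model
        self.trajectory = trajectory
        self.config = config or FSOConfig()
        self.dt = dt
        self._prev = np.zeros(model.n_muscles)

    def reset(self) -> None:
        self._prev = np.zeros(self.model.n_muscles)

    def activations(self, t: float, theta: float, theta_dot: float) -> np.ndarray:
        t_next = t + self.dt
        try:
            a = fso_step(
                self.model,
                theta,
                theta_dot,
                float(self.trajectory.theta(t_next)),
                float(self.trajectory.theta_dot(t_next)),
                self.config,
                self.dt,
            )
        except ControllerError as exc:
            log.warning("FSO solver failure at t=%.4f (%s); holding previous", t, exc)
            return self._prev
        self._prev = a
        return a


class SynergyPIDController:
    """Signed-activation PID driving the posture-dependent synergy table."""

    name = "pid_posture"

    def __init__(self, table: SynergyTable, trajectory: TrajectorySpec,
                 config: PIDConfig | None = None, dt: float = DEFAULT_DT):
        self.table = table
        self.trajectory = trajectory
        self.config = config or PIDConfig()
        self.dt = dt
        self._pid = _PIDLoop(self.config, dt)

    def reset(self) -> None:
        self._pid.reset()

    def activations(self, t: float, theta: float, theta_dot: float) -> np.ndarray:
        error = float(self.trajectory.theta(t)) - theta
        u = self._pid.step(error)
        a_pos, a_neg = split_signed_activation(u)
        return reconstruct_activations(self.table, a_pos, a_neg, theta)


class StaticSynergyPIDController:
    """Same PID loop, but the synergies are fixed NNMF columns."""

    name = "pid_nnmf"

    def __init__(self, synergies: StaticSynergies, trajectory: TrajectorySpec,
                 config: PIDConfig | None = None, dt: float = DEFAULT_DT):
        if synergies.col_pos is None or synergies.col_neg is None:
            raise ContractError("synergies must be scaled/assigned to roles first")
        self.s_pos = synergies.S[:, synergies.col_pos]
        self.s_neg = synergies.S[:, synergies.col_neg]
        self.trajectory = trajectory
        self.config = config or PIDConfig()
        self.dt = dt
        self._pid = _PIDLoop(self.config, dt)

    def reset(self) -> None:
        self._pid.reset()

    def activations(self, t: float, theta: float, theta_dot: float) -> np.ndarray:
        error = float(self.trajectory.theta(t)) - theta
        u = self._pid.step(error)
        a_pos, a_neg = split_signed_activation(u)
        return a_pos * self.s_pos + a_neg * self.s_neg


def simulate_tracking(
    model: OneDoFModel,
    controller,
    trajectory: TrajectorySpec,
    dt: float = DEFAULT_DT,
) -> SimulationResult:
    """Closed-loop tracking run; starts on the trajectory, fixed-step RK4."""
    n = int(round(trajectory.duration / dt)) + 1
    t = np.arange(n) * dt
    theta = np.empty(n)
    theta_dot = np.empty(n)
    acts = np.empty((model.n_muscles, n))
    tau_prod = np.empty(n)

    desired = trajectory.theta(t)
    desired_dot = trajectory.theta_dot(t)
    desired_ddot = trajectory.theta_ddot(t)
    tau_demand = (
        np.array([model.inertia_at(th) for th in desired]) * desired_ddot
        + model.damping * desired_dot
        - np.array([model.gravity_at(th) for th in desired])
    )

    controller.reset()
    th, thd = float(desired[0]), float(desired_dot[0])
    for k in range(n):
        a = np.asarray(controller.activations(t[k], th, thd), dtype=float)
        acts[:, k] = a
        theta[k], theta_dot[k] = th, thd
        tau_prod[k] = active_torque(model, th, thd, a)
        if k < n - 1:
            th, thd = step(model, th, thd, a, dt)

    result = SimulationResult(
        time=t,
        theta=theta,
        theta_dot=theta_dot,
        activations=acts,
        torque_demand=tau_demand,
        torque_produced=tau_prod,
        muscle_names=model.muscle_names,
        desired_theta=desired,
    )
    result.effort = effort(result)
    return result


def effort(result: SimulationResult) -> float:
    """Time-averaged integral of summed squared activations."""
    tf = float(result.time[-1] - result.time[0])
    if tf <= 0:
        raise DomainError("effort needs a run of positive duration")
    integrand = np.sum(result.activations**2, axis=0)
    return float(np.trapezoid(integrand, result.time) / tf)


def rms_tracking_error(result: SimulationResult) -> float:
    if result.desired_theta is None:
        raise ContractError("result carries no desired trajectory")
    err = result.theta - result.desired_theta
    return float(np.sqrt(np.mean(err**2)))


@dataclass
class ComparisonReport:
    """Per-controller effort and tracking summary on a shared task."""

    entries: dict[str, dict]
    results: dict[str, SimulationResult] = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {"controllers": self.entries}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def write(self, outdir) -> None:
        import pathlib

        import pandas as pd

        outdir = pathlib.Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "comparison.json").write_text(self.to_json())
        rows = [
            {"method": name, **vals} for name, vals in self.entries.items()
        ]
        pd.DataFrame(rows).to_csv(outdir / "comparison.csv", index=False, float_format="%.10g")
        for name, res in self.results.items():
            res.to_csv(outdir / f"run_{name}.csv")


def run_comparison(
    model: OneDoFModel,
    trajectory: TrajectorySpec,
    controllers: dict[str, object],
    dt: float = DEFAULT_DT,
) -> ComparisonReport:
    """Run every controller on the identical task and tabulate the outcome."""
    entries: dict[str, dict] = {}
    results: dict[str, SimulationResult] = {}
    for name, ctrl in controllers.items():
        res = simulate_tracking(model, ctrl, trajectory, dt)
        entries[name] = {
            "effort": float(res.effort),
            "rms_tracking_error": rms_tracking_error(res),
            "max_activation": float(res.activations.max()),
        }
        results[name] = res
    return ComparisonReport(entries=entries, results=results)
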