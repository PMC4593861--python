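"""Posture-dependent synergy-ratio tables for 1-DoF operational spaces.

Two synergies suffice for a one-dimensional operational space: one for
positive torque and one for negative torque.  Each synergy is a vector of
posture-dependent ratios between every muscle's minimum-effort activation
and that of a designated *representative* muscle; a representative must
keep a constant torque direction over the whole working range.  Scaling a
synergy by a single representative activation then reproduces the full
minimum-effort force sharing without solving any optimization online.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ContractError,
    DegenerateRepresentativeError,
    InvalidRepresentativeError,
    RangeError,
)
from .plant import OneDoFModel, net_torque

__all__ = [
    "SynergyTable",
    "RepresentativeReport",
    "probe_h",
    "build_synergy_table",
    "validate_representatives",
    "reconstruct_activations",
]


def probe_h(
    model: OneDoFModel,
    muscle_index: int,
    theta: float,
    a_probe: float = 0.5,
) -> float:
    """Torque transform of one muscle measured through the plant.

    The muscle is activated alone at ``(theta, theta_dot=0)`` and the
    resulting operational-space torque (with the passive gravity/damping
    contribution subtracted) is divided by the probe activation.  This is
    the numerical route to ``h`` that needs no analytic model insight.
    """
    if not model.contains(theta):
        raise RangeError(f"theta={theta} outside {model.theta_range}")
    if not 0 < a_probe <= 1:
        raise ContractError("a_probe must lie in (0, 1]")
    a = np.zeros(model.n_muscles)
    baseline = net_torque(model, theta, 0.0, a)
    a[muscle_index] = a_probe
    torque = net_torque(model, theta, 0.0, a)
    return (torque - baseline) / a_probe


def _probe_matrix(model: OneDoFModel, theta_grid: np.ndarray, a_probe: float) -> np.ndarray:
    return np.array(
        [[probe_h(model, i, th, a_probe) for th in theta_grid] for i in range(model.n_muscles)]
    )


@dataclass
class RepresentativeReport:
    """Per-muscle sign-constancy summary over a posture grid."""

    muscle_names: list[str]
    always_positive: np.ndarray
    always_negative: np.ndarray
    switches_sign: np.ndarray
    rep_pos: int
    rep_neg: int

    def as_dict(self) -> dict:
        return {
            name: (
                "positive"
                if self.always_positive[i]
                else "negative"
                if self.always_negative[i]
                else "switching"
            )
            for i, name in enumerate(self.muscle_names)
        }


def validate_representatives(
    model: OneDoFModel,
    theta_grid,
    rep_pos: int,
    rep_neg: int,
    a_probe: float = 0.5,
) -> RepresentativeReport:
    """Check that the chosen representatives never change torque direction.

    Raises :class:`InvalidRepresentativeError` naming the failing posture if
    the positive representative's transform is not strictly positive, or the
    negative one's not strictly negative, anywhere on the grid.  On success
    returns a sign-constancy report for every muscle.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    if theta_grid.size == 0:
        raise ContractError("theta_grid must be non-empty")
    H = _probe_matrix(model, theta_grid, a_probe)

    for idx, want_pos in ((rep_pos, True), (rep_neg, False)):
        h = H[idx]
        bad = np.where(h <= 0 if want_pos else h >= 0)[0]
        if bad.size:
            th = theta_grid[bad[0]]
            direction = "positive" if want_pos else "negative"
            raise InvalidRepresentativeError(
                f"{model.muscle_names[idx]} is not a valid {direction} representative: "
                f"h={h[bad[0]]:.4g} at theta={th:.4f}"
            )

    return RepresentativeReport(
        muscle_names=model.muscle_names,
        always_positive=np.all(H > 0, axis=1),
        always_negative=np.all(H < 0, axis=1),
        switches_sign=(H.min(axis=1) < 0) & (H.max(axis=1) > 0),
        rep_pos=rep_pos,
        rep_neg=rep_neg,
    )


@dataclass
class SynergyTable:
    """Ratio tables of the two synergies over a posture grid.

    ``S_pos[i, g]`` is muscle ``i``'s share of the positive-torque synergy at
    grid posture ``g`` (1 for the representative, 0 for muscles acting the
    other way); similarly ``S_neg``.  ``h_rep_pos/h_rep_neg`` store the
    representatives' torque transforms so that torque demands can be turned
    into representative activations without revisiting the plant.
    """

    muscle_names: list[str]
    theta_grid: np.ndarray
    S_pos: np.ndarray
    S_neg: np.ndarray
    rep_pos: int
    rep_neg: int
    h_rep_pos: np.ndarray
    h_rep_neg: np.ndarray
    theta_dot_grid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        if np.any(np.diff(self.theta_grid) <= 0):
            raise ContractError("theta_grid must be strictly increasing")
        if np.any(self.S_pos < 0) or np.any(self.S_neg < 0):
            raise ContractError("synergy ratios must be non-negative")

    @property
    def n_muscles(self) -> int:
        return len(self.muscle_names)

    def _check_span(self, theta: float) -> None:
        if not self.theta_grid[0] <= theta <= self.theta_grid[-1]:
            raise RangeError(f"theta={theta} outside table span")

    def _interp_rows(self, M: np.ndarray, theta: float) -> np.ndarray:
        g = self.theta_grid
        j = int(np.clip(np.searchsorted(g, theta) - 1, 0, len(g) - 2))
        w = (theta - g[j]) / (g[j + 1] - g[j])
        return (1.0 - w) * M[..., j] + w * M[..., j + 1]

    def ratios_at(self, theta: float) -> tuple[np.ndarray, np.ndarray]:
        """Linearly interpolated (S_pos, S_neg) columns at ``theta``."""
        self._check_span(theta)
        return self._interp_rows(self.S_pos, theta), self._interp_rows(self.S_neg, theta)

    def rep_activation_for_torque(self, theta: float, T: float) -> tuple[float, float]:
        """Representative activations reproducing the minimum-effort optimum.

        For a positive demand the positive representative's optimal
        activation is ``T / (h_rep * sum_i S_pos_i^2)`` (and symmetrically
        for negative demand); combined with the ratio table this equals the
        closed-form optimum of the sharing problem.
        """
        self._check_span(theta)
        if T == 0:
            return 0.0, 0.0
        s_pos, s_neg = self.ratios_at(theta)
        if T > 0:
            h_rep = float(np.interp(theta, self.theta_grid, self.h_rep_pos))
            return T / (h_rep * float(s_pos @ s_pos)), 0.0
        h_rep = float(np.interp(theta, self.theta_grid, self.h_rep_neg))
        return 0.0, T / (h_rep * float(s_neg @ s_neg))

    def activations_for_torque(self, theta: float, T: float) -> np.ndarray:
        a_pos, a_neg = self.rep_activation_for_torque(theta, T)
        return reconstruct_activations(self, a_pos, a_neg, theta)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "muscle_names": self.muscle_names,
            "theta_grid": self.theta_grid.tolist(),
            "S_pos": self.S_pos.tolist(),
            "S_neg": self.S_neg.tolist(),
            "rep_pos": int(self.rep_pos),
            "rep_neg": int(self.rep_neg),
            "h_rep_pos": self.h_rep_pos.tolist(),
            "h_rep_neg": self.h_rep_neg.tolist(),
        }
        if self.theta_dot_grid is not None:
            d["theta_dot_grid"] = self.theta_dot_grid.tolist()
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "SynergyTable":
        return cls(
            muscle_names=list(d["muscle_names"]),
            theta_grid=np.asarray(d["theta_grid"], dtype=float),
            S_pos=np.asarray(d["S_pos"], dtype=float),
            S_neg=np.asarray(d["S_neg"], dtype=float),
            rep_pos=int(d["rep_pos"]),
            rep_neg=int(d["rep_neg"]),
            h_rep_pos=np.asarray(d["h_rep_pos"], dtype=float),
            h_rep_neg=np.asarray(d["h_rep_neg"], dtype=float),
            theta_dot_grid=(
                np.asarray(d["theta_dot_grid"], dtype=float) if "theta_dot_grid" in d else None
            ),
        )

    @classmethod
    def load(cls, path) -> "SynergyTable":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_csv(self, path) -> None:
        """Flat CSV export (one row per grid point) for surface plots."""
        import pandas as pd

        data = {"theta": self.theta_grid}
        for i, name in enumerate(self.muscle_names):
            data[f"S_pos_{name}"] = self.S_pos[i]
            data[f"S_neg_{name}"] = self.S_neg[i]
        pd.DataFrame(data).to_csv(path, index=False, float_format="%.10g")


def build_synergy_table(
    model: OneDoFModel,
    theta_grid=None,
    rep_pos: int | None = None,
    rep_neg: int | None = None,
    a_probe: float = 0.5,
    n_grid: int = 101,
) -> SynergyTable:
    """Probe the plant over a posture grid and assemble the ratio tables.

    At each grid point every muscle's torque transform ``h_i`` is measured
    with :func:`probe_h`; the ratio to the representative is kept where it
    is positive and clamped to zero otherwise, so a muscle contributes to at
    most one synergy at any posture.  Velocity dependence is deliberately
    dropped (the transform is probed at zero velocity): it complicates the
    tables for negligible gain in accuracy.
    """
    if theta_grid is None:
        theta_grid = np.linspace(*model.theta_range, n_grid)
    theta_grid = np.asarray(theta_grid, dtype=float)
    if rep_pos is None:
        rep_pos = model.meta.get("rep_pos")
    if rep_neg is None:
        rep_neg = model.meta.get("rep_neg")
    if rep_pos is None or rep_neg is None:
        raise ContractError("rep_pos and rep_neg must be given or present in model.meta")

    validate_representatives(model, theta_grid, rep_pos, rep_neg, a_probe)
    H = _probe_matrix(model, theta_grid, a_probe)
    if np.any(H[rep_pos] == 0) or np.any(H[rep_neg] == 0):
        raise DegenerateRepresentativeError("representative transform vanishes on the grid")

    S_pos = np.clip(H / H[rep_pos], 0.0, None)
    S_neg = np.clip(H / H[rep_neg], 0.0, None)
    return SynergyTable(
        muscle_names=model.muscle_names,
        theta_grid=theta_grid,
        S_pos=S_pos,
        S_neg=S_neg,
        rep_pos=rep_pos,
        rep_neg=rep_neg,
        h_rep_pos=H[rep_pos],
        h_rep_neg=H[rep_neg],
    )


def reconstruct_activations(
    table: SynergyTable,
    a_pos: float,
    a_neg: float,
    theta: float,
) -> np.ndarray:
    """Full activation vector from the two synergy commands at ``theta``."""
    if a_pos < 0 or a_neg < 0:
        raise ContractError("representative activations must be non-negative")
    s_pos, s_neg = table.ratios_at(theta)
    return a_pos * s_pos + a_neg * s_neg
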