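"""Static-synergy baseline via non-negative matrix factorization.

The activation matrix ``A`` (muscles x samples) collects minimum-effort
activations recorded while the plant follows a seeded random motion.  NNMF
decomposes ``A ~ S @ C`` with both factors non-negative; each column of
``S`` is a *static* synergy.  After scaling each column so its
representative muscle's weight is one, the columns can drive the same
signed-activation controller as the posture-dependent tables — the point of
the baseline being that a static synergy cannot follow muscles whose
function changes with posture.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .errors import ContractError, DegenerateInputError, ScalingError
from .force_sharing import SharingProblem, optimal_activations
from .plant import OneDoFModel, h_vector

__all__ = [
    "ActivationMatrix",
    "StaticSynergies",
    "generate_training_data",
    "factorize",
    "scale_to_representatives",
    "vaf",
]


@dataclass
class ActivationMatrix:
    """Non-negative muscles-by-samples activation data with sample postures."""

    A: np.ndarray
    muscle_names: list[str]
    sample_theta: np.ndarray
    sample_time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != len(self.muscle_names):
            raise ContractError("A must be (n_muscles, n_samples)")
        if np.any(self.A < 0):
            raise ContractError("activation matrix must be non-negative")

    def to_csv(self, path) -> None:
        import pandas as pd

        cols = (
            [f"{t:.6f}" for t in self.sample_time]
            if self.sample_time is not None
            else [str(i) for i in range(self.A.shape[1])]
        )
        df = pd.DataFrame(self.A, index=self.muscle_names, columns=cols)
        df.to_csv(path, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, sample_theta=None) -> "ActivationMatrix":
        import pandas as pd

        df = pd.read_csv(path, index_col=0)
        try:
            times = np.array([float(c) for c in df.columns])
        except ValueError:
            times = None
        n = df.shape[1]
        return cls(
            A=df.to_numpy(dtype=float),
            muscle_names=[str(i) for i in df.index],
            sample_theta=np.zeros(n) if sample_theta is None else np.asarray(sample_theta),
            sample_time=times,
        )


@dataclass
class StaticSynergies:
    """A factorization ``A ~ S @ C`` plus its variance accounted for."""

    S: np.ndarray
    C: np.ndarray
    vaf: float
    muscle_names: list[str]
    col_pos: int | None = None
    col_neg: int | None = None

    def __post_init__(self) -> None:
        if np.any(self.S < 0) or np.any(self.C < 0):
            raise ContractError("factors must be non-negative")

    @property
    def n_synergies(self) -> int:
        return self.S.shape[1]

    def to_dict(self) -> dict:
        d = {
            "S": self.S.tolist(),
            "C": self.C.tolist(),
            "vaf": float(self.vaf),
            "muscle_names": self.muscle_names,
        }
        if self.col_pos is not None:
            d["col_pos"] = int(self.col_pos)
            d["col_neg"] = int(self.col_neg)
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def weights_to_csv(self, path) -> None:
        import pandas as pd

        df = pd.DataFrame(
            self.S,
            index=self.muscle_names,
            columns=[f"synergy_{k}" for k in range(self.n_synergies)],
        )
        df.to_csv(path, float_format="%.10g")


def vaf(A: np.ndarray, S: np.ndarray, C: np.ndarray) -> float:
    """Variance accounted for: 1 - ||A - SC||_F^2 / ||A||_F^2."""
    denom = float(np.sum(A**2))
    if denom == 0:
        raise DegenerateInputError("cannot compute VAF of an all-zero matrix")
    return 1.0 - float(np.sum((A - S @ C) ** 2)) / denom


def generate_training_data(
    model: OneDoFModel,
    trajectory,
    n_samples: int = 400,
) -> ActivationMatrix:
    """Minimum-effort activations along a prescribed random motion.

    The plant is driven along ``trajectory`` kinematically; at each of
    ``n_samples`` uniformly spaced times the torque required by inverse
    dynamics is shared optimally across the muscles (closed form), yielding
    one column of the training matrix.  Fully deterministic for a given
    trajectory.
    """
    t = np.linspace(0.0, trajectory.duration, n_samples)
    theta = trajectory.theta(t)
    theta_dot = trajectory.theta_dot(t)
    theta_ddot = trajectory.theta_ddot(t)
    A = np.zeros((model.n_muscles, n_samples))
    for k in range(n_samples):
        th, thd = float(theta[k]), float(theta_dot[k])
        T = (
            model.inertia_at(th) * float(theta_ddot[k])
            + model.damping * thd
            - model.gravity_at(th)
        )
        h = h_vector(model, th, thd)
        A[:, k] = optimal_activations(SharingProblem(h, T))
    return ActivationMatrix(
        A=A, muscle_names=model.muscle_names, sample_theta=theta, sample_time=t
    )


def factorize(
    A: ActivationMatrix | np.ndarray,
    n: int = 2,
    max_iter: int = 5000,
    tol: float = 1e-8,
    seed: int = 0,
    n_restarts: int = 10,
) -> StaticSynergies:
    """Multiplicative-update NNMF with seeded random restarts.

    Minimizes the Frobenius reconstruction error with the standard
    multiplicative update rule from non-negative random initializations;
    the best of ``n_restarts`` runs is kept and reported with its VAF.
    """
    if isinstance(A, ActivationMatrix):
        names, M = A.muscle_names, A.A
    else:
        M = np.asarray(A, dtype=float)
        names = [f"m{i}" for i in range(M.shape[0])]
    if n < 1:
        raise ContractError("n must be >= 1")
    if np.all(M == 0):
        raise DegenerateInputError("activation matrix is all zeros")

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        for k in range(n_restarts):
            nmf = NMF(
                n_components=n,
                init="random",
                solver="mu",
                beta_loss="frobenius",
                tol=tol,
                max_iter=max_iter,
                random_state=seed + k,
            )
            S = nmf.fit_transform(M)
            C = nmf.components_
            err = float(np.sum((M - S @ C) ** 2))
            if best is None or err < best[0]:
                best = (err, S, C)
    _, S, C = best
    return StaticSynergies(S=S, C=C, vaf=vaf(M, S, C), muscle_names=names)


def scale_to_representatives(
    syn: StaticSynergies,
    rep_pos: int,
    rep_neg: int,
    h_mid: np.ndarray | None = None,
) -> StaticSynergies:
    """Scale each synergy column so its representative's weight equals one.

    Columns are first assigned to the positive/negative torque role by which
    representative dominates them (relative to column norm); ties are broken
    by the sign of the torque the column would produce at mid-range posture
    if ``h_mid`` is supplied.  The product ``S @ C`` is unchanged.
    """
    S, C = syn.S.copy(), syn.C.copy()
    if S.shape[1] < 2:
        raise ContractError("need at least two synergies to assign both roles")
    norms = np.linalg.norm(S, axis=0)
    norms[norms == 0] = 1.0
    score_pos = S[rep_pos] / norms
    score_neg = S[rep_neg] / norms
    col_pos = int(np.argmax(score_pos))
    col_neg = int(np.argmax(score_neg))
    if col_pos == col_neg:
        if h_mid is not None:
            torque_sign = np.sign(h_mid @ S)
            if torque_sign[col_pos] >= 0:
                col_neg = int(np.argmax(np.where(np.arange(S.shape[1]) != col_pos, score_neg, -np.inf)))
            else:
                col_pos = int(np.argmax(np.where(np.arange(S.shape[1]) != col_neg, score_pos, -np.inf)))
        else:
            raise ScalingError("could not disambiguate synergy roles; provide h_mid")

    for col, rep in ((col_pos, rep_pos), (col_neg, rep_neg)):
        w = S[rep, col]
        if w <= 0:
            raise ScalingError(
                f"representative {syn.muscle_names[rep]} has zero weight in column {col}"
            )
        S[:, col] /= w
        C[col, :] *= w

    return StaticSynergies(
        S=S,
        C=C,
        vaf=syn.vaf,
        muscle_names=syn.muscle_names,
        col_pos=col_pos,
        col_neg=col_neg,
    )
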