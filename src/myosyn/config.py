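"""Structured-file (YAML/JSON) serialization of plant models.

Angles are radians, forces newtons, lengths meters throughout.  Gravity is
stored as a constant operational-space torque (or null); callable gravity
terms can be attached programmatically but are not serialized.
"""

from __future__ import annotations

import json
import pathlib

import numpy as np
import yaml

from .errors import ContractError
from .muscle_mechanics import MuscleParams
from .plant import OneDoFModel

__all__ = ["model_from_dict", "model_to_dict", "load_model", "save_model"]

_MUSCLE_KEYS = (
    "f0max",
    "pennation",
    "length_poly",
    "l_opt",
    "l_slack",
    "v_max",
    "fl_width",
    "fv_shape",
    "fv_ceiling",
)


def model_from_dict(d: dict) -> OneDoFModel:
    muscles = []
    for md in d["muscles"]:
        kwargs = {k: md[k] for k in _MUSCLE_KEYS if k in md}
        muscles.append(MuscleParams(name=md["name"], **kwargs))
    m = d.get("model", {})
    gravity = m.get("gravity")
    gravity_fn = None
    if gravity is not None:
        g_const = float(gravity)
        gravity_fn = lambda theta, g=g_const: g  # noqa: E731
    names = [mu.name for mu in muscles]
    meta = dict(m.get("meta", {}))
    for key in ("rep_pos", "rep_neg"):
        if key in m:
            val = m[key]
            meta[key] = names.index(val) if isinstance(val, str) else int(val)
    if gravity is not None:
        meta["gravity_const"] = float(gravity)
    return OneDoFModel(
        muscles=muscles,
        inertia=float(m.get("inertia", 1.0)),
        damping=float(m.get("damping", 0.0)),
        gravity_torque=gravity_fn,
        theta_range=tuple(m.get("theta_range", (0.0, np.pi))),
        name=str(m.get("name", "model")),
        meta=meta,
    )


def model_to_dict(model: OneDoFModel) -> dict:
    if callable(model.inertia):
        raise ContractError("callable inertia cannot be serialized")
    m = {
        "name": model.name,
        "inertia": float(model.inertia),
        "damping": float(model.damping),
        "gravity": model.meta.get("gravity_const"),
        "theta_range": [float(x) for x in model.theta_range],
    }
    for key in ("rep_pos", "rep_neg"):
        if key in model.meta:
            m[key] = model.muscle_names[model.meta[key]]
    extra_meta = {
        k: v for k, v in model.meta.items()
        if k not in ("rep_pos", "rep_neg", "gravity_const")
    }
    if extra_meta:
        m["meta"] = extra_meta
    return {
        "model": m,
        "muscles": [
            {
                "name": mu.name,
                "f0max": float(mu.f0max),
                "pennation": float(mu.pennation),
                "length_poly": [float(c) for c in mu.length_poly],
                "l_opt": float(mu.l_opt),
                "l_slack": float(mu.l_slack),
                "v_max": float(mu.v_max),
                "fl_width": float(mu.fl_width),
                "fv_shape": float(mu.fv_shape),
                "fv_ceiling": float(mu.fv_ceiling),
            }
            for mu in model.muscles
        ],
    }


def load_model(path) -> OneDoFModel:
    path = pathlib.Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return model_from_dict(data)


def save_model(model: OneDoFModel, path) -> None:
    path = pathlib.Path(path)
    d = model_to_dict(model)
    if path.suffix == ".json":
        path.write_text(json.dumps(d, indent=2))
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
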