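"""Shipped example plants.

``forearm_model()`` loads the packaged 7-muscle elbow model; the crank
model is generated on demand by :func:`myosyn.plant.make_crank_model`
(re-exported here for convenience).
"""

from __future__ import annotations

from importlib import resources

import yaml

from .config import model_from_dict
from .plant import OneDoFModel, make_crank_model

__all__ = ["forearm_model", "make_crank_model"]


def forearm_model() -> OneDoFModel:
    """The default 7-muscle elbow flexion/extension fixture."""
    text = resources.files("myosyn").joinpath("data/forearm.yaml").read_text()
    return model_from_dict(yaml.safe_load(text))
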