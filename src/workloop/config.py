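"""YAML configuration for muscles, load, protocol and noise settings.

A single config file holds sections ``muscle`` (agonist), optional
``muscle2`` (antagonist; defaults to a copy of the agonist), ``load``
(either M/b/k or f_n/zeta/k), ``protocol`` and ``noise``.  All quantities
are SI.  Omitted sections fall back to the package defaults.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .experiment_emulation import SessionConfig
from .load_dynamics import LoadParams, default_load_params
from .muscle_model import MuscleParams, default_muscle_params

__all__ = ["load_config", "save_config", "session_from_config"]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    out = {}
    m1 = MuscleParams.from_dict(cfg["muscle"]) if "muscle" in cfg else default_muscle_params()
    m2 = MuscleParams.from_dict(cfg["muscle2"]) if "muscle2" in cfg else m1
    out["muscles"] = (m1, m2)
    out["load"] = LoadParams.from_dict(cfg["load"]) if "load" in cfg else default_load_params()
    out["protocol"] = cfg.get("protocol", {})
    out["noise"] = cfg.get("noise", {})
    return out


def save_config(path, muscles=None, load=None, protocol=None, noise=None) -> None:
    cfg = {}
    if muscles is not None:
        cfg["muscle"] = muscles[0].to_dict()
        cfg["muscle2"] = muscles[1].to_dict()
    if load is not None:
        cfg["load"] = load.to_dict()
    if protocol:
        cfg["protocol"] = protocol
    if noise:
        cfg["noise"] = noise
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))


def session_from_config(cfg: dict, seed: int = 0) -> SessionConfig:
    proto = cfg.get("protocol", {})
    noise = cfg.get("noise", {})
    kw = dict(load=cfg["load"], muscles=cfg["muscles"], seed=seed)
    if "frequencies" in proto:
        kw["frequencies"] = tuple(float(f) for f in proto["frequencies"])
    for key in ("repetitions", "cycles", "discard_first"):
        if key in proto:
            kw[key] = proto[key]
    for src, dst in (("force_noise_frac", "force_noise_frac"),
                     ("position_noise_frac", "position_noise_frac"),
                     ("fatigue_rate", "fatigue_rate")):
        if src in noise:
            kw[dst] = float(noise[src])
    return SessionConfig(**kw)
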