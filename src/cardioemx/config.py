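"""Parameter bundles and YAML configuration files.

The global unit system is fixed (mm, ms, kPa, mV; derived force unit mN);
parameter files must declare it.  A config file is a flat mapping with one
block per component, mirroring the constitutive symbol names::

    units: {length: mm, time: ms, stress: kPa, potential: mV}
    passive:
      model: HO
      a: 0.248
      b: 7.209
      ...
    electro:
      alpha: 0.01
      d_iso: 0.1
      G_s: 10.0
      ...
    active:
      k_T: 0.49
      Phi_r: -80.0
    solver:
      dt: 1.0

Any omitted key falls back to the built-in defaults (the rat-scale
parameter set used throughout the benchmarks).
"""

from __future__ import annotations

import dataclasses
from typing import Tuple

import yaml

from .active_stress import ActiveParams
from .constitutive import HOParams, TICParams, TIIParams, make_law, PassiveLaw
from .electrophysiology import ElectroParams
from .fem_core import SolverConfig

__all__ = ["UNITS", "default_passive_params", "load_config", "params_from_dict",
           "manifest_dict"]

UNITS = {"length": "mm", "time": "ms", "stress": "kPa", "potential": "mV"}

_PASSIVE_CLS = {"TIC": TICParams, "TII": TIIParams, "HO": HOParams}


def default_passive_params(model: str):
    """Built-in rat-scale parameter set for 'TIC' | 'TII' | 'HO'."""
    return _PASSIVE_CLS[model.upper()]()


def _build(cls, block: dict):
    fields = {f.name for f in dataclasses.fields(cls) if f.init}
    unknown = set(block) - fields
    if unknown:
        raise KeyError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**block)


def params_from_dict(cfg: dict) -> Tuple[PassiveLaw, ElectroParams,
                                         ActiveParams, SolverConfig]:
    """Materialize (law, electro, active, solver) from a config mapping."""
    units = cfg.get("units", UNITS)
    if dict(units) != UNITS:
        raise ValueError(f"config units must be {UNITS}, got {units}")
    pblock = dict(cfg.get("passive", {}))
    model = pblock.pop("model", "HO").upper()
    law = make_law(model, _build(_PASSIVE_CLS[model], pblock) if pblock else None)
    electro = _build(ElectroParams, dict(cfg.get("electro", {})))
    active = _build(ActiveParams, dict(cfg.get("active", {})))
    solver = _build(SolverConfig, dict(cfg.get("solver", {})))
    return law, electro, active, solver


def load_config(path) -> Tuple[PassiveLaw, ElectroParams, ActiveParams,
                               SolverConfig]:
    """Read a YAML parameter file (see module docstring for the layout)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return params_from_dict(cfg)


def manifest_dict(law: PassiveLaw, electro: ElectroParams,
                  active: ActiveParams, solver: SolverConfig,
                  extra: dict | None = None) -> dict:
    """Run manifest: every parameter and solver setting, JSON-serializable."""
    from . import __version__
    man = {
        "package": "cardioemx",
        "version": __version__,
        "units": UNITS,
        "passive": {"model": law.params.model_id,
                    **{k: v for k, v in dataclasses.asdict(law.params).items()
                       if k != "model_id"}},
        "electro": dataclasses.asdict(electro),
        "active": dataclasses.asdict(active),
        "solver": dataclasses.asdict(solver),
    }
    if extra:
        man.update(extra)
    return man


def save_config(path, law, electro, active, solver) -> None:
    man = manifest_dict(law, electro, active, solver)
    man.pop("package")
    man.pop("version")
    with open(path, "w") as fh:
        yaml.safe_dump(man, fh, sort_keys=False)
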