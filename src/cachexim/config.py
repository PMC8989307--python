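"""Scenario YAML configuration.

A scenario file names the schedule in the mini-language and overrides
model parameters by their conventional symbols, e.g.::

    schedule: "5on2off:35"
    t_end: 56
    tumour: true          # include the tumour stage (or a mapping of overrides)
    morphine: false
    aged: false
    params:               # optional overrides, keyed by symbol
      Rd: 6.8
      tau: 8
      p1: 0.133
    host0: {S: 267.5, M: 4732.5}   # optional explicit initial state
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import yaml

from .coupled import Scenario
from .pharmacokinetics import PKParams
from .schedules import parse_schedule
from .tissue import ChemoEffect, HostState, MuscleParams, TumourParams

__all__ = ["load_scenario", "dump_scenario"]

_PK = ("k10", "k12", "k21", "V1", "V2")
_MUSCLE = ("p0", "p1", "nu0", "nu1", "d0", "m", "density")
_CHEMO = ("Rd", "tau")
_TUMOUR = ("mu0", "mu1", "eta", "kappa", "T0")


def _split_params(params: dict) -> tuple[dict, dict, dict, dict]:
    groups = ({}, {}, {}, {})
    for key, value in params.items():
        for group, names in zip(groups, (_PK, _MUSCLE, _CHEMO, _TUMOUR)):
            if key in names:
                group[key] = float(value)
                break
        else:
            raise KeyError(f"unknown parameter symbol {key!r} in scenario config")
    return groups


def load_scenario(path: str | Path) -> Scenario:
    """Build a :class:`Scenario` from a YAML file."""
    cfg = yaml.safe_load(Path(path).read_text())
    if not isinstance(cfg, dict) or "schedule" not in cfg:
        raise ValueError("scenario config must be a mapping with a 'schedule' key")
    pk_over, mp_over, ce_over, tp_over = _split_params(cfg.get("params") or {})

    tumour = cfg.get("tumour", False)
    if isinstance(tumour, dict):
        tp_over.update({k: float(v) for k, v in tumour.items()})
        tumour = True
    tp = TumourParams(**tp_over) if tumour else None
    if tp is None and tp_over:
        raise ValueError("tumour parameter overrides given but tumour not enabled")

    host0 = cfg.get("host0")
    if host0 is not None:
        host0 = HostState(S=float(host0["S"]), M=float(host0["M"]))

    return Scenario(
        schedule=parse_schedule(cfg["schedule"]),
        pk=replace(PKParams(), **pk_over),
        mp=replace(MuscleParams(), **mp_over),
        ce=replace(ChemoEffect(), **ce_over),
        tp=tp,
        host0=host0,
        t_end=float(cfg.get("t_end", 56.0)),
        morphine=bool(cfg.get("morphine", False)),
        aged=bool(cfg.get("aged", False)),
        resolution=float(cfg.get("resolution", 0.005)),
    )


def dump_scenario(scenario: Scenario, path: str | Path) -> None:
    """Write a scenario back to YAML (events inline if not mini-language built)."""
    cfg = {
        "schedule": scenario.schedule.label,
        "t_end": scenario.t_end,
        "morphine": scenario.morphine,
        "aged": scenario.aged,
        "resolution": scenario.resolution,
        "params": {
            **{k: getattr(scenario.pk, k) for k in _PK},
            **{k: getattr(scenario.mp, k) for k in _MUSCLE},
            **{k: getattr(scenario.ce, k) for k in _CHEMO},
        },
        "tumour": {k: getattr(scenario.tp, k) for k in _TUMOUR} if scenario.tp else False,
    }
    if scenario.host0 is not None:
        cfg["host0"] = {"S": scenario.host0.S, "M": scenario.host0.M}
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=False))
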