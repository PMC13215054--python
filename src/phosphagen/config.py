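"""Structured configuration files and the published protocol presets.

Configurations are plain YAML documents (one per terminal).  A defaults
file ships with the package carrying the published model constants and a
clearly labelled synthetic terminal; :func:`load_config` reads it when no
path is given.  The four stimulation protocols the model was exercised
with are available as presets:

========== ======================================================
locomotion  42 Hz trains, 0.8 s duty in 1 s cycles, 240 cycles
ca_pumping  50 Hz trains, 2 s duty in 4 s cycles, 60 cycles
train_60hz  a single 60 Hz train of 30 APs
train_80hz  a single 80 Hz train, 10 s duty
========== ======================================================
"""

from __future__ import annotations

from importlib import resources

import yaml

from .core import (
    EquilibriumConstants,
    InitialConditions,
    InvalidParameterError,
    TerminalParams,
    ThermoConstants,
)
from .equilibration import EquilibrationOptions
from .production import HillInverseTurnover
from .stimulus import FiringProtocol

__all__ = [
    "PROTOCOL_PRESETS",
    "protocol_preset",
    "load_config",
    "terminal_from_dict",
    "protocol_from_dict",
]


def _presets() -> dict:
    return {
        "locomotion": FiringProtocol(rate=42.0, duty=0.8, full_cycle=1.0, n_cycles=240),
        "ca_pumping": FiringProtocol(rate=50.0, duty=2.0, full_cycle=4.0, n_cycles=60),
        "train_60hz": FiringProtocol.single_train(rate=60.0, n_spikes=30),
        "train_80hz": FiringProtocol(rate=80.0, duty=10.0, full_cycle=10.0, n_cycles=1),
    }


PROTOCOL_PRESETS = tuple(_presets())


def protocol_preset(name: str, include_endpoint: bool = True) -> FiringProtocol:
    presets = _presets()
    if name not in presets:
        raise InvalidParameterError(
            f"unknown preset {name!r}; choose from {sorted(presets)}")
    p = presets[name]
    if not include_endpoint:
        p = FiringProtocol(rate=p.rate, duty=p.duty, full_cycle=p.full_cycle,
                           n_cycles=p.n_cycles, t_start=p.t_start,
                           include_endpoint=False)
    return p


def terminal_from_dict(d: dict) -> TerminalParams:
    return TerminalParams(
        name=str(d.get("name", "unnamed")),
        n_atp={k: float(v) for k, v in d["n_atp"].items()},
        tau={k: float(v) for k, v in d["tau"].items()},
        base_rate=float(d["base_rate"]),
        volume=float(d["volume"]),
        mito_density=float(d["mito_density"]),
        max_rate_per_density=float(d.get("max_rate_per_density", 0.154)),
        phosphagen_present=bool(d.get("phosphagen_present", True)),
    )


def protocol_from_dict(d: dict) -> FiringProtocol:
    if "preset" in d:
        return protocol_preset(d["preset"], bool(d.get("include_endpoint", True)))
    return FiringProtocol(
        rate=float(d["rate"]),
        duty=float(d["duty"]),
        full_cycle=float(d["full_cycle"]),
        n_cycles=int(d.get("n_cycles", 1)),
        t_start=float(d.get("t_start", 0.0)),
        include_endpoint=bool(d.get("include_endpoint", True)),
    )


def load_config(path=None) -> dict:
    """Read a YAML configuration into typed objects.

    Returns a dict with keys ``terminal``, ``protocol``, ``initial``,
    ``k``, ``thermo``, ``equil``, ``turnover``, ``cap_exponent``, ``dt``
    and ``record_stride``.  With no path, the shipped defaults file
    (published constants, synthetic terminal) is read.
    """
    if path is None:
        text = resources.files("phosphagen").joinpath("data/defaults.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)

    c = raw.get("constants", {})
    p = raw.get("production", {})
    e = raw.get("equilibration", {})
    s = raw.get("simulation", {})
    ini = raw.get("initial", {})
    if p.get("turnover", "hill_inverse") != "hill_inverse":
        raise InvalidParameterError(
            "only the 'hill_inverse' turnover is configurable from YAML; pass "
            "a custom callable to ProductionModel from Python")
    return {
        "terminal": terminal_from_dict(raw["terminal"]),
        "protocol": protocol_from_dict(raw.get("protocol", {"preset": "locomotion"})),
        "initial": InitialConditions(
            atp0=float(ini.get("atp0", 2.16)),
            argp0=float(ini.get("argp0", 7.5)),
            arg0=float(ini.get("arg0", 3.3)),
            pi0=float(ini.get("pi0", 3.8)),
        ),
        "k": EquilibriumConstants(k_ad=float(c.get("k_ad", 1.0)),
                                  k_ph=float(c.get("k_ph", 39.6))),
        "thermo": ThermoConstants(
            delta_g0=float(c.get("delta_g0", -30.6)),
            gas_constant=float(c.get("gas_constant", 8.31445e-3)),
            temperature=float(c.get("temperature", 300.0)),
        ),
        "equil": EquilibrationOptions(
            tol=float(e.get("tol", 1e-10)),
            max_iter=int(e.get("max_iter", 100)),
            enforce_phosphagen=bool(raw["terminal"].get("phosphagen_present", True)),
        ),
        "turnover": HillInverseTurnover(k_half=float(p.get("k_half", 0.5)),
                                        h=float(p.get("h", 2.0))),
        "cap_exponent": float(p.get("cap_exponent", 5.0)),
        "dt": float(s.get("dt", 1e-4)),
        "record_stride": int(s.get("record_stride", 10)),
    }
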