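"""Run configuration: schema-validated YAML for network, protocol, engine
and analysis parameters, with content hashing for provenance."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from importlib import resources

import numpy as np
import yaml

from .circuits import (
    DEFAULT_WEIGHTS,
    NetworkSpec,
    StimulusProtocol,
    build_full_model,
    build_statocyst,
)

__all__ = ["RunConfig", "load_config", "builtin_config"]

_SCHEMA = {
    "network": {
        "builder": str,              # "full" | "statocyst"
        "hunting": bool,
        "src_src_weights": list,
        "overrides": dict,           # DEFAULT_WEIGHTS keys
    },
    "protocol": {
        "mode": str,                 # "routine" | "hunting"
        "pressed_src": (str, type(None)),
        "I_statolith": (int, float),
        "I_hunting": (int, float),
        "switch_events": list,       # [[t_ms, "SRCk"], ...]
        "duration": (int, float),
        "seed": int,
    },
    "engine": {
        "tol": (int, float),
        "dt_out": (int, float),
        "smooth_transmitter": bool,
    },
    "analysis": {
        "activation_threshold": (int, float),
        "envelope_ms": (int, float),
        "psth_window": list,
        "psth_bin": (int, float),
        "rate_kernel_ms": (int, float),
        "phaselock_min_len": int,
        "phaselock_min_active": int,
        "phaselock_min_occurrences": int,
        "episode_min_repeats": int,
        "lyapunov_n_exp": int,
        "lyapunov_t_total": (int, float),
        "transient_ms": (int, float),
    },
}

_DEFAULTS = {
    "network": {"builder": "full", "hunting": False, "src_src_weights": None,
                "overrides": {}},
    "protocol": {"mode": "routine", "pressed_src": "SRC1",
                 "I_statolith": DEFAULT_WEIGHTS["I_statolith"],
                 "I_hunting": DEFAULT_WEIGHTS["I_hunting"],
                 "switch_events": [], "duration": 60000.0, "seed": 0},
    "engine": {"tol": 1e-6, "dt_out": 0.5, "smooth_transmitter": False},
    "analysis": {"activation_threshold": 0.0, "envelope_ms": 400.0,
                 "psth_window": [0.0, 4000.0],
                 "psth_bin": 100.0, "rate_kernel_ms": 100.0,
                 "phaselock_min_len": 3, "phaselock_min_active": 4,
                 "phaselock_min_occurrences": 30, "episode_min_repeats": 3,
                 "lyapunov_n_exp": 4, "lyapunov_t_total": 60000.0,
                 "transient_ms": 20000.0},
}


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    network: dict
    protocol: dict
    engine: dict
    analysis: dict

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        cfg = {}
        unknown = set(raw) - set(_SCHEMA)
        if unknown:
            raise ConfigError(f"unknown config section(s): {sorted(unknown)}")
        for section, schema in _SCHEMA.items():
            merged = dict(_DEFAULTS[section])
            given = raw.get(section, {}) or {}
            for key, value in given.items():
                if key not in schema:
                    raise ConfigError(f"unknown key {section}.{key}")
                expected = schema[key]
                if value is not None and not isinstance(value, expected):
                    raise ConfigError(
                        f"{section}.{key}: expected {expected}, got {type(value).__name__}"
                    )
                merged[key] = value
            cfg[section] = merged
        self = cls(**cfg)
        self.validate()
        return self

    def validate(self) -> None:
        if self.network["builder"] not in ("full", "statocyst"):
            raise ConfigError("network.builder must be 'full' or 'statocyst'")
        if self.protocol["mode"] not in ("routine", "hunting"):
            raise ConfigError("protocol.mode must be 'routine' or 'hunting'")
        if self.engine["tol"] <= 0:
            raise ConfigError("engine.tol must be positive")
        w = self.network["src_src_weights"]
        if w is not None and len(w) != 12:
            raise ConfigError("network.src_src_weights must have 12 entries")

    # -- builders -----------------------------------------------------------

    def build_network(self) -> NetworkSpec:
        hunting = self.protocol["mode"] == "hunting" or self.network["hunting"]
        ov = dict(self.network["overrides"])
        unknown = set(ov) - set(DEFAULT_WEIGHTS)
        if unknown:
            raise ConfigError(f"unknown weight override(s): {sorted(unknown)}")
        merged = {**DEFAULT_WEIGHTS, **ov}
        w = self.network["src_src_weights"] or merged["src_src"]
        if self.network["builder"] == "statocyst":
            return build_statocyst(weights=w, hunting=hunting,
                                   h_weight=merged["h_src"])
        from .circuits import build_cerebral_interface, build_wing_cpg, compose
        return compose(
            build_statocyst(weights=w, hunting=hunting, h_weight=merged["h_src"]),
            build_cerebral_interface(
                g_src_cg=merged["src_cg"], g_cg_cg=merged["cg_cg"],
                g_cg_cg3=merged["cg_cg3"], g_cg3_cpg=merged["cg3_cpg"],
                E_src_cg=merged["src_cg_E"]),
            build_wing_cpg(
                g_half_inh=merged["cpg_half_inh"], g_cross_inh=merged["cpg_cross_inh"],
                g_drive=merged["cpg_drive"], g_gap=merged["cpg_gap"]),
        )

    def build_protocol(self) -> StimulusProtocol:
        p = self.protocol
        hunting = p["mode"] == "hunting"
        return StimulusProtocol(
            duration=float(p["duration"]),
            pressed_src=None if hunting else p["pressed_src"],
            I_statolith=float(p["I_statolith"]),
            switch_events=tuple((float(t), s) for t, s in p["switch_events"]),
            hunting_on=hunting,
            I_hunting=float(p["I_hunting"]),
            seed=int(p["seed"]),
        )

    # -- provenance ---------------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)


def builtin_config(name: str) -> RunConfig:
    """Shipped canonical configs: 'routine' or 'hunting'."""
    text = resources.files("clionesim.data").joinpath(f"{name}.yaml").read_text()
    return RunConfig.from_dict(yaml.safe_load(text))
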