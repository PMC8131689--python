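"""Run configuration: YAML loading, defaults, and typed sub-configs."""

from __future__ import annotations

import copy
from pathlib import Path

import yaml

from . import hrm, reference
from .synthetic_data import GeneratorConfig

DEFAULTS: dict = {
    "seed": 0,
    "outdir": "cacaoflow_run",
    "generator": {
        "n_days": 14,
        "start": "2015-01-13",
        "interval_min": 1,
        "n_plants": 4,
        "n_flow_rows": reference.N_FIT + reference.N_VALIDATION,
        "noise_sd": 0.015,
        "plant_effect_sd": 0.005,
        "day_effect_sd": 0.005,
    },
    "probe": {"k_cm2_s": 0.0025, "x_cm": 0.6, "depths_mm": [5.0, 20.0]},
    "wood": {"rho_b": 500.0, "rho_s": 1000.0, "m_c": 1.0, "C_w": 1200.0, "C_s": 4186.0, "S_cm2": 40.0},
    "wound": {"coeffs": [1.0, 0.0, 0.0]},
    "baseline": {"window": None},
    "model": {"method": "reml", "nested": False, "alpha": 0.05},
    "split": {"fraction": reference.N_VALIDATION / (reference.N_FIT + reference.N_VALIDATION), "mode": "chronological"},
}


class ConfigError(ValueError):
    """Bad or missing configuration key (CLI exit code 2)."""


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge the YAML file at ``path`` (if any) over the defaults.

    Unknown keys raise :class:`ConfigError` naming the key, so typos fail
    loudly rather than silently falling back to a default.
    """
    cfg = copy.deepcopy(DEFAULTS)
    user = {}
    if path is not None:
        text = Path(path).read_text()
        user = yaml.safe_load(text) or {}
    if overrides:
        user = _merge(user, overrides)
    for key, val in user.items():
        if key not in cfg:
            raise ConfigError(f"unknown config key {key!r}")
        if isinstance(cfg[key], dict):
            if not isinstance(val, dict):
                raise ConfigError(f"config key {key!r} must be a mapping")
            for sub in val:
                if sub not in cfg[key]:
                    raise ConfigError(f"unknown config key {key}.{sub}")
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _merge(base: dict, over: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in over.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def generator_config(cfg: dict) -> GeneratorConfig:
    g = cfg["generator"]
    return GeneratorConfig(
        seed=int(cfg["seed"]),
        n_days=int(g["n_days"]),
        start=str(g["start"]),
        interval_min=int(g["interval_min"]),
        n_plants=int(g["n_plants"]),
        n_flow_rows=int(g["n_flow_rows"]),
        noise_sd=float(g["noise_sd"]),
        plant_effect_sd=float(g["plant_effect_sd"]),
        day_effect_sd=float(g["day_effect_sd"]),
    )


def probe_geometry(cfg: dict) -> hrm.ProbeGeometry:
    p = cfg["probe"]
    return hrm.ProbeGeometry(k=float(p["k_cm2_s"]), x=float(p["x_cm"]), depths=tuple(p["depths_mm"]))


def sapwood_properties(cfg: dict) -> hrm.SapwoodProperties:
    w = cfg["wood"]
    return hrm.SapwoodProperties(
        rho_b=float(w["rho_b"]), rho_s=float(w["rho_s"]), m_c=float(w["m_c"]),
        C_w=float(w["C_w"]), C_s=float(w["C_s"]), S=float(w["S_cm2"]),
    )
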