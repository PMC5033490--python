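"""YAML-backed configuration: every classification table is overridable data.

``default_config()`` returns the package defaults as a plain nested dict;
``load_config(path)`` deep-merges a user YAML file over them.  Modules take
an optional ``config`` argument and fall back to the defaults, so library
use never requires a file on disk.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import constants as C


def default_config() -> dict[str, Any]:
    return {
        "seqdis": {
            "hydropathy_scale": dict(C.KYTE_DOOLITTLE),
            "ch_window": C.CH_WINDOW,
            "ch_boundary": {"slope": C.CH_SLOPE, "intercept": C.CH_INTERCEPT,
                            "eps": C.CH_BOUNDARY_EPS},
            "classes": {
                "disorder_promoting": sorted(C.DISORDER_PROMOTING),
                "order_promoting": sorted(C.ORDER_PROMOTING),
                "neutral": sorted(C.DISORDER_NEUTRAL),
            },
            "n_boot": 1000,
        },
        "hydro": {
            "state_laws": {k: list(v) for k, v in C.STATE_LAWS.items()},
            "ff0_tracks": {k: [list(p) for p in v] for k, v in C.FF0_TRACKS.items()},
            "ff0_elongated_threshold": C.FF0_ELONGATED_THRESHOLD,
            "rg_rs": {"sphere": C.RG_RS_SPHERE, "sphere_tol": C.RG_RS_SPHERE_TOL,
                      "oblate": list(C.RG_RS_OBLATE), "prolate": list(C.RG_RS_PROLATE)},
        },
        "cdspec": {
            "ht_max": C.CD_HT_MAX,
            "regions": copy.deepcopy(C.CD_REGIONS),
        },
        "saxs": {
            "srg_max": C.GUINIER_SRG_MAX,
            "flory": {"prefactor": C.FLORY_PREFACTOR, "exponent": C.FLORY_EXPONENT},
        },
        "ensemble": {
            "bond": C.CA_BOND,
            "clash_radius": C.CA_CLASH_RADIUS,
            "angle_range": list(C.CA_ANGLE_RANGE),
            "pool_size": 10000,
            "ensemble_size": 20,
            "population": 100,
            "generations": 200,
            "mutation_rate": 0.05,
        },
    }


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for key, val in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(val, Mapping):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def load_config(path: str | Path | None = None) -> dict[str, Any]:
    """Package defaults, optionally deep-merged with a YAML override file."""
    cfg = default_config()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = _deep_merge(cfg, override)
    return cfg
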