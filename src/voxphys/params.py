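"""Parameter handling for the voice synthesizer and analysis chain.

All physical constants live in a versioned YAML file (``assets/params_default.yaml``)
so every number that enters the physics is auditable and overridable.  The loader
validates completeness and basic unit sanity; modules receive plain nested dicts.
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from pathlib import Path

import yaml

_REQUIRED_SECTIONS = (
    "tissues",
    "posture",
    "body_cover",
    "flow",
    "tract",
    "simulation",
    "conditioning",
    "features",
    "corrections",
    "grid",
    "regression",
    "ibif",
)

_TISSUE_FIELDS = ("L0", "area", "sigma_am", "eps_m", "b_act", "sigma0", "B", "tau_s", "tau_e")
_MUSCLES = ("LCA", "IA", "PCA", "CT", "TA")
_CONNECTIVE = ("LIG", "MUC")


class ParameterError(ValueError):
    """Raised when a parameter file is incomplete or non-physical."""


def _asset_path(name: str) -> Path:
    return Path(resources.files("voxphys").joinpath("assets", name))


def load_params(path: str | Path | None = None) -> dict:
    """Load and validate a parameter file; ``None`` loads the packaged defaults."""
    if path is None:
        path = _asset_path("params_default.yaml")
    with open(path) as fh:
        params = yaml.safe_load(fh)
    _coerce_numbers(params)
    validate_params(params)
    return params


def _coerce_numbers(node) -> None:
    """Convert numeric-looking string leaves to float in place.

    YAML 1.1 only recognizes exponent literals with a signed exponent
    (``1.0e+6``); plain ``1.0e6`` loads as a string, which would otherwise
    poison numeric arrays downstream.
    """
    if isinstance(node, dict):
        for k, v in node.items():
            if isinstance(v, (dict, list)):
                _coerce_numbers(v)
            elif isinstance(v, str):
                try:
                    node[k] = float(v)
                except ValueError:
                    pass


def default_params() -> dict:
    return load_params(None)


def merge_overrides(params: dict, overrides: dict) -> dict:
    """Deep-merge ``overrides`` into a copy of ``params``."""
    out = copy.deepcopy(params)

    def _merge(dst, src):
        for k, v in src.items():
            if isinstance(v, dict) and isinstance(dst.get(k), dict):
                _merge(dst[k], v)
            else:
                dst[k] = v

    _merge(out, overrides)
    validate_params(out)
    return out


def validate_params(params: dict) -> None:
    for sec in _REQUIRED_SECTIONS:
        if sec not in params:
            raise ParameterError(f"missing parameter section: {sec}")
    tissues = params["tissues"]
    for name in _MUSCLES + _CONNECTIVE:
        if name not in tissues:
            raise ParameterError(f"missing tissue block: {name}")
        block = tissues[name]
        for field in _TISSUE_FIELDS:
            if field not in block:
                raise ParameterError(f"tissue {name}: missing field {field}")
            block[field] = float(block[field])
        if block["L0"] <= 0 or block["area"] <= 0:
            raise ParameterError(f"tissue {name}: rest length and area must be > 0")
    for name in _MUSCLES:
        if tissues[name]["sigma_am"] <= 0:
            raise ParameterError(f"muscle {name}: active stress ceiling must be > 0")
    for name in _CONNECTIVE:
        if tissues[name]["sigma_am"] != 0.0:
            raise ParameterError(f"{name}: connective tissue must have zero active stress")
    bc = params["body_cover"]
    for field in ("L0", "T0", "Dc0", "Db0", "rho_tissue", "mu_cover", "mu_body"):
        if float(bc[field]) <= 0:
            raise ParameterError(f"body_cover.{field} must be > 0")
    att = float(params["tract"]["attenuation"])
    if not 0.0 < att <= 1.0:
        raise ParameterError("tract.attenuation must lie in (0, 1]")


def area_function_path(name: str) -> Path:
    """Path to a packaged area-function CSV asset."""
    return _asset_path(name)
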