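"""Strict JSON/YAML (de)serialization with unit-suffixed keys.

Every concentration, rate or constant is stored under a key carrying its
unit (``l_tot_mM``, ``k_d_uM``, ``r2_f_per_s``), so files are
self-documenting and unit mistakes surface as schema errors.  Unknown keys
are rejected.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Any

import yaml

from .echo_processing import AcquisitionParams
from .equilibria import BindingConstants, SampleComposition
from .relaxation_model import OrthohydrogenModel, RelaxationRates
from .synthetic_data import ScenarioConfig

__all__ = [
    "to_dict",
    "from_dict",
    "dump_yaml",
    "load_yaml",
    "dump_json",
    "load_json",
    "SchemaError",
]


class SchemaError(ValueError):
    """Raised on unknown keys or malformed serialized objects."""


# (dataclass field, serialized key) per type; order defines output order
_SCHEMAS: dict[type, list[tuple[str, str]]] = {
    SampleComposition: [
        ("c_tot", "c_tot_mM"),
        ("l_tot", "l_tot_mM"),
        ("col_tot", "col_tot_mM"),
        ("p_tot", "p_tot_mM"),
        ("s_tot", "s_tot_mM"),
        ("volume", "volume_mL"),
    ],
    BindingConstants: [
        ("k_eq", "k_eq_per_mM"),
        ("k_d", "k_d_uM"),
        ("k_d2", "k_d2_uM"),
    ],
    RelaxationRates: [
        ("r2_f", "r2_f_per_s"),
        ("r2_cl", "r2_cl_per_s"),
        ("r2_pl", "r2_pl_per_s"),
        ("r2_ortho", "r2_ortho_per_s"),
    ],
    OrthohydrogenModel: [
        ("amplitude_ratio", "amplitude_ratio"),
        ("r2_ortho", "r2_ortho_per_s"),
        ("sign", "sign"),
    ],
    AcquisitionParams: [
        ("tau", "tau_s"),
        ("n_echoes", "n_echoes"),
        ("p90", "p90_s"),
        ("dwell", "dwell_s"),
        ("larmor_hz", "larmor_hz"),
        ("n_samples", "n_samples"),
    ],
}

# ScenarioConfig nests the typed blocks above plus scalars
_SCENARIO_SCALARS = [
    ("snr", "snr"),
    ("seed", "seed"),
    ("replicates", "replicates"),
    ("amplitude", "amplitude_au"),
    ("offset_hz", "offset_hz"),
    ("t2_star", "t2_star_s"),
    ("shot_sd", "shot_sd"),
]


def _encode(v: Any) -> Any:
    if isinstance(v, float) and math.isinf(v):
        return ".inf" if v > 0 else "-.inf"
    return v


def _decode(v: Any) -> Any:
    if v == ".inf":
        return math.inf
    if v == "-.inf":
        return -math.inf
    return v


def to_dict(obj: Any) -> dict[str, Any]:
    """Serialize a supported object to a plain dict with unit-suffixed keys."""
    if isinstance(obj, ScenarioConfig):
        d: dict[str, Any] = {
            "composition": to_dict(obj.composition),
            "constants": to_dict(obj.constants),
            "rates": to_dict(obj.rates),
            "ortho": to_dict(obj.ortho) if obj.ortho is not None else None,
            "acquisition": to_dict(obj.acquisition),
        }
        for attr, key in _SCENARIO_SCALARS:
            d[key] = _encode(getattr(obj, attr))
        return d
    schema = _SCHEMAS.get(type(obj))
    if schema is None:
        raise SchemaError(f"no serialization schema for {type(obj).__name__}")
    return {key: _encode(getattr(obj, attr)) for attr, key in schema}


def from_dict(cls: type, data: dict[str, Any]) -> Any:
    """Deserialize ``data`` into ``cls``; unknown keys raise :class:`SchemaError`."""
    if cls is ScenarioConfig:
        allowed = {"composition", "constants", "rates", "ortho", "acquisition"} | {
            key for _, key in _SCENARIO_SCALARS
        }
        unknown = set(data) - allowed
        if unknown:
            raise SchemaError(f"unknown keys for ScenarioConfig: {sorted(unknown)}")
        kwargs: dict[str, Any] = {
            "composition": from_dict(SampleComposition, data["composition"]),
            "constants": from_dict(BindingConstants, data["constants"]),
            "rates": from_dict(RelaxationRates, data["rates"]),
        }
        if data.get("ortho") is not None:
            kwargs["ortho"] = from_dict(OrthohydrogenModel, data["ortho"])
        if "acquisition" in data:
            kwargs["acquisition"] = from_dict(AcquisitionParams, data["acquisition"])
        for attr, key in _SCENARIO_SCALARS:
            if key in data:
                kwargs[attr] = _decode(data[key])
        return ScenarioConfig(**kwargs)
    schema = _SCHEMAS.get(cls)
    if schema is None:
        raise SchemaError(f"no serialization schema for {cls.__name__}")
    key_to_attr = {key: attr for attr, key in schema}
    unknown = set(data) - set(key_to_attr)
    if unknown:
        raise SchemaError(f"unknown keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {key_to_attr[k]: _decode(v) for k, v in data.items() if v is not None}
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"invalid {cls.__name__} payload: {exc}") from exc


def dump_yaml(obj: Any, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(obj), sort_keys=False))


def load_yaml(cls: type, path: str | Path) -> Any:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"expected a mapping in {path}")
    return from_dict(cls, data)


def dump_json(obj: Any, path: str | Path) -> None:
    Path(path).write_text(json.dumps(to_dict(obj), indent=2))


def load_json(cls: type, path: str | Path) -> Any:
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise SchemaError(f"expected a JSON object in {path}")
    return from_dict(cls, data)
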