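"""Configuration files and tabular output.

Configs are YAML or JSON mappings; unknown keys are rejected (no silent
typos), missing optional keys are filled with the model defaults (``g = 1``,
``extinction_threshold = 5``), and range violations name the offending key.
Tables are written as UTF-8 CSV with a deterministic column order and
floats at 12 significant digits; a sibling ``<name>.meta.json`` records the
resolved configuration, seed, package version and a timestamp so that every
run is reproducible from its outputs.  No biological sequence or variant
formats are involved anywhere in this package: all I/O is parameters in,
tables out.
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Mapping

import pandas as pd
import yaml

__all__ = ["ConfigError", "load_config", "write_table", "COMMAND_SCHEMAS"]


class ConfigError(ValueError):
    """A configuration file failed validation."""


def _positive(x) -> bool:
    return x > 0


def _unit_interval(x) -> bool:
    return 0 <= x < 1


# key -> (default or REQUIRED, validator or None, description of the constraint)
_REQUIRED = object()

_CHAIN_KEYS: dict[str, tuple] = {
    "N": (_REQUIRED, lambda x: int(x) == x and x >= 2, "integer >= 2"),
    "f": (1.0, _positive, "> 0"),
    "g": (1.0, _positive, "> 0"),
    "theta": (0.0, lambda x: x > -1, "> -1"),
    "regime": ("unbiased", lambda x: x in ("unbiased", "payoff", "conformity"),
               "one of unbiased|payoff|conformity"),
}

_RESCUE_KEYS: dict[str, tuple] = {
    "N0": (_REQUIRED, lambda x: int(x) == x and x >= 1, "integer >= 1"),
    "i0": (1, lambda x: int(x) == x and x >= 0, "integer >= 0"),
    "q": (_REQUIRED, _unit_interval, "in [0, 1)"),
    "r": (_REQUIRED, _unit_interval, "in [0, 1)"),
    "f": (1.0, _positive, "> 0"),
    "g": (1.0, _positive, "> 0"),
    "extinction_threshold": (5, lambda x: int(x) == x and x >= 0, "integer >= 0"),
    "max_steps": (None, lambda x: x is None or (int(x) == x and x >= 1), "integer >= 1"),
    "reps": (500, lambda x: int(x) == x and x >= 1, "integer >= 1"),
    "seed": (None, lambda x: x is None or int(x) == x, "integer"),
}

COMMAND_SCHEMAS: dict[str, dict[str, tuple]] = {
    "fixation": {**_CHAIN_KEYS, "mode": ("de-novo", lambda x: x in ("de-novo", "standing"),
                                         "one of de-novo|standing"),
                 "pre_regime": ("unbiased", lambda x: x in ("unbiased", "conformity"),
                                "one of unbiased|conformity")},
    "spectrum": {**_CHAIN_KEYS, "mu": (_REQUIRED, _positive, "> 0")},
    "foresight": {
        "N": (_REQUIRED, lambda x: int(x) == x and x >= 2, "integer >= 2"),
        "g": (1.0, _positive, "> 0"),
        "f_sv": (_REQUIRED, None, "range spec"),
        "f_dn": (_REQUIRED, None, "range spec"),
        "pre_regime": ("unbiased", lambda x: x in ("unbiased", "conformity"),
                       "one of unbiased|conformity"),
        "theta": (0.0, lambda x: x > -1, "> -1"),
    },
    "rescue": _RESCUE_KEYS,
    "validate": {**_CHAIN_KEYS,
                 "reps": (10_000, lambda x: int(x) == x and x >= 100, "integer >= 100"),
                 "seed": (0, lambda x: int(x) == x, "integer")},
}


def load_config(path: str | Path, command: str = "fixation") -> dict[str, Any]:
    """Load and validate a YAML/JSON config for one CLI command.

    Unknown keys raise :class:`ConfigError` naming the key; defaults are
    filled for anything optional that is absent.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ConfigError(f"config {path} must be a mapping, got {type(raw).__name__}")
    try:
        schema = COMMAND_SCHEMAS[command]
    except KeyError:
        raise ConfigError(f"no config schema for command {command!r}") from None

    unknown = set(raw) - set(schema)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} for command {command!r}; "
            f"allowed: {sorted(schema)}"
        )
    resolved: dict[str, Any] = {}
    for key, (default, check, constraint) in schema.items():
        if key in raw:
            value = raw[key]
        elif default is _REQUIRED:
            raise ConfigError(f"missing required config key {key!r} for {command!r}")
        else:
            value = default
        if key in raw and check is not None and not check(value):
            raise ConfigError(f"config key {key!r}={value!r} violates constraint: {constraint}")
        resolved[key] = value
    return resolved


def write_table(
    records: Iterable[Mapping[str, Any]] | pd.DataFrame,
    path: str | Path,
    metadata: Mapping[str, Any] | None = None,
    columns: list[str] | None = None,
) -> Path:
    """Write records to CSV (12 significant digits) plus a JSON metadata sidecar.

    The CSV body is a deterministic function of the records, so two runs
    with the same configuration and seed produce byte-identical tables; the
    timestamp lives only in the sidecar.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        frame = records.copy()
    else:
        records = list(records)
        frame = pd.DataFrame(records, columns=columns if records == [] else None)
    if columns is not None and len(frame):
        frame = frame[columns]
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.12g", encoding="utf-8", lineterminator="\n")

    from . import __version__

    meta = {
        "package": "culturesweep",
        "version": __version__,
        "created": datetime.now(timezone.utc).isoformat(),
        **(dict(metadata) if metadata else {}),
    }
    meta_path = path.with_suffix(path.suffix + ".meta.json") if path.suffix != ".json" \
        else path.with_name(path.stem + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, default=str) + "\n", encoding="utf-8")
    return path
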