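"""Configuration files, delimited-table output and run provenance.

Configs and parameter sets are flat namespaced key–value text::

    metabolic.k8 = 8.0
    electro.g_NaAla = 50
    run.seed = 1

Tables are written as comma-separated UTF-8 text with LF endings and a
``.meta`` sidecar recording the effective configuration, so every output
is reproducible from its sidecar.
"""

from __future__ import annotations

import difflib
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import pandas as pd

from .metabolic import MetabolicParameters
from .electro import ElectroParameters

__all__ = [
    "RunConfig",
    "ConfigError",
    "load_config",
    "parse_kv_text",
    "format_kv_text",
    "save_params",
    "load_params",
    "write_table",
]

_RUN_KEYS: Dict[str, float] = {
    "seed": 0,
    "tol": 1e-8,
    "t_max": 2.0e4,
    "t_end_ms": 240000.0,
    "burn_in": 0.5,
}


class ConfigError(ValueError):
    """Raised for unparseable or unknown configuration entries."""


@dataclass
class RunConfig:
    """Validated run configuration with defaults filled in."""

    metabolic: MetabolicParameters = field(default_factory=MetabolicParameters)
    electro: ElectroParameters = field(default_factory=ElectroParameters)
    run: Dict[str, float] = field(default_factory=lambda: dict(_RUN_KEYS))

    def as_flat_dict(self) -> Dict[str, float]:
        out: Dict[str, float] = {}
        for k, v in self.metabolic.as_dict().items():
            out[f"metabolic.{k}"] = v
        for k, v in self.electro.as_dict().items():
            out[f"electro.{k}"] = v
        for k, v in self.run.items():
            out[f"run.{k}"] = v
        return out

    def digest(self) -> str:
        payload = json.dumps(self.as_flat_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]


def parse_kv_text(text: str) -> Dict[str, float]:
    """Parse ``key = value`` lines; '#' starts a comment."""
    out: Dict[str, float] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"line {lineno}: expected 'key = value', got {raw!r}")
        key, _, val = line.partition("=")
        key = key.strip()
        try:
            out[key] = float(val.strip())
        except ValueError:
            raise ConfigError(
                f"line {lineno}: value for {key!r} is not numeric: {val.strip()!r}"
            ) from None
    return out


def format_kv_text(entries: Dict[str, float]) -> str:
    lines = [f"{k} = {v!r}" for k, v in entries.items()]
    return "\n".join(lines) + "\n"


def _suggest(key: str, valid) -> str:
    match = difflib.get_close_matches(key, list(valid), n=1)
    return f"; did you mean {match[0]!r}?" if match else ""


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a flat key–value config file.

    An empty file yields all defaults.  Unknown keys raise
    :class:`ConfigError` naming the key and the nearest valid name.
    """
    text = Path(path).read_text(encoding="utf-8")
    entries = parse_kv_text(text)
    cfg = RunConfig()
    met_valid = set(cfg.metabolic.as_dict())
    ele_valid = set(cfg.electro.as_dict())
    for key, val in entries.items():
        ns, _, name = key.partition(".")
        if ns == "metabolic" and name in met_valid:
            cfg.metabolic[name] = val
        elif ns == "electro" and name in ele_valid:
            cfg.electro[name] = val
        elif ns == "run" and name in _RUN_KEYS:
            cfg.run[name] = val
        else:
            if ns == "metabolic":
                valid = (f"metabolic.{k}" for k in met_valid)
            elif ns == "electro":
                valid = (f"electro.{k}" for k in ele_valid)
            elif ns == "run":
                valid = (f"run.{k}" for k in _RUN_KEYS)
            else:
                valid = (
                    [f"metabolic.{k}" for k in met_valid]
                    + [f"electro.{k}" for k in ele_valid]
                    + [f"run.{k}" for k in _RUN_KEYS]
                )
            raise ConfigError(f"unknown key {key!r}{_suggest(key, valid)}")
    return cfg


def save_params(params: MetabolicParameters | ElectroParameters, path: str | Path,
                namespace: Optional[str] = None) -> None:
    """Write a parameter set as flat namespaced key–value text (lossless)."""
    if namespace is None:
        namespace = "metabolic" if isinstance(params, MetabolicParameters) else "electro"
    entries = {f"{namespace}.{k}": v for k, v in params.as_dict().items()}
    Path(path).write_text(format_kv_text(entries), encoding="utf-8")


def load_params(path: str | Path) -> Tuple[str, Dict[str, float]]:
    """Read a parameter file; returns (namespace, {name: value})."""
    entries = parse_kv_text(Path(path).read_text(encoding="utf-8"))
    namespaces = {k.partition(".")[0] for k in entries}
    if len(namespaces) != 1:
        raise ConfigError(f"expected one namespace, found {sorted(namespaces)}")
    ns = namespaces.pop()
    return ns, {k.partition(".")[2]: v for k, v in entries.items()}


def write_table(df: pd.DataFrame, path: str | Path,
                provenance: Optional[Dict[str, object]] = None) -> None:
    """Write a scan/time-course table as CSV plus a ``.meta`` sidecar."""
    path = Path(path)
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")
    if provenance is not None:
        meta = path.with_suffix(path.suffix + ".meta")
        lines = [f"{k}: {json.dumps(v, sort_keys=True, default=str)}"
                 for k, v in sorted(provenance.items())]
        meta.write_text("\n".join(lines) + "\n", encoding="utf-8")
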