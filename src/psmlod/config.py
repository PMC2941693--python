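"""Flat key-value configuration files.

Format: one ``key = value`` pair per line, ``#`` comments, blank lines
ignored.  Keys mirror the ``ScoringParams`` field names; CLI flags
override config values.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

from .pipeline import ScoringParams

__all__ = ["read_config", "params_from_config"]


def read_config(path: str | Path) -> dict[str, str]:
    """Parse a flat key=value config file into a string dict."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


def _coerce(value: str, typ) -> object:
    if typ is bool:
        low = value.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ValueError(f"cannot parse boolean from {value!r}")
    return typ(value)


def params_from_config(
    config: dict[str, str], overrides: dict[str, object] | None = None
) -> ScoringParams:
    """Build ScoringParams from a config dict, then apply CLI overrides."""
    params = ScoringParams()
    known = {f.name: f.type for f in fields(ScoringParams)}
    for key, value in config.items():
        if key not in known:
            raise ValueError(f"unknown config key {key!r}")
        current = getattr(params, key)
        setattr(params, key, _coerce(value, type(current)))
    for key, value in (overrides or {}).items():
        if value is not None:
            setattr(params, key, value)
    return params
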