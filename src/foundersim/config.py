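"""Configuration loading and small parameter utilities.

A configuration is a flat key = value text file whose keys are the model's
parameter symbols (``F``, ``M``, ``gamma``, ``lambda``, ``Y``, ``tau``,
``r``, ``K``, ``m``, ``sr``, ``e``, ``n``, ``s``, ``delta``, ``c``,
``bank``, ``replicates``, ``seed``).  Command-line flags override file
values; anything unspecified falls back to the baseline defaults of
:class:`~foundersim.engine.SimulationParams`.
"""

from __future__ import annotations

from pathlib import Path
from typing import Any, Mapping

from .engine import SimulationParams

__all__ = ["load_config", "parse_config_text", "individuals_per_liter"]

# config key -> SimulationParams field
_KEY_ALIASES = {
    "lambda": "lam",
    "bank": "bank_present",
}

_INT_FIELDS = {"F", "M", "Y", "n", "s", "replicates", "seed"}
_BOOL_FIELDS = {"bank_present"}
_FLOAT_FIELDS = {"tau", "r", "K", "m", "sr", "e", "delta", "c",
                 "gamma", "lam"}
_ALL_FIELDS = _INT_FIELDS | _BOOL_FIELDS | _FLOAT_FIELDS

_TRUE = {"true", "yes", "on", "1"}
_FALSE = {"false", "no", "off", "0"}


def _coerce(field: str, raw: Any) -> Any:
    if isinstance(raw, str):
        raw = raw.strip()
    if field in _BOOL_FIELDS:
        if isinstance(raw, bool):
            return raw
        low = str(raw).lower()
        if low in _TRUE:
            return True
        if low in _FALSE:
            return False
        raise ValueError(f"cannot parse boolean value {raw!r}")
    if field in _INT_FIELDS:
        # accept scientific notation for counts (e.g. M = 1e5)
        val = float(raw)
        if val != int(val):
            raise ValueError(f"{field} must be an integer, got {raw!r}")
        return int(val)
    return float(raw)


def parse_config_text(text: str) -> dict[str, Any]:
    """Parse flat ``key = value`` lines; '#' starts a comment."""
    values: dict[str, Any] = {}
    unknown: list[str] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected 'key = value', got {line!r}")
        key, raw = (part.strip() for part in line.split("=", 1))
        field = _KEY_ALIASES.get(key, key)
        if field not in _ALL_FIELDS:
            unknown.append(key)
            continue
        values[field] = _coerce(field, raw)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    return values


def load_config(path: str | Path | None = None,
                **overrides: Any) -> SimulationParams:
    """Build validated :class:`SimulationParams` from a file and overrides.

    ``overrides`` (typically CLI flags) take precedence over file values.
    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offender.
    """
    values: dict[str, Any] = {}
    if path is not None:
        values.update(parse_config_text(Path(path).read_text()))
    unknown = []
    for key, raw in overrides.items():
        if raw is None:
            continue
        field = _KEY_ALIASES.get(key, key)
        if field not in _ALL_FIELDS:
            unknown.append(key)
            continue
        values[field] = _coerce(field, raw)
    if unknown:
        raise ValueError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    return SimulationParams(**values)


def individuals_per_liter(K: float, area_m2: float = 200.0,
                          depth_m: float = 1.0) -> float:
    """Density (individuals per liter) of ``K`` individuals in a pond.

    The reference habitat is a small 200 m^2 pond of 1 m depth, so
    K = 2e7 corresponds to 100 individuals per liter.
    """
    liters = area_m2 * depth_m * 1000.0
    return K / liters
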