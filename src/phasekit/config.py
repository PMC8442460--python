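"""YAML configuration with defaults, validation and flag overrides.

A single flat mapping configures every stage; unknown keys and type
mismatches are rejected eagerly so a misspelled option never silently
falls back to a default. Command-line flags take precedence over the
file.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any, Mapping

import yaml


@dataclass
class Config:
    """Validated parameter set (flat; stage inputs are CLI arguments).

    ``min_sv_read_support`` and ``min_snv_read_support`` are recorded
    for provenance — they parameterize the upstream callers, not any
    stage here.
    """

    conflict_threshold: int = 0
    min_tagged_reads: int = 1
    het_only: bool = True
    overlap_fallback: bool = False
    filter_mode: str = "soft"
    bins: int = 200
    smooth_window: int = 9
    tolerance: float = 0.05
    min_snps: int = 10
    orient_h1: str = "paternal"
    merge_confirmed: bool = False
    flip: bool = True
    llr_cutoff: float = 2.0
    rnames_key: str = "RNAMES"
    sample: str = "SAMPLE"
    seed: int = 0
    min_sv_read_support: int = 3
    min_snv_read_support: int = 2

    def __post_init__(self) -> None:
        if self.conflict_threshold < 0:
            raise ValueError("conflict_threshold must be >= 0")
        if not 0.0 <= self.tolerance <= 1.0:
            raise ValueError("tolerance must be in [0, 1]")
        if self.min_snps < 1:
            raise ValueError("min_snps must be >= 1")
        if self.llr_cutoff < 0:
            raise ValueError("llr_cutoff must be >= 0")
        if self.filter_mode not in ("soft", "hard"):
            raise ValueError("filter_mode must be 'soft' or 'hard'")
        if self.orient_h1 not in ("paternal", "maternal"):
            raise ValueError("orient_h1 must be 'paternal' or 'maternal'")


_FIELD_TYPES = {f.name: f.type for f in fields(Config)}


def _coerce(key: str, value: Any) -> Any:
    expected = _FIELD_TYPES[key]
    if expected == "int":
        if isinstance(value, bool) or not isinstance(value, int):
            raise ValueError(f"config key {key!r}: expected integer, got {value!r}")
        return value
    if expected == "float":
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ValueError(f"config key {key!r}: expected number, got {value!r}")
        return float(value)
    if expected == "bool":
        if not isinstance(value, bool):
            raise ValueError(f"config key {key!r}: expected boolean, got {value!r}")
        return value
    if not isinstance(value, str):
        raise ValueError(f"config key {key!r}: expected string, got {value!r}")
    return value


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> Config:
    """Build a Config from an optional YAML file plus flag overrides.

    The file must be a flat mapping of known keys; ``overrides``
    entries with value ``None`` (unset flags) are ignored.
    """
    values: dict[str, Any] = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        for key, value in data.items():
            if key not in _FIELD_TYPES:
                raise ValueError(f"{path}: unknown config key {key!r}")
            values[key] = _coerce(key, value)
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        if key not in _FIELD_TYPES:
            raise ValueError(f"unknown config key {key!r}")
        values[key] = _coerce(key, value)
    return Config(**values)
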