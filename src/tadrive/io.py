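"""Configuration parsing and result serialization.

Configs are flat ``key = value`` text files (``#`` comments allowed).
Command-line flags override config-file values; the override is logged.
Tabular results go to TSV with a ``#``-prefixed metadata header; scalar
results to JSON. Floats are serialized with ``repr``, which round-trips
IEEE doubles exactly.
"""

from __future__ import annotations

import datetime
import json
import logging
import sys
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Dict, IO, Iterable, List, Optional, Sequence, Union

logger = logging.getLogger(__name__)

#: recognized configuration keys and their parsers
CONFIG_SCHEMA = {
    "model": str,
    "element1": str,
    "element2": str,
    "S": float,
    "k1": float,
    "k2": float,
    "b": float,
    "p0": float,
    "Y0": float,
    "generations": int,
    "comparator": str,
    "seed": int,
    "out": str,
}

_MODELS = ("monoecious", "androdioecious")
_ELEMENTS = ("medea", "peel", "none")
_COMPARATORS = ("after_n", "absorbing")


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or out of domain."""


@dataclass
class RunConfig:
    """Validated run configuration shared by the CLI subcommands.

    The seed governs fixture generation only; the dynamics themselves
    are deterministic.
    """

    model: str = "monoecious"
    element1: str = "medea"
    element2: str = "medea"
    S: float = 0.0
    k1: float = 1.0
    k2: float = 0.0
    b: float = 1.0
    p0: float = 0.01
    Y0: float = 0.0
    generations: int = 100
    comparator: str = "after_n"
    seed: int = 0
    out: Optional[str] = None

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ConfigError(f"model must be one of {_MODELS}; got {self.model!r}")
        for key in ("element1", "element2"):
            if getattr(self, key) not in _ELEMENTS:
                raise ConfigError(
                    f"{key} must be one of {_ELEMENTS}; got {getattr(self, key)!r}"
                )
        for key in ("S", "k1", "k2"):
            v = getattr(self, key)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{key} must lie in [0, 1]; got {v!r}")
        if self.b <= 0.0:
            raise ConfigError(f"b must be > 0; got {self.b!r}")
        if not (0.0 <= self.p0 <= 1.0) or not (0.0 <= self.Y0 <= 1.0):
            raise ConfigError("p0 and Y0 must lie in [0, 1]")
        if self.generations < 0:
            raise ConfigError(f"generations must be >= 0; got {self.generations!r}")
        if self.comparator not in _COMPARATORS:
            raise ConfigError(
                f"comparator must be one of {_COMPARATORS}; got {self.comparator!r}"
            )

    def to_dict(self) -> Dict[str, object]:
        return asdict(self)


def read_config_file(path: Union[str, Path]) -> Dict[str, object]:
    """Parse a flat ``key = value`` config file.

    Unknown keys are rejected with a message listing the valid keys.
    """
    values: Dict[str, object] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key not in CONFIG_SCHEMA:
            raise ConfigError(
                f"{path}:{lineno}: unknown key {key!r}; valid keys are "
                f"{sorted(CONFIG_SCHEMA)}"
            )
        try:
            values[key] = CONFIG_SCHEMA[key](value)
        except ValueError as exc:
            raise ConfigError(f"{path}:{lineno}: bad value for {key!r}: {exc}") from exc
    return values


def merge_config(
    file_values: Dict[str, object], flag_values: Dict[str, object]
) -> RunConfig:
    """Combine config-file values with CLI flags; flags win with a warning."""
    merged = dict(file_values)
    for key, value in flag_values.items():
        if value is None:
            continue
        if key in merged and merged[key] != value:
            logger.warning(
                "flag --%s=%r overrides config value %r", key, value, merged[key]
            )
        merged[key] = value
    try:
        return RunConfig(**merged)  # type: ignore[arg-type]
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def _fmt(value: object) -> str:
    if isinstance(value, float):  # includes numpy scalars, coerced for clean repr
        return repr(float(value))
    return str(value)


def metadata_lines(config: Optional[Dict[str, object]] = None) -> List[str]:
    """Standard ``#`` metadata header: version, config echo, timestamp."""
    from . import __version__

    lines = [f"# tadrive {__version__}"]
    if config:
        lines.append(
            "# config: " + " ".join(f"{k}={_fmt(v)}" for k, v in sorted(config.items()))
        )
    lines.append(
        "# written: " + datetime.datetime.now(datetime.timezone.utc).isoformat()
    )
    return lines


def write_tsv(
    rows: Iterable[Sequence[object]],
    columns: Sequence[str],
    path: Union[str, Path, IO[str], None] = None,
    config: Optional[Dict[str, object]] = None,
) -> None:
    """Write rows as TSV with a ``#`` metadata header block.

    ``path`` may be a filesystem path, an open text stream, or None for
    standard output.
    """
    lines = metadata_lines(config)
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    text = "\n".join(lines) + "\n"
    if path is None:
        sys.stdout.write(text)
    elif hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text)


def write_json(
    obj: Dict[str, object], path: Union[str, Path, IO[str], None] = None
) -> None:
    """Write a scalar-result object as JSON (floats via repr round-trip)."""
    text = json.dumps(obj, indent=2, allow_nan=True) + "\n"
    if path is None:
        sys.stdout.write(text)
    elif hasattr(path, "write"):
        path.write(text)  # type: ignore[union-attr]
    else:
        Path(path).write_text(text)


def read_tsv(path: Union[str, Path]) -> tuple[List[str], List[List[str]]]:
    """Read a TSV written by :func:`write_tsv`; returns (columns, rows)."""
    columns: List[str] = []
    rows: List[List[str]] = []
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#") or not raw.strip():
            continue
        if not columns:
            columns = raw.split("\t")
        else:
            rows.append(raw.split("\t"))
    return columns, rows
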