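"""Config-file loading, validation and run manifests.

Configs are flat YAML/JSON mappings validated against the dataclasses
they populate: unknown keys are rejected by name, omitted keys take the
dataclass defaults, and the dataclass's own ``__post_init__`` invariants
run on construction.  Every CLI run writes a :class:`RunManifest` beside
its outputs with enough information to re-run the command.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
import time
from pathlib import Path

import yaml

logger = logging.getLogger("fedaffect")


class ConfigSchemaError(ValueError):
    """A config file violates the schema of its target dataclass."""


def load_config(path, cls):
    """Load a YAML/JSON mapping into dataclass ``cls``.

    Unknown keys raise :class:`ConfigSchemaError` listing the valid
    keys; invariant violations surface as the dataclass's own errors.
    An empty file yields all defaults.
    """
    raw = Path(path).read_text()
    data = yaml.safe_load(raw) or {}
    if not isinstance(data, dict):
        raise ConfigSchemaError(f"{path}: expected a key-value mapping")
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigSchemaError(
            f"{path}: unknown key(s) {sorted(unknown)}; valid keys: {sorted(valid)}"
        )
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigSchemaError(f"{path}: {exc}") from exc


def config_to_dict(cfg) -> dict:
    """Dataclass -> JSON-serializable mapping (arrays to lists)."""
    out = {}
    for f in dataclasses.fields(cfg):
        v = getattr(cfg, f.name)
        if hasattr(v, "tolist"):
            v = v.tolist()
        elif isinstance(v, frozenset):
            v = sorted(v)
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


@dataclasses.dataclass
class RunManifest:
    """What was run, with what, on what — enough to re-run the command."""

    command: str
    config: dict
    seeds: list[int]
    inputs: list[str]
    outputs: list[str]
    package_version: str = ""
    timestamp: str = ""

    def write(self, out_dir) -> Path:
        from . import __version__

        self.package_version = self.package_version or __version__
        self.timestamp = self.timestamp or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime()
        )
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "manifest.json"
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2))
        return path


def setup_logging(level: str = "INFO", logfile=None) -> None:
    """Log to stderr and optionally a file; idempotent."""
    root = logging.getLogger("fedaffect")
    root.setLevel(getattr(logging, level.upper(), logging.INFO))
    if not any(isinstance(h, logging.StreamHandler) for h in root.handlers):
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        root.addHandler(h)
    if logfile is not None:
        fh = logging.FileHandler(logfile)
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
        root.addHandler(fh)
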