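"""Shared helpers for loading the packaged YAML configuration files.

Everything that is nutritional *data* rather than algorithm — Schofield BMR
coefficients, diet-quality component cut-offs, the screener item definition,
recommended dietary allowances, example blood reference ranges, advice rules —
ships as YAML under ``dietscreen/data`` and can be overridden by passing an
explicit path to the loader functions in each module.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .errors import ConfigurationError

_DATA_PACKAGE = "dietscreen.data"


def default_config_path(name: str) -> Path:
    """Return the filesystem path of a packaged default config file."""
    path = resources.files(_DATA_PACKAGE).joinpath(name)
    return Path(str(path))


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigurationError(f"configuration file {path} must contain a mapping")
    return data
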