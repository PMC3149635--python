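"""Access to the packaged preset experiment configurations.

Each preset is a YAML file describing either a fixed session-list protocol
(possibly with several drug arms), a reexposure-duration sweep, a parameter
grid, or a retrieval-preference measurement.  Presets are configuration,
not code: they can be copied, edited and passed back in as files.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

__all__ = ["available_presets", "load_preset", "preset_path"]

_DIR = "preset_configs"


def _root():
    return resources.files("reconsim") / _DIR


def available_presets() -> list[str]:
    """Names of all bundled preset experiments."""
    return sorted(
        p.name[: -len(".yaml")] for p in _root().iterdir() if p.name.endswith(".yaml")
    )


def preset_path(name: str) -> Path:
    """Filesystem path of a bundled preset (for copying/editing)."""
    return Path(str(_root() / f"{name}.yaml"))


def load_preset(name: str) -> dict:
    """Load a preset by bundled name or by path to a YAML file.

    Raises ``KeyError`` listing the valid names if the preset is unknown.
    """
    candidate = Path(name)
    if candidate.suffix in (".yaml", ".yml") and candidate.exists():
        with open(candidate) as fh:
            cfg = yaml.safe_load(fh)
    else:
        res = _root() / f"{name}.yaml"
        if not res.is_file():
            raise KeyError(
                f"unknown preset {name!r}; available presets: {', '.join(available_presets())}"
            )
        cfg = yaml.safe_load(res.read_text())
    if "label" not in cfg:
        cfg["label"] = name
    return cfg
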