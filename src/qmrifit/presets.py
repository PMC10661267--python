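"""Organ-specific presets: fitting bounds and segmentation thresholds.

Each preset is a YAML file shipped with the package giving per-parameter
bounds for the DCE and DW fitters and the segmented-IVIM b threshold. The
values are literature-informed defaults and are meant to be edited; any
field may also be overridden on the command line.
"""

from __future__ import annotations

from importlib import resources

import yaml

__all__ = ["available_presets", "load_preset"]


def available_presets() -> list:
    root = resources.files("qmrifit") / "presets"
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))


def load_preset(name: str) -> dict:
    """Load a named organ preset (e.g. 'brain', 'prostate')."""
    root = resources.files("qmrifit") / "presets"
    path = root / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(f"unknown preset '{name}'; available: {available_presets()}")
    data = yaml.safe_load(text)
    for section in ("dce_bounds", "dw_bounds"):
        if section in data:
            data[section] = {k: tuple(v) for k, v in data[section].items()}
    return data
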