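"""Packaged example pipeline configurations.

``example_config(name)`` loads one of the shipped YAML configs as a
validated :class:`~bilayerlab.pipeline.PipelineConfig`:

* ``wt_kcl``    — WT conductance recovery in the 500:50 mM KCl bath
* ``wt_ca``     — WT recovery in the 150:15 mM CaCl2 bath
* ``mutant_ca`` — D91/93/94A-like recovery in the 150:15 mM CaCl2 bath
"""

from __future__ import annotations

from importlib import resources

from ..pipeline import PipelineConfig

__all__ = ["example_config", "example_config_path", "EXAMPLE_NAMES"]

EXAMPLE_NAMES = ("wt_kcl", "wt_ca", "mutant_ca")


def example_config_path(name: str):
    if name not in EXAMPLE_NAMES:
        raise KeyError(f"unknown example config {name!r}; have {EXAMPLE_NAMES}")
    return resources.files(__package__) / f"{name}.yaml"


def example_config(name: str, seed: int | None = None) -> PipelineConfig:
    """Load a packaged config; ``seed`` overrides the config's default."""
    import yaml

    data = yaml.safe_load(example_config_path(name).read_text())
    if seed is not None:
        data["seed"] = seed
    return PipelineConfig(**data)
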