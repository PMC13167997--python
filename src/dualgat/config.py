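"""Run configuration: model constants loadable from a YAML file.

Keys (all optional, defaults in parentheses): ``nu`` (0.485),
``p3_mmhg`` (4.0), ``g0_mm`` (1.53), ``g1_mm`` (1.80), and a
``tear_presets`` mapping of name -> surface tension in N/m. The loaded
configuration is echoed to the log so every run records the constants
it used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import yaml

from .core import (
    DEFAULT_G0_MM,
    DEFAULT_G1_MM,
    DEFAULT_NU,
    DEFAULT_P3_MMHG,
    TEAR_PRESETS,
    PrismGeometry,
)

__all__ = ["ModelConfig", "load_config"]

log = logging.getLogger("dualgat")


@dataclass(frozen=True)
class ModelConfig:
    """Immutable bundle of the model constants for one run."""

    nu: float = DEFAULT_NU
    p3_mmhg: float = DEFAULT_P3_MMHG
    g0_mm: float = DEFAULT_G0_MM
    g1_mm: float = DEFAULT_G1_MM
    tear_presets: dict = field(default_factory=lambda: dict(TEAR_PRESETS))

    def prism(self) -> PrismGeometry:
        return PrismGeometry(g0=self.g0_mm, g1=self.g1_mm)

    def echo(self) -> None:
        log.info(
            "model constants: nu=%.4g p3=%.4g mmHg g0=%.4g mm g1=%.4g mm presets=%s",
            self.nu, self.p3_mmhg, self.g0_mm, self.g1_mm, self.tear_presets,
        )


def load_config(path=None, **overrides) -> ModelConfig:
    """Build a :class:`ModelConfig` from an optional YAML file plus overrides.

    Overrides passed as keyword arguments win over file values; ``None``
    overrides are ignored. The result is validated (via the prism
    constructor) and echoed to the log.
    """
    values: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        unknown = set(loaded) - {"nu", "p3_mmhg", "g0_mm", "g1_mm", "tear_presets"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        values.update(loaded)
    values.update({k: v for k, v in overrides.items() if v is not None})
    cfg = ModelConfig(**values)
    cfg.prism()  # validates g0 < g1
    if not (0.0 <= cfg.nu <= 0.5):
        raise ValueError(f"nu must be in [0, 0.5], got {cfg.nu}")
    cfg.echo()
    return cfg
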