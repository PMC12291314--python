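"""Pipeline configuration: a small YAML-backed schema shared by all subcommands."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import UsageError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """Everything the pipeline needs beyond the data itself.

    ``treatments`` fixes the treatment display order (labels like "24h" do
    not sort lexically); ``control`` names the reference group for delta
    bands, relative profiles and OEC / Q_A-RC fractions.
    """

    seed: int = 1
    t0_us: float = 20.0
    control: str = "0h"
    treatments: list[str] = field(default_factory=lambda: ["0h", "4h", "8h", "24h"])
    variety_pair: list[str] = field(default_factory=lambda: ["NH5", "FH18"])
    alpha: float = 0.05
    correlation_pooling: str = "pooled"  # or "per_variety"
    qa_rc_mode: str = "quotient"  # or "product"
    n_reps: int = 3
    noise_cv: float = 0.01
    trait_noise_cv: float = 0.04
    transients_csv: str | None = None
    physiology_csv: str | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise UsageError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.correlation_pooling not in ("pooled", "per_variety"):
            raise UsageError(f"unknown correlation_pooling {self.correlation_pooling!r}")
        if self.qa_rc_mode not in ("quotient", "product"):
            raise UsageError(f"unknown qa_rc_mode {self.qa_rc_mode!r}")
        if self.control not in self.treatments:
            raise UsageError(
                f"control {self.control!r} not among treatments {self.treatments}"
            )


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config; missing path yields the defaults."""
    if path is None:
        return PipelineConfig()
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise UsageError(f"{path}: config must be a mapping")
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise UsageError(f"{path}: unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**data)
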