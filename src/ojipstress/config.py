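"""Pipeline run configuration: paths, labels, thresholds, generator knobs."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigurationError


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, with study defaults.

    Marker times are fixed protocol constants (20 us, 300 us, 2 ms,
    30 ms) and are intentionally not part of the configuration.
    """

    out_dir: str = "results"
    control_label: str = "MT"
    p_star: float = 0.05  # single-star significance threshold
    p_double: float = 0.01  # double-star threshold
    seed: int = 7
    n_replicates: int = 3
    noise_cv: float = 0.02
    replicate_sd: float = 0.05
    preset_file: str | None = None  # None -> packaged default presets

    def __post_init__(self):
        if not 0 < self.p_double < self.p_star < 1:
            raise ConfigurationError(
                f"significance thresholds must satisfy 0 < {self.p_double} < {self.p_star} < 1"
            )
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be at least 1")
        if self.noise_cv < 0 or self.replicate_sd < 0:
            raise ConfigurationError("noise levels must be nonnegative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False), encoding="utf-8")

    def presets(self):
        from .synthetic_data import default_presets, load_presets

        if self.preset_file:
            return load_presets(self.preset_file)
        return default_presets(
            noise_cv=self.noise_cv, replicate_sd=self.replicate_sd
        )
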