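"""Run configuration: defaults ← YAML file ← command-line overrides.

A fully defaulted :class:`RunConfig` reproduces the full-scale pipeline
(16,384-point grid, 22,000 pairs split 18,000/2,000/2,000, depth 6,
learning rate 1e-4, 100 epochs, threshold 0.5).  Unknown keys are rejected
with the list of valid keys, so typos fail loudly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, is_dataclass
from pathlib import Path
from typing import Any, Mapping

import yaml

__all__ = ["RunConfig", "SimulatorSection", "AugmentationSection", "ModelSection",
           "IdentificationSection", "EvaluationSection", "ConfigError", "load_config"]


class ConfigError(ValueError):
    """Unparseable configuration or unknown key."""


@dataclass
class SimulatorSection:
    n_compounds: int = 24
    multiplets_per_compound: tuple[int, int] = (2, 8)
    ppm_range: tuple[float, float] = (0.5, 9.5)
    linewidth_gamma: float = 0.0015
    J_range: tuple[float, float] = (2.0, 12.0)
    spectrometer_freq: float = 400.0
    n_points: int = 16384
    ppm_low: float = -1.0
    ppm_high: float = 11.0


@dataclass
class AugmentationSection:
    n_pairs: int = 22_000
    ratio_range: tuple[float, float] = (0.2, 1.0)
    components_range: tuple[int, int] = (2, 5)
    noise_sigma: float = 0.005
    positive_fraction: float = 0.5
    split_sizes: tuple[int, int, int] = (18_000, 2_000, 2_000)
    mask_solvent: bool = False


@dataclass
class ModelSection:
    n_conv_layers: int = 6
    n_kernels: int = 32
    kernel_size: int = 5
    pool_size: int = 2
    dense_units: int = 100
    dropout_rate: float = 0.2
    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32


@dataclass
class IdentificationSection:
    threshold: float = 0.5


@dataclass
class EvaluationSection:
    max_shift: float = 0.052
    shift_step: float = 0.003


@dataclass
class RunConfig:
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    augmentation: AugmentationSection = field(default_factory=AugmentationSection)
    model: ModelSection = field(default_factory=ModelSection)
    identification: IdentificationSection = field(default_factory=IdentificationSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)
    seed: int = 1
    outdir: str = "pscnn-run"
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the full configuration, for run manifests."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _merge_into(obj: Any, data: Mapping[str, Any], path: str = "") -> None:
    valid = {f.name: f for f in fields(obj)}
    for key, value in data.items():
        where = f"{path}{key}"
        if key not in valid:
            raise ConfigError(
                f"unknown configuration key {where!r}; valid keys at this level: "
                f"{sorted(valid)}"
            )
        current = getattr(obj, key)
        if is_dataclass(current):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{where!r} must be a mapping of sub-keys")
            _merge_into(current, value, path=f"{where}.")
        else:
            if isinstance(current, tuple) and isinstance(value, (list, tuple)):
                value = tuple(value)
            setattr(obj, key, value)


def load_config(
    path: str | Path | None = None,
    overrides: Mapping[str, Any] | None = None,
) -> RunConfig:
    """Build a RunConfig as defaults ← file ← overrides, in that precedence.

    ``overrides`` uses dotted keys (``"model.learning_rate"``) or nested
    mappings; an empty/absent file yields all defaults.
    """
    config = RunConfig()
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"no such config file: {path}")
        try:
            data = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
        if data is None:
            data = {}
        if not isinstance(data, Mapping):
            raise ConfigError(f"{path}: top level must be a mapping")
        _merge_into(config, data)
    if overrides:
        nested: dict[str, Any] = {}
        for key, value in overrides.items():
            parts = key.split(".")
            node = nested
            for part in parts[:-1]:
                node = node.setdefault(part, {})
            node[parts[-1]] = value
        _merge_into(config, nested)
    return config
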