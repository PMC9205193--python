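"""YAML run configuration with full schema validation.

Unknown keys are rejected so a typo never silently falls back to a default.
Every run writes the resolved configuration beside its outputs.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ConfigError
from .synthetic import SyntheticConfig

__all__ = ["RunConfig", "load_config", "dump_config"]


def _from_mapping(cls, data: dict, section: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {section!r} must be a mapping")
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in section {section!r}")
    coerced = dict(data)
    for key in ("n_per_group", "within_network_rho", "affected_networks",
                "e1_grid", "e2_grid", "kinds"):
        if key in coerced and isinstance(coerced[key], list):
            coerced[key] = tuple(coerced[key])
    if "affected_networks" in coerced:
        coerced["affected_networks"] = frozenset(coerced["affected_networks"])
    return cls(**coerced)


@dataclass
class PathsConfig:
    input_dir: str = "."
    output_dir: str = "results"
    features_csv: str = "features.csv"
    network_map_csv: str = "network_map.csv"
    labels_csv: str = "labels.csv"
    voxels_csv: str = "voxels.csv"
    atlas_csv: str = "atlas.csv"


@dataclass
class ExtractionConfig:
    alpha: float = 0.05
    z_threshold: float = 3.0
    top_k: int = 3
    n_components: int | None = None  # None -> MDL estimate

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError(f"extraction.alpha must be in (0, 1), got {self.alpha}")
        if self.top_k < 1:
            raise ConfigError(f"extraction.top_k must be >= 1, got {self.top_k}")


@dataclass
class CouplingConfig:
    e1: int = 3
    e2: int = 2
    e1_grid: tuple[int, ...] = (2, 3, 4)
    e2_grid: tuple[int, ...] = (1, 2, 3, 4, 5)
    alpha: float = 0.05
    scale: bool = True
    transductive: bool = False

    def __post_init__(self) -> None:
        for name, val in (("e1", self.e1), ("e2", self.e2)):
            if not 1 <= val <= 6:
                raise ConfigError(f"coupling.{name} must be in 1..6, got {val}")
        if not 0 < self.alpha < 1:
            raise ConfigError(f"coupling.alpha must be in (0, 1), got {self.alpha}")


@dataclass
class ClassifierConfig:
    C: float = 1.0
    rounds: int = 1
    folds: int = 10
    positive_label: int = 1

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ConfigError(f"classifier.C must be positive, got {self.C}")
        if self.rounds < 1 or self.folds < 2:
            raise ConfigError("classifier.rounds must be >= 1 and folds >= 2")


@dataclass
class RunConfig:
    mode: str = "features"  # features | voxels
    seed: int = 0
    log_level: str = "INFO"
    paths: PathsConfig = field(default_factory=PathsConfig)
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    coupling: CouplingConfig = field(default_factory=CouplingConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("features", "voxels"):
            raise ConfigError(f"mode must be 'features' or 'voxels', got {self.mode!r}")


_SECTIONS = {
    "paths": PathsConfig,
    "synthetic": SyntheticConfig,
    "extraction": ExtractionConfig,
    "coupling": CouplingConfig,
    "classifier": ClassifierConfig,
}


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    top_known = {"mode", "seed", "log_level", *_SECTIONS}
    unknown = set(raw) - top_known
    if unknown:
        raise ConfigError(f"{path}: unknown top-level key(s) {sorted(unknown)}")
    kwargs: dict = {k: raw[k] for k in ("mode", "seed", "log_level") if k in raw}
    for name, cls in _SECTIONS.items():
        if name in raw:
            kwargs[name] = _from_mapping(cls, raw[name], name)
    return RunConfig(**kwargs)


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Write the fully resolved configuration as YAML."""
    data = asdict(config)
    data["synthetic"]["affected_networks"] = sorted(
        config.synthetic.affected_networks
    )
    for section in ("synthetic", "coupling"):
        for key, val in data[section].items():
            if isinstance(val, tuple):
                data[section][key] = list(val)
    if isinstance(data["synthetic"]["n_per_group"], tuple):
        data["synthetic"]["n_per_group"] = list(data["synthetic"]["n_per_group"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))
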