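"""YAML study configuration with strict validation.

Every field has a documented default except the master ``seed`` (required:
every random decision in a study is derived from it) and the data source
(exactly one of ``manifest`` or ``synthetic``).  Unknown keys are rejected
with their full key path so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import yaml

from .classify import SplitSpec, SVMConfig
from .ga import GAConfig
from .study import STANDARD_COMPARISONS
from .synthetic import SyntheticSpec


class ConfigError(ValueError):
    pass


@dataclass
class ReplicateCounts:
    runs: int = 1000
    sweep_reps: int = 1000
    permutation_draws: int = 100000


@dataclass
class StudyConfig:
    seed: int
    manifest: str | None = None
    synthetic: SyntheticSpec | None = None
    output_dir: str = "roiselect_out"
    comparisons: list[tuple[str, str]] = field(
        default_factory=lambda: [list(c) for c in STANDARD_COMPARISONS]
    )
    n_max: int | None = None
    jobs: int = 1
    verbose: bool = False
    ga: GAConfig = field(default_factory=GAConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    svm: SVMConfig = field(default_factory=SVMConfig)
    replicates: ReplicateCounts = field(default_factory=ReplicateCounts)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(data).__name__}")
    allowed = {f.name for f in fields(cls)}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"unknown key {path}.{key}" if path else
                              f"unknown key {key}")
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{path or 'config'}: {exc}") from exc


def load_config(path) -> StudyConfig:
    """Parse and validate a YAML study configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> StudyConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    allowed = {f.name for f in fields(StudyConfig)}
    for key in raw:
        if key not in allowed:
            raise ConfigError(f"unknown key {key}")
    if "seed" not in raw:
        raise ConfigError("missing required key: seed")
    data = dict(raw)
    for name, cls in (("ga", GAConfig), ("split", SplitSpec), ("svm", SVMConfig),
                      ("replicates", ReplicateCounts)):
        if name in data:
            data[name] = _build(cls, data[name] or {}, name)
    if "synthetic" in data and data["synthetic"] is not None:
        syn = dict(data["synthetic"])
        for tup_key in ("n_per_class", "planted_set", "class_labels"):
            if tup_key in syn and isinstance(syn[tup_key], list):
                syn[tup_key] = tuple(syn[tup_key])
        syn.setdefault("seed", data["seed"])
        data["synthetic"] = _build(SyntheticSpec, syn, "synthetic")
    if data.get("manifest") is None and data.get("synthetic") is None:
        raise ConfigError("config needs a data source: manifest or synthetic")
    if data.get("manifest") is not None and data.get("synthetic") is not None:
        raise ConfigError("manifest and synthetic are mutually exclusive")
    comparisons = data.get("comparisons")
    if comparisons is not None:
        for i, pair in enumerate(comparisons):
            if not (isinstance(pair, (list, tuple)) and len(pair) == 2):
                raise ConfigError(
                    f"comparisons[{i}]: expected a [class_a, class_b] pair"
                )
        data["comparisons"] = [list(p) for p in comparisons]
    return _build(StudyConfig, data, "")


def resolved_dict(config: StudyConfig) -> dict:
    """Fully-resolved configuration (all defaults filled), YAML-serializable."""

    def plain(obj):
        if hasattr(obj, "__dataclass_fields__"):
            return {f.name: plain(getattr(obj, f.name))
                    for f in fields(obj)}
        if isinstance(obj, tuple):
            return [plain(v) for v in obj]
        if isinstance(obj, list):
            return [plain(v) for v in obj]
        return obj

    return plain(config)
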