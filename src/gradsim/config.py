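"""Run configuration: factor levels, repetitions, seeding, validation.

The defaults reproduce the full study conditions: six response shapes, six
sampling strategies, budgets {6, 12, 24, 48, 96} with every admissible
locations-times-replicates factorization, noise levels 20% and 100%, both
knowledge scenarios, both predictor-extremes scenarios, and 1000
repetitions per factor combination.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import yaml

from .designs import (
    DEFAULT_TOTALS,
    DEFAULT_WEIGHT_FLOOR,
    MAX_REPLICATES,
    MIN_LOCATIONS,
    STRATEGY_IDS,
)
from .observe import DEFAULT_SD_FLOOR_FRACTION
from .shapes import DEFAULT_GRID_SIZE, SHAPE_IDS

__all__ = ["RunConfig", "load_config", "save_config", "config_hash"]

KNOWLEDGE_LEVELS = ("known", "unknown")
EXTREMES_LEVELS = ("with", "without")


class ConfigError(ValueError):
    """Invalid or unknown configuration content."""


@dataclass
class RunConfig:
    shapes: List[str] = field(default_factory=lambda: list(SHAPE_IDS))
    strategies: List[str] = field(default_factory=lambda: list(STRATEGY_IDS))
    totals: List[int] = field(default_factory=lambda: list(DEFAULT_TOTALS))
    min_locations: int = MIN_LOCATIONS
    max_replicates: int = MAX_REPLICATES
    noise_levels: List[float] = field(default_factory=lambda: [0.2, 1.0])
    knowledge: List[str] = field(default_factory=lambda: list(KNOWLEDGE_LEVELS))
    extremes: List[str] = field(default_factory=lambda: list(EXTREMES_LEVELS))
    reps: int = 1000
    master_seed: int = 1
    sd_floor_fraction: float = DEFAULT_SD_FLOOR_FRACTION
    candidate_grid_size: int = DEFAULT_GRID_SIZE
    eval_grid_size: int = DEFAULT_GRID_SIZE
    max_order: int = 4
    weight_floor: float = DEFAULT_WEIGHT_FLOOR
    ps_normalizer: str = "true_centered"
    known_order_overrides: Dict[str, int] = field(default_factory=dict)
    out: Optional[str] = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        bad = [s for s in self.shapes if s not in SHAPE_IDS]
        if bad:
            raise ConfigError(f"unknown shape id(s) {bad}; valid ids: {list(SHAPE_IDS)}")
        bad = [s for s in self.strategies if s not in STRATEGY_IDS]
        if bad:
            raise ConfigError(
                f"unknown strategy id(s) {bad}; valid ids: {list(STRATEGY_IDS)}"
            )
        bad = [k for k in self.knowledge if k not in KNOWLEDGE_LEVELS]
        if bad:
            raise ConfigError(f"unknown knowledge level(s) {bad}; valid: {KNOWLEDGE_LEVELS}")
        bad = [e for e in self.extremes if e not in EXTREMES_LEVELS]
        if bad:
            raise ConfigError(f"unknown extremes level(s) {bad}; valid: {EXTREMES_LEVELS}")
        if self.reps <= 0:
            raise ConfigError("reps must be > 0")
        if any(n < 0 for n in self.noise_levels):
            raise ConfigError("noise levels must be >= 0")
        if self.ps_normalizer not in ("true_centered", "true_raw"):
            raise ConfigError("ps_normalizer must be 'true_centered' or 'true_raw'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON config file; an empty file yields the full defaults.

    Unknown keys are rejected with the list of valid keys; unknown factor
    ids are rejected naming the valid ids.
    """
    text = Path(path).read_text()
    data = yaml.safe_load(text) if text.strip() else {}
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(valid)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path) -> None:
    """Serialize the effective configuration (YAML) for provenance."""
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    """Stable short hash of the effective configuration."""
    payload = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
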