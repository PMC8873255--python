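"""Run configuration: every threshold of the analysis in one place.

All numeric choices flagged as exploratory in the underlying method
(slack radius, duration window, grid resolution, the 120-degree
complexity threshold, the 5-minute graph dwell cut, ...) are collected
here with their defaults, validated on load, and echoed into every
output directory so a run can be reproduced from its artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    # segmentation
    slack_radius: float = 10.0
    min_duration: float = 60.0
    max_duration: float = 1200.0
    min_length: float = 100.0
    gap_threshold: float = 60.0
    # grid / mobility domain
    cell_size: float = 100.0
    jaccard_threshold: float = 0.5
    # shape / temporal
    complexity_threshold: float = 120.0
    static_radius: float = 10.0
    min_stop_duration: float = 60.0
    # mobility graph
    dwell_threshold: float = 300.0
    min_nodes: int = 10
    # participant feature representation
    bins: int = 10
    # classification
    runs: int = 50
    sgd_steps: int = 10000
    learning_rate: float = 1e-3
    repeats: int = 20
    test_fraction: float = 0.2
    min_alone_segments: int = 5  # patients need strictly more than this
    master_seed: int = 0

    def __post_init__(self) -> None:
        positive = [
            "slack_radius", "min_duration", "max_duration", "min_length",
            "gap_threshold", "cell_size", "complexity_threshold",
            "static_radius", "min_stop_duration", "dwell_threshold",
            "learning_rate",
        ]
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.min_duration < self.max_duration:
            raise ValueError("min_duration must be below max_duration")
        if not 0 < self.jaccard_threshold < 1:
            raise ValueError("jaccard_threshold must be in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        for name in ("bins", "runs", "sgd_steps", "repeats", "min_nodes"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be at least 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from a JSON or YAML file; unknown keys are rejected."""
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
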