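"""Pipeline configuration: one JSON-serialisable object for every stage.

All study constants are defaults here (never literals in stage code): the
10 umol/L IC50 cutoff, the two molecular-weight boundaries, the 0.9
cross-class similarity filter, the 80/20 split with 5-fold CV repeated 10
times, the consensus (0.5), novelty (0.1 / 0.2) and scaffold-overlap (0.9)
thresholds, and the single seed every random stage derives from.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    paths: dict = field(
        default_factory=lambda: {
            "activity": None,
            "library": None,
            "reference": None,
            "scaffolds": None,
            "output": "abxscreen_out",
        }
    )
    fingerprint: dict = field(
        default_factory=lambda: {"family": "path", "n_bits": 1024, "max_path_len": 7, "radius": 2}
    )
    cutoff_umol: float = 10.0
    filters: dict = field(
        default_factory=lambda: {
            "max_mw_benchmark": 1000.0,  # strict '>' removal
            "max_mw_library": 1000.0,    # '>=' removal
            "cross_sim": 0.9,
        }
    )
    cv: dict = field(
        default_factory=lambda: {"k": 5, "repeats": 10, "test_frac": 0.2, "grid_search": False}
    )
    grids: dict = field(default_factory=dict)
    thresholds: dict = field(
        default_factory=lambda: {
            "consensus": 0.5,
            "novelty_mean": 0.1,
            "novelty_max": 0.2,
            "overlap": 0.9,
        }
    )
    n_negative_sets: int = 10
    generator: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        for name, lo, hi in (
            ("thresholds.consensus", 0, 1),
            ("thresholds.novelty_mean", 0, 1),
            ("thresholds.novelty_max", 0, 1),
            ("thresholds.overlap", 0, 1),
            ("filters.cross_sim", 0, 1),
        ):
            section, key = name.split(".")
            v = getattr(self, section)[key]
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
        if self.cutoff_umol <= 0:
            raise ValueError("cutoff_umol must be positive")
        if not 0 < self.cv["test_frac"] < 1:
            raise ValueError("cv.test_frac must lie strictly between 0 and 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        cfg = cls()
        for key, value in data.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, dict) and isinstance(value, dict):
                current.update(value)
            else:
                setattr(cfg, key, value)
        cfg.validate()
        return cfg

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        return cls.from_json(Path(path).read_text())

    def save(self, path) -> None:
        Path(path).write_text(self.to_json())

    def apply_overrides(self, overrides: list[str]) -> None:
        """Apply ``section.key=value`` (or ``key=value``) override strings."""
        for item in overrides:
            if "=" not in item:
                raise ValueError(f"override {item!r} is not key=value")
            dotted, raw = item.split("=", 1)
            try:
                value = json.loads(raw)
            except json.JSONDecodeError:
                value = raw
            parts = dotted.split(".")
            if len(parts) == 1:
                if not hasattr(self, parts[0]):
                    raise ValueError(f"unknown config key {parts[0]!r}")
                setattr(self, parts[0], value)
            else:
                obj = getattr(self, parts[0], None)
                if not isinstance(obj, dict):
                    raise ValueError(f"unknown config section {parts[0]!r}")
                for p in parts[1:-1]:
                    obj = obj.setdefault(p, {})
                obj[parts[-1]] = value
        self.validate()
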