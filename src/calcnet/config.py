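"""Declarative run configuration for the end-to-end experiment.

One document holds every tunable of the pipeline with the package defaults;
unknown keys are rejected so silent typos cannot change a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .core import CalcnetError


@dataclass
class RunConfig:
    """All pipeline defaults in one place.

    Cohort sizes mirror the study design at desk scale: 150 training
    calcifications per class and a disjoint 50 + 50 test cohort.
    """

    # cohorts
    n_train_stones: int = 150
    n_train_phleboliths: int = 150
    n_test_stones: int = 50
    n_test_phleboliths: int = 50
    # segmentation
    threshold_hu: float = 250.0
    # patches
    patch_size: int = 31
    hu_window: tuple[float, float] = (-100.0, 1500.0)
    mirror: bool = True
    # network / training
    candidate: str = "C"
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-3
    val_fraction: float = 0.1
    # scoring / comparator
    cutoff: float = 0.5
    hu_cutoff: float = 643.0
    vol_cutoff: float = 171.0
    # statistics
    ci_method: str = "clopper_pearson"
    ci_level: float = 0.95
    # randomness
    seed: int = 42

    def __post_init__(self) -> None:
        if self.candidate.upper() not in ("A", "B", "C"):
            raise CalcnetError(f"unknown candidate {self.candidate!r}")
        self.candidate = self.candidate.upper()
        self.hu_window = tuple(float(v) for v in self.hu_window)
        for name in ("n_train_stones", "n_train_phleboliths",
                     "n_test_stones", "n_test_phleboliths"):
            if getattr(self, name) < 0:
                raise CalcnetError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hu_window"] = list(self.hu_window)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise CalcnetError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise CalcnetError("config file must hold a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
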