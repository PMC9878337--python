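"""Run configuration: every threshold in one serialisable, validated object."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved parameters for one pipeline run.

    Defaults are the method's published operating point: tissue labelling
    at |fc| > 2 and p < 0.001, perturbation reversal at |FC| > 2, adverse
    at |FC| > 15, denominator floor 0.1, enrichment significance at
    q < 0.05.
    """

    fc_scale: str = "log2"
    fc_threshold: float = 2.0
    p_threshold: float = 0.001
    reversal_threshold: float = 2.0
    adverse_threshold: float = 15.0
    adverse_mode: str = "symmetric"
    floor: float = 0.1
    alpha: float = 0.05
    cohort_strategy: str = "all"
    cohort_cell_line: str | None = None
    cohort_specific_gene: str | None = None
    cohort_min_score: float = 0.0
    seed: int = 0
    paths: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.fc_scale not in ("log2", "signed_ratio"):
            raise ConfigError(f"fc_scale must be log2 or signed_ratio, got {self.fc_scale!r}")
        for name in ("fc_threshold", "reversal_threshold", "adverse_threshold", "floor"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive, got {getattr(self, name)}")
        if not (0 < self.p_threshold < 1):
            raise ConfigError(f"p_threshold must lie in (0, 1), got {self.p_threshold}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.adverse_threshold <= self.reversal_threshold:
            raise ConfigError(
                "adverse_threshold must exceed reversal_threshold "
                f"({self.adverse_threshold} <= {self.reversal_threshold})"
            )
        if self.adverse_mode not in ("symmetric", "strict_paper"):
            raise ConfigError(f"adverse_mode must be symmetric or strict_paper, got {self.adverse_mode!r}")
        if self.cohort_strategy not in ("all", "mutation_match", "specific_mutation"):
            raise ConfigError(f"unknown cohort_strategy {self.cohort_strategy!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def log_resolved(self) -> None:
        """Log every resolved parameter so a run can be reproduced exactly."""
        for key, val in sorted(self.to_dict().items()):
            logger.info("config %s = %r", key, val)
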