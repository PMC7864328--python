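"""Run configuration: thresholds, cohort generator and analysis settings.

Configuration is a plain nested mapping loadable from YAML or JSON; the
packaged defaults describe the reference study conditions (479 cases, 21
with missing data, up to 7 corrections, mean age 68.6 within 39-96, 49%
male) and a five-phenotype mixture of post-initial-cut knee presentations.
"""

from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .core import CHANNELS, Thresholds

__all__ = [
    "Demographics",
    "CohortConfig",
    "AnalysisConfig",
    "RunConfig",
    "ConfigError",
    "default_config_dict",
    "load_config",
]

_DEFAULT_CONFIG_PATH = Path(__file__).parent / "data" / "default_config.yaml"


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration documents."""


@dataclass(frozen=True)
class Demographics:
    """Truncated-normal age distribution and sex split of the cohort."""

    age_mean: float = 68.6
    age_sd: float = 9.0
    age_min: float = 39.0
    age_max: float = 96.0
    male_fraction: float = 0.49

    def __post_init__(self) -> None:
        if self.age_sd <= 0 or self.age_min >= self.age_max:
            raise ConfigError("invalid age distribution parameters")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ConfigError("male_fraction must be in [0, 1]")


def _validate_phenotypes(phenotypes: dict[str, dict]) -> dict[str, dict]:
    if not phenotypes:
        raise ConfigError("phenotype mixture must not be empty")
    total = 0.0
    for name, spec in phenotypes.items():
        if "weight" not in spec:
            raise ConfigError(f"phenotype {name!r} lacks a weight")
        w = float(spec["weight"])
        if w < 0:
            raise ConfigError(f"phenotype {name!r} has negative weight")
        total += w
        for ch in CHANNELS:
            if ch not in spec:
                raise ConfigError(f"phenotype {name!r} lacks channel {ch!r}")
            lo, hi = spec[ch]
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi:
                raise ConfigError(f"phenotype {name!r}, channel {ch!r}: bad range {spec[ch]!r}")
    if abs(total - 1.0) > 1e-9:
        raise ConfigError(f"phenotype weights must sum to 1 (got {total!r})")
    return phenotypes


@dataclass(frozen=True)
class CohortConfig:
    n: int = 479
    n_missing: int = 21
    max_corrections: int = 7
    batch_prob: float = 0.0
    demographics: Demographics = field(default_factory=Demographics)
    phenotypes: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigError("cohort n must be >= 1")
        if not 0 <= self.n_missing < self.n:
            raise ConfigError("n_missing must satisfy 0 <= n_missing < n")
        if self.max_corrections < 1:
            raise ConfigError("max_corrections must be >= 1")
        if not 0.0 <= self.batch_prob <= 1.0:
            raise ConfigError("batch_prob must be in [0, 1]")
        if not self.phenotypes:
            object.__setattr__(
                self, "phenotypes",
                copy.deepcopy(default_config_dict()["cohort"]["phenotypes"]),
            )
        _validate_phenotypes(self.phenotypes)


@dataclass(frozen=True)
class AnalysisConfig:
    criterion: str = "reml"  # "reml" or "ml"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.criterion not in ("reml", "ml"):
            raise ConfigError("analysis criterion must be 'reml' or 'ml'")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError("alpha must be in (0, 1)")


@dataclass(frozen=True)
class RunConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    calibration_path: Optional[str] = None
    cohort: CohortConfig = field(default_factory=CohortConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        base = default_config_dict()
        doc = _deep_merge(base, doc or {})
        cohort_doc = dict(doc.get("cohort", {}))
        demo = Demographics(**cohort_doc.pop("demographics", {}))
        try:
            cohort = CohortConfig(demographics=demo, **cohort_doc)
            analysis = AnalysisConfig(**doc.get("analysis", {}))
            thresholds = Thresholds.from_dict(doc.get("thresholds", {}) or {})
        except TypeError as err:
            raise ConfigError(str(err)) from err
        return cls(
            thresholds=thresholds,
            calibration_path=doc.get("calibration"),
            cohort=cohort,
            analysis=analysis,
        )

    def to_dict(self) -> dict[str, Any]:
        return {
            "thresholds": self.thresholds.to_dict(),
            "calibration": self.calibration_path,
            "cohort": {
                "n": self.cohort.n,
                "n_missing": self.cohort.n_missing,
                "max_corrections": self.cohort.max_corrections,
                "batch_prob": self.cohort.batch_prob,
                "demographics": {
                    "age_mean": self.cohort.demographics.age_mean,
                    "age_sd": self.cohort.demographics.age_sd,
                    "age_min": self.cohort.demographics.age_min,
                    "age_max": self.cohort.demographics.age_max,
                    "male_fraction": self.cohort.demographics.male_fraction,
                },
                "phenotypes": copy.deepcopy(self.cohort.phenotypes),
            },
            "analysis": {
                "criterion": self.analysis.criterion,
                "alpha": self.analysis.alpha,
            },
        }


def default_config_dict() -> dict[str, Any]:
    """The packaged default configuration as a plain nested dict."""
    with open(_DEFAULT_CONFIG_PATH) as fh:
        return yaml.safe_load(fh)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict) and k != "phenotypes":
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = copy.deepcopy(v)
    return out


def load_config(path: Optional[str | Path] = None) -> RunConfig:
    """Load a YAML/JSON run configuration, merged over the packaged defaults."""
    if path is None:
        return RunConfig.from_dict({})
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"config root must be a mapping, got {type(doc).__name__}")
    return RunConfig.from_dict(doc)
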