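"""Declarative pipeline configuration (YAML).

One document with five sections — io, preprocess, features, evaluation,
synthetic — holding every tunable with its default, so a run is fully
described by one file plus one seed. Unknown keys are rejected rather than
ignored: a typo must fail loudly, not silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any

import yaml

from .evaluation import DEFAULT_MODELS, ExperimentConfig, ModelSpec
from .features import FeatureParams
from .preprocess import PreprocessParams
from .synthetic import SyntheticCohortSpec

__all__ = ["IoParams", "PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class IoParams:
    """Cohort-loading filters."""

    phase: str | None = "pre"        # null lifts the phase filter
    require_quality: bool = True
    canonical_channels: int = 16


_MODEL_SHORTHAND = {
    "random_forest": ModelSpec("random_forest"),
    "logistic_regression": ModelSpec("logistic_regression"),
    "svm_linear": ModelSpec("svm", "linear"),
    "svm_rbf": ModelSpec("svm", "rbf"),
    "svm_poly": ModelSpec("svm", "poly"),
}


def _build_section(cls, data: dict[str, Any], section: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown keys in section '{section}': "
                          f"{sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """All pipeline parameters, nested by stage."""

    io: IoParams = field(default_factory=IoParams)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    evaluation: ExperimentConfig = field(default_factory=ExperimentConfig)
    synthetic: SyntheticCohortSpec = field(default_factory=SyntheticCohortSpec)

    def to_dict(self) -> dict[str, Any]:
        def section(obj) -> dict[str, Any]:
            out = {}
            for f in fields(obj):
                v = getattr(obj, f.name)
                if isinstance(v, tuple) and v and isinstance(v[0], ModelSpec):
                    v = [m.name for m in v]
                elif isinstance(v, tuple):
                    v = list(v)
                out[f.name] = v
            return out

        return {name: section(getattr(self, name))
                for name in ("io", "preprocess", "features", "evaluation",
                             "synthetic")}

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data or {})
        unknown = set(data) - {"io", "preprocess", "features", "evaluation",
                               "synthetic"}
        if unknown:
            raise ConfigError(f"unknown top-level sections: {sorted(unknown)}")
        ev = dict(data.get("evaluation", {}))
        if "models" in ev:
            try:
                ev["models"] = tuple(_MODEL_SHORTHAND[m] for m in ev["models"])
            except KeyError as err:
                raise ConfigError(
                    f"unknown model {err.args[0]!r}; choose from "
                    f"{sorted(_MODEL_SHORTHAND)}") from None
        for key in ("split_modes", "impute_schemes"):
            if key in ev:
                ev[key] = tuple(ev[key])
        sy = dict(data.get("synthetic", {}))
        for key in ("tests_per_patient", "channel_counts"):
            if key in sy:
                sy[key] = tuple(sy[key])
        try:
            return cls(
                io=_build_section(IoParams, data.get("io", {}), "io"),
                preprocess=_build_section(PreprocessParams,
                                          data.get("preprocess", {}),
                                          "preprocess"),
                features=_build_section(FeatureParams,
                                        data.get("features", {}), "features"),
                evaluation=_build_section(ExperimentConfig, ev, "evaluation"),
                synthetic=_build_section(SyntheticCohortSpec, sy, "synthetic"),
            )
        except (TypeError, ValueError) as err:
            if isinstance(err, ConfigError):
                raise
            raise ConfigError(str(err)) from err

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def with_seed(self, seed: int) -> "PipelineConfig":
        """Override every seed-bearing section at once."""
        return replace(self,
                       evaluation=replace(self.evaluation, base_seed=seed),
                       synthetic=replace(self.synthetic, seed=seed))
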