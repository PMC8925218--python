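"""Run configuration: YAML loading with strict key validation.

A run config has three blocks mirroring the pipeline stages plus a seed:

.. code-block:: yaml

    seed: 1
    cohort:            # population model (CohortConfig fields)
      n_subjects: 10
      eta_median: 43.9
    gait:              # sampling / scene rendering (GaitConfig fields)
      frame_rate: 50.0
    analysis:          # per-trial analysis (AnalysisConfig fields)
      contact_threshold_n: 10.0

Unknown keys are rejected with the full key path, so typos fail loudly.
:func:`paper_defaults` returns the configuration calibrated to the source
study's reported cohort (its values are the dataclass defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import InvalidConfigError
from .synthetic import CohortConfig, GaitConfig

__all__ = ["AnalysisConfig", "RunConfig", "paper_defaults", "load_config"]


@dataclass
class AnalysisConfig:
    """Knobs of the per-trial analysis stage."""

    contact_threshold_n: float = 10.0  # N, fallback force-threshold contact
    min_consecutive: int = 1
    smoothing: bool = False  # local-polynomial smoothing of strain

    def __post_init__(self) -> None:
        if self.contact_threshold_n <= 0:
            raise InvalidConfigError("contact_threshold_n must be positive")
        if self.min_consecutive < 1:
            raise InvalidConfigError("min_consecutive must be >= 1")


@dataclass
class RunConfig:
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def paper_defaults() -> RunConfig:
    """The default, study-calibrated configuration."""
    return RunConfig()


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: expected a mapping")
    known = {f.name for f in fields(cls)}
    for key in data:
        if key not in known:
            raise InvalidConfigError(f"unknown config key '{path}.{key}'")
    # YAML gives lists where dataclasses may want tuples (e.g. age_range)
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in data.items()
    }
    try:
        return cls(**coerced)
    except InvalidConfigError as exc:
        raise InvalidConfigError(f"{path}: {exc}") from exc


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run config; missing blocks fall back to defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        return RunConfig()
    if not isinstance(raw, dict):
        raise InvalidConfigError("top level of config must be a mapping")
    known = {"seed", "cohort", "gait", "analysis"}
    for key in raw:
        if key not in known:
            raise InvalidConfigError(f"unknown config key '{key}'")
    return RunConfig(
        seed=int(raw.get("seed", 0)),
        cohort=_build(CohortConfig, raw.get("cohort", {}), "cohort"),
        gait=_build(GaitConfig, raw.get("gait", {}), "gait"),
        analysis=_build(AnalysisConfig, raw.get("analysis", {}), "analysis"),
    )
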