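"""End-to-end helpers tying the stages together in memory.

The CLI, the examples and the reproduction script all run through these,
so file-based and in-memory runs follow identical code paths.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig, RunConfig
from .mechanics import analyze_trial
from .stats import CohortRecord, compare_conditions, pearson_matrix, summarize
from .synthetic import HeelParams, sample_cohort, simulate_stance

__all__ = ["analyze_cohort", "run_cohort", "cohort_report"]


def analyze_cohort(
    pairs: list[tuple[HeelParams, "object"]],
    analysis: AnalysisConfig | None = None,
    scenes: dict | None = None,
) -> list[CohortRecord]:
    """Analyze one trial per heel and join the subject covariates.

    ``pairs`` is a list of (HeelParams, TrialTimeSeries); ``scenes``
    optionally maps (subject_id, side, condition) to a GeometryScene, in
    which case thickness is recomputed from geometry.
    """
    analysis = analysis or AnalysisConfig()
    records = []
    for p, ts in pairs:
        scene = scenes.get((p.subject_id, p.side, p.condition)) if scenes else None
        props = analyze_trial(
            ts,
            scene=scene,
            contact_threshold_n=analysis.contact_threshold_n,
            min_consecutive=analysis.min_consecutive,
            smoothing=analysis.smoothing,
        )
        records.append(
            CohortRecord(
                subject_id=p.subject_id,
                side=p.side,
                condition=p.condition,
                age=p.age,
                bmi=p.bmi,
                properties=props,
            )
        )
    return records


def run_cohort(cfg: RunConfig, seed: int | None = None) -> list[CohortRecord]:
    """Sample, simulate and analyze a full cohort for one seed."""
    seed = cfg.seed if seed is None else seed
    pairs = [
        (p, simulate_stance(p, cfg.gait, seed)) for p in sample_cohort(cfg.cohort, seed)
    ]
    return analyze_cohort(pairs, cfg.analysis)


def cohort_report(records: list[CohortRecord]) -> dict:
    """Summary table, per-condition correlation matrices, paired comparison."""
    out: dict = {"summary": summarize(records)}
    conditions = sorted({r.condition for r in records})
    out["correlations"] = {
        c: pearson_matrix(records, condition=c) for c in conditions
    }
    if len(conditions) == 2:
        comparison, standardized = compare_conditions(records)
        out["comparison"] = comparison
        out["standardized"] = standardized
    return out


def median_properties(records: list[CohortRecord], condition: str) -> pd.Series:
    """Median of each property over the heels of one condition."""
    from .stats import PROPERTY_NAMES, records_to_frame

    df = records_to_frame(records)
    df = df[df["condition"] == condition]
    return df[list(PROPERTY_NAMES)].median()
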