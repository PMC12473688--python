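"""Rule-based expert decision tree over the aggregated gait features.

The tree mirrors how veterinarians triage: the head algorithm first
isolates the most severe grade (pronounced head bobbing), the spine
algorithm then separates near-sound cows (grades 1-2, straight back)
from the rest and resolves 1 vs 2, the legs algorithm splits grade 3
from 4-6 on the track-up shortfall, and the head algorithm finally
separates grade 6 from the merged 4-5 class.  Grades 4 and 5 are emitted
as one merged class (ordinal 4.5 by default) because they are clinically
hard to tell apart.

Threshold values are farm- and pipeline-specific and were never
published; :func:`calibrate_thresholds` reproduces the calibration role
the experts played by placing each threshold at the midpoint between the
class-conditional medians of the two grades adjacent to its split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .aggregation import AggregatedFeatures

__all__ = ["ExpertTreeConfig", "classify_expert", "calibrate_thresholds"]


@dataclass(frozen=True)
class ExpertTreeConfig:
    """Thresholds of the decision tree (all on aggregated features).

    ``theta_head_7``: head_drop at or above -> grade 7.
    ``theta_spine_12_36``: spine_value at or above -> grades 1-2 side.
    ``theta_spine_1_2``: spine_value at or above -> grade 1 (else 2).
    ``theta_legs_3_46``: legs_value at or below -> grade 3.
    ``theta_head_45_6``: head_drop at or above -> grade 6 (else merged 4-5).
    ``merged_45_output``: ordinal emitted for the merged 4-5 leaf.
    """

    theta_head_7: float
    theta_spine_12_36: float
    theta_spine_1_2: float
    theta_legs_3_46: float
    theta_head_45_6: float
    merged_45_output: float = 4.5

    def __post_init__(self) -> None:
        vals = [
            self.theta_head_7,
            self.theta_spine_12_36,
            self.theta_spine_1_2,
            self.theta_legs_3_46,
            self.theta_head_45_6,
        ]
        if not all(np.isfinite(vals)):
            raise ValueError("all thresholds must be finite")
        if self.theta_spine_1_2 < self.theta_spine_12_36:
            raise ValueError(
                "theta_spine_1_2 must be >= theta_spine_12_36 "
                "(a straighter spine cannot mean a worse grade)"
            )


def classify_expert(features: AggregatedFeatures, config: ExpertTreeConfig) -> float:
    """Route one passage through the tree; returns a grade in
    {1, 2, 3, merged_45_output, 6, 7}.

    Sentinel (``None``) head features — passages without detected steps —
    take the healthy branch at both head nodes (no evidence of bobbing);
    a sentinel legs value takes the grade-3 branch for the same reason.
    Equality always takes the branch stated in :class:`ExpertTreeConfig`.
    """
    head = features.head_drop
    if head is not None and head >= config.theta_head_7:
        return 7.0
    if features.spine_value >= config.theta_spine_12_36:
        if features.spine_value >= config.theta_spine_1_2:
            return 1.0
        return 2.0
    legs = features.legs_value
    if legs is None or legs <= config.theta_legs_3_46:
        return 3.0
    if head is not None and head >= config.theta_head_45_6:
        return 6.0
    return float(config.merged_45_output)


# split name -> (feature column, grade below the boundary, grade above)
_SPLITS = {
    "theta_head_7": ("head_drop", 6, 7),
    "theta_spine_12_36": ("spine_value", 2, 3),
    "theta_spine_1_2": ("spine_value", 1, 2),
    "theta_legs_3_46": ("legs_value", 3, 4),
    "theta_head_45_6": ("head_drop", 5, 6),
}


def calibrate_thresholds(
    features: list[AggregatedFeatures] | pd.DataFrame,
    merged_45_output: float = 4.5,
) -> ExpertTreeConfig:
    """Set each threshold from labeled feature rows.

    Each threshold becomes the midpoint between the class-conditional
    medians of its feature for the two grades adjacent to the split
    boundary (e.g. grades 3 and 4 for the legs split).  Deterministic;
    raises when a split has no data on one of its sides.
    """
    if isinstance(features, pd.DataFrame):
        df = features
    else:
        from .aggregation import features_to_frame

        df = features_to_frame(features)
    if df["label"].isna().any():
        raise ValueError("calibration requires a grade label on every row")
    thetas = {}
    for split, (col, lo, hi) in _SPLITS.items():
        med = {}
        for grade in (lo, hi):
            vals = df.loc[df["label"] == grade, col].dropna()
            if vals.empty:
                raise ValueError(f"split {split}: no data for grade {grade}")
            med[grade] = float(vals.median())
        thetas[split] = (med[lo] + med[hi]) / 2.0
    return ExpertTreeConfig(merged_45_output=merged_45_output, **thetas)
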