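"""Collapse per-frame indicator series into per-passage scalar features.

The expert tree and the classical ML backends consume one number per
indicator and passage:

* ``spine_value`` — each spine channel (angle ratio, distance ratio) is
  smoothed with a centred moving average, its local minima are averaged
  (the arch is deepest where the ratios dip), and the two channel
  aggregates are blended with a configurable weight.
* ``head_min`` / ``head_drop`` — the global minimum of the smoothed,
  step-gated head height, and the mean per-step drop from the step's
  initial loading phase to the within-stance minimum.  The drop is the
  head-bob amplitude in cow-height units.
* ``legs_value`` — per pair, the minimum normalized track-up distance in
  each rear-hoof touchdown window, averaged over steps, then averaged
  over the two pairs.

Passages where no step was detected yield ``None`` sentinels for the
head and leg features; downstream consumers decide (the expert tree
takes the healthy branch, the ML backend imputes the training median).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gait_events import initial_phase
from .indicators import REAR_OF_PAIR, IndicatorSeries

logger = logging.getLogger("bovigait")

__all__ = [
    "AggregateConfig",
    "AggregatedFeatures",
    "smooth",
    "local_minima",
    "aggregate_spine",
    "aggregate_head",
    "aggregate_legs",
    "build_features",
    "features_to_frame",
    "frame_to_features",
]


@dataclass(frozen=True)
class AggregateConfig:
    """Aggregation tuning: smoothing window (odd, frames), angle/distance
    blend weight for the spine value, and the initial-phase fraction of a
    stance used as the head-drop reference."""

    window: int = 5
    spine_blend: float = 0.5
    initial_phase_frac: float = 0.2


@dataclass
class AggregatedFeatures:
    """The per-passage scalars fed to the expert tree and ML backends."""

    passage_id: str
    spine_value: float
    head_min: float | None
    head_drop: float | None
    legs_value: float | None
    n_steps: int
    label: int | None = None


# ---------------------------------------------------------------------------
# Series primitives
# ---------------------------------------------------------------------------


def smooth(values: np.ndarray, window: int, valid: np.ndarray | None = None) -> np.ndarray:
    """Centred moving average with reflect padding, over valid frames only.

    Invalid frames neither contribute to their neighbours' averages nor
    receive a value (they stay NaN).
    """
    values = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be an odd positive integer")
    if valid is None:
        valid = np.isfinite(values)
    valid = np.asarray(valid, dtype=bool)
    out = np.where(valid, values, np.nan)
    if window == 1 or values.size == 0:
        return out
    half = window // 2
    pad_mode = "reflect" if half <= values.size - 1 else "edge"
    v = np.pad(np.where(valid, values, 0.0), half, mode=pad_mode)
    m = np.pad(valid.astype(float), half, mode=pad_mode)
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="valid")
    den = np.convolve(m, kernel, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        avg = num / den
    out[valid & (den > 0)] = avg[valid & (den > 0)]
    return out


def local_minima(values: np.ndarray, valid: np.ndarray | None = None) -> list[int]:
    """Indices of local minima of a (smoothed) series.

    A frame is a minimum when its value is below both valid neighbours;
    a constant plateau flanked by larger values yields one index at the
    floor of the plateau centre.  Endpoints are never minima.  Invalid
    frames are skipped when determining neighbours.
    """
    values = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(values)
    idx = np.flatnonzero(np.asarray(valid, dtype=bool) & np.isfinite(values))
    if idx.size < 3:
        return []
    v = values[idx]
    minima: list[int] = []
    # maximal runs of equal value over the compressed sequence
    i = 0
    m = v.size
    while i < m:
        j = i
        while j + 1 < m and v[j + 1] == v[i]:
            j += 1
        if i > 0 and j < m - 1 and v[i - 1] > v[i] and v[j + 1] > v[i]:
            minima.append(int((idx[i] + idx[j]) // 2))
        i = j + 1
    return minima


# ---------------------------------------------------------------------------
# Per-indicator aggregates
# ---------------------------------------------------------------------------


def _minima_aggregate(values: np.ndarray, valid: np.ndarray, window: int) -> float:
    """Mean of smoothed local-minima values; global minimum when the
    series has no interior minimum (e.g. short or monotone passages)."""
    sm = smooth(values, window, valid)
    mins = local_minima(sm)
    if mins:
        return float(np.mean(sm[mins]))
    finite = sm[np.isfinite(sm)]
    return float(np.min(finite))


def aggregate_spine(
    series: IndicatorSeries,
    blend_weight: float = 0.5,
    window: int = 5,
) -> float:
    """Blend of the angle and distance spine aggregates in (0, 1]."""
    if not 0.0 <= blend_weight <= 1.0:
        raise ValueError("blend_weight must be in [0, 1]")
    have = {
        name: series.valid[name].any()
        for name in ("spine_angle_ratio", "spine_distance_ratio")
    }
    if not any(have.values()):
        raise ValueError("no valid spine frames")
    parts = {}
    for name in have:
        if have[name]:
            parts[name] = _minima_aggregate(series.values[name], series.valid[name], window)
    if len(parts) == 1:
        logger.warning("passage %s: only one spine channel valid", series.passage_id)
        return next(iter(parts.values()))
    return (
        blend_weight * parts["spine_angle_ratio"]
        + (1.0 - blend_weight) * parts["spine_distance_ratio"]
    )


def aggregate_head(
    series: IndicatorSeries,
    window: int = 5,
    initial_phase_frac: float = 0.2,
) -> tuple[float | None, float | None]:
    """(head_min, head_drop) from the smoothed, step-gated head channel.

    ``head_min`` is the global minimum of the smoothed values and
    separates the most severe grade from the rest; ``head_drop`` is the
    mean over steps of (initial-phase mean - within-stance minimum) and
    quantifies head bobbing.  Returns ``(None, None)`` when no step has
    valid head frames (not computable).
    """
    sm = smooth(series.values["head_norm"], window, series.valid["head_norm"])
    finite = np.isfinite(sm)
    if not finite.any():
        return None, None
    head_min = float(np.min(sm[finite]))
    drops = []
    for events in series.steps.values():
        for ev in events:
            s, e = ev.stance_interval
            stance_vals = sm[s : e + 1]
            stance_vals = stance_vals[np.isfinite(stance_vals)]
            ps, pe = initial_phase(ev, initial_phase_frac)
            init_vals = sm[ps : pe + 1]
            init_vals = init_vals[np.isfinite(init_vals)]
            if stance_vals.size == 0 or init_vals.size == 0:
                continue
            drops.append(float(np.mean(init_vals) - np.min(stance_vals)))
    if not drops:
        return None, None
    return head_min, float(np.mean(drops))


def aggregate_legs(series: IndicatorSeries) -> float | None:
    """Mean over pairs of the mean per-step minimum track-up distance.

    Per pair, each rear-hoof step contributes the minimum valid distance
    within its touchdown window; the per-step minima are averaged over
    steps and the two pair values averaged.  ``None`` when neither pair
    has any valid data (not computable).
    """
    window = max(0, round(series.config.leg_window * series.fps / 30.0))
    F = series.n_frames
    pair_values = []
    for pair, rear in REAR_OF_PAIR.items():
        vals = series.values[f"leg_dist_{pair}"]
        step_minima = []
        for ev in series.steps.get(rear, []):
            lo = max(0, ev.touchdown_frame - window)
            hi = min(F - 1, ev.touchdown_frame + window)
            seg = vals[lo : hi + 1]
            seg = seg[np.isfinite(seg)]
            if seg.size:
                step_minima.append(float(np.min(seg)))
        if step_minima:
            pair_values.append(float(np.mean(step_minima)))
    if not pair_values:
        return None
    if len(pair_values) == 1:
        logger.warning("passage %s: leg data for a single pair only", series.passage_id)
    return float(np.mean(pair_values))


def build_features(
    series: IndicatorSeries,
    config: AggregateConfig | None = None,
    label: int | None = None,
) -> AggregatedFeatures:
    """Bundle the three aggregates (plus the auxiliary head minimum)."""
    config = config or AggregateConfig()
    spine_value = aggregate_spine(series, config.spine_blend, config.window)
    head_min, head_drop = aggregate_head(series, config.window, config.initial_phase_frac)
    legs_value = aggregate_legs(series)
    return AggregatedFeatures(
        passage_id=series.passage_id,
        spine_value=spine_value,
        head_min=head_min,
        head_drop=head_drop,
        legs_value=legs_value,
        n_steps=series.n_steps,
        label=label,
    )


# ---------------------------------------------------------------------------
# Tabular round-trip
# ---------------------------------------------------------------------------

_COLUMNS = ["passage_id", "spine_value", "head_min", "head_drop", "legs_value", "n_steps", "label"]


def features_to_frame(features: list[AggregatedFeatures]) -> pd.DataFrame:
    rows = [
        (
            f.passage_id,
            f.spine_value,
            np.nan if f.head_min is None else f.head_min,
            np.nan if f.head_drop is None else f.head_drop,
            np.nan if f.legs_value is None else f.legs_value,
            f.n_steps,
            np.nan if f.label is None else f.label,
        )
        for f in features
    ]
    return pd.DataFrame(rows, columns=_COLUMNS)


def frame_to_features(df: pd.DataFrame) -> list[AggregatedFeatures]:
    out = []
    for _, row in df.iterrows():
        out.append(
            AggregatedFeatures(
                passage_id=str(row["passage_id"]),
                spine_value=float(row["spine_value"]),
                head_min=None if pd.isna(row["head_min"]) else float(row["head_min"]),
                head_drop=None if pd.isna(row["head_drop"]) else float(row["head_drop"]),
                legs_value=None if pd.isna(row["legs_value"]) else float(row["legs_value"]),
                n_steps=int(row["n_steps"]),
                label=None if pd.isna(row["label"]) else int(row["label"]),
            )
        )
    return out
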