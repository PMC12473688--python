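"""Per-frame locomotion indicators: spine curvature, head height, leg track-up.

Three interpretable gait signs drive the lameness score:

* **Spine curvature** — a lame cow arches its back.  Quantified two ways
  on the five spine points (Neck, Spine_1..Spine_4) after normalizing
  coordinates to the cow's bounding box: an *angle ratio* (the angle at
  Spine_2 between rays to Neck and Spine_4, read off a least-squares
  circle fitted to the spine, divided by 180 deg) and a *distance ratio*
  (chord Neck-Spine_4 over the polyline length through all five points).
  Both are 1.0 for a perfectly straight spine and fall as the arch grows.
* **Head height** — severe lameness shows as vertical head bobbing
  phase-locked to loading of the affected limb.  The eye's height is
  scaled between the lowest hoof (ground) and the highest spine point
  (back line), and only read while some hoof is in stance.
* **Leg track-up distance** — the horizontal gap between same-side front
  and rear hooves, normalized by cow height, sampled around rear-hoof
  touchdowns.  A sound cow places the rear hoof in the front hoof's
  print (gap near zero); the shortfall grows with lameness.

All four values are ratios of lengths, hence invariant to translation
and uniform scaling of the input coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gait_events import GaitConfig, StepEvent, detect_steps
from .skeleton_io import SKELETON, FrameObservation, PassageTrack, SkeletonSpec

logger = logging.getLogger("bovigait")

__all__ = [
    "CircleFit",
    "IndicatorConfig",
    "IndicatorSeries",
    "fit_circle",
    "spine_angle_ratio",
    "spine_distance_ratio",
    "head_position_norm",
    "leg_pair_distance",
    "compute_indicator_series",
]

LEG_PAIRS = {"FR_BR": ("FR_Hoof", "BR_Hoof"), "FL_BL": ("FL_Hoof", "BL_Hoof")}
#: rear hoof of each same-side pair; its touchdowns gate the distance window
REAR_OF_PAIR = {"FR_BR": "BR", "FL_BL": "BL"}


@dataclass(frozen=True)
class IndicatorConfig:
    """Indicator tuning.

    ``angle_mode`` selects whether the spine angle is measured between
    radial projections onto the fitted circle (noise-robust; matches the
    raw angle in the noiseless limit) or directly between the raw
    keypoints.  ``height_mode`` selects the cow-height proxy used to
    normalize head and leg values: ``anatomical`` (lowest hoof to highest
    spine point) or ``bbox`` (bounding-box height).  ``leg_window`` is
    the half-width in frames (at 30 fps, scaled by fps/30) of the
    touchdown window in which leg distances are read.
    """

    angle_mode: str = "projected"  # or "raw"
    height_mode: str = "anatomical"  # or "bbox"
    leg_window: int = 10

    def __post_init__(self) -> None:
        if self.angle_mode not in ("projected", "raw"):
            raise ValueError(f"unknown angle_mode {self.angle_mode!r}")
        if self.height_mode not in ("anatomical", "bbox"):
            raise ValueError(f"unknown height_mode {self.height_mode!r}")


# ---------------------------------------------------------------------------
# Circle fit (Kasa algebraic least squares)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircleFit:
    center: tuple[float, float]
    radius: float
    rms_residual: float
    degenerate: bool


def fit_circle(points: np.ndarray) -> CircleFit:
    """Algebraic least-squares circle through >= 3 points.

    Minimizes ``sum((x^2 + y^2 + D x + E y + F)^2)`` (the Kasa
    formulation), solved on centred, rms-scaled coordinates for
    conditioning.  The fit is flagged degenerate when the points are
    collinear within tolerance: normal-equation condition number above
    1e8 or fitted radius above 1e6 times the point spread.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (x, y) points")
    centroid = pts.mean(axis=0)
    q = pts - centroid
    scale = float(np.sqrt(np.mean(np.sum(q**2, axis=1))))
    if scale == 0.0:
        raise ValueError("all points coincident")
    u = q / scale
    A = np.column_stack([u[:, 0], u[:, 1], np.ones(len(u))])
    b = -(u[:, 0] ** 2 + u[:, 1] ** 2)
    M = A.T @ A
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e8:
        return CircleFit((np.nan, np.nan), np.inf, np.nan, degenerate=True)
    D, E, F = np.linalg.solve(M, A.T @ b)
    cu = np.array([-D / 2.0, -E / 2.0])
    r2 = float(cu @ cu - F)
    if r2 <= 0.0:
        return CircleFit((np.nan, np.nan), np.inf, np.nan, degenerate=True)
    radius = float(np.sqrt(r2)) * scale
    center = cu * scale + centroid
    spread = float(np.max(np.linalg.norm(pts - pts.mean(axis=0), axis=1)))
    if radius > 1e6 * max(spread, np.finfo(float).tiny):
        return CircleFit((np.nan, np.nan), np.inf, np.nan, degenerate=True)
    resid = np.linalg.norm(pts - center, axis=1) - radius
    return CircleFit(
        (float(center[0]), float(center[1])),
        radius,
        float(np.sqrt(np.mean(resid**2))),
        degenerate=False,
    )


# ---------------------------------------------------------------------------
# Spine curvature
# ---------------------------------------------------------------------------


def _angle_deg(vertex: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """Angle at ``vertex`` between rays to ``a`` and ``b``, in degrees."""
    va, vb = a - vertex, b - vertex
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        return np.nan
    c = float(np.clip(va @ vb / (na * nb), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def angle_ratio_from_points(spine_points: np.ndarray, angle_mode: str = "projected") -> float:
    """Spine angle ratio from the ordered 5 spine points (Neck..Spine_4).

    Fits a circle to all five points, radially projects Neck, Spine_2
    and Spine_4 onto it and returns the angle at projected Spine_2
    divided by 180.  On a degenerate (straight-spine) fit, or with
    ``angle_mode='raw'``, the raw three-point angle is used, which
    approaches 1.0 for a collinear spine.
    """
    pts = np.asarray(spine_points, dtype=float)
    neck, s2, s4 = pts[0], pts[2], pts[4]
    if angle_mode == "projected":
        fit = fit_circle(pts)
        if not fit.degenerate:
            c = np.asarray(fit.center)
            proj = []
            for p in (neck, s2, s4):
                d = p - c
                n = np.linalg.norm(d)
                if n == 0.0:
                    break
                proj.append(c + fit.radius * d / n)
            if len(proj) == 3:
                return _angle_deg(proj[1], proj[0], proj[2]) / 180.0
    return _angle_deg(s2, neck, s4) / 180.0


def distance_ratio_from_points(spine_points: np.ndarray) -> float:
    """Chord length Neck-Spine_4 over the polyline length of the chain."""
    pts = np.asarray(spine_points, dtype=float)
    chord = float(np.linalg.norm(pts[-1] - pts[0]))
    path = float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))
    if path == 0.0:
        return np.nan
    return chord / path


def _bbox_normalized_spine(frame: FrameObservation, skeleton: SkeletonSpec) -> np.ndarray | None:
    idx = skeleton.indices(skeleton.groups["spine"])
    if not frame.visible[idx].all():
        return None
    x1, y1, x2, y2 = frame.bbox
    pts = frame.keypoints[idx].astype(float)
    return (pts - [x1, y1]) / [x2 - x1, y2 - y1]


def spine_angle_ratio(
    frame: FrameObservation,
    skeleton: SkeletonSpec = SKELETON,
    angle_mode: str = "projected",
) -> float:
    """Angle ratio in (0, 1] for one frame; NaN when spine points are missing."""
    pts = _bbox_normalized_spine(frame, skeleton)
    if pts is None:
        return np.nan
    return angle_ratio_from_points(pts, angle_mode)


def spine_distance_ratio(frame: FrameObservation, skeleton: SkeletonSpec = SKELETON) -> float:
    """Distance ratio in (0, 1] for one frame; NaN when spine points are missing."""
    pts = _bbox_normalized_spine(frame, skeleton)
    if pts is None:
        return np.nan
    return distance_ratio_from_points(pts)


# ---------------------------------------------------------------------------
# Head height and leg distances (canonical y-up frame)
# ---------------------------------------------------------------------------


def _ground_and_back(frame: FrameObservation, skeleton: SkeletonSpec) -> tuple[float, float]:
    """(lowest visible hoof y, highest visible spine y); NaN when unavailable."""
    hoof_idx = skeleton.indices(skeleton.hoof_set)
    spine_idx = skeleton.indices(skeleton.groups["spine"])
    hv = frame.visible[hoof_idx]
    sv = frame.visible[spine_idx]
    if not hv.any() or not sv.any():
        return np.nan, np.nan
    y_ground = float(np.min(frame.keypoints[hoof_idx][hv, 1]))
    y_back = float(np.max(frame.keypoints[spine_idx][sv, 1]))
    return y_ground, y_back


def _height(frame: FrameObservation, skeleton: SkeletonSpec, height_mode: str) -> float:
    if height_mode == "bbox":
        return float(frame.bbox[3] - frame.bbox[1])
    y_ground, y_back = _ground_and_back(frame, skeleton)
    return y_back - y_ground


def head_position_norm(frame: FrameObservation, skeleton: SkeletonSpec = SKELETON) -> float:
    """Eye height scaled between the lowest hoof and the highest spine point.

    0 at ground level, 1 at the back line; not clamped.  Requires the
    canonical y-up frame.  NaN when the needed points are missing or the
    posture is implausible (back at or below ground).
    """
    eye = skeleton.index("Eye")
    if not frame.visible[eye]:
        return np.nan
    y_ground, y_back = _ground_and_back(frame, skeleton)
    if not np.isfinite(y_ground) or y_back <= y_ground:
        return np.nan
    return (float(frame.keypoints[eye, 1]) - y_ground) / (y_back - y_ground)


def leg_pair_distance(
    frame: FrameObservation,
    pair: str,
    skeleton: SkeletonSpec = SKELETON,
    height_mode: str = "anatomical",
) -> float:
    """|x_front_hoof - x_rear_hoof| / cow height for a same-side pair."""
    front, rear = LEG_PAIRS[pair]
    fi, ri = skeleton.index(front), skeleton.index(rear)
    if not (frame.visible[fi] and frame.visible[ri]):
        return np.nan
    h = _height(frame, skeleton, height_mode)
    if not np.isfinite(h) or h <= 0.0:
        return np.nan
    return abs(float(frame.keypoints[fi, 0] - frame.keypoints[ri, 0])) / h


# ---------------------------------------------------------------------------
# Whole-passage series
# ---------------------------------------------------------------------------

CHANNELS = (
    "spine_angle_ratio",
    "spine_distance_ratio",
    "head_norm",
    "leg_dist_FR_BR",
    "leg_dist_FL_BL",
)


@dataclass
class IndicatorSeries:
    """Per-frame indicator values with validity flags and attached steps.

    ``values[name]`` is a float array over frames (NaN where invalid) and
    ``valid[name]`` the matching boolean mask; channels are gated as the
    pipeline prescribes (head on stance windows, leg distances on
    rear-hoof touchdown windows).
    """

    frame_index: np.ndarray
    values: dict[str, np.ndarray]
    valid: dict[str, np.ndarray]
    steps: dict[str, list[StepEvent]]
    fps: float = 30.0
    passage_id: str = ""
    config: IndicatorConfig = field(default_factory=IndicatorConfig)

    def __post_init__(self) -> None:
        n = self.frame_index.size
        for name in CHANNELS:
            if self.values[name].size != n or self.valid[name].size != n:
                raise ValueError(f"channel {name} length mismatch")

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    @property
    def n_steps(self) -> int:
        return sum(len(v) for v in self.steps.values())

    def to_dataframe(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"frame": self.frame_index}
        for name in CHANNELS:
            cols[name] = self.values[name]
        for name in CHANNELS:
            cols[f"valid_{name}"] = self.valid[name]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compute_indicator_series(
    track: PassageTrack,
    config: IndicatorConfig | None = None,
    gait_config: GaitConfig | None = None,
    steps: dict[str, list[StepEvent]] | None = None,
) -> IndicatorSeries:
    """Apply the per-frame indicators to a canonicalized track.

    Spine ratios are computed on every frame with a full set of spine
    points.  The head value is recorded only on frames inside a detected
    step's stance window (pooled over all hooves).  Each leg-pair
    distance is recorded on frames within ``leg_window`` frames of one of
    its rear hoof's touchdowns.  Everything else is flagged invalid.
    """
    if not track.canonical:
        raise ValueError("track must be canonicalized first")
    config = config or IndicatorConfig()
    if steps is None:
        steps = detect_steps(track, gait_config or GaitConfig())
    F = track.n_frames
    vals = {name: np.full(F, np.nan) for name in CHANNELS}

    window = max(0, round(config.leg_window * track.fps / 30.0))
    head_gate = np.zeros(F, dtype=bool)
    for events in steps.values():
        for ev in events:
            s, e = ev.stance_interval
            head_gate[s : e + 1] = True
    leg_gate = {pair: np.zeros(F, dtype=bool) for pair in LEG_PAIRS}
    for pair, rear in REAR_OF_PAIR.items():
        for ev in steps.get(rear, []):
            lo = max(0, ev.touchdown_frame - window)
            hi = min(F - 1, ev.touchdown_frame + window)
            leg_gate[pair][lo : hi + 1] = True
    if sum(len(v) for v in steps.values()) == 0:
        logger.warning(
            "passage %s: no steps detected; head/leg channels are entirely invalid",
            track.passage_id,
        )

    for i in range(F):
        frame = track.frame(i)
        vals["spine_angle_ratio"][i] = spine_angle_ratio(frame, track.skeleton, config.angle_mode)
        vals["spine_distance_ratio"][i] = spine_distance_ratio(frame, track.skeleton)
        if head_gate[i]:
            vals["head_norm"][i] = head_position_norm(frame, track.skeleton)
        for pair in LEG_PAIRS:
            if leg_gate[pair][i]:
                vals[f"leg_dist_{pair}"][i] = leg_pair_distance(
                    frame, pair, track.skeleton, config.height_mode
                )

    valid = {name: np.isfinite(vals[name]) for name in CHANNELS}
    return IndicatorSeries(
        frame_index=track.frame_index.copy(),
        values=vals,
        valid=valid,
        steps=steps,
        fps=track.fps,
        passage_id=track.passage_id,
        config=config,
    )
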