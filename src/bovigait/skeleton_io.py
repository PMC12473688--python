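"""Skeleton definition, keypoint-track I/O and coordinate canonicalization.

The pipeline consumes per-frame detections of a single cow crossing the
field of view: a bounding box plus 22 named anatomical keypoints (eye,
neck, four spine points and four legs with four joints each).  Everything
downstream assumes one canonical coordinate frame: the cow walks rightward
and the vertical axis increases upward (ground near zero).  Raw video
detections are in image coordinates (y grows downward) and may be
leftward passages, so :func:`canonicalize` is applied once at ingestion.

Two on-disk formats are supported: a COCO-style keypoint JSON (one image
and one annotation per frame, keypoints as flattened ``(x, y, v)``
triplets) and a flat long-format CSV with one row per keypoint per frame
plus a ``__bbox__`` row carrying the box corners.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("bovigait")

__all__ = [
    "SkeletonSpec",
    "SKELETON",
    "FrameObservation",
    "PassageTrack",
    "SchemaError",
    "read_track",
    "write_track",
    "canonicalize",
    "infer_direction",
    "interpolate_missing",
]


class SchemaError(ValueError):
    """Raised when an input file violates the track schema."""


# ---------------------------------------------------------------------------
# Skeleton
# ---------------------------------------------------------------------------

_KEYPOINT_NAMES = (
    "Eye",
    "Neck",
    "Spine_1",
    "Spine_2",
    "Spine_3",
    "Spine_4",
    "FR_Hoof",
    "FR_Fetlock",
    "FR_Carpal",
    "FR_Elbow",
    "FL_Hoof",
    "FL_Fetlock",
    "FL_Carpal",
    "FL_Elbow",
    "BL_Hoof",
    "BL_Fetlock",
    "BL_Ankle",
    "BL_Knee",
    "BR_Hoof",
    "BR_Fetlock",
    "BR_Ankle",
    "BR_Knee",
)


@dataclass(frozen=True)
class SkeletonSpec:
    """The 22 named keypoints and their anatomical groups."""

    names: tuple[str, ...] = _KEYPOINT_NAMES
    groups: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "spine": ("Neck", "Spine_1", "Spine_2", "Spine_3", "Spine_4"),
            "head": ("Eye",),
            "FR": ("FR_Hoof", "FR_Fetlock", "FR_Carpal", "FR_Elbow"),
            "FL": ("FL_Hoof", "FL_Fetlock", "FL_Carpal", "FL_Elbow"),
            "BL": ("BL_Hoof", "BL_Fetlock", "BL_Ankle", "BL_Knee"),
            "BR": ("BR_Hoof", "BR_Fetlock", "BR_Ankle", "BR_Knee"),
        }
    )

    def __post_init__(self) -> None:
        if len(self.names) != 22 or len(set(self.names)) != 22:
            raise ValueError("skeleton must define exactly 22 unique keypoints")
        if len(self.hoof_set) != 4:
            raise ValueError("skeleton must define exactly 4 hooves")
        spine = self.groups["spine"]
        if len(spine) != 5 or "Neck" not in spine:
            raise ValueError("spine group must be Neck plus four spine points")

    @property
    def hoof_set(self) -> tuple[str, ...]:
        return tuple(n for n in self.names if n.endswith("_Hoof"))

    @property
    def hoof_labels(self) -> tuple[str, ...]:
        """Leg labels (FR/FL/BL/BR) that own a hoof."""
        return tuple(n.split("_")[0] for n in self.hoof_set)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def indices(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)


#: Module-level default skeleton shared by the whole pipeline.
SKELETON = SkeletonSpec()


# ---------------------------------------------------------------------------
# Track containers
# ---------------------------------------------------------------------------


@dataclass
class FrameObservation:
    """One frame: bounding box plus 22 keypoints with visibility."""

    frame_index: int
    bbox: np.ndarray  # (4,) x1, y1, x2, y2
    keypoints: np.ndarray  # (22, 2)
    visible: np.ndarray  # (22,) bool

    def __post_init__(self) -> None:
        self.bbox = np.asarray(self.bbox, dtype=float)
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        x1, y1, x2, y2 = self.bbox
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate bbox {self.bbox} at frame {self.frame_index}")
        if self.keypoints.shape != (22, 2):
            raise SchemaError(
                f"frame {self.frame_index}: expected 22 keypoints, "
                f"got shape {self.keypoints.shape}"
            )


@dataclass
class PassageTrack:
    """One cow crossing: stacked per-frame observations.

    Arrays are stacked over frames for vectorized downstream math:
    ``keypoints`` is ``(F, 22, 2)``, ``bbox`` is ``(F, 4)`` with corners
    ``x1, y1, x2, y2``, ``visible``/``imputed`` are ``(F, 22)`` booleans.
    ``canonical`` records whether :func:`canonicalize` has been applied.
    """

    frame_index: np.ndarray
    bbox: np.ndarray
    keypoints: np.ndarray
    visible: np.ndarray
    fps: float = 30.0
    direction: str = "rightward"
    passage_id: str = ""
    label: int | None = None
    imputed: np.ndarray | None = None
    canonical: bool = False
    skeleton: SkeletonSpec = field(default_factory=lambda: SKELETON)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=int)
        self.bbox = np.asarray(self.bbox, dtype=float)
        self.keypoints = np.asarray(self.keypoints, dtype=float)
        self.visible = np.asarray(self.visible, dtype=bool)
        if self.frame_index.size == 0:
            raise SchemaError("no frames")
        if np.any(np.diff(self.frame_index) <= 0):
            raise SchemaError("frame_index must be strictly increasing")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.keypoints.shape[1:] != (22, 2):
            raise SchemaError(f"expected (F, 22, 2) keypoints, got {self.keypoints.shape}")
        if self.direction not in ("rightward", "leftward"):
            raise ValueError(f"unknown direction {self.direction!r}")
        if not (np.all(self.bbox[:, 0] < self.bbox[:, 2]) and np.all(self.bbox[:, 1] < self.bbox[:, 3])):
            raise SchemaError("degenerate bbox (need x1<x2 and y1<y2 in every frame)")
        if self.imputed is None:
            self.imputed = np.zeros_like(self.visible)
        self.imputed = np.asarray(self.imputed, dtype=bool)

    @property
    def n_frames(self) -> int:
        return int(self.frame_index.size)

    def frame(self, i: int) -> FrameObservation:
        """The i-th stored frame as a standalone observation."""
        return FrameObservation(
            frame_index=int(self.frame_index[i]),
            bbox=self.bbox[i].copy(),
            keypoints=self.keypoints[i].copy(),
            visible=self.visible[i].copy(),
        )

    def copy(self) -> "PassageTrack":
        return replace(
            self,
            frame_index=self.frame_index.copy(),
            bbox=self.bbox.copy(),
            keypoints=self.keypoints.copy(),
            visible=self.visible.copy(),
            imputed=self.imputed.copy(),
        )


# ---------------------------------------------------------------------------
# Reading / writing
# ---------------------------------------------------------------------------


def _track_from_frames(frames, fps, direction, passage_id, label) -> PassageTrack:
    frames = sorted(frames, key=lambda f: f["frame_index"])
    idx = [f["frame_index"] for f in frames]
    if len(set(idx)) != len(idx):
        raise SchemaError("duplicate frame_index")
    return PassageTrack(
        frame_index=np.array(idx),
        bbox=np.array([f["bbox"] for f in frames]),
        keypoints=np.array([f["keypoints"] for f in frames]),
        visible=np.array([f["visible"] for f in frames]),
        fps=fps,
        direction=direction,
        passage_id=passage_id,
        label=label,
    )


def _read_coco_json(path) -> PassageTrack:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"malformed JSON in {path}: {exc}") from exc
    info = doc.get("info", {})
    cats = doc.get("categories", [])
    if cats and len(cats[0].get("keypoints", [])) != 22:
        raise SchemaError("category must declare 22 keypoints")
    ann_by_image = {a["image_id"]: a for a in doc.get("annotations", [])}
    frames = []
    for img in doc.get("images", []):
        ann = ann_by_image.get(img["id"])
        if ann is None:
            raise SchemaError(f"image id {img['id']} has no annotation")
        kps = np.asarray(ann["keypoints"], dtype=float)
        if kps.size != 66:
            raise SchemaError(
                f"frame {img.get('frame_index', img['id'])}: expected 22 keypoint "
                f"triplets, got {kps.size // 3}"
            )
        kps = kps.reshape(22, 3)
        x, y, w, h = ann["bbox"]
        frames.append(
            {
                "frame_index": int(img.get("frame_index", img["id"])),
                "bbox": [x, y, x + w, y + h],
                "keypoints": kps[:, :2],
                "visible": kps[:, 2] > 0,
            }
        )
    if not frames:
        raise SchemaError("no frames")
    return _track_from_frames(
        frames,
        fps=float(info.get("fps", 30.0)),
        direction=info.get("direction", "rightward"),
        passage_id=str(info.get("passage_id", "")),
        label=info.get("label"),
    )


def _read_csv(path) -> PassageTrack:
    df = pd.read_csv(path)
    required = {"passage_id", "frame", "keypoint", "x", "y", "visible"}
    if not required.issubset(df.columns):
        raise SchemaError(f"CSV missing columns {sorted(required - set(df.columns))}")
    pid = str(df["passage_id"].iloc[0])
    fps = float(df["fps"].iloc[0]) if "fps" in df.columns else 30.0
    direction = str(df["direction"].iloc[0]) if "direction" in df.columns else "rightward"
    label = None
    if "label" in df.columns and pd.notna(df["label"].iloc[0]):
        label = int(df["label"].iloc[0])
    frames = []
    for fi, grp in df.groupby("frame", sort=True):
        bbox_rows = grp[grp["keypoint"] == "__bbox__"]
        if len(bbox_rows) != 1:
            raise SchemaError(f"frame {fi}: expected exactly one __bbox__ row")
        br = bbox_rows.iloc[0]
        kp_rows = grp[grp["keypoint"] != "__bbox__"].set_index("keypoint")
        if set(kp_rows.index) != set(SKELETON.names):
            raise SchemaError(
                f"frame {fi}: expected the 22 skeleton keypoints, got {len(kp_rows)}"
            )
        kp_rows = kp_rows.loc[list(SKELETON.names)]
        frames.append(
            {
                "frame_index": int(fi),
                "bbox": [br["x"], br["y"], br["x2"], br["y2"]],
                "keypoints": kp_rows[["x", "y"]].to_numpy(dtype=float),
                "visible": kp_rows["visible"].to_numpy(dtype=bool),
            }
        )
    if not frames:
        raise SchemaError("no frames")
    if len({f["frame_index"] for f in frames}) != len(frames):
        raise SchemaError("duplicate frame_index")
    return _track_from_frames(frames, fps, direction, pid, label)


def read_track(path, format: str = "coco_json") -> PassageTrack:
    """Read a passage track in raw image coordinates (y grows downward).

    Parameters
    ----------
    path
        File to read.
    format
        ``"coco_json"`` or ``"csv"`` (the long dialect written by
        :func:`write_track`).
    """
    if format == "coco_json":
        return _read_coco_json(path)
    if format == "csv":
        return _read_csv(path)
    raise ValueError(f"unknown format {format!r}")


def write_track(track: PassageTrack, path, format: str = "coco_json") -> None:
    """Write a track; inverse of :func:`read_track` for both formats."""
    if format == "coco_json":
        images, annotations = [], []
        for i in range(track.n_frames):
            fi = int(track.frame_index[i])
            images.append({"id": fi, "frame_index": fi})
            x1, y1, x2, y2 = track.bbox[i]
            kps = np.concatenate(
                [track.keypoints[i], np.where(track.visible[i], 2.0, 0.0)[:, None]],
                axis=1,
            )
            annotations.append(
                {
                    "id": fi,
                    "image_id": fi,
                    "category_id": 1,
                    "bbox": [x1, y1, x2 - x1, y2 - y1],
                    "keypoints": kps.ravel().tolist(),
                    "num_keypoints": int(track.visible[i].sum()),
                }
            )
        doc = {
            "info": {
                "passage_id": track.passage_id,
                "fps": track.fps,
                "direction": track.direction,
                "label": track.label,
            },
            "categories": [
                {"id": 1, "name": "cow", "keypoints": list(track.skeleton.names)}
            ],
            "images": images,
            "annotations": annotations,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    elif format == "csv":
        rows = []
        for i in range(track.n_frames):
            fi = int(track.frame_index[i])
            x1, y1, x2, y2 = track.bbox[i]
            rows.append((track.passage_id, fi, "__bbox__", x1, y1, True, x2, y2))
            for k, name in enumerate(track.skeleton.names):
                rows.append(
                    (
                        track.passage_id,
                        fi,
                        name,
                        track.keypoints[i, k, 0],
                        track.keypoints[i, k, 1],
                        bool(track.visible[i, k]),
                        np.nan,
                        np.nan,
                    )
                )
        df = pd.DataFrame(
            rows,
            columns=["passage_id", "frame", "keypoint", "x", "y", "visible", "x2", "y2"],
        )
        df["fps"] = track.fps
        df["direction"] = track.direction
        df["label"] = track.label if track.label is not None else np.nan
        df.to_csv(path, index=False)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Canonicalization
# ---------------------------------------------------------------------------


def infer_direction(track: PassageTrack) -> str:
    """Direction of motion from the median per-frame bbox-center displacement."""
    cx = (track.bbox[:, 0] + track.bbox[:, 2]) / 2.0
    med = np.median(np.diff(cx))
    return "rightward" if med >= 0 else "leftward"


def canonicalize(track: PassageTrack) -> PassageTrack:
    """Map a raw track into the canonical frame (y up, motion rightward).

    The vertical axis is flipped about the track-wide maximum bbox bottom
    (``y' = H - y`` with ``H = max y2``); a per-frame reference would
    inject box jitter into the kinematics.  Leftward passages are
    mirrored about the track-wide maximum bbox right edge.  Both maps are
    isometries, so within-frame geometry is preserved exactly.
    Idempotent: canonical tracks are returned as copies, unchanged.
    """
    if track.n_frames < 2:
        raise ValueError("cannot infer motion from a single-frame track")
    out = track.copy()
    if track.canonical:
        return out
    # vertical flip: image y grows downward -> canonical y grows upward
    H = float(np.max(track.bbox[:, 3]))
    out.keypoints[:, :, 1] = H - out.keypoints[:, :, 1]
    y1 = H - track.bbox[:, 3]
    y2 = H - track.bbox[:, 1]
    out.bbox[:, 1], out.bbox[:, 3] = y1, y2
    # horizontal mirror for leftward passages
    if track.direction == "leftward":
        W = float(np.max(track.bbox[:, 2]))
        out.keypoints[:, :, 0] = W - out.keypoints[:, :, 0]
        x1 = W - track.bbox[:, 2]
        x2 = W - track.bbox[:, 0]
        out.bbox[:, 0], out.bbox[:, 2] = x1, x2
        out.direction = "rightward"
    out.canonical = True
    return out


# ---------------------------------------------------------------------------
# Gap interpolation
# ---------------------------------------------------------------------------


def interpolate_missing(track: PassageTrack, max_gap: int = 3) -> PassageTrack:
    """Fill short invisibility gaps per keypoint by linear interpolation.

    Runs of ``visible == False`` no longer than ``max_gap`` frames that
    are flanked by visible observations are filled linearly (positions
    interpolated against frame index) and marked visible with the
    ``imputed`` flag set.  Gaps at the track start or end are never
    extrapolated, and longer gaps are left untouched.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    out = track.copy()
    if max_gap == 0:
        return out
    t = out.frame_index.astype(float)
    for k in range(22):
        vis = out.visible[:, k]
        if not vis.any():
            logger.warning(
                "keypoint %s never visible in passage %s; left missing",
                out.skeleton.names[k],
                out.passage_id,
            )
            continue
        if vis.all():
            continue
        miss_idx = np.flatnonzero(~vis)
        for start, stop in _runs(miss_idx):
            length = stop - start + 1
            if length > max_gap:
                continue
            if start == 0 or stop == len(vis) - 1:
                continue  # no extrapolation
            lo, hi = start - 1, stop + 1
            for dim in (0, 1):
                out.keypoints[start : stop + 1, k, dim] = np.interp(
                    t[start : stop + 1], [t[lo], t[hi]],
                    [out.keypoints[lo, k, dim], out.keypoints[hi, k, dim]],
                )
            out.visible[start : stop + 1, k] = True
            out.imputed[start : stop + 1, k] = True
    return out


def _runs(indices: np.ndarray):
    """Maximal runs of consecutive integers as (first, last) pairs."""
    if indices.size == 0:
        return
    breaks = np.flatnonzero(np.diff(indices) > 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [indices.size - 1]))
    for s, e in zip(starts, ends):
        yield int(indices[s]), int(indices[e])
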