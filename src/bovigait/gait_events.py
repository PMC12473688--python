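"""Step detection: stance/swing segmentation of hoof trajectories.

Two of the three lameness indicators are only meaningful around steps
(the head dips as the affected limb loads; the leg track-up distance is
read off around a rear-hoof touchdown), so the pipeline needs a step
detector even though it works purely from keypoint positions.

A hoof is in *stance* (ground contact) when its smoothed horizontal speed
drops below a fraction of its own track-wide fast-phase speed, for a
minimum number of consecutive frames.  The threshold is relative, which
makes detection invariant to the spatial scale of the video.  A *step*
is a swing-to-stance transition; its touchdown frame is the first frame
of the stance run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton_io import PassageTrack

__all__ = ["StepEvent", "GaitConfig", "stance_mask", "stance_intervals", "detect_steps"]


@dataclass(frozen=True)
class StepEvent:
    """A swing-to-stance transition of one hoof."""

    hoof: str  # FR / FL / BR / BL
    touchdown_frame: int  # position within the track (row index)
    stance_interval: tuple[int, int]  # inclusive [start, end] row indices

    def __post_init__(self) -> None:
        s, e = self.stance_interval
        if not (s <= self.touchdown_frame <= e):
            raise ValueError("touchdown must lie inside its stance interval")


@dataclass(frozen=True)
class GaitConfig:
    """Step-detector tuning.

    ``speed_frac`` is the stance threshold as a fraction of the hoof's
    95th-percentile smoothed speed; ``min_run`` (frames at 30 fps, scaled
    by fps/30 elsewhere) suppresses spurious one-frame stances;
    ``initial_phase_frac`` defines a step's initial loading phase as the
    leading fraction of its stance interval.
    """

    speed_frac: float = 0.15
    min_run: int = 3
    initial_phase_frac: float = 0.2


def _scaled_min_run(min_run: int, fps: float) -> int:
    return max(1, round(min_run * fps / 30.0))


def stance_mask(
    track: PassageTrack,
    hoof: str,
    speed_frac: float = 0.15,
    min_run: int = 3,
) -> np.ndarray:
    """Boolean per-frame stance mask for one hoof.

    The hoof's x-speed is estimated by central differences, smoothed with
    a 5-frame moving average, and compared against ``speed_frac`` times
    its track-wide 95th percentile.  Slow runs shorter than ``min_run``
    (scaled by fps/30) are reassigned to swing.
    """
    k = track.skeleton.index(f"{hoof}_Hoof")
    vis = track.visible[:, k]
    if vis.mean() < 0.5:
        raise ValueError(f"insufficient hoof visibility for {hoof} "
                         f"({vis.mean():.0%} of frames)")
    x = track.keypoints[:, k, 0]
    speed = np.abs(np.gradient(x, track.frame_index.astype(float)))
    # centred 5-frame moving average with reflect padding
    pad = np.pad(speed, 2, mode="reflect")
    kernel = np.ones(5) / 5.0
    speed = np.convolve(pad, kernel, mode="valid")
    thresh = speed_frac * np.percentile(speed, 95)
    mask = speed <= thresh
    run = _scaled_min_run(min_run, track.fps)
    if run > 1:
        for s, e in _bool_runs(mask):
            if e - s + 1 < run:
                mask[s : e + 1] = False
    return mask


def stance_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive [start, end] intervals of the True runs of a mask."""
    return list(_bool_runs(np.asarray(mask, dtype=bool)))


def detect_steps(
    track: PassageTrack,
    config: GaitConfig | None = None,
    hooves: tuple[str, ...] | None = None,
) -> dict[str, list[StepEvent]]:
    """Detect steps (swing-to-stance transitions) for each hoof.

    A stance run starting at frame 0 has no preceding swing, hence no
    touchdown: it is not reported as a step.  Returns a mapping from leg
    label to its ordered step events.
    """
    config = config or GaitConfig()
    hooves = hooves or track.skeleton.hoof_labels
    steps: dict[str, list[StepEvent]] = {}
    for hoof in hooves:
        mask = stance_mask(track, hoof, config.speed_frac, config.min_run)
        steps[hoof] = events_from_mask(mask, hoof)
    return steps


def events_from_mask(mask: np.ndarray, hoof: str) -> list[StepEvent]:
    """Step events of one hoof from its stance mask: one per
    swing-to-stance transition; a stance run at frame 0 has no step."""
    events = []
    for s, e in stance_intervals(mask):
        if s == 0:
            continue  # stance at track start: interval exists, no step
        events.append(StepEvent(hoof=hoof, touchdown_frame=s, stance_interval=(s, e)))
    return events


def initial_phase(step: StepEvent, frac: float = 0.2) -> tuple[int, int]:
    """Inclusive frame range of a step's initial loading phase.

    Defined as the first ``ceil(frac * stance_length)`` frames of the
    stance interval.
    """
    s, e = step.stance_interval
    n = int(np.ceil(frac * (e - s + 1)))
    return s, s + max(n, 1) - 1


def _bool_runs(mask: np.ndarray):
    """(start, end) inclusive index pairs of True runs."""
    m = np.asarray(mask, dtype=bool)
    if m.size == 0:
        return
    diff = np.diff(m.astype(int))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1))
    if m[0]:
        starts = [0] + starts
    if m[-1]:
        ends = ends + [m.size - 1]
    for s, e in zip(starts, ends):
        yield int(s), int(e)
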