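"""Synthetic 22-keypoint gait generator with grade-controlled pathology.

The generator emits passage tracks of a single cow crossing the field of
view at 30 fps, in raw image coordinates (y grows downward), with known
ground truth — so every pipeline stage can be tested end to end without
restricted farm video.  Three pathological signals scale with the
7-point lameness grade:

* **back arch** — the five spine points lie on a circular arc whose
  sagitta (as a fraction of the spine chord) grows with grade;
* **head bob** — the eye oscillates vertically with an amplitude that is
  a fraction of cow height, phase-locked to the affected limb's stance
  (zero below grade 6);
* **track-up shortfall** — the affected-side rear hoof lands a
  grade-dependent fraction of cow height behind the print its front
  hoof just vacated (a sound cow steps into the print exactly).

Kinematic conventions (chosen once as the study conditions; see
docs/methods.md): 960x540 px video geometry, back height 270 px, spine
chord 360 px, walking speed 8 px/frame, stance = swing = 15 frames
(1 s stride), and diagonal (trot-like) limb phasing — FR+BL move
together, FL+BR together — so every hoof touches down at the same phase
modulo a half-cycle.  The head-dip waveform is flat-bottomed, zero
around touchdowns, once per half-cycle with its trough mid-stance of the
affected limb; with the default 5-frame smoothing this makes the
recovered per-step head drop equal the injected amplitude exactly on
noiseless data, and the minimum same-side hoof gap at a rear touchdown
equal the injected offset exactly.

The grade maps are calibration constants of the simulator, not claims
about real cows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton_io import SKELETON, PassageTrack, write_track

__all__ = ["GaitParams", "GaitTruth", "simulate_passage", "simulate_cohort"]

# grade -> arch sagitta as fraction of spine chord
SAGITTA_BY_GRADE = {1: 0.00, 2: 0.02, 3: 0.05, 4: 0.08, 5: 0.11, 6: 0.14, 7: 0.18}
# grade -> head-bob amplitude as fraction of cow height
BOB_BY_GRADE = {1: 0.0, 2: 0.0, 3: 0.0, 4: 0.0, 5: 0.0, 6: 0.08, 7: 0.25}
# grade -> rear-hoof landing shortfall as fraction of cow height
OFFSET_BY_GRADE = {1: 0.00, 2: 0.02, 3: 0.06, 4: 0.12, 5: 0.18, 6: 0.26, 7: 0.35}

# fixed scene geometry (pixels; 960x540 video, side view)
BACK_HEIGHT = 270.0  # hoof ground line to spine chord
SPINE_CHORD = 360.0
GROUND_Y_IMG = 470.0  # image row of the ground line
EYE_HEIGHT_FRAC = 0.8  # eye baseline as fraction of (back height + sagitta)
SWING_LIFT = 12.0
BBOX_MARGIN = 5.0
ATTACH_HEIGHT_FRAC = 0.65
JOINT_FRACS = {"Fetlock": 0.18, "Carpal": 0.45, "Ankle": 0.45, "Elbow": 0.75, "Knee": 0.75}
SHOULDER_DX, HIP_DX = 150.0, -150.0
EYE_DX, NECK_DX = 225.0, 180.0


@dataclass(frozen=True)
class GaitParams:
    """Simulation parameters; grade-dependent fields default to the maps above."""

    grade: int = 1
    arch_sagitta: float | None = None
    head_bob_amp: float | None = None
    track_up_offset: float | None = None
    stance_frames: int = 15
    swing_frames: int = 15
    n_cycles: int = 4
    speed: float = 8.0  # px / frame
    noise_sigma: float = 2.0  # px, on every keypoint coordinate
    fps: float = 30.0
    seed: int = 0
    direction: str = "rightward"
    affected_limb: str = "BR"

    def __post_init__(self) -> None:
        if not 1 <= self.grade <= 7:
            raise ValueError("grade must be in 1..7")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.affected_limb not in ("BR", "BL"):
            raise ValueError("affected_limb must be a rear limb (BR or BL)")
        for name, default in (
            ("arch_sagitta", SAGITTA_BY_GRADE[self.grade]),
            ("head_bob_amp", BOB_BY_GRADE[self.grade]),
            ("track_up_offset", OFFSET_BY_GRADE[self.grade]),
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, default)

    @property
    def cycle(self) -> int:
        return self.stance_frames + self.swing_frames


@dataclass
class GaitTruth:
    """Generator ground truth for one passage."""

    params: GaitParams
    stance_intervals: dict[str, list[tuple[int, int]]]
    touchdowns: dict[str, list[int]]  # touchdowns preceded by a swing
    head_baseline: float = EYE_HEIGHT_FRAC
    height: float = BACK_HEIGHT


def _smoothstep(u: np.ndarray) -> np.ndarray:
    """Swing progress profile with zero velocity at both ends."""
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _head_dip(t: np.ndarray, params: GaitParams) -> np.ndarray:
    """Flat-bottomed dip waveform in [0, 1], period = half gait cycle.

    Zero around every touchdown phase, full depth mid-stance; the trough
    falls inside the affected limb's stance.
    """
    P = params.cycle / 2.0
    phi = np.mod(t, P)
    a, b, c, d = (6.0, 7.0, 11.0, 12.0)
    a, b, c, d = (v * P / 15.0 for v in (a, b, c, d))
    w = np.zeros_like(phi, dtype=float)
    up = (phi >= a) & (phi < b)
    w[up] = (phi[up] - a) / (b - a)
    w[(phi >= b) & (phi <= c)] = 1.0
    down = (phi > c) & (phi <= d)
    w[down] = (d - phi[down]) / (d - c)
    return w


def simulate_passage(params: GaitParams) -> tuple[PassageTrack, GaitTruth]:
    """Simulate one rightward passage; returns the raw-coordinate track
    (image convention, y down) plus the ground truth."""
    St, Sw, T = params.stance_frames, params.swing_frames, params.cycle
    F = params.n_cycles * T
    t = np.arange(F, dtype=float)
    v = params.speed
    height_eff = BACK_HEIGHT + params.arch_sagitta * SPINE_CHORD

    # limb phasing: diagonal pairs; affected rear limb touches down at t=0 mod T
    offsets = {"FL": 0, "BR": 0, "FR": St, "BL": St}
    shortfall = {
        "BR": params.track_up_offset if params.affected_limb == "BR" else 0.0,
        "BL": params.track_up_offset if params.affected_limb == "BL" else 0.0,
    }
    front_of = {"BR": "FR", "BL": "FL"}
    attach_dx = {"FR": SHOULDER_DX, "FL": SHOULDER_DX, "BR": HIP_DX, "BL": HIP_DX}

    def front_print(t_td: np.ndarray) -> np.ndarray:
        # the front hoof stands under the shoulder mid-stance
        return SHOULDER_DX + v * (t_td + St / 2.0)

    def print_at(leg: str, t_td: np.ndarray) -> np.ndarray:
        if leg in ("FR", "FL"):
            return front_print(t_td)
        # rear hoof lands `shortfall * height` behind the print its
        # same-side front hoof vacated one half-cycle earlier
        return front_print(t_td - St) - shortfall[leg] * height_eff

    hoof_xy: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    truth_stance: dict[str, list[tuple[int, int]]] = {}
    truth_touchdowns: dict[str, list[int]] = {}
    for leg, off in offsets.items():
        phi = np.mod(t - off, T)
        t_td = t - phi
        in_stance = phi < St
        x = np.empty(F)
        y = np.zeros(F)
        x[in_stance] = print_at(leg, t_td[in_stance])
        u = (phi[~in_stance] - St) / Sw
        p0 = print_at(leg, t_td[~in_stance])
        p1 = print_at(leg, t_td[~in_stance] + T)
        x[~in_stance] = p0 + (p1 - p0) * _smoothstep(u)
        y[~in_stance] = SWING_LIFT * np.sin(np.pi * u) ** 2
        hoof_xy[leg] = (x, y)
        # ground truth
        intervals, tds = [], []
        for k in range(-1, params.n_cycles + 1):
            s = off + k * T
            e = s + St - 1
            if e < 0 or s > F - 1:
                continue
            intervals.append((max(s, 0), min(e, F - 1)))
            if s > 0:
                tds.append(s)
        truth_stance[leg] = intervals
        truth_touchdowns[leg] = tds

    # spine: five points on a circular arc above the body centre
    body = v * t
    s_px = params.arch_sagitta * SPINE_CHORD
    spine_dx = np.array([NECK_DX, NECK_DX / 2.0, 0.0, -NECK_DX / 2.0, -NECK_DX])
    if s_px > 0:
        R = ((SPINE_CHORD / 2.0) ** 2 + s_px**2) / (2.0 * s_px)
        yc = BACK_HEIGHT + s_px - R
        spine_y = yc + np.sqrt(R**2 - spine_dx**2)
    else:
        spine_y = np.full(5, BACK_HEIGHT)

    # eye with phase-locked vertical bob
    dip = _head_dip(t, params)
    eye_y = (EYE_HEIGHT_FRAC - params.head_bob_amp * dip) * height_eff
    eye_x = body + EYE_DX

    # assemble keypoints in skeleton order (canonical y-up cow frame)
    kps = np.zeros((F, 22, 2))
    kps[:, SKELETON.index("Eye")] = np.column_stack([eye_x, eye_y])
    for j, name in enumerate(SKELETON.groups["spine"]):
        k = SKELETON.index(name)
        kps[:, k, 0] = body + spine_dx[j]
        kps[:, k, 1] = spine_y[j]
    for leg in ("FR", "FL", "BL", "BR"):
        hx, hy = hoof_xy[leg]
        ax = body + attach_dx[leg]
        ay = ATTACH_HEIGHT_FRAC * BACK_HEIGHT
        kps[:, SKELETON.index(f"{leg}_Hoof")] = np.column_stack([hx, hy])
        for joint, frac in JOINT_FRACS.items():
            name = f"{leg}_{joint}"
            if name not in SKELETON.names:
                continue
            k = SKELETON.index(name)
            kps[:, k, 0] = hx + frac * (ax - hx)
            kps[:, k, 1] = hy + frac * (ay - hy)

    # keypoint noise, then conversion to image coordinates (y down)
    rng = np.random.default_rng(params.seed)
    if params.noise_sigma > 0:
        kps = kps + rng.normal(0.0, params.noise_sigma, size=kps.shape)
    kps[:, :, 1] = GROUND_Y_IMG - kps[:, :, 1]
    if params.direction == "leftward":
        mirror = float(kps[:, :, 0].min() + kps[:, :, 0].max())
        kps[:, :, 0] = mirror - kps[:, :, 0]

    # per-frame tight bbox + margin, as a detector would produce
    x1 = kps[:, :, 0].min(axis=1) - BBOX_MARGIN
    x2 = kps[:, :, 0].max(axis=1) + BBOX_MARGIN
    y1 = kps[:, :, 1].min(axis=1) - BBOX_MARGIN
    y2 = kps[:, :, 1].max(axis=1) + BBOX_MARGIN
    track = PassageTrack(
        frame_index=np.arange(F),
        bbox=np.column_stack([x1, y1, x2, y2]),
        keypoints=kps,
        visible=np.ones((F, 22), dtype=bool),
        fps=params.fps,
        direction=params.direction,
        passage_id=f"sim_g{params.grade}_s{params.seed}",
        label=params.grade,
    )
    truth = GaitTruth(
        params=params,
        stance_intervals=truth_stance,
        touchdowns=truth_touchdowns,
        height=height_eff,
    )
    return track, truth


def derive_seed(seed: int, grade: int, replicate: int) -> int:
    """Deterministic per-passage seed below 2**31."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(int(grade), int(replicate)))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_cohort(
    n_per_grade: int,
    seed: int = 42,
    params_overrides: dict | None = None,
    out_dir=None,
) -> tuple[list[tuple[PassageTrack, GaitTruth]], pd.DataFrame]:
    """Simulate a balanced labeled cohort: 7 * n_per_grade passages.

    Per-passage seeds are derived deterministically from (seed, grade,
    replicate).  When ``out_dir`` is given, tracks are written as COCO
    keypoint JSON plus a ``manifest.csv`` with the ground-truth columns.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    overrides = dict(params_overrides or {})
    passages = []
    rows = []
    for grade in range(1, 8):
        for rep in range(n_per_grade):
            p = GaitParams(grade=grade, seed=derive_seed(seed, grade, rep), **overrides)
            track, truth = simulate_passage(p)
            passages.append((track, truth))
            rows.append(
                {
                    "passage_id": track.passage_id + f"_r{rep}",
                    "grade": grade,
                    "seed": p.seed,
                    "arch_sagitta": p.arch_sagitta,
                    "head_bob_amp": p.head_bob_amp,
                    "track_up_offset": p.track_up_offset,
                    "noise_sigma": p.noise_sigma,
                    "n_frames": track.n_frames,
                }
            )
            track.passage_id = rows[-1]["passage_id"]
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import os

        os.makedirs(out_dir, exist_ok=True)
        for track, _ in passages:
            write_track(track, os.path.join(out_dir, f"{track.passage_id}.json"), "coco_json")
        manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return passages, manifest


def grade_archetype(grade: int, seed: int = 0, **overrides) -> GaitParams:
    """Noiseless parameters for a grade's textbook presentation."""
    return replace(GaitParams(grade=grade, seed=seed, noise_sigma=0.0), **overrides)
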