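"""Shared fixtures: synthetic passages and derived features.

Everything is generated programmatically; the expensive cohorts are
session-scoped so the monotonicity, expert-tree and ML tests share them.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from bovigait.aggregation import build_features
from bovigait.indicators import compute_indicator_series
from bovigait.skeleton_io import canonicalize
from bovigait.synthetic_gait import GaitParams, simulate_cohort, simulate_passage


def features_for_track(track, label=None):
    series = compute_indicator_series(canonicalize(track))
    return build_features(series, label=label)


@pytest.fixture(scope="session")
def archetypes():
    """Noiseless textbook passage per grade: {grade: (track, truth)}."""
    out = {}
    for g in range(1, 8):
        out[g] = simulate_passage(GaitParams(grade=g, seed=g, noise_sigma=0.0))
    return out


@pytest.fixture(scope="session")
def archetype_series(archetypes):
    return {
        g: compute_indicator_series(canonicalize(track))
        for g, (track, _) in archetypes.items()
    }


@pytest.fixture(scope="session")
def noiseless_features():
    """Small noiseless labeled cohort (5 per grade) as feature objects."""
    passages, _ = simulate_cohort(5, seed=1, params_overrides={"noise_sigma": 0.0})
    return [features_for_track(tr, label=tr.label) for tr, _ in passages]


@pytest.fixture(scope="session")
def cohort140_features():
    """The default study cohort: 20 passages per grade, 2 px keypoint
    noise, seed 42; returned as a feature DataFrame with labels."""
    from bovigait.aggregation import features_to_frame

    passages, _ = simulate_cohort(20, seed=42)
    feats = [features_for_track(tr, label=tr.label) for tr, _ in passages]
    return features_to_frame(feats)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
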