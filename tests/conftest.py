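"""Shared fixtures: window builders and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

import hrvstress as hs
from hrvstress.preprocess import RRWindow


def make_window(rr=None, beat_times=None, start_s=0.0, window_len=300.0,
                label="non_stress", subject_id="s1", window_id="w0") -> RRWindow:
    """Build an RRWindow from an RR sequence (beat times default to the
    cumulative sum) or from explicit beat times."""
    if beat_times is None:
        rr = np.asarray(rr, dtype=float)
        beat_times = start_s + np.cumsum(rr)
    else:
        beat_times = np.asarray(beat_times, dtype=float)
        rr = np.asarray(rr, dtype=float)
    return RRWindow(
        subject_id=subject_id,
        window_id=window_id,
        start_s=start_s,
        end_s=start_s + window_len,
        beat_times=beat_times,
        rr=rr,
        label=label,
    )


@pytest.fixture
def window_factory():
    return make_window


@pytest.fixture(scope="session")
def clean_lab_records():
    """Three clean (uncorrupted) lab-protocol records."""
    cfg = hs.SimConfig(protocol="lab", n_subjects=3, seed=7,
                       gap_rate=0.0, ectopic_rate=0.0)
    return hs.simulate_lab_dataset(cfg)


@pytest.fixture(scope="session")
def lab_feature_table():
    """Feature table from a small clean lab dataset (6 subjects, sliding)."""
    cfg = hs.SimConfig(protocol="lab", n_subjects=6, seed=11,
                       gap_rate=0.0, ectopic_rate=0.0)
    return hs.dataset_feature_table(hs.simulate_lab_dataset(cfg), mode="sliding")


def random_corrupted_window(rng: np.random.Generator) -> RRWindow:
    """A 5-min window with random RR levels, random beat deletions and the
    occasional large gap — exercises the missing-data scorer broadly."""
    rr0 = rng.uniform(0.4, 1.2)
    n = int(320 / rr0)
    rr = np.clip(rr0 + rng.normal(0, 0.08 * rr0, n), 0.301, 1.299)
    t = np.cumsum(rr)
    keep = rng.random(n) > rng.uniform(0.0, 0.35)
    keep[0] = True
    w = make_window(rr=rr[keep], beat_times=t[keep])
    return w
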