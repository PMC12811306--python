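import numpy as np
import pandas as pd
import pytest

import utitask as ut


@pytest.fixture(scope="session")
def small_cohort():
    """One small simulated cohort shared across read-only tests."""
    cfg = ut.SimulationConfig(n_participants=30, seed=7)
    participants, trials, samples, truth = ut.simulate_cohort(cfg)
    return {"config": cfg, "participants": participants, "trials": trials,
            "samples": samples, "truth": truth}


@pytest.fixture(scope="session")
def small_metrics(small_cohort):
    metrics = ut.compute_trial_metrics(
        small_cohort["samples"], small_cohort["trials"])
    flagged, reports = ut.exclude_outliers(metrics)
    return {"metrics": metrics, "flagged": flagged, "reports": reports}


def write_dataset(tmp_path, participants, trials, samples):
    ut.write_participants(participants, tmp_path / "participants.csv")
    ut.write_trials(trials, tmp_path / "trials.csv")
    ut.write_samples(samples, tmp_path / "samples.csv")
    return (tmp_path / "samples.csv", tmp_path / "trials.csv",
            tmp_path / "participants.csv")


def random_polyline(rng, n_points=None, scale=100.0):
    """A random open polyline with distinct endpoints."""
    n = n_points or rng.integers(3, 30)
    while True:
        pts = rng.normal(0, scale, size=(n, 2))
        if np.linalg.norm(pts[-1] - pts[0]) > 1e-6:
            return pts


def arc_positions(polyline, points):
    """Arc-length position of each point along the polyline, found by
    projection onto every segment (independent of the resampler's own
    bookkeeping).  Positions are made monotone to disambiguate
    self-intersections."""
    polyline = np.asarray(polyline, dtype=float)
    seg = np.diff(polyline, axis=0)
    lengths = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(lengths)])
    positions = []
    prev = 0.0
    for p in points:
        candidates = []
        for i in range(len(seg)):
            if lengths[i] == 0:
                continue
            t = np.clip(np.dot(p - polyline[i], seg[i]) / lengths[i] ** 2,
                        0.0, 1.0)
            d = np.linalg.norm(p - (polyline[i] + t * seg[i]))
            candidates.append((d, s[i] + t * lengths[i]))
        close = [pos for d, pos in candidates if d < 1e-6]
        ahead = [pos for pos in close if pos >= prev - 1e-6]
        prev = min(ahead) if ahead else min(pos for _, pos in candidates)
        positions.append(prev)
    return np.asarray(positions)
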