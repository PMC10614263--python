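"""Shared fixtures and the independent brute-force stability oracle."""

from __future__ import annotations

import numpy as np
import pytest

from gliamotion import SimulationConfig

# ---------------------------------------------------------------------------
# Brute-force oracle: stability by direct enumeration of (block, lifetime)
# events against the >=3-frame persistence rule. Independent of the
# detection/classification code path.
# ---------------------------------------------------------------------------


def oracle_stability(event_spec, n_frames, threshold_frames=3):
    """(n_events, n_stable, SI) straight from the toy event specification.

    An event's observable persistence is its lifetime clipped at the movie
    end; it is stable iff that persistence reaches the threshold.
    """
    n_stable = 0
    for onset, _block, lifetime in event_spec:
        persistence = min(lifetime, n_frames - onset)
        if persistence >= threshold_frames:
            n_stable += 1
    n = len(event_spec)
    return n, n_stable, (n_stable / n if n else float("nan"))


def random_toy_spec(rng: np.random.Generator, n_frames: int = 8,
                    shape=(64, 64)):
    """Random toy series spec: 3x3 blocks on separated sites flanking a bar.

    Sites are >=3 px apart so the 1-px dilation tolerance of the persistence
    check cannot couple neighbouring events, and every block is 4-adjacent to
    the always-present base bar.
    """
    base = np.zeros(shape, dtype=bool)
    base[4:60, 30:34] = True  # vertical bar, width 4
    sites = []
    for r in range(5, 54, 6):
        sites.append((r, 27))   # left flank: cols 27-29 touch col 30
        sites.append((r, 34))   # right flank: cols 34-36 touch col 33
    rng.shuffle(sites)
    n_events = int(rng.integers(3, 13))
    spec = []
    for r, c in sites[:n_events]:
        block = np.zeros(shape, dtype=bool)
        block[r:r + 3, c:c + 3] = True
        onset = int(rng.integers(1, n_frames))
        lifetime = int(rng.integers(1, n_frames + 1))
        spec.append((onset, block, lifetime))
    return spec, base


@pytest.fixture
def small_sim_config():
    """A fast, small-field simulation used across module tests."""
    return SimulationConfig(image_size=256, n_z=5, n_cells=2,
                            n_primary_processes=4, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
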