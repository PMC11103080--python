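import numpy as np
import pytest

from sonoagree import curation, simulate
from sonoagree.model import default_manifest


@pytest.fixture(scope="session")
def manifest():
    return default_manifest()


@pytest.fixture(scope="session")
def small_study():
    """A reduced simulated panel (6 humans + AI, 2 scans per region) kept
    small so the full pipeline runs in seconds."""
    config = simulate.StudyConfig(n_humans=6, scans_per_region=2, seed=11)
    return simulate.simulate_study(config)


@pytest.fixture(scope="session")
def small_curated(small_study):
    man, anns = small_study
    curated, report = curation.curate(anns, man)
    return man, curated, report


@pytest.fixture(scope="session")
def replica_study():
    return simulate.replica_study_annotations(seed=3)


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive implementations)
# ---------------------------------------------------------------------------


def point_in_polygon(x, y, vertices):
    """Even-odd crossing-number test for a single point, written as the
    textbook scalar loop."""
    inside = False
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        if (y1 <= y) != (y2 <= y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x < x_at:
                inside = not inside
    return inside


def brute_force_mask(polygons, width, height):
    grid = np.zeros((height, width), dtype=bool)
    for i in range(height):
        for j in range(width):
            grid[i, j] = any(
                point_in_polygon(j + 0.5, i + 0.5, poly) for poly in polygons
            )
    return grid


def brute_force_directed_hausdorff(a, b):
    """O(n*m) double loop over all point pairs."""
    best = 0.0
    for p in np.asarray(a, dtype=float):
        nearest = min(float(np.hypot(p[0] - q[0], p[1] - q[1])) for q in np.asarray(b, dtype=float))
        if nearest > best:
            best = nearest
    return best


@pytest.fixture(scope="session")
def oracles():
    return {
        "mask": brute_force_mask,
        "pip": point_in_polygon,
        "hausdorff": brute_force_directed_hausdorff,
    }
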