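import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from topovar import PointCloud


def ring_coords(n: int = 8, radius: float = 5.0,
                center=(0.0, 0.0, 0.0)) -> np.ndarray:
    angles = 2.0 * np.pi * np.arange(n) / n
    pts = np.zeros((n, 3))
    pts[:, 0] = radius * np.cos(angles)
    pts[:, 1] = radius * np.sin(angles)
    return pts + np.asarray(center, dtype=float)


def make_cloud(coords: np.ndarray, chain: str = "A") -> PointCloud:
    keys = [(chain, str(i + 1)) for i in range(len(coords))]
    return PointCloud(keys, coords)


@pytest.fixture
def square_cloud() -> PointCloud:
    return make_cloud(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                                [1.0, 1.0, 0.0], [0.0, 1.0, 0.0]]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
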