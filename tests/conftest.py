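"""Shared test helpers: a brute-force GLCM oracle and small image builders.

The oracle enumerates every pixel position with a double loop and counts
co-occurrences directly; it is deliberately independent of the vectorized
implementation it cross-checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from glcmskin import GrayImage

ANGLE_UNIT = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def glcm_oracle_counts(pixels: np.ndarray, levels: int, distance: int,
                       angle: int, symmetric: bool) -> np.ndarray:
    """Naive O(H*W) pair enumeration; raw integer counts."""
    ur, uc = ANGLE_UNIT[angle]
    dr, dc = ur * distance, uc * distance
    H, W = pixels.shape
    M = np.zeros((levels, levels), dtype=np.int64)
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W:
                M[pixels[r, c], pixels[r2, c2]] += 1
                if symmetric:
                    M[pixels[r2, c2], pixels[r, c]] += 1
    return M


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230811)


def random_gray(rng: np.random.Generator, shape=(9, 9), levels=8) -> GrayImage:
    return GrayImage(rng.integers(0, levels, size=shape), levels=levels)
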