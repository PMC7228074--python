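"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library code paths they check:
zone labeling is a hand-written breadth-first search over explicit
neighbour offsets, and the masked mean is a plain Python loop.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from gliotex.glszm import GLSZMatrix


def bfs_glszm(volume: np.ndarray, mask: np.ndarray, region_label: int) -> dict:
    """Brute-force GLSZM: ``{(level, size): count}`` via BFS flood fill."""
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    offsets = [off for off in itertools.product((-1, 0, 1), repeat=volume.ndim)
               if any(off)]
    in_region = {tuple(idx) for idx in np.argwhere((mask == region_label) & (volume >= 1))}
    seen = set()
    counts: dict = {}
    for start in sorted(in_region):
        if start in seen:
            continue
        level = int(volume[start])
        queue = [start]
        seen.add(start)
        size = 0
        while queue:
            vox = queue.pop()
            size += 1
            for off in offsets:
                nb = tuple(v + o for v, o in zip(vox, off))
                if nb in in_region and nb not in seen and int(volume[nb]) == level:
                    seen.add(nb)
                    queue.append(nb)
        counts[(level, size)] = counts.get((level, size), 0) + 1
    return counts


@pytest.fixture
def toy_matrix() -> GLSZMatrix:
    """The worked 2x2 example: one two-voxel zone of level 1, singletons of 2 and 3."""
    return GLSZMatrix(counts={(1, 2): 1, (2, 1): 1, (3, 1): 1},
                      n_zones=3, n_voxels=4, gray_level_range=3)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
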