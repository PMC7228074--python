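"""Gray level size zone matrix (GLSZM) computation.

A *zone* is a maximal set of connected voxels sharing one gray level inside
a segmented region; connectivity is 26-neighbour in 3D (8-neighbour for 2D
arrays).  The matrix entry ``s(i, j)`` counts the zones of gray level ``i``
and size ``j`` voxels.  Voxels with intensity 0 (the "absent value" code of
the normalized scale) or outside the region of interest never contribute.

The matrix is held sparsely as a ``{(gray_level, zone_size): count}``
mapping because zone sizes can reach the full region size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class GLSZMatrix:
    """Sparse GLSZM with its bookkeeping totals.

    Attributes
    ----------
    counts : dict[tuple[int, int], int]
        ``(gray_level, zone_size) -> number of zones``; only nonzero cells.
    n_zones : int
        ``N_s``, the total number of zones.
    n_voxels : int
        ``N_v``, the number of region voxels with intensity >= 1.
    gray_level_range : int
        Largest gray level present in the region.
    """

    counts: dict = field(default_factory=dict)
    n_zones: int = 0
    n_voxels: int = 0
    gray_level_range: int = 0

    def __post_init__(self) -> None:
        voxel_total = sum(j * c for (_, j), c in self.counts.items())
        zone_total = sum(self.counts.values())
        if voxel_total != self.n_voxels:
            raise ValueError(
                f"zone sizes account for {voxel_total} voxels, expected N_v={self.n_voxels}"
            )
        if zone_total != self.n_zones:
            raise ValueError(
                f"counts sum to {zone_total} zones, expected N_s={self.n_zones}"
            )
        if any(c <= 0 for c in self.counts.values()):
            raise ValueError("zone counts must be positive integers")

    def gray_level_marginal(self) -> dict:
        """``g_i = sum_j s(i, j)`` — zones per gray level."""
        g: dict = {}
        for (i, _), c in self.counts.items():
            g[i] = g.get(i, 0) + c
        return g

    def zone_size_marginal(self) -> dict:
        """``z_j = sum_i s(i, j)`` — zones per size."""
        z: dict = {}
        for (_, j), c in self.counts.items():
            z[j] = z.get(j, 0) + c
        return z


def zone_marginals(matrix: GLSZMatrix) -> tuple:
    """Return ``(gray level marginal, zone size marginal)`` of a matrix."""
    return matrix.gray_level_marginal(), matrix.zone_size_marginal()


def compute_glszm(volume: np.ndarray, mask: np.ndarray, region_label: int) -> GLSZMatrix:
    """Compute the GLSZM of ``volume`` restricted to one mask region.

    Parameters
    ----------
    volume : ndarray
        Normalized intensity volume; integer gray levels, 0 = absent value.
    mask : ndarray
        Segmentation label volume of the same shape.
    region_label : int
        Label of the region to analyse (e.g. 1 for NCR/NET, 2 for ED under
        the BRATS convention).

    Returns
    -------
    GLSZMatrix

    Raises
    ------
    ValueError
        If shapes differ, the volume holds non-integer values, or the region
        contains no voxel with intensity >= 1.
    """
    volume = np.asarray(volume)
    mask = np.asarray(mask)
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    if not np.issubdtype(volume.dtype, np.integer):
        if not np.all(np.equal(np.mod(volume, 1), 0)):
            raise ValueError("volume must contain integer gray levels")
        volume = volume.astype(np.int64)

    in_region = (mask == region_label) & (volume >= 1)
    n_voxels = int(in_region.sum())
    if n_voxels == 0:
        raise ValueError(f"region label {region_label} is absent or holds no nonzero voxels")

    # full connectivity: 26 neighbours in 3D, 8 in 2D
    structure = ndimage.generate_binary_structure(volume.ndim, volume.ndim)

    counts: dict = {}
    levels = np.unique(volume[in_region])
    for level in levels:
        labeled, n_comp = ndimage.label((volume == level) & in_region, structure=structure)
        if n_comp == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for size in sizes:
            key = (int(level), int(size))
            counts[key] = counts.get(key, 0) + 1

    n_zones = sum(counts.values())
    return GLSZMatrix(
        counts=counts,
        n_zones=n_zones,
        n_voxels=n_voxels,
        gray_level_range=int(levels.max()),
    )


def glszm_to_records(matrix: GLSZMatrix) -> list:
    """Flatten a matrix to ``(gray_level, zone_size, count)`` triplets (CSV dump)."""
    return [(i, j, c) for (i, j), c in sorted(matrix.counts.items())]
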