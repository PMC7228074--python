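"""Landmark-based MRI intensity normalization (Nyúl-style).

Raw MRI intensities are scanner- and protocol-dependent, so volumes from a
multi-institutional cohort are standardized to a common integer scale
0–255 before texture analysis (0 is reserved for "absence of a value", i.e.
background).  The procedure:

1. Per contrast, grade and dataset group, pick two *reference volumes* —
   the ones with the lowest and highest mean brain intensity, the mean
   taken over brain voxels excluding all tumor labels (the tumor
   environment is too heterogeneous to anchor a scale).  Gliomas that
   contributed reference volumes are excluded from further analysis.
2. Learn a *standard scale*: for each reference volume, landmark
   intensities (percentile cutoffs + deciles) are computed over non-tumor
   brain voxels and affinely mapped so that the lowest/highest cutoffs land
   on 1 and 255; the mapped landmarks are averaged across references.
3. Normalize any volume by the piecewise-linear map sending its own
   landmarks onto the standard positions, rounding to integers and
   clamping to [1, 255] (background stays 0).

The landmark set defaults to the 1st and 99th percentiles plus deciles
10–90.  Bias-field correction is assumed to have been applied upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Percentile cutoffs + deciles: the standard landmark configuration.
DEFAULT_LANDMARK_PERCENTILES = (1.0, 10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 90.0, 99.0)

TUMOR_LABELS = (1, 2, 4)  # NCR/NET, ED, ET under the BRATS convention
OUTPUT_LOW, OUTPUT_HIGH = 1.0, 255.0


@dataclass(frozen=True)
class StandardScale:
    """Learned landmark positions on the 0–255 output scale."""

    percentiles: tuple
    positions: tuple
    contrast: str = ""

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if len(pos) != len(self.percentiles):
            raise ValueError("positions and percentiles must have equal length")
        if np.any(np.diff(pos) < 0) or pos[-1] <= pos[0]:
            raise ValueError("landmark positions must be increasing")


def _brain_non_tumor(volume: np.ndarray, mask: np.ndarray) -> np.ndarray:
    if volume.shape != mask.shape:
        raise ValueError(f"volume shape {volume.shape} != mask shape {mask.shape}")
    keep = volume > 0
    for label in TUMOR_LABELS:
        keep &= mask != label
    return np.asarray(volume)[keep]


def mean_intensity_excluding_tumor(volume: np.ndarray, mask: np.ndarray) -> float:
    """Mean intensity over brain voxels outside every tumor label."""
    values = _brain_non_tumor(volume, mask)
    if values.size == 0:
        raise ValueError("no brain voxels outside the tumor region")
    return float(values.mean())


def select_reference_volumes(stratum) -> tuple:
    """Pick the lowest- and highest-mean volumes of one stratum.

    ``stratum`` is a sequence of ``(glioma id, volume, mask)`` triples, all
    from one (contrast, grade, dataset group) cell.  Returns
    ``(lowest_mean_id, highest_mean_id)``; ties break toward the
    lexicographically smallest id.  Requires at least two volumes.
    """
    entries = list(stratum)
    if len(entries) < 2:
        raise ValueError(f"reference selection needs >= 2 volumes, got {len(entries)}")
    means = sorted(
        ((mean_intensity_excluding_tumor(vol, msk), str(gid)) for gid, vol, msk in entries),
        key=lambda t: (t[0], t[1]),
    )
    return means[0][1], means[-1][1]


def select_references_across_strata(strata: dict) -> tuple:
    """Apply reference selection to every stratum.

    ``strata`` maps a stratum key (e.g. ``(contrast, grade, group)``) to its
    ``(id, volume, mask)`` triples.  Returns ``(per-stratum pairs, excluded
    glioma ids)``; the id set lets callers drop reference gliomas from
    further analysis.
    """
    pairs = {key: select_reference_volumes(entries) for key, entries in strata.items()}
    excluded = {gid for pair in pairs.values() for gid in pair}
    return pairs, excluded


def _volume_landmarks(volume, mask, percentiles) -> np.ndarray:
    values = _brain_non_tumor(volume, mask)
    if values.size == 0:
        raise ValueError("no brain voxels outside the tumor region")
    marks = np.percentile(values, percentiles)
    if marks[-1] <= marks[0]:
        raise ValueError("degenerate (constant) volume: landmarks collapse")
    return marks


def learn_standard_scale(reference_volumes, masks, landmark_percentiles=DEFAULT_LANDMARK_PERCENTILES,
                         contrast: str = "") -> StandardScale:
    """Average the references' mapped landmarks into a standard scale."""
    percentiles = tuple(float(p) for p in landmark_percentiles)
    if len(percentiles) < 2 or any(b <= a for a, b in zip(percentiles, percentiles[1:])):
        raise ValueError("landmark percentiles must be strictly increasing")
    if not 0 < percentiles[0] < percentiles[-1] < 100:
        raise ValueError("landmark percentiles must lie inside (0, 100)")
    reference_volumes = list(reference_volumes)
    masks = list(masks)
    if not reference_volumes or len(reference_volumes) != len(masks):
        raise ValueError("need >= 1 reference volume with a mask apiece")

    mapped = []
    for vol, msk in zip(reference_volumes, masks):
        marks = _volume_landmarks(vol, msk, percentiles)
        scale = (OUTPUT_HIGH - OUTPUT_LOW) / (marks[-1] - marks[0])
        mapped.append(OUTPUT_LOW + (marks - marks[0]) * scale)
    positions = np.mean(mapped, axis=0)
    return StandardScale(percentiles=percentiles, positions=tuple(positions), contrast=contrast)


def _monotone_interp(values, src, dst):
    """np.interp with duplicate source landmarks collapsed (mean target)."""
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    uniq, inverse = np.unique(src, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("degenerate landmark set")
    collapsed = np.zeros(len(uniq))
    counts = np.bincount(inverse)
    np.add.at(collapsed, inverse, dst)
    collapsed /= counts
    return np.interp(values, uniq, collapsed)


def normalize_volume(volume: np.ndarray, mask: np.ndarray, scale: StandardScale) -> np.ndarray:
    """Map a raw volume onto the standard scale.

    Brain voxels go through the piecewise-linear landmark map, are rounded
    to the nearest integer and clamped to [1, 255]; background stays 0.
    The map is monotone non-decreasing by construction.
    """
    volume = np.asarray(volume, dtype=float)
    marks = _volume_landmarks(volume, mask, scale.percentiles)
    out = np.zeros(volume.shape, dtype=np.int16)
    brain = volume > 0
    mapped = _monotone_interp(volume[brain], marks, scale.positions)
    out[brain] = np.clip(np.rint(mapped), OUTPUT_LOW, OUTPUT_HIGH).astype(np.int16)
    return out
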