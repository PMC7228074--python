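"""Synthetic imbalanced two-class glioma cohorts.

Real cohorts of this kind (e.g. the BRATS multi-institutional collection)
are imbalanced — roughly 64 low-grade vs 191 high-grade gliomas after
exclusions — and the two grades differ in the *coarseness* of the intensity
texture inside the necrotic / non-enhancing tumor core (NCR/NET), in a
contrast-dependent way.  This module emulates exactly those properties, in
two forms:

* :func:`generate_volume_cohort` — labeled 3D volume pairs (T1Gd, T2) plus a
  BRATS-style segmentation mask, where the NCR/NET texture is built from
  blocky gray-level zones whose characteristic edge length is controlled per
  (grade, contrast).  Zones are produced by nearest-seed (Voronoi) labeling
  of Poisson-seeded points, which directly controls the zone-size statistics
  that the GLSZM measures.
* :func:`generate_feature_table` — a fast path that skips imaging: feature
  columns drawn from class-conditional Gaussians with configurable
  per-feature mean shifts.

No attempt is made to simulate MRI physics, bias fields or registration
artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import ndimage

from .features import DEFAULT_SOURCES, REGION_LABELS

logger = logging.getLogger(__name__)

GRADES = ("LGG", "HGG")

#: Default characteristic zone edge length (voxels) per (grade, contrast).
#: High-grade cores are coarser on T1Gd, low-grade cores coarser on T2,
#: mirroring the contrast-dependent heterogeneity the method detects.
DEFAULT_ZONE_SCALES = {
    ("LGG", "T1Gd"): 1.5,
    ("HGG", "T1Gd"): 3.0,
    ("LGG", "T2"): 3.0,
    ("HGG", "T2"): 1.5,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic cohort.

    ``region_fraction`` is the fraction of the grid occupied by the NCR/NET
    core; ``noise_prob`` is the per-voxel probability of relabeling to a
    uniformly random gray level after the zone texture is laid down.
    """

    n_lgg: int = 64
    n_hgg: int = 191
    grid_shape: tuple = (32, 32, 32)
    region_fraction: float = 0.08
    zone_scale_by_class_and_contrast: dict = field(
        default_factory=lambda: dict(DEFAULT_ZONE_SCALES)
    )
    gray_levels: int = 8
    noise_prob: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lgg < 0 or self.n_hgg < 0:
            raise ValueError("n_lgg and n_hgg must be non-negative")
        if self.n_lgg + self.n_hgg < 1:
            raise ValueError("cohort must contain at least one glioma (n_lgg + n_hgg >= 1)")
        if len(self.grid_shape) != 3 or any(s < 4 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3D with every extent >= 4")
        if not 0 < self.region_fraction <= 1:
            raise ValueError("region_fraction must lie in (0, 1]")
        if not 0 <= self.noise_prob <= 1:
            raise ValueError("noise_prob must lie in [0, 1]")
        if self.gray_levels < 1:
            raise ValueError("gray_levels must be >= 1")
        for key, scale in self.zone_scale_by_class_and_contrast.items():
            if scale < 1:
                raise ValueError(f"zone edge length for {key} must be >= 1 voxel")


@dataclass
class GliomaRecord:
    """One synthetic glioma: id, grade, per-contrast volumes and the mask."""

    id: str
    grade: str
    volumes: dict
    mask: np.ndarray


def _voronoi_texture(shape, region_mask, scale, gray_levels, rng) -> np.ndarray:
    """Blocky gray-level texture on ``region_mask`` voxels.

    Poisson-seeded points with mean spacing ``scale`` are dropped over the
    region's bounding box; each voxel takes the gray level of its nearest
    seed (uniform over 1..gray_levels per cell).
    """
    coords = np.argwhere(region_mask)
    n_vox = len(coords)
    if n_vox == 0:
        return np.zeros(shape, dtype=np.int16)
    expected = max(1, int(round(n_vox / scale**3)))
    n_seeds = max(1, rng.poisson(expected))
    seeds = coords[rng.integers(0, n_vox, size=n_seeds)] + rng.uniform(-0.5, 0.5, size=(n_seeds, 3))
    _, cell = cKDTree(seeds).query(coords)
    levels = rng.integers(1, gray_levels + 1, size=n_seeds)
    out = np.zeros(shape, dtype=np.int16)
    out[tuple(coords.T)] = levels[cell]
    return out


def _build_anatomy(shape, region_fraction):
    """Brain / NCR-NET / ED geometry shared by every glioma of a spec."""
    grid = np.indices(shape).astype(float)
    center = (np.asarray(shape, dtype=float) - 1) / 2
    radii = np.asarray(shape, dtype=float) / 2 - 0.5
    dist2 = sum(((grid[a] - center[a]) / radii[a]) ** 2 for a in range(3))
    brain = dist2 <= 1.0

    # central NCR/NET sphere with the requested voxel fraction of the grid
    target = region_fraction * np.prod(shape)
    r_core = (3 * target / (4 * np.pi)) ** (1 / 3)
    core_dist2 = sum((grid[a] - center[a]) ** 2 for a in range(3))
    core = core_dist2 <= r_core**2
    core &= brain

    shell = ndimage.binary_dilation(core, iterations=2) & brain & ~core
    return brain, core, shell


def generate_volume_cohort(spec: SyntheticSpec) -> list:
    """Generate the volumetric cohort described by ``spec``.

    Returns a list of :class:`GliomaRecord`.  Deterministic under
    ``spec.seed``: the same spec yields bitwise-identical voxels.  Mask
    labels follow the BRATS convention (1 = NCR/NET, 2 = ED, 0 background).
    """
    brain, core, shell = _build_anatomy(spec.grid_shape, spec.region_fraction)
    mask = np.zeros(spec.grid_shape, dtype=np.int16)
    mask[shell] = REGION_LABELS["ED"]
    mask[core] = REGION_LABELS["NCRNET"]

    contrasts = sorted({c for (_, c) in spec.zone_scale_by_class_and_contrast})
    ss = np.random.SeedSequence(spec.seed)
    cohort: list = []
    order = [("LGG", k) for k in range(spec.n_lgg)] + [("HGG", k) for k in range(spec.n_hgg)]
    children = ss.spawn(len(order))
    for (grade, k), child in zip(order, children):
        rng = np.random.default_rng(child)
        volumes = {}
        for contrast in contrasts:
            scale = spec.zone_scale_by_class_and_contrast[(grade, contrast)]
            vol = np.zeros(spec.grid_shape, dtype=np.int16)
            # surrounding brain tissue: mildly blocky, grade-independent
            outside = brain & ~core
            vol += _voronoi_texture(spec.grid_shape, outside, 2.0, spec.gray_levels, rng)
            vol += _voronoi_texture(spec.grid_shape, core, scale, spec.gray_levels, rng)
            if spec.noise_prob > 0:
                flip = (rng.random(spec.grid_shape) < spec.noise_prob) & brain
                vol[flip] = rng.integers(1, spec.gray_levels + 1, size=int(flip.sum()))
            volumes[contrast] = vol
        cohort.append(GliomaRecord(id=f"{grade}-{k + 1:03d}", grade=grade, volumes=volumes, mask=mask.copy()))
    return cohort


def all_feature_columns(sources=DEFAULT_SOURCES) -> list:
    cols = []
    for src in sources:
        cols.extend(src.columns())
    return cols


def generate_feature_table(spec: SyntheticSpec, effect: dict | None = None) -> pd.DataFrame:
    """Draw a per-glioma feature table directly (no imaging).

    Every feature column is i.i.d. standard normal for LGGs; for HGGs the
    mean is shifted by ``effect[column]`` (in units of the standard
    deviation) where given, otherwise the two classes share the null
    distribution.  Column names must come from the 13 features x the four
    default (contrast, region) sources.
    """
    effect = dict(effect or {})
    columns = all_feature_columns()
    unknown = sorted(set(effect) - set(columns))
    if unknown:
        raise ValueError(f"unknown feature id(s): {unknown}")

    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    rows = []
    for grade, n in (("LGG", spec.n_lgg), ("HGG", spec.n_hgg)):
        values = rng.standard_normal((n, len(columns)))
        if grade == "HGG":
            for col, shift in effect.items():
                values[:, columns.index(col)] += shift
        for k in range(n):
            rows.append({"id": f"{grade}-{k + 1:03d}", "grade": grade,
                         **dict(zip(columns, values[k]))})
    return pd.DataFrame(rows, columns=["id", "grade", *columns])


def write_cohort(cohort, out_dir, spacing_mm: float = 1.0) -> pd.DataFrame:
    """Write a volume cohort as NIfTI files plus a CSV manifest.

    Returns the manifest DataFrame (id, grade, per-contrast paths, mask path).
    """
    import nibabel as nib
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag([spacing_mm] * 3 + [1.0])
    records = []
    for rec in cohort:
        row = {"id": rec.id, "grade": rec.grade}
        for contrast, vol in rec.volumes.items():
            path = out / f"{rec.id}_{contrast}.nii.gz"
            nib.save(nib.Nifti1Image(vol.astype(np.int16), affine), path)
            row[f"path_{contrast}"] = str(path)
        mask_path = out / f"{rec.id}_seg.nii.gz"
        nib.save(nib.Nifti1Image(rec.mask.astype(np.int16), affine), mask_path)
        row["path_mask"] = str(mask_path)
        records.append(row)
    manifest = pd.DataFrame(records)
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest


def read_cohort(manifest_path) -> list:
    """Load a cohort previously written by :func:`write_cohort`."""
    import nibabel as nib
    manifest = pd.read_csv(manifest_path)
    cohort = []
    for _, row in manifest.iterrows():
        volumes = {}
        for col in manifest.columns:
            if col.startswith("path_") and col != "path_mask":
                volumes[col[len("path_"):]] = np.asarray(
                    nib.load(row[col]).dataobj, dtype=np.int32)
        mask = np.asarray(nib.load(row["path_mask"]).dataobj, dtype=np.int16)
        cohort.append(GliomaRecord(id=row["id"], grade=row["grade"], volumes=volumes, mask=mask))
    return cohort
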