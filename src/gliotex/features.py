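"""The thirteen GLSZM texture features and cohort-level feature tables.

With ``s(i, j)`` the zone counts, ``N_s`` the zone total, ``N_v`` the region
voxel count, ``p(i, j) = s(i, j) / N_s``, and marginals
``g_i = sum_j s(i, j)``, ``z_j = sum_i s(i, j)``:

========  =====================================================
SZE       small zone emphasis,        (1/N_s) sum s(i,j) / j^2
LZE       large zone emphasis,        (1/N_s) sum s(i,j) * j^2
GLNU      gray-level nonuniformity,   (1/N_s) sum_i g_i^2
ZSNU      zone-size nonuniformity,    (1/N_s) sum_j z_j^2
ZP        zone percentage,            N_s / N_v
LGZE      low gray-level emphasis,    (1/N_s) sum s(i,j) / i^2
HGZE      high gray-level emphasis,   (1/N_s) sum s(i,j) * i^2
SZLGE     small zone low gray-level,  (1/N_s) sum s(i,j) / (i^2 j^2)
SZHGE     small zone high gray-level, (1/N_s) sum s(i,j) i^2 / j^2
LZLGE     large zone low gray-level,  (1/N_s) sum s(i,j) j^2 / i^2
LZHGE     large zone high gray-level, (1/N_s) sum s(i,j) i^2 j^2
GLVAR     gray-level variance,        sum p(i,j) (i - mu_i)^2
ZSVAR     zone-size variance,         sum p(i,j) (j - mu_j)^2
========  =====================================================

Feature identifiers use the ``F_szm.*`` notation of the standardized
radiomics nomenclature.  A *feature source* is one (MRI contrast, tumor
region) pair; cohort tables carry one column per (source, feature).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .glszm import GLSZMatrix, compute_glszm

logger = logging.getLogger(__name__)

#: Canonical order of the thirteen features.
FEATURE_NAMES = (
    "F_szm.sze",
    "F_szm.lze",
    "F_szm.glnu",
    "F_szm.zsnu",
    "F_szm.z.perc",
    "F_szm.lgze",
    "F_szm.hgze",
    "F_szm.szlge",
    "F_szm.szhge",
    "F_szm.lzlge",
    "F_szm.lzhge",
    "F_szm.gl.var",
    "F_szm.zs.var",
)

#: Region names: NCR/NET = necrotic & non-enhancing tumor core, ED = edema.
REGION_LABELS = {"NCRNET": 1, "ED": 2, "ET": 4}
CONTRASTS = ("T1Gd", "T2")


@dataclass(frozen=True)
class FeatureSource:
    """One (contrast, region) origin of a 13-feature block."""

    contrast: str
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGION_LABELS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {sorted(REGION_LABELS)}")

    @property
    def region_label(self) -> int:
        return REGION_LABELS[self.region]

    def column(self, feature: str) -> str:
        """Column name for one feature of this source, e.g. ``T2_NCRNET_F_szm.z.perc``."""
        return f"{self.contrast}_{self.region}_{feature}"

    def columns(self) -> list:
        return [self.column(f) for f in FEATURE_NAMES]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contrast}:{self.region}"


def parse_source(text: str) -> FeatureSource:
    """Parse ``"T1Gd:NCRNET"`` into a :class:`FeatureSource`."""
    contrast, _, region = text.partition(":")
    if not region:
        raise ValueError(f"source {text!r} must look like CONTRAST:REGION, e.g. T1Gd:NCRNET")
    return FeatureSource(contrast, region)


DEFAULT_SOURCES = (
    FeatureSource("T1Gd", "NCRNET"),
    FeatureSource("T1Gd", "ED"),
    FeatureSource("T2", "NCRNET"),
    FeatureSource("T2", "ED"),
)


def compute_features(matrix: GLSZMatrix) -> dict:
    """Evaluate all thirteen features of one GLSZM.

    Returns a ``{feature name: value}`` mapping in :data:`FEATURE_NAMES`
    order.  Raises ``ValueError`` on an empty matrix.
    """
    if matrix.n_zones < 1:
        raise ValueError("cannot compute features of an empty GLSZM")

    ns = matrix.n_zones
    nv = matrix.n_voxels
    items = matrix.counts.items()

    sze = sum(c / (j * j) for (_, j), c in items) / ns
    lze = sum(c * j * j for (_, j), c in items) / ns
    lgze = sum(c / (i * i) for (i, _), c in items) / ns
    hgze = sum(c * i * i for (i, _), c in items) / ns
    szlge = sum(c / (i * i * j * j) for (i, j), c in items) / ns
    szhge = sum(c * i * i / (j * j) for (i, j), c in items) / ns
    lzlge = sum(c * j * j / (i * i) for (i, j), c in items) / ns
    lzhge = sum(c * i * i * j * j for (i, j), c in items) / ns

    g = matrix.gray_level_marginal()
    z = matrix.zone_size_marginal()
    glnu = sum(v * v for v in g.values()) / ns
    zsnu = sum(v * v for v in z.values()) / ns

    mu_i = sum(c * i for (i, _), c in items) / ns
    mu_j = sum(c * j for (_, j), c in items) / ns
    gl_var = sum(c * (i - mu_i) ** 2 for (i, _), c in items) / ns
    zs_var = sum(c * (j - mu_j) ** 2 for (_, j), c in items) / ns

    return {
        "F_szm.sze": sze,
        "F_szm.lze": lze,
        "F_szm.glnu": glnu,
        "F_szm.zsnu": zsnu,
        "F_szm.z.perc": ns / nv,
        "F_szm.lgze": lgze,
        "F_szm.hgze": hgze,
        "F_szm.szlge": szlge,
        "F_szm.szhge": szhge,
        "F_szm.lzlge": lzlge,
        "F_szm.lzhge": lzhge,
        "F_szm.gl.var": gl_var,
        "F_szm.zs.var": zs_var,
    }


def extract_cohort_features(cohort, sources) -> pd.DataFrame:
    """Build the per-glioma feature table for a set of sources.

    Parameters
    ----------
    cohort : iterable of records
        Each record needs ``id``, ``grade``, ``volumes`` (contrast ->
        ndarray) and ``mask`` attributes (:class:`gliotex.synthetic.GliomaRecord`
        satisfies this).
    sources : sequence of FeatureSource

    Returns
    -------
    DataFrame with columns ``id, grade`` then 13 columns per source.
    Gliomas for which any required region is empty are excluded with a
    logged warning.
    """
    sources = list(sources)
    columns = ["id", "grade"]
    for src in sources:
        columns.extend(src.columns())

    rows = []
    for rec in cohort:
        row = {"id": rec.id, "grade": rec.grade}
        try:
            for src in sources:
                if src.contrast not in rec.volumes:
                    raise ValueError(f"missing contrast {src.contrast}")
                matrix = compute_glszm(rec.volumes[src.contrast], rec.mask, src.region_label)
                for name, value in compute_features(matrix).items():
                    row[src.column(name)] = value
        except ValueError as exc:
            logger.warning("excluding glioma %s: %s", rec.id, exc)
            continue
        rows.append(row)

    return pd.DataFrame(rows, columns=columns)
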