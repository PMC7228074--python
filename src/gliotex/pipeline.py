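"""End-to-end orchestration: grading single gliomas and the full training experiment.

The grading path mirrors the clinical flow: (bias-corrected) volumes ->
intensity normalization -> GLSZM per (contrast, region) -> texture
features -> linear model -> LGG/HGG call.  The training path mirrors the
full experiment: balanced splits, per-subset rank-sum ranking, ordered
consensus, averaged unique models for every source combination, evaluation
on the fixed testing subset, then reduced models of the best model.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import pandas as pd
import yaml

from .features import DEFAULT_SOURCES, FeatureSource, parse_source
from .models import (
    LinearModel,
    build_reduced_models,
    build_unique_model,
    combination_columns,
    combination_name,
    enumerate_combinations,
    predict_table,
)
from .evaluation import evaluate
from .ranking import SIGNIFICANCE_LEVEL, OrderedConsensus, RankedFeatures, build_consensus, rank_subset
from .splitting import DataSplit, make_split

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated knobs of the training experiment."""

    sources: tuple = tuple(str(s) for s in DEFAULT_SOURCES)
    landmark_percentiles: tuple = (1, 10, 20, 30, 40, 50, 60, 70, 80, 90, 99)
    n_test_per_class: int = 34
    n_train_per_class: int = 30
    n_subsets: int = 100
    significance_level: float = SIGNIFICANCE_LEVEL
    class_targets: tuple = (-10.0, 10.0)
    match_order: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("at least one feature source is required")
        for s in self.sources:
            parse_source(str(s))  # raises on malformed entries
        if self.n_test_per_class < 1 or self.n_train_per_class < 2:
            raise ValueError("per-class subset sizes too small")
        if self.n_subsets < 1:
            raise ValueError("n_subsets must be >= 1")
        if not 0 < self.significance_level < 1:
            raise ValueError("significance_level must lie in (0, 1)")
        if not self.class_targets[0] < self.class_targets[1]:
            raise ValueError("class targets must satisfy LGG target < HGG target")

    @property
    def source_objects(self) -> tuple:
        return tuple(parse_source(str(s)) for s in self.sources)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        for key in ("sources", "landmark_percentiles", "class_targets"):
            if key in payload:
                payload[key] = tuple(payload[key])
        return cls(**payload)


@dataclass
class CombinationResult:
    """Everything the experiment produced for one source combination."""

    name: str
    columns: list
    d: int
    consensus: OrderedConsensus | None
    ranked: list
    models: list = field(default_factory=list)   # (t, LinearModel, EvaluationReport)
    excluded: bool = False


@dataclass
class ExperimentResult:
    combinations: list
    best: tuple | None            # (CombinationResult, t, model, report)
    reduced: list                 # (index tuple, model, report)
    best_reduced: tuple | None    # (index tuple, model, report)
    split: DataSplit

    @property
    def excluded_names(self) -> list:
        return [c.name for c in self.combinations if c.excluded]


def _indexed(features_df: pd.DataFrame) -> pd.DataFrame:
    if features_df.index.name == "id":
        return features_df
    return features_df.set_index("id")


def rank_all_subsets(features_df, split, columns, threshold) -> list:
    """Per-subset :class:`RankedFeatures` over the given feature columns."""
    return [rank_subset(features_df, s, columns, threshold) for s in split.subsets]


def run_training_experiment(features_df: pd.DataFrame, config: PipelineConfig,
                            split: DataSplit | None = None) -> ExperimentResult:
    """Run the complete ensemble experiment on a feature table.

    ``features_df`` needs ``id``, ``grade`` and one column per (source,
    feature).  Builds the split (unless given), ranks features in every
    training subset for every source combination, forms the ordered
    consensus, fits the d averaged unique models per surviving combination,
    evaluates them on the fixed testing subset, and finally builds and
    evaluates the reduced models of the best model.
    """
    table = _indexed(features_df)
    if split is None:
        by_grade = table.groupby("grade").groups
        split = make_split(
            [str(i) for i in by_grade.get("LGG", [])],
            [str(i) for i in by_grade.get("HGG", [])],
            n_test_per_class=config.n_test_per_class,
            n_train_per_class=config.n_train_per_class,
            n_subsets=config.n_subsets,
            seed=config.seed,
        )
    testing = table.loc[list(split.testing_ids)]
    sources = config.source_objects
    missing = [c for src in sources for c in src.columns() if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks configured columns: {missing[:5]}...")

    # p-values depend only on (subset, feature): rank the union of columns
    # once per subset, then slice per combination.
    all_columns = [c for src in sources for c in src.columns()]
    t0 = time.perf_counter()
    base = rank_all_subsets(table, split, all_columns, threshold=1.1)  # keep all, with p
    logger.info("ranked %d subsets x %d features in %.2fs",
                len(base), len(all_columns), time.perf_counter() - t0)
    p_by_subset = [dict(zip(r.features, r.p_values)) for r in base]

    results: list = []
    candidates: list = []
    for combo in enumerate_combinations(sources):
        name = combination_name(combo)
        cols = combination_columns(combo)
        ranked = []
        for r, pmap in zip(base, p_by_subset):
            pairs = sorted(((pmap[c], c) for c in cols), key=lambda t: (t[0], t[1]))
            kept = [(c, p) for p, c in pairs if p < config.significance_level]
            ranked.append(RankedFeatures(subset_index=r.subset_index,
                                         features=tuple(c for c, _ in kept),
                                         p_values=tuple(p for _, p in kept)))
        consensus = build_consensus(ranked)
        res = CombinationResult(name=name, columns=cols, d=consensus.d,
                                consensus=consensus, ranked=ranked)
        if consensus.d == 0:
            res.excluded = True
            logger.info("combination %s excluded (d = 0)", name)
            results.append(res)
            continue
        for t in range(1, consensus.d + 1):
            try:
                model = build_unique_model(table, split.subsets, ranked, consensus, t,
                                           match_order=config.match_order, combination=name)
            except ValueError as exc:
                logger.warning("combination %s, t=%d: %s", name, t, exc)
                continue
            report = evaluate(model, testing)
            res.models.append((t, model, report))
            candidates.append((res, t, model, report))
        results.append(res)

    best = None
    if candidates:
        # highest accuracy, then lowest clipped MAE, then fewest variables
        best = min(candidates, key=lambda c: (-c[3].accuracy, c[3].mae, c[1]))

    reduced: list = []
    best_reduced = None
    if best is not None and best[2].t >= 2:
        res, _, best_model, _ = best
        for combo_idx, model in build_reduced_models(best_model, table, split.subsets,
                                                     res.ranked, match_order=config.match_order):
            reduced.append((combo_idx, model, evaluate(model, testing)))
        # best results with the fewest variables and lowest mae
        best_reduced = min(reduced, key=lambda c: (-c[2].accuracy, len(c[0]), c[2].mae))

    return ExperimentResult(combinations=results, best=best, reduced=reduced,
                            best_reduced=best_reduced, split=split)


def _sources_for_model(model: LinearModel) -> list:
    sources = []
    for var in model.variables:
        contrast, region, _ = var.split("_", 2)
        src = FeatureSource(contrast, region)
        if src not in sources:
            sources.append(src)
    return sources


def grade_cohort(cohort, model: LinearModel, normalize: bool = False,
                 scales: dict | None = None) -> pd.DataFrame:
    """Grade volumetric records with a linear model.

    Each record (``id``, ``volumes``, ``mask``, optional ``grade``) is taken
    through normalization (optional; ``scales`` maps contrast ->
    :class:`~gliotex.normalization.StandardScale`), GLSZM and feature
    computation restricted to the model's sources, then the model.  A
    failing glioma is logged and skipped; the run continues.
    """
    from .glszm import compute_glszm
    from .features import compute_features
    from .normalization import normalize_volume

    sources = _sources_for_model(model)
    rows = []
    for rec in cohort:
        t0 = time.perf_counter()
        try:
            feats = {}
            for src in sources:
                vol = rec.volumes[src.contrast]
                if normalize:
                    vol = normalize_volume(vol, rec.mask, scales[src.contrast])
                matrix = compute_glszm(vol, rec.mask, src.region_label)
                for name, value in compute_features(matrix).items():
                    feats[src.column(name)] = value
            y_hat = sum(b * feats[v] for v, b in zip(model.variables, model.coefficients))
            y_hat += model.intercept
        except (KeyError, ValueError) as exc:
            logger.error("glioma %s failed: %s", rec.id, exc)
            continue
        from .evaluation import classify
        rows.append({"id": rec.id, "grade": getattr(rec, "grade", None),
                     "y_hat": y_hat, "call": classify(y_hat)})
        logger.info("graded %s in %.3fs -> %s", rec.id, time.perf_counter() - t0,
                    rows[-1]["call"])
    return pd.DataFrame(rows, columns=["id", "grade", "y_hat", "call"])


def grade_feature_table(features_df: pd.DataFrame, model: LinearModel) -> pd.DataFrame:
    """Grade gliomas straight from a feature table (imaging skipped)."""
    from .evaluation import classify

    table = _indexed(features_df)
    preds = predict_table(model, table)
    out = pd.DataFrame({
        "id": table.index,
        "grade": table["grade"] if "grade" in table.columns else None,
        "y_hat": preds.to_numpy(),
    })
    out["call"] = out["y_hat"].map(classify)
    return out
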