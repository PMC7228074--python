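"""Averaged linear classification models built from the subset ensemble.

For a chosen model size *t*, the training subsets whose first *t* ranked
features coincide with the first *t* consensus features are selected (w of
them); an ordinary least-squares regression against class targets −10
(LGG) / +10 (HGG) is fitted on each, and the coefficient vectors —
including the intercept — are averaged into a single *unique model*

    ybar_1 x_1 + ... + ybar_t x_t + ybar_{t+1} = y_hat .

*Reduced models* re-run the same machinery on every non-empty subset of
the best model's variables: a variable subset C with largest index m keeps
the training subsets whose first m ranked features match the first m
consensus features, and fits only the variables in C.

"Coincide" is interpreted as *set* equality over the leading positions by
default (order-exact matching is available via ``match_order=True``).

The published three-variable classifier — zone percentage and zone-size
variance from T2/NCR-NET plus zone-size nonuniformity from T1Gd/NCR-NET —
ships as a packaged JSON asset; see :func:`published_model`.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CLASS_TARGETS = {"LGG": -10.0, "HGG": 10.0}


@dataclass(frozen=True)
class LinearModel:
    """Averaged linear classifier (variables in consensus order)."""

    variables: tuple
    coefficients: tuple
    intercept: float
    w: int = 1
    combination: str = ""
    targets: tuple = (-10.0, 10.0)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.variables):
            raise ValueError("one coefficient per variable required")
        if self.w < 1:
            raise ValueError("w (contributing subsets) must be >= 1")

    @property
    def t(self) -> int:
        return len(self.variables)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.variables),
            "coefficients": list(self.coefficients),
            "intercept": self.intercept,
            "w": self.w,
            "combination": self.combination,
            "targets": list(self.targets),
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "LinearModel":
        return cls(
            variables=tuple(payload["variables"]),
            coefficients=tuple(float(c) for c in payload["coefficients"]),
            intercept=float(payload["intercept"]),
            w=int(payload.get("w", 1)),
            combination=payload.get("combination", ""),
            targets=tuple(payload.get("targets", (-10.0, 10.0))),
        )


def published_model() -> LinearModel:
    """The packaged three-variable classifier (coefficients as published)."""
    payload = json.loads(
        resources.files("gliotex").joinpath("data/published_model.json").read_text()
    )
    return LinearModel.from_dict(payload)


def enumerate_combinations(sources) -> list:
    """All non-empty subsets of the feature sources, by size then position.

    Four sources yield the canonical 15 combinations (4 singles, 6 pairs,
    4 triples, 1 quadruple).
    """
    sources = list(sources)
    if len(set(sources)) != len(sources):
        raise ValueError("sources must be distinct")
    combos = []
    for size in range(1, len(sources) + 1):
        combos.extend(tuple(c) for c in itertools.combinations(sources, size))
    return combos


def combination_name(combo) -> str:
    return "+".join(str(src) for src in combo)


def combination_columns(combo) -> list:
    cols = []
    for src in combo:
        cols.extend(src.columns())
    return cols


def select_matching_subsets(ranked, consensus, t: int, match_order: bool = False) -> list:
    """Indices (into ``ranked``) of subsets whose leading ranking matches.

    A subset qualifies when its first ``t`` ordered features equal the first
    ``t`` consensus features — as a set by default, as an exact sequence
    when ``match_order`` is true.
    """
    if not 1 <= t <= consensus.d:
        raise ValueError(f"t={t} outside 1..d={consensus.d}")
    head = consensus.features[:t]
    target = tuple(head) if match_order else frozenset(head)
    selected = []
    for pos, r in enumerate(ranked):
        if r.d_i < t:
            continue
        lead = r.features[:t] if match_order else frozenset(r.features[:t])
        if lead == target:
            selected.append(pos)
    if not selected:
        raise ValueError(f"no qualifying training subsets for t={t}")
    return selected


def fit_subset_regression(features_df: pd.DataFrame, subset, variables,
                          targets: dict = CLASS_TARGETS) -> np.ndarray:
    """OLS fit of one training subset; returns (t+1,) coefficients, last = intercept."""
    variables = list(variables)
    if not variables:
        raise ValueError("at least one predictor variable is required")
    table = features_df.loc[list(subset.ids)]
    X = np.column_stack([table[variables].to_numpy(dtype=float),
                         np.ones(len(table))])
    y = table["grade"].map(targets).to_numpy(dtype=float)
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise ValueError(f"rank-deficient design matrix (rank {rank} < {X.shape[1]})")
    return coef


class _DesignCache:
    """Per-subset numpy views of the feature table, shared across many fits.

    The ensemble averages thousands of small OLS fits; going through pandas
    row/column indexing for each one dominates the runtime, so the rows of
    every training subset and the class targets are resolved to plain
    arrays once.
    """

    def __init__(self, features_df: pd.DataFrame, subsets, variables):
        self.variables = list(variables)
        self.values = features_df[self.variables].to_numpy(dtype=float)
        self.targets = features_df["grade"].map(CLASS_TARGETS).to_numpy(dtype=float)
        index = features_df.index
        self.rows = []
        for s in subsets:
            rows = index.get_indexer(list(s.ids))
            if (rows < 0).any():
                raise KeyError(f"subset {s.index} holds ids absent from the feature table")
            self.rows.append(rows)

    def fit(self, subset_pos: int, col_idx) -> np.ndarray:
        rows = self.rows[subset_pos]
        X = np.column_stack([self.values[rows][:, col_idx], np.ones(len(rows))])
        coef, _, rank, _ = np.linalg.lstsq(X, self.targets[rows], rcond=None)
        if rank < X.shape[1]:
            raise ValueError(f"rank-deficient design matrix (rank {rank} < {X.shape[1]})")
        return coef


def build_unique_model(features_df, subsets, ranked, consensus, t: int,
                       match_order: bool = False, combination: str = "") -> LinearModel:
    """Average the per-subset OLS fits of the w qualifying subsets (size t)."""
    selected = select_matching_subsets(ranked, consensus, t, match_order=match_order)
    variables = list(consensus.features[:t])
    cache = _DesignCache(features_df, subsets, variables)
    col_idx = np.arange(t)
    coefs = np.mean([cache.fit(k, col_idx) for k in selected], axis=0)
    return LinearModel(
        variables=tuple(variables),
        coefficients=tuple(coefs[:-1]),
        intercept=float(coefs[-1]),
        w=len(selected),
        combination=combination,
    )


def build_reduced_models(best_model: LinearModel, features_df, subsets, ranked,
                         match_order: bool = False) -> list:
    """Averaged models for every non-empty subset of the best model's variables.

    Returns ``[(variable index tuple, LinearModel), ...]`` with 1-based
    indices in the best model's order.  A subset of variables C with largest
    index m keeps the training subsets whose first m ranked features match
    x_1..x_m; combinations with no qualifying subset are skipped with a
    warning.
    """
    if best_model.t < 2:
        raise ValueError("reduced models require a best model with >= 2 variables")
    x = best_model.variables
    full = range(1, best_model.t + 1)
    cache = _DesignCache(features_df, subsets, x)

    # qualifying subsets depend only on m = max(C); resolve each m once
    selected_by_m = {}
    for m in full:
        head = frozenset(x[:m]) if not match_order else tuple(x[:m])
        selected_by_m[m] = [
            pos for pos, r in enumerate(ranked)
            if r.d_i >= m
            and (frozenset(r.features[:m]) if not match_order else r.features[:m]) == head
        ]

    out = []
    for size in range(1, best_model.t + 1):
        for combo in itertools.combinations(full, size):
            selected = selected_by_m[max(combo)]
            if not selected:
                logger.warning("no qualifying subsets for variable combination %s; skipped", combo)
                continue
            variables = [x[i - 1] for i in combo]
            col_idx = np.asarray(combo) - 1
            coefs = np.mean([cache.fit(k, col_idx) for k in selected], axis=0)
            model = LinearModel(
                variables=tuple(variables),
                coefficients=tuple(coefs[:-1]),
                intercept=float(coefs[-1]),
                w=len(selected),
                combination=best_model.combination,
            )
            out.append((combo, model))
    return out


def apply_model(model: LinearModel, features) -> float:
    """Evaluate y_hat = sum beta_s x_s + intercept for one glioma.

    ``features`` is any mapping (dict, pandas Series) from variable id to
    value; a missing variable raises ``KeyError``.
    """
    total = model.intercept
    for var, beta in zip(model.variables, model.coefficients):
        total += beta * float(features[var])
    return float(total)


def predict_table(model: LinearModel, features_df: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`apply_model` over a feature table (indexed by id)."""
    missing = [v for v in model.variables if v not in features_df.columns]
    if missing:
        raise KeyError(f"feature table lacks model variables: {missing}")
    X = features_df[list(model.variables)].to_numpy(dtype=float)
    return pd.Series(X @ np.asarray(model.coefficients) + model.intercept,
                     index=features_df.index, name="y_hat")
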