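"""Per-subset feature ranking and the cross-subset ordered consensus.

In every balanced training subset each feature is compared between the two
grades with the two-sided Wilcoxon rank-sum test.  Features are ordered by
ascending p-value and truncated at the significance threshold (p < 0.05);
the number kept in subset *i* is D_i, and d = min_i D_i caps the size of
any model built later.  Across subsets, one histogram per rank position
s = 1..d is formed from the features that landed at that position, and the
modal feature of each histogram — skipping features already taken — gives
the ordered highest-frequency consensus x_1..x_d.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy import stats

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class RankedFeatures:
    """Significant features of one training subset, in ascending-p order."""

    subset_index: int
    features: tuple      # ordered ids, truncated at p < threshold
    p_values: tuple      # matching p-values, non-decreasing

    @property
    def d_i(self) -> int:
        return len(self.features)


@dataclass(frozen=True)
class OrderedConsensus:
    """The ordered highest-frequency features across all subsets."""

    d: int
    features: tuple               # x_1..x_d, all distinct
    histograms: tuple             # per position: {feature id: frequency}


def ranksum_p(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Normal approximation with tie and continuity corrections (the standard
    choice at n ~ 30 per group).  Fully tied samples give p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method="asymptotic", use_continuity=True).pvalue)


def _ranksum_p_matrix(lgg_values: np.ndarray, hgg_values: np.ndarray) -> np.ndarray:
    """Vectorized rank-sum p-values, one per feature column."""
    res = stats.mannwhitneyu(lgg_values, hgg_values, alternative="two-sided",
                             method="asymptotic", use_continuity=True, axis=0)
    return np.asarray(res.pvalue, dtype=float)


def rank_subset(features_df, subset, feature_columns, threshold: float = SIGNIFICANCE_LEVEL) -> RankedFeatures:
    """Rank ``feature_columns`` within one training subset.

    ``features_df`` must be indexed by glioma id with a ``grade`` column.
    Features are ordered by ascending p; ties break lexicographically on
    the feature id.  Only features with p < ``threshold`` are kept.
    """
    table = features_df.loc[list(subset.ids)]
    if table[feature_columns].isna().any().any():
        raise ValueError("missing feature values in training subset")
    lgg = table.loc[table["grade"] == "LGG", feature_columns].to_numpy(dtype=float)
    hgg = table.loc[table["grade"] == "HGG", feature_columns].to_numpy(dtype=float)
    pvals = _ranksum_p_matrix(lgg, hgg)

    order = sorted(range(len(feature_columns)), key=lambda k: (pvals[k], feature_columns[k]))
    kept = [(feature_columns[k], pvals[k]) for k in order if pvals[k] < threshold]
    return RankedFeatures(
        subset_index=subset.index,
        features=tuple(f for f, _ in kept),
        p_values=tuple(p for _, p in kept),
    )


def build_consensus(ranked) -> OrderedConsensus:
    """Combine per-subset orderings into the ordered consensus.

    d = min D_i; the consensus is empty when d = 0 (the caller then drops
    the combination).  Frequency ties break toward the feature with the
    lower mean p-value across subsets, then lexicographically.  If every
    feature of a position's histogram is already chosen, the unchosen
    feature with the highest total frequency across all position histograms
    is taken instead, so the result always holds d distinct features.
    """
    ranked = list(ranked)
    if not ranked:
        raise ValueError("need at least one ranked subset")
    d = min(r.d_i for r in ranked)
    if d == 0:
        return OrderedConsensus(d=0, features=(), histograms=())

    # mean p per feature across subsets, for deterministic tie-breaking
    p_sum: Counter = Counter()
    p_cnt: Counter = Counter()
    for r in ranked:
        for f, p in zip(r.features, r.p_values):
            p_sum[f] += p
            p_cnt[f] += 1
    mean_p = {f: p_sum[f] / p_cnt[f] for f in p_sum}

    histograms = []
    for s in range(d):
        histograms.append(Counter(r.features[s] for r in ranked))

    def best_of(counter, chosen):
        candidates = [f for f in counter if f not in chosen]
        if not candidates:
            return None
        return min(candidates, key=lambda f: (-counter[f], mean_p[f], f))

    overall = Counter()
    for h in histograms:
        overall.update(h)

    chosen: list = []
    for s in range(d):
        pick = best_of(histograms[s], chosen)
        if pick is None:
            pick = best_of(overall, chosen)
        if pick is None:  # fewer distinct features than d cannot happen: each
            # subset contributes d distinct features, so the pool has >= d
            raise RuntimeError("consensus underflow")
        chosen.append(pick)

    return OrderedConsensus(d=d, features=tuple(chosen),
                            histograms=tuple(dict(h) for h in histograms))
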