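"""Data division and under-sampling into balanced subsets.

An imbalanced cohort (few LGGs, many HGGs) is divided into one fixed,
class-balanced *testing subset* and many class-balanced *training subsets*.
The LGG training block is drawn once and shared by every training subset
(in the canonical 64/191 configuration it is simply all LGGs left after the
testing draw); the HGG members are re-drawn independently for each subset,
so an HGG may recur across subsets but never within one.  Ensemble models
built per subset later extract complementary information from these draws.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class TrainingSubset:
    """One balanced training draw."""

    index: int
    lgg_ids: tuple
    hgg_ids: tuple

    @property
    def ids(self) -> tuple:
        return self.lgg_ids + self.hgg_ids


@dataclass(frozen=True)
class DataSplit:
    """Fixed testing subset plus the list of balanced training subsets."""

    testing_lgg: tuple
    testing_hgg: tuple
    subsets: tuple
    seed: int = 0

    @property
    def testing_ids(self) -> tuple:
        return self.testing_lgg + self.testing_hgg

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "testing_lgg": list(self.testing_lgg),
            "testing_hgg": list(self.testing_hgg),
            "subsets": [
                {"index": s.index, "lgg": list(s.lgg_ids), "hgg": list(s.hgg_ids)}
                for s in self.subsets
            ],
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "DataSplit":
        subsets = tuple(
            TrainingSubset(index=s["index"], lgg_ids=tuple(s["lgg"]), hgg_ids=tuple(s["hgg"]))
            for s in payload["subsets"]
        )
        return cls(
            testing_lgg=tuple(payload["testing_lgg"]),
            testing_hgg=tuple(payload["testing_hgg"]),
            subsets=subsets,
            seed=int(payload.get("seed", 0)),
        )


def make_split(lgg_ids, hgg_ids, n_test_per_class: int = 34, n_train_per_class: int = 30,
               n_subsets: int = 100, seed: int = 0) -> DataSplit:
    """Draw the testing subset and ``n_subsets`` balanced training subsets.

    Sampling is without replacement within each draw; HGG draws are
    independent across subsets.  Reference-normalization gliomas must have
    been excluded by the caller.  Deterministic under ``seed``.
    """
    lgg_ids = sorted(str(i) for i in lgg_ids)
    hgg_ids = sorted(str(i) for i in hgg_ids)
    need = n_test_per_class + n_train_per_class
    for grade, pool in (("LGG", lgg_ids), ("HGG", hgg_ids)):
        if len(pool) < need:
            raise ValueError(
                f"{grade} pool has {len(pool)} gliomas but {need} are needed "
                f"({n_test_per_class} testing + {n_train_per_class} training); "
                f"short by {need - len(pool)}"
            )

    rng = np.random.default_rng(seed)
    test_lgg = tuple(sorted(rng.choice(lgg_ids, size=n_test_per_class, replace=False)))
    test_hgg = tuple(sorted(rng.choice(hgg_ids, size=n_test_per_class, replace=False)))

    lgg_pool = [i for i in lgg_ids if i not in set(test_lgg)]
    hgg_pool = [i for i in hgg_ids if i not in set(test_hgg)]

    # the shared LGG block: all remaining LGGs when the counts line up,
    # otherwise one fixed draw reused across subsets
    if len(lgg_pool) == n_train_per_class:
        train_lgg = tuple(lgg_pool)
    else:
        train_lgg = tuple(sorted(rng.choice(lgg_pool, size=n_train_per_class, replace=False)))

    subsets = []
    for i in range(n_subsets):
        hgg_draw = tuple(sorted(rng.choice(hgg_pool, size=n_train_per_class, replace=False)))
        subsets.append(TrainingSubset(index=i, lgg_ids=train_lgg, hgg_ids=hgg_draw))

    return DataSplit(testing_lgg=test_lgg, testing_hgg=test_hgg, subsets=tuple(subsets), seed=seed)
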