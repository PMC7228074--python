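"""Averaged linear models: combination enumeration, subset matching, OLS, reduction."""

import numpy as np
import pandas as pd
import pytest

from gliotex.features import DEFAULT_SOURCES
from gliotex.models import (
    LinearModel,
    apply_model,
    build_reduced_models,
    build_unique_model,
    enumerate_combinations,
    fit_subset_regression,
    predict_table,
    published_model,
    select_matching_subsets,
)
from gliotex.ranking import OrderedConsensus, RankedFeatures
from gliotex.splitting import TrainingSubset


def _ranked(seq, index=0):
    return RankedFeatures(subset_index=index, features=tuple(seq),
                          p_values=tuple(0.001 * (k + 1) for k in range(len(seq))))


def _consensus(seq):
    return OrderedConsensus(d=len(seq), features=tuple(seq),
                            histograms=tuple({f: 1} for f in seq))


class TestEnumerateCombinations:
    @pytest.mark.parametrize("k,expected", [(1, 1), (2, 3), (3, 7), (4, 15)])
    def test_cardinality(self, k, expected):
        assert len(enumerate_combinations(DEFAULT_SOURCES[:k])) == expected

    def test_ordered_by_size_then_position(self):
        combos = enumerate_combinations(DEFAULT_SOURCES)
        sizes = [len(c) for c in combos]
        assert sizes == sorted(sizes)
        assert combos[0] == (DEFAULT_SOURCES[0],)
        assert combos[-1] == tuple(DEFAULT_SOURCES)

    def test_duplicate_sources_error(self):
        with pytest.raises(ValueError, match="distinct"):
            enumerate_combinations([DEFAULT_SOURCES[0], DEFAULT_SOURCES[0]])


class TestSelectMatchingSubsets:
    RANKED = [_ranked(("A", "B", "C"), 0), _ranked(("B", "A", "C"), 1),
              _ranked(("A", "C", "B"), 2)]
    CONS = _consensus(("A", "B", "C"))

    def test_set_match_accepts_swapped_leading_pair(self):
        assert select_matching_subsets(self.RANKED, self.CONS, t=2) == [0, 1]

    def test_set_match_rejects_wrong_members(self):
        # (A, C) != {A, B} even though A leads
        assert 2 not in select_matching_subsets(self.RANKED, self.CONS, t=2)

    def test_order_match_is_stricter(self):
        assert select_matching_subsets(self.RANKED, self.CONS, t=2, match_order=True) == [0]

    def test_no_qualifying_subsets_errors(self):
        with pytest.raises(ValueError, match="no qualifying"):
            select_matching_subsets([_ranked(("C", "B", "A"))], self.CONS, t=1)

    def test_t_out_of_range_errors(self):
        with pytest.raises(ValueError, match="t="):
            select_matching_subsets(self.RANKED, self.CONS, t=4)


def _training_table(rng, n=30, columns=("A", "B", "C")):
    ids_l = [f"L{k:03d}" for k in range(n)]
    ids_h = [f"H{k:03d}" for k in range(n)]
    table = pd.DataFrame(
        rng.normal(size=(2 * n, len(columns))), columns=list(columns),
        index=ids_l + ids_h)
    table.insert(0, "grade", ["LGG"] * n + ["HGG"] * n)
    table.index.name = "id"
    subset = TrainingSubset(index=0, lgg_ids=tuple(ids_l), hgg_ids=tuple(ids_h))
    return table, subset


class TestFitSubsetRegression:
    def test_perfect_predictor_recovers_unit_coefficient(self, rng):
        table, subset = _training_table(rng)
        table["A"] = np.where(table["grade"] == "HGG", 10.0, -10.0)
        coefs = fit_subset_regression(table, subset, ["A"])
        assert coefs == pytest.approx([1.0, 0.0], abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        table, subset = _training_table(rng)
        coefs = fit_subset_regression(table, subset, ["A", "B"])
        X = np.column_stack([table[["A", "B"]].to_numpy(), np.ones(60)])
        y = np.where(table["grade"] == "HGG", 10.0, -10.0)
        oracle = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.abs(coefs - oracle).max() < 1e-8

    def test_empty_variable_list_errors(self, rng):
        table, subset = _training_table(rng)
        with pytest.raises(ValueError, match="at least one"):
            fit_subset_regression(table, subset, [])

    def test_rank_deficiency_errors(self, rng):
        table, subset = _training_table(rng)
        table["B"] = 2 * table["A"]
        with pytest.raises(ValueError, match="rank"):
            fit_subset_regression(table, subset, ["A", "B"])


class TestBuildUniqueModel:
    def test_w_equals_one_matches_single_fit(self, rng):
        table, subset = _training_table(rng)
        model = build_unique_model(table, [subset], [_ranked(("A", "B", "C"))],
                                   _consensus(("A", "B", "C")), t=2)
        direct = fit_subset_regression(table, subset, ["A", "B"])
        assert model.w == 1
        assert model.coefficients == pytest.approx(tuple(direct[:-1]))
        assert model.intercept == pytest.approx(direct[-1])

    def test_identical_subsets_average_to_either_fit(self, rng):
        table, subset = _training_table(rng)
        subsets = [subset, TrainingSubset(1, subset.lgg_ids, subset.hgg_ids)]
        ranked = [_ranked(("A", "B", "C"), 0), _ranked(("A", "B", "C"), 1)]
        model = build_unique_model(table, subsets, ranked, _consensus(("A", "B", "C")), t=1)
        direct = fit_subset_regression(table, subset, ["A"])
        assert model.w == 2
        assert model.coefficients[0] == pytest.approx(direct[0])

    def test_hand_averaged_coefficients(self, rng):
        """Coefficients of the unique model equal the mean of the w separate fits."""
        tables = []
        fits = []
        big = []
        subsets = []
        for i in range(3):
            t, s = _training_table(rng, n=10)
            t.index = [f"{i}{gid}" for gid in t.index]
            s = TrainingSubset(i, tuple(f"{i}{g}" for g in s.lgg_ids),
                               tuple(f"{i}{g}" for g in s.hgg_ids))
            tables.append(t)
            subsets.append(s)
            big.append(t)
        table = pd.concat(big)
        for s in subsets:
            fits.append(fit_subset_regression(table, s, ["A", "B"]))
        ranked = [_ranked(("A", "B"), i) for i in range(3)]
        model = build_unique_model(table, subsets, ranked, _consensus(("A", "B")), t=2)
        mean_fit = np.mean(fits, axis=0)
        assert model.coefficients == pytest.approx(tuple(mean_fit[:-1]))
        assert model.intercept == pytest.approx(mean_fit[-1])
        assert model.w == 3

    def test_prediction_is_mean_of_member_predictions(self, rng):
        """Averaging coefficients commutes with averaging predictions (linearity)."""
        table, subset = _training_table(rng)
        s2 = TrainingSubset(1, subset.lgg_ids[::-1], subset.hgg_ids[:15] + subset.hgg_ids[15:])
        subsets = [subset, s2]
        ranked = [_ranked(("A", "B"), i) for i in range(2)]
        model = build_unique_model(table, subsets, ranked, _consensus(("A", "B")), t=2)
        fits = [fit_subset_regression(table, s, ["A", "B"]) for s in subsets]
        for _ in range(10):
            x = dict(zip(("A", "B"), rng.normal(size=2)))
            member_preds = [f[0] * x["A"] + f[1] * x["B"] + f[2] for f in fits]
            assert apply_model(model, x) == pytest.approx(np.mean(member_preds), abs=1e-8)


class TestReducedModels:
    def _setup(self, rng, n_vars=3):
        cols = tuple("ABCDE"[:n_vars])
        table, subset = _training_table(rng, columns=cols)
        subsets = [subset]
        ranked = [_ranked(cols)]
        best = build_unique_model(table, subsets, ranked, _consensus(cols), t=n_vars)
        return best, table, subsets, ranked

    @pytest.mark.parametrize("n_vars,expected", [(3, 7), (5, 31)])
    def test_candidate_combination_counts(self, rng, n_vars, expected):
        best, table, subsets, ranked = self._setup(rng, n_vars)
        reduced = build_reduced_models(best, table, subsets, ranked)
        assert len(reduced) == expected

    def test_full_combination_reproduces_best_model(self, rng):
        best, table, subsets, ranked = self._setup(rng)
        reduced = dict(build_reduced_models(best, table, subsets, ranked))
        full = reduced[(1, 2, 3)]
        assert full.coefficients == pytest.approx(best.coefficients)
        assert full.intercept == pytest.approx(best.intercept)

    def test_single_variable_model_errors(self, rng):
        table, subset = _training_table(rng)
        best = build_unique_model(table, [subset], [_ranked(("A",))], _consensus(("A",)), t=1)
        with pytest.raises(ValueError, match=">= 2"):
            build_reduced_models(best, table, [subset], [_ranked(("A",))])


class TestApplyModel:
    def test_published_intercept_only(self):
        model = published_model()
        zeros = {v: 0.0 for v in model.variables}
        assert apply_model(model, zeros) == pytest.approx(-19.500)

    def test_published_unit_vector(self):
        model = published_model()
        x = {"T2_NCRNET_F_szm.z.perc": 1.0, "T2_NCRNET_F_szm.zs.var": 0.0,
             "T1Gd_NCRNET_F_szm.zsnu": 1.0}
        assert apply_model(model, x) == pytest.approx(26.035)

    def test_missing_variable_raises(self):
        model = published_model()
        with pytest.raises(KeyError):
            apply_model(model, {"T2_NCRNET_F_szm.z.perc": 1.0})

    def test_predict_table_matches_apply_model(self, rng):
        model = LinearModel(variables=("A", "B"), coefficients=(2.0, -1.0), intercept=0.5)
        table = pd.DataFrame(rng.normal(size=(5, 2)), columns=["A", "B"],
                             index=[f"g{k}" for k in range(5)])
        preds = predict_table(model, table)
        for gid in table.index:
            assert preds[gid] == pytest.approx(apply_model(model, table.loc[gid]))


def test_model_serialization_roundtrip():
    model = published_model()
    assert LinearModel.from_dict(model.to_dict()) == model


def test_model_validation():
    with pytest.raises(ValueError, match="coefficient"):
        LinearModel(variables=("A",), coefficients=(1.0, 2.0), intercept=0.0)
    with pytest.raises(ValueError, match="w"):
        LinearModel(variables=("A",), coefficients=(1.0,), intercept=0.0, w=0)
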