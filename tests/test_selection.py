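"""Feature selection: serial kNN against a brute-force oracle, LASSO
shrinkage properties, forest importance arithmetic, consensus set algebra."""

import numpy as np
import pytest

import evsig as ev
from evsig.containers import contrast_arrays
from evsig.selection import FeatureSignature, lasso_lambda_max

from conftest import make_matrix, make_sheet


def _labelled_data(n_per=20, G=10, informative=2, gap=3.0, seed=0):
    """Two informative features separated by `gap`, the rest noise."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((2 * n_per, G))
    X[:n_per, :informative] += gap
    feats = [f"f{j}" for j in range(G)]
    m = make_matrix(X, features=feats)
    sheet = make_sheet(["primary"] * n_per + ["control"] * n_per)
    return m, sheet, feats


class TestSerialKnn:
    def test_perfect_feature_first_gives_accuracy_one(self):
        m, sheet, feats = _labelled_data(gap=10.0)
        res = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL,
                            k_values=(1,), n_values=(1,), ranked_features=feats)
        assert res.best_score == 1.0
        assert (res.best_k, res.best_n) == (1, 1)

    def test_grid_matches_brute_force_oracle(self):
        """Every grid cell equals an independent naive leave-one-out kNN
        re-evaluation."""
        m, sheet, feats = _labelled_data(gap=1.5, seed=3)
        res = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL,
                            k_values=(1, 3, 5), n_values=(1, 2, 3, 5),
                            cv_mode="loo", ranked_features=feats)
        X, y, _, _ = contrast_arrays(m.subset_features(feats), sheet,
                                     ev.MELANOMA_VS_CONTROL)
        for _, row in res.grid.iterrows():
            k, N = int(row["k"]), int(row["n"])
            correct = 0
            for i in range(len(y)):
                d = np.sqrt(((X[:, :N] - X[i, :N]) ** 2).sum(axis=1))
                order = sorted(j for j in range(len(y)) if j != i)
                order.sort(key=lambda j: (d[j], j))
                vote = y[order[:k]].mean()
                correct += int(vote > 0.5) == y[i]
            assert row["score"] == pytest.approx(correct / len(y))

    def test_k1_auc_equals_balanced_accuracy(self):
        """With k = 1 the vote scores are 0/1, so the AUC over vote scores
        reduces to balanced accuracy."""
        m, sheet, feats = _labelled_data(gap=1.0, seed=5)
        res = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL,
                            k_values=(1,), n_values=(3,), metric="auc",
                            cv_mode="loo", ranked_features=feats)
        X, y, _, _ = contrast_arrays(m.subset_features(feats), sheet,
                                     ev.MELANOMA_VS_CONTROL)
        votes = np.empty(len(y))
        for i in range(len(y)):
            d = np.sqrt(((X[:, :3] - X[i, :3]) ** 2).sum(axis=1))
            order = sorted((j for j in range(len(y)) if j != i),
                           key=lambda j: (d[j], j))
            votes[i] = y[order[0]]
        sens = votes[y == 1].mean()
        spec = 1 - votes[y == 0].mean()
        assert res.best_score == pytest.approx((sens + spec) / 2)

    def test_even_k_rejected(self):
        m, sheet, feats = _labelled_data()
        with pytest.raises(ValueError, match="odd"):
            ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL, k_values=(2,),
                          ranked_features=feats)

    def test_oversized_n_skipped(self):
        m, sheet, feats = _labelled_data(G=4)
        res = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL,
                            k_values=(1,), n_values=(2, 99), ranked_features=feats)
        assert set(res.grid["n"]) == {2}

    def test_loso_excludes_same_subject_replicates(self):
        """A subject's duplicate is its nearest neighbour; leave-one-subject-out
        must not let it vote."""
        vals = [[0.0], [0.01], [1.0], [1.01], [0.4], [0.6], [0.45], [0.62]]
        obs = [f"s{i//2}_r{i%2}" for i in range(8)]
        subj = [f"s{i//2}" for i in range(8)]
        m = make_matrix(vals, obs=obs, features=["F"])
        sheet = make_sheet(["primary"] * 4 + ["control"] * 4, subjects=subj, obs=obs,
                           replicate_index=[1, 2] * 4)
        loo = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL, k_values=(1,),
                            n_values=(1,), cv_mode="loo", ranked_features=["F"])
        loso = ev.serial_knn(m, sheet, ev.MELANOMA_VS_CONTROL, k_values=(1,),
                             n_values=(1,), cv_mode="loso", ranked_features=["F"])
        assert loo.best_score == 1.0       # replicate leakage
        assert loso.best_score < 1.0       # leakage removed


class TestLassoLogistic:
    def test_full_shrinkage_above_lambda_max(self):
        m, sheet, _ = _labelled_data(seed=7)
        X, y, _, _ = contrast_arrays(m, sheet, ev.MELANOMA_VS_CONTROL)
        Xs = (X - X.mean(0)) / X.std(0)
        lmax = lasso_lambda_max(Xs, y.astype(float))
        sig = ev.lasso_logistic(m, sheet, ev.MELANOMA_VS_CONTROL, seed=0,
                                lambda_values=[lmax * 1.05])
        assert sig.features == []

    def test_strong_feature_selected_across_seeds(self):
        """One strong feature among 20 noise features is selected in at
        least 19 of 20 seeds."""
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((40, 21))
            X[:20, 0] += 2.5
            m = make_matrix(X, features=[f"f{j}" for j in range(21)])
            sheet = make_sheet(["primary"] * 20 + ["control"] * 20)
            sig = ev.lasso_logistic(m, sheet, ev.MELANOMA_VS_CONTROL,
                                    n_lambda=20, seed=seed)
            hits += "f0" in sig.features
        assert hits >= 19

    def test_rescaling_invariance(self):
        m, sheet, feats = _labelled_data(seed=9)
        sig_a = ev.lasso_logistic(m, sheet, ev.MELANOMA_VS_CONTROL, seed=1)
        scaled = m.values.copy()
        scaled[feats[0]] *= 10.0
        sig_b = ev.lasso_logistic(m.with_values(scaled), sheet,
                                  ev.MELANOMA_VS_CONTROL, seed=1)
        assert set(sig_a.features) == set(sig_b.features)

    def test_one_se_rule_not_smaller_lambda_than_min(self):
        m, sheet, _ = _labelled_data(seed=11)
        s_min = ev.lasso_logistic(m, sheet, ev.MELANOMA_VS_CONTROL, rule="min", seed=2)
        s_1se = ev.lasso_logistic(m, sheet, ev.MELANOMA_VS_CONTROL, rule="1se", seed=2)
        assert s_1se.params["lambda"] >= s_min.params["lambda"]
        assert len(s_1se.features) <= len(s_min.features)


class TestForestImportance:
    @pytest.mark.parametrize("G,fraction,expected", [(10, 0.1, 1), (107, 0.1, 11)])
    def test_signature_size_is_ceiling(self, G, fraction, expected):
        rng = np.random.default_rng(0)
        m = make_matrix(rng.standard_normal((20, G)))
        sheet = make_sheet(["primary"] * 10 + ["control"] * 10)
        sig = ev.forest_importance(m, sheet, ev.MELANOMA_VS_CONTROL,
                                   n_trees=20, top_fraction=fraction, seed=0)
        assert len(sig.features) == expected

    def test_separating_feature_ranks_first(self):
        m, sheet, feats = _labelled_data(G=8, informative=1, gap=8.0, seed=13)
        sig = ev.forest_importance(m, sheet, ev.MELANOMA_VS_CONTROL,
                                   n_trees=200, top_fraction=0.25, seed=3)
        assert sig.features[0] == feats[0]

    def test_deterministic(self):
        m, sheet, _ = _labelled_data(seed=15)
        a = ev.forest_importance(m, sheet, ev.MELANOMA_VS_CONTROL, n_trees=50, seed=4)
        b = ev.forest_importance(m, sheet, ev.MELANOMA_VS_CONTROL, n_trees=50, seed=4)
        assert a.features == b.features


class TestConsensus:
    def _sig(self, feats, source="knn"):
        return FeatureSignature(list(feats), source)

    def test_three_way_intersection(self):
        strict, _ = ev.consensus([self._sig("ABC"), self._sig("BCD", "lasso"),
                                  self._sig("BC", "forest")])
        assert set(strict.features) == {"B", "C"}

    def test_disjoint_inputs_both_empty(self):
        strict, lenient = ev.consensus([self._sig("AB"), self._sig("CD", "lasso"),
                                        self._sig("EF", "forest")])
        assert strict.features == [] and lenient.features == []

    def test_lenient_is_union_of_pairwise_intersections(self):
        strict, lenient = ev.consensus([self._sig("AB"), self._sig("B", "lasso"),
                                        self._sig("AB", "forest")])
        assert strict.features == ["B"]
        assert set(lenient.features) == {"A", "B"}

    def test_idempotent_on_identical_signatures(self):
        s = self._sig(["X", "Y", "Z"])
        strict, lenient = ev.consensus([s, s, s])
        assert strict.features == ["X", "Y", "Z"]
        assert lenient.features == ["X", "Y", "Z"]
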