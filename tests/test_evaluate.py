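"""Signature evaluation: NIR and exact binomial machinery against printed
cohort arithmetic, clustering-as-classifier against brute force, grid
search, agreement indices, PCA invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.cluster.hierarchy import fcluster, linkage

import evsig as ev

from conftest import make_matrix, make_sheet


class TestNir:
    def test_cohort_replicate_level(self):
        """68 melanoma vs 26 control observations give the cohort's 72.34%."""
        labels = ["melanoma"] * 68 + ["control"] * 26
        assert ev.nir(labels) * 100 == pytest.approx(72.34, abs=0.005)

    def test_cohort_subject_level(self):
        assert ev.nir([1] * 34 + [0] * 13) == pytest.approx(34 / 47)

    def test_balanced(self):
        assert ev.nir([0, 1, 0, 1]) == 0.5


class TestBinomialAccTest:
    @pytest.mark.parametrize("correct,n,nir_,expected", [
        (40, 47, 34 / 47, 0.031),   # combined signature, subject level
        (54, 94, 68 / 94, 0.999),   # 8-protein kNN signature, replicate level
        (39, 47, 34 / 47, 0.066),   # metabolite signature, subject level
        (69, 94, 68 / 94, 0.461),   # 2-protein grid signature, replicate level
    ])
    def test_reconstructs_printed_p_values(self, correct, n, nir_, expected):
        assert ev.binomial_acc_test(correct, n, nir_) == pytest.approx(expected, abs=0.005)

    def test_half_cubed(self):
        assert ev.binomial_acc_test(3, 3, 0.5) == pytest.approx(0.125)

    def test_monotone_decreasing_in_correct(self):
        ps = [ev.binomial_acc_test(c, 47, 34 / 47) for c in range(48)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestClopperPearson:
    def test_reconstructs_printed_interval(self):
        """54/94 correct (57.45%) gives the printed (46.82%, 67.60%) exact
        interval (upper bound printed from the 3-decimal proportion)."""
        lo, hi = ev.clopper_pearson(54, 94)
        assert lo * 100 == pytest.approx(46.82, abs=0.01)
        assert hi * 100 == pytest.approx(67.60, abs=0.01)

    def test_boundaries(self):
        assert ev.clopper_pearson(0, 10)[0] == 0.0
        assert ev.clopper_pearson(10, 10)[1] == 1.0

    def test_symmetric_at_half(self):
        lo, hi = ev.clopper_pearson(5, 10)
        assert lo == pytest.approx(1 - hi)

    @given(st.integers(1, 40), st.integers(2, 8))
    @settings(max_examples=30, deadline=None)
    def test_contains_point_estimate_and_shrinks_with_n(self, s, mult):
        n = 40
        lo, hi = ev.clopper_pearson(s, n)
        assert lo <= s / n <= hi
        lo2, hi2 = ev.clopper_pearson(s * mult, n * mult)
        assert hi2 - lo2 <= hi - lo + 1e-12


class TestClusterClassify:
    def test_separated_blobs_perfect(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.3, (10, 3)), rng.normal(5, 0.3, (8, 3))])
        m = make_matrix(X)
        sheet = make_sheet(["primary"] * 10 + ["control"] * 8)
        res = ev.cluster_classify(m, m.feature_ids, sheet, ev.MELANOMA_VS_CONTROL)
        assert res.accuracy == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert res.level == "subject"

    def test_label_mapping_is_optimal_over_both_assignments(self):
        """Flipping the class labels must leave accuracy unchanged."""
        rng = np.random.default_rng(1)
        X = rng.standard_normal((14, 4))
        m = make_matrix(X)
        a = ev.cluster_classify(m, m.feature_ids,
                                make_sheet(["primary"] * 8 + ["control"] * 6),
                                ev.MELANOMA_VS_CONTROL)
        b = ev.cluster_classify(m, m.feature_ids,
                                make_sheet(["control"] * 8 + ["primary"] * 6),
                                ev.MELANOMA_VS_CONTROL)
        assert a.accuracy == b.accuracy

    def test_matches_exhaustive_oracle_on_small_instance(self):
        """Confusion counts equal a naive re-derivation that clusters with
        scipy directly and tries both cluster->label maps by hand."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((12, 3))
        m = make_matrix(X)
        y = np.array([1] * 7 + [0] * 5)
        sheet = make_sheet(["primary"] * 7 + ["control"] * 5)
        res = ev.cluster_classify(m, m.feature_ids, sheet, ev.MELANOMA_VS_CONTROL)

        clusters = fcluster(linkage(X, method="complete"), 2, "maxclust")
        best = None
        for pos in (1, 2):
            pred = (clusters == pos).astype(int)
            acc = (pred == y).mean()
            if best is None or acc > best[0]:
                best = (acc, pred)
        acc, pred = best
        assert res.accuracy == pytest.approx(acc)
        assert res.tp == int(((pred == 1) & (y == 1)).sum())
        assert res.fn == int(((pred == 0) & (y == 1)).sum())
        assert res.tn + res.fp == 5

    def test_level_inferred_replicate(self, small_normalised):
        prot_n, _, sheet, _ = small_normalised
        res = ev.cluster_classify(prot_n, ["PRG4", "APOC4"], sheet,
                                  ev.MELANOMA_VS_CONTROL)
        assert res.level == "replicate"
        assert res.n == 98

    def test_missing_class_rejected(self):
        m = make_matrix(np.ones((4, 2)))
        sheet = make_sheet(["primary"] * 4)
        with pytest.raises(ValueError):
            ev.cluster_classify(m, m.feature_ids, sheet, ev.MELANOMA_VS_CONTROL)


class TestGridSearch:
    def _data(self, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((20, 4))
        X[:11, 0] += 4.0
        X[:11, 1] -= 4.0
        m = make_matrix(X, features=["a", "b", "c", "d"])
        sheet = make_sheet(["primary"] * 11 + ["control"] * 9)
        return m, sheet

    def test_single_candidate_returned(self):
        m, sheet = self._data()
        sig, res, board = ev.grid_search(m, ["a"], sheet, ev.MELANOMA_VS_CONTROL)
        assert sig.features == ["a"]
        assert len(board) == 1

    def test_enumerates_all_nonempty_subsets(self):
        m, sheet = self._data()
        _, _, board = ev.grid_search(m, ["a", "b", "c", "d"], sheet,
                                     ev.MELANOMA_VS_CONTROL)
        assert len(board) == 15

    def test_winner_matches_brute_force_oracle(self):
        m, sheet = self._data(seed=4)
        sig, res, _ = ev.grid_search(m, ["a", "b", "c", "d"], sheet,
                                     ev.MELANOMA_VS_CONTROL)
        best = None
        for size in (1, 2, 3, 4):
            for subset in itertools.combinations(sorted(["a", "b", "c", "d"]), size):
                e = ev.cluster_classify(m, list(subset), sheet, ev.MELANOMA_VS_CONTROL)
                key = (-e.accuracy, size, subset)
                if best is None or key < best[0]:
                    best = (key, subset)
        assert tuple(sig.features) == best[1]

    def test_winner_invariant_to_candidate_order(self):
        m, sheet = self._data(seed=5)
        sig_a, _, _ = ev.grid_search(m, ["a", "b", "c", "d"], sheet,
                                     ev.MELANOMA_VS_CONTROL)
        sig_b, _, _ = ev.grid_search(m, ["d", "c", "b", "a"], sheet,
                                     ev.MELANOMA_VS_CONTROL)
        assert sig_a.features == sig_b.features

    def test_too_many_candidates_rejected(self):
        m, sheet = self._data()
        with pytest.raises(ValueError, match="pre-filter"):
            ev.grid_search(m, [f"x{i}" for i in range(13)], sheet,
                           ev.MELANOMA_VS_CONTROL)


class TestClusteringAgreement:
    def test_identical_partitions(self):
        ari, nmi = ev.clustering_agreement([0, 0, 1, 1], [1, 1, 0, 0])
        assert ari == 1.0 and nmi == 1.0

    def test_singletons_vs_one_cluster(self):
        ari, _ = ev.clustering_agreement([0, 1, 2, 3], [0, 0, 0, 0])
        assert ari == 0.0

    def test_hand_computed_contingency(self):
        """6 elements, two 2-cluster partitions: ARI from the pair-counting
        formula computed by hand."""
        a = [0, 0, 0, 1, 1, 1]
        b = [0, 0, 1, 1, 1, 1]
        # contingency [[2,1],[0,3]]; sum C(nij,2)=1+3=4; row/col pair sums:
        # C(3,2)+C(3,2)=6, C(2,2)+C(4,2)=7; expected=6*7/C(6,2)=42/15
        expected = (4 - 42 / 15) / (0.5 * (6 + 7) - 42 / 15)
        ari, _ = ev.clustering_agreement(a, b)
        assert ari == pytest.approx(expected)


class TestPcaScores:
    def test_collinear_data_one_component(self):
        t = np.linspace(0, 1, 30)
        X = np.column_stack([2 * t, -3 * t])
        m = make_matrix(X)
        scores = ev.pca_scores(m, 2)
        var = scores.var(axis=0, ddof=1)
        assert var.iloc[0] / var.sum() > 0.999

    def test_score_covariance_diagonal_and_variance_conserved(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((25, 6))
        m = make_matrix(X)
        scores = ev.pca_scores(m, 6).to_numpy()
        cov = np.cov(scores, rowvar=False)
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-9
        total = np.var(X - X.mean(0), axis=0, ddof=1).sum()
        assert np.trace(cov) == pytest.approx(total)

    def test_components_ordered_by_variance(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((30, 5)) * np.array([5, 1, 3, 0.5, 2])
        scores = ev.pca_scores(make_matrix(X), 5)
        var = scores.var(axis=0).to_numpy()
        assert (np.diff(var) <= 1e-9).all()
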