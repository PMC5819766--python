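"""Diversity, co-expression and overall importance scores."""

import numpy as np
import pandas as pd
import pytest

from sentinelpanel import (
    FoldChangeMatrix,
    cluster_comparisons,
    cluster_genes,
    compute_cis,
    compute_dis,
    compute_eigengenes,
    compute_ois,
    compute_scores,
    fold_cis,
    partition_studies,
    select_top_n,
    within_cluster_dis,
)
from sentinelpanel.errors import (
    DegenerateInputError,
    InputError,
    ParameterError,
)


def _fcm_from_array(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    idx = [f"{prefix}{i:03d}" for i in range(arr.shape[0])]
    cols = [f"c{j:03d}" for j in range(arr.shape[1])]
    return FoldChangeMatrix(pd.DataFrame(arr, index=idx, columns=cols))


def _orthogonal_component_matrix(variances, n_comps=8, seed=0):
    """Build a matrix whose uncentered component variances are prescribed."""
    rng = np.random.default_rng(seed)
    n_genes = len(variances) + 2
    A = rng.normal(size=(n_genes, n_genes))
    Q, _ = np.linalg.qr(A)
    B = rng.normal(size=(n_comps, n_comps))
    P, _ = np.linalg.qr(B)
    s = np.sqrt(np.asarray(variances, dtype=float))
    X = Q[:, : len(s)] @ np.diag(s) @ P[: len(s), :]
    return _fcm_from_array(X)


class TestEigengenes:
    def test_g_minimal_for_var_fraction(self):
        # component variances 81, 18, 1 -> cumulative fractions .81, .99, 1
        fcm = _orthogonal_component_matrix([81.0, 18.0, 1.0])
        decomp = compute_eigengenes(fcm, var_fraction=0.9)
        assert decomp.G == 2

    def test_equal_variances_need_all_components(self):
        fcm = _orthogonal_component_matrix([10.0, 10.0, 10.0])
        assert compute_eigengenes(fcm, var_fraction=0.9).G == 3

    def test_rank_one_matrix_g_is_one(self):
        u = np.arange(1, 6, dtype=float)[:, None]
        v = np.array([[1.0, -2.0, 0.5]])
        decomp = compute_eigengenes(_fcm_from_array(u @ v), var_fraction=0.99)
        assert decomp.G == 1

    def test_loadings_orthonormal_and_eigenvalues_sorted(self):
        fcm = _orthogonal_component_matrix([50.0, 30.0, 15.0, 5.0])
        d = compute_eigengenes(fcm, var_fraction=0.999)
        gram = d.loadings.T @ d.loadings
        assert np.allclose(gram, np.eye(d.G), atol=1e-8)
        assert np.all(np.diff(d.eigenvalues) <= 1e-12)

    def test_zero_matrix_degenerate(self):
        with pytest.raises(DegenerateInputError):
            compute_eigengenes(_fcm_from_array(np.zeros((4, 4))))


class TestClusterComparisons:
    def test_separated_clouds_recovered(self):
        rng = np.random.default_rng(5)
        cloud1 = rng.normal(0.0, 0.5, size=(30, 10))
        cloud2 = rng.normal(20.0, 0.5, size=(30, 10))
        X = np.vstack([cloud1, cloud2]).T  # genes x comparisons
        fcm = _fcm_from_array(X)
        decomp = compute_eigengenes(fcm, var_fraction=0.95)
        labels = cluster_comparisons(decomp, k=2, seed=1)
        first, second = labels[:30], labels[30:]
        assert len(set(first)) == 1 and len(set(second)) == 1
        assert first[0] != second[0]

    def test_k_equals_n_comparisons(self):
        fcm = _orthogonal_component_matrix([9.0, 4.0, 1.0], n_comps=5)
        decomp = compute_eigengenes(fcm, var_fraction=0.99)
        labels = cluster_comparisons(decomp, k=5, seed=0)
        assert len(set(labels)) == 5

    def test_deterministic_given_seed(self):
        fcm = _orthogonal_component_matrix([9.0, 4.0, 1.0], n_comps=12)
        decomp = compute_eigengenes(fcm, var_fraction=0.99)
        a = cluster_comparisons(decomp, k=3, seed=42)
        b = cluster_comparisons(decomp, k=3, seed=42)
        assert np.array_equal(a, b)

    def test_too_few_comparisons_raises(self):
        fcm = _orthogonal_component_matrix([9.0, 4.0], n_comps=4)
        decomp = compute_eigengenes(fcm, var_fraction=0.99)
        with pytest.raises(ParameterError):
            cluster_comparisons(decomp, k=5, seed=0)


class TestWithinClusterDis:
    def test_conservation_sums_to_min_g_rank(self):
        fcm = _orthogonal_component_matrix([30.0, 20.0, 10.0, 5.0], n_comps=6)
        for G in (1, 2, 3):
            s = within_cluster_dis(fcm, G)
            assert s.sum() == pytest.approx(G, abs=1e-8)

    def test_truncates_to_available_rank(self):
        u = np.arange(1, 7, dtype=float)[:, None]
        v = np.ones((1, 4))
        s = within_cluster_dis(_fcm_from_array(u @ v), G=3)
        assert s.sum() == pytest.approx(1.0, abs=1e-8)  # rank 1 < G

    def test_dominant_gene_loads_fully(self):
        X = np.zeros((4, 5))
        X[0] = [3.0, -1.0, 2.0, 0.5, -2.0]
        X[1:] = 1e-9
        s = within_cluster_dis(_fcm_from_array(X), G=1)
        assert s.iloc[0] == pytest.approx(1.0, abs=1e-6)


class TestDis:
    def test_single_cluster_equals_within_scores(self):
        fcm = _orthogonal_component_matrix([30.0, 10.0, 2.0], n_comps=8)
        dis = compute_dis(fcm, k=1, var_fraction=0.9, seed=0)
        decomp = compute_eigengenes(fcm, var_fraction=0.9)
        expected = within_cluster_dis(fcm, decomp.G)
        assert np.allclose(dis.to_numpy(), expected.to_numpy(), atol=1e-9)

    def test_planted_dominant_gene_ranks_first(self):
        rng = np.random.default_rng(7)
        n_genes, n_comps = 40, 36
        X = rng.normal(0.0, 0.05, size=(n_genes, n_comps))
        X[0] += rng.normal(0, 1, n_comps) * 5.0  # dominates component 1
        fcm = _fcm_from_array(X)
        dis = compute_dis(fcm, k=3, var_fraction=0.9, seed=0)
        assert dis.idxmax() == "g000"

    def test_scale_invariance(self):
        fcm = _orthogonal_component_matrix([30.0, 10.0, 2.0], n_comps=8)
        scaled = FoldChangeMatrix(fcm.values * 7.0, fcm.study_ids)
        a = compute_dis(fcm, k=2, seed=3)
        b = compute_dis(scaled, k=2, seed=3)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


class TestPartitionStudies:
    def _studies(self, n_studies, per_study=2):
        return pd.Series(
            [f"s{i}" for i in range(n_studies) for _ in range(per_study)])

    def test_exact_split(self):
        folds = partition_studies(self._studies(40), n_folds=20, seed=0)
        sizes = folds.groupby(folds).size()
        assert (sizes == 4).all()  # 2 studies x 2 comparisons each

    def test_remainder_spread(self):
        studies = self._studies(41, per_study=1)
        folds = partition_studies(studies, n_folds=20, seed=1)
        counts = folds.groupby(folds).size().to_numpy()
        assert sorted(counts)[-1] == 3 and sorted(counts)[0] == 2
        assert (np.array(sorted(counts)) == sorted([2] * 19 + [3])).all()

    def test_studies_never_straddle_folds(self):
        studies = self._studies(10, per_study=3)
        folds = partition_studies(studies, n_folds=5, seed=2)
        df = pd.DataFrame({"study": studies.to_numpy(),
                           "fold": folds.to_numpy()})
        assert (df.groupby("study")["fold"].nunique() == 1).all()

    def test_deterministic(self):
        studies = self._studies(12)
        a = partition_studies(studies, n_folds=4, seed=9)
        b = partition_studies(studies, n_folds=4, seed=9)
        assert a.equals(b)

    def test_too_few_studies_raises(self):
        with pytest.raises(ParameterError):
            partition_studies(self._studies(3), n_folds=4, seed=0)


class TestClusterGenes:
    def test_proportional_and_antiproportional_merge(self):
        base = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.vstack([base, 2 * base, -base])
        clustering = cluster_genes(_fcm_from_array(X), h=0.5)
        assert clustering.labels.nunique() == 1

    def test_independent_noise_all_singletons(self):
        # with m=4000 comparisons all pairwise |r| < ~0.06, so every
        # 1-|r| distance exceeds the h=0.9 cut
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 4000))
        clustering = cluster_genes(_fcm_from_array(X), h=0.9)
        assert clustering.labels.nunique() == 20

    def test_constant_gene_is_singleton(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0],
                      [2.0, 4.0, 6.0, 8.0],
                      [5.0, 5.0, 5.0, 5.0]])
        clustering = cluster_genes(_fcm_from_array(X), h=0.9)
        labels = clustering.labels
        assert labels.iloc[0] == labels.iloc[1]
        assert (labels == labels.iloc[2]).sum() == 1

    def test_fold_too_small_raises(self):
        with pytest.raises(ParameterError):
            cluster_genes(_fcm_from_array(np.ones((3, 2))), h=0.9)


class TestFoldCis:
    def test_singleton_gene_scores_zero(self):
        X = np.array([[1.0, 2.0, 3.0, 4.0], [0.0, 5.0, -1.0, 2.0],
                      [3.0, 3.0, 3.0, 3.0]])
        fcm = _fcm_from_array(X)
        clustering = cluster_genes(fcm, h=0.9)
        cis = fold_cis(fcm, clustering)
        assert cis.iloc[2] == 0.0

    def test_perfectly_correlated_pair_scores_one(self):
        base = np.array([1.0, -2.0, 0.5, 3.0])
        fcm = _fcm_from_array(np.vstack([base, 3 * base]))
        clustering = cluster_genes(fcm, h=0.5)
        cis = fold_cis(fcm, clustering)
        assert np.allclose(cis.to_numpy(), 1.0, atol=1e-12)

    def test_three_gene_cluster_hand_value(self):
        """Cluster mate correlations r=0.8 and r=0.6 give CIS=(0.64+0.36)/2."""
        from sentinelpanel.scoring import GeneClustering

        rng = np.random.default_rng(0)
        # construct three unit-variance series with prescribed correlations:
        # B = 0.8A + sqrt(1-.64) e1 ; C chosen with corr(A,C)=0.6
        n = 2000
        a = rng.standard_normal(n)
        e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
        b = 0.8 * a + np.sqrt(1 - 0.64) * e1
        c = 0.6 * a + np.sqrt(1 - 0.36) * e2
        fcm = _fcm_from_array(np.vstack([a, b, c]))
        clustering = GeneClustering(pd.Series([1, 1, 1], index=fcm.gene_ids))
        cis = fold_cis(fcm, clustering)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        assert cis.iloc[0] == pytest.approx((r_ab**2 + r_ac**2) / 2, abs=1e-12)
        assert cis.iloc[1] == pytest.approx((r_ab**2 + r_bc**2) / 2, abs=1e-12)


class TestCis:
    def test_bounds_and_determinism(self, small_corpus):
        _, fcm, _, _ = small_corpus
        a = compute_cis(fcm, n_folds=4, h=0.9, seed=5)
        b = compute_cis(fcm, n_folds=4, h=0.9, seed=5)
        assert a.between(0.0, 1.0).all()
        assert np.array_equal(a.to_numpy(), b.to_numpy())

    def test_module_genes_outrank_noise(self, small_corpus):
        _, fcm, truth, _ = small_corpus
        cis = compute_cis(fcm, n_folds=4, h=0.9, seed=1)
        module = truth.all_module_genes
        noise = [g for g in fcm.gene_ids if g not in set(module)]
        assert cis[module].median() > cis[noise].median()

    def test_scale_invariance(self, small_corpus):
        _, fcm, _, _ = small_corpus
        scaled = FoldChangeMatrix(fcm.values * 3.5, fcm.study_ids)
        a = compute_cis(fcm, n_folds=4, seed=2)
        b = compute_cis(scaled, n_folds=4, seed=2)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)


class TestOis:
    def test_formula_hand_values(self):
        dis = pd.Series({"a": 0.1, "b": 0.2, "c": 0.3, "d": 0.4, "e": 0.5})
        cis = pd.Series({"a": 0.5, "b": 0.1, "c": 0.3, "d": 0.4, "e": 0.9})
        scores = compute_ois(dis, cis)
        tab = scores.table
        # gene e: rank_DIS=5, rank_CIS=5 -> sqrt((25+25)/2)/5 = 1
        assert tab.loc["e", "OIS"] == pytest.approx(1.0)
        # gene a: rank_DIS=1, rank_CIS=4 -> sqrt((1+16)/2)/5
        assert tab.loc["a", "OIS"] == pytest.approx(np.sqrt(8.5) / 5)
        # gene d: rank_DIS=4, rank_CIS=3 -> sqrt((16+9)/2)/5 ~ 0.70711
        cis2 = pd.Series({"a": 0.5, "b": 0.1, "c": 0.2, "d": 0.4, "e": 0.9})
        tab2 = compute_ois(dis, cis2).table
        assert tab2.loc["d", "rank_DIS"] == 4
        assert tab2.loc["d", "rank_CIS"] == 3
        assert tab2.loc["d", "OIS"] == pytest.approx(0.70711, abs=1e-5)

    def test_ranks_are_permutation_with_ties_by_gene_id(self):
        dis = pd.Series({"b": 1.0, "a": 1.0, "c": 0.5})
        cis = pd.Series({"b": 0.2, "a": 0.2, "c": 0.2})
        tab = compute_ois(dis, cis).table
        assert sorted(tab["rank_DIS"]) == [1, 2, 3]
        assert sorted(tab["rank_CIS"]) == [1, 2, 3]
        # tie between a and b resolved by ascending id: a before b
        assert tab.loc["a", "rank_DIS"] < tab.loc["b", "rank_DIS"]

    def test_ois_strictly_increasing_in_each_rank(self):
        n = 10
        for rc in range(1, n):
            for rd in range(1, n + 1):
                low = np.sqrt((rc**2 + rd**2) / 2) / n
                high = np.sqrt(((rc + 1) ** 2 + rd**2) / 2) / n
                assert high > low

    def test_min_rank_gene(self):
        dis = pd.Series({chr(97 + i): float(i) for i in range(5)})
        tab = compute_ois(dis, dis).table
        assert tab.loc["a", "OIS"] == pytest.approx(0.2)  # sqrt(1)/5

    def test_mismatched_universes_raise(self):
        with pytest.raises(InputError):
            compute_ois(pd.Series({"a": 1.0}), pd.Series({"b": 1.0}))


class TestSelectTopN:
    def test_selects_all_when_n_equals_universe(self):
        from conftest import make_scores

        scores = make_scores({"a": 0.9, "b": 0.5, "c": 0.1})
        assert set(select_top_n(scores, 3).genes) == {"a", "b", "c"}

    def test_top_two(self):
        from conftest import make_scores

        scores = make_scores({"a": 0.9, "b": 0.5, "c": 0.1})
        assert select_top_n(scores, 2).genes == ["a", "b"]

    def test_tie_at_cut_prefers_smaller_id(self):
        from conftest import make_scores

        scores = make_scores({"z": 0.5, "y": 0.5, "a": 0.9})
        sel = select_top_n(scores, 2)
        assert sel.genes == ["a", "y"]

    def test_n_too_large_raises(self):
        from conftest import make_scores

        with pytest.raises(ParameterError):
            select_top_n(make_scores({"a": 1.0}), 2)


def test_full_scoring_deterministic(small_corpus):
    _, fcm, _, _ = small_corpus
    a = compute_scores(fcm, k=4, n_folds=4, seed=17)
    b = compute_scores(fcm, k=4, n_folds=4, seed=17)
    pd.testing.assert_frame_equal(a.table, b.table)
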