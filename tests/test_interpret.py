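"""Tests for contribution ranking, patient scores, clustering, association
and gene targeting scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from porcupine import (
    CovariateTable,
    HeterogeneityScores,
    PathwayPCA,
    SubtypeKMeans,
    associate_covariates,
    cluster_subtypes,
    edge_contributions,
    gene_contribution_summary,
    gene_targeting_scores,
    patient_scores,
    zscale_edges,
)


def _unit(v):
    v = np.asarray(v, dtype=float)
    return v / np.linalg.norm(v)


class TestEdgeContributions:
    def test_equal_loadings_have_no_top_edges(self):
        ids = [("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B")]
        prof = edge_contributions(np.full(4, 0.5), ids)
        assert prof.expected_score == pytest.approx(0.5)
        assert not prof.top_edges.any()
        assert prof.tf_target_counts == {}
        assert prof.tf_labels == []

    def test_dominant_edge_flagged(self):
        ids = [("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B")]
        loadings = np.sqrt([0.97, 0.01, 0.01, 0.01])
        prof = edge_contributions(loadings, ids)
        # expected 0.5; only |0.985| > 0.75
        np.testing.assert_array_equal(prof.top_edges, [True, False, False, False])
        assert prof.tf_target_counts == {"T1": 1}

    def test_negative_loading_counts_by_magnitude(self):
        ids = [("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B")]
        loadings = -np.sqrt([0.97, 0.01, 0.01, 0.01])
        loadings[1:] *= -1
        prof = edge_contributions(_unit(loadings), ids)
        assert prof.top_edges[0]

    def test_hand_enumerated_toy_3tfs_4genes(self):
        tfs = ["T1", "T2", "T3"]
        genes = ["A", "B", "C", "D"]
        ids = [(t, g) for g in genes for t in tfs]
        raw = np.array([4, 0.5, 0.5,   # A: T1 top
                        4, 4, 0.5,     # B: T1, T2 top
                        0.5, 0.5, 0.5, # C: none
                        4, 0.5, 0.5])  # D: T1 top
        loadings = _unit(raw)
        prof = edge_contributions(loadings, ids)
        # by hand: E_p=12, expected=1/sqrt(12)=0.2887; threshold 0.4330
        # normalized: 4/|raw| = 0.566 > 0.433; 0.5/|raw| = 0.0707 < 0.433
        assert prof.tf_target_counts == {"T1": 3, "T2": 1}
        # 95th percentile of (3, 1) = 2.9; only T1 exceeds it
        assert prof.tf_labels == ["T1"]

    def test_sum_of_tf_counts_equals_top_edges(self):
        rng = np.random.default_rng(2)
        ids = [(f"T{i%5}", f"G{i//5}") for i in range(40)]
        loadings = _unit(rng.normal(size=40))
        prof = edge_contributions(loadings, ids)
        assert sum(prof.tf_target_counts.values()) == int(prof.top_edges.sum())
        assert prof.expected_score**2 * 40 == pytest.approx(1.0, abs=1e-12)

    def test_non_unit_norm_rejected(self):
        with pytest.raises(ValueError, match="unit-norm"):
            edge_contributions(np.array([1.0, 1.0]), [("T", "A"), ("T", "B")])


class TestGeneContributionSummary:
    def test_hand_aggregation(self):
        tfs = ["T1", "T2", "T3"]
        genes = ["A", "B", "C", "D"]
        ids = [(t, g) for g in genes for t in tfs]
        raw = np.array([4, 3.5, 0.5, 4, 0.5, 0.5, 0.5, 0.5, 0.5, 4, 0.5, 0.5])
        prof = edge_contributions(_unit(raw), ids)
        table = gene_contribution_summary(prof)
        assert table["gene"].tolist() == ["A", "B", "D"]
        assert table["n_top_edges"].tolist() == [2, 1, 1]
        # B and D tie on count; B's max |loading| equals D's, so name breaks it
        assert table.iloc[0]["max_abs_loading"] == pytest.approx(
            4 / np.linalg.norm(raw)
        )

    def test_no_top_edges_gives_empty_table(self):
        ids = [("T1", "A"), ("T1", "B"), ("T2", "A"), ("T2", "B")]
        table = gene_contribution_summary(edge_contributions(np.full(4, 0.5), ids))
        assert table.empty


class TestPatientScores:
    def test_scores_match_eigendecomposition_projection(self):
        rng = np.random.default_rng(13)
        X, _ = zscale_edges(rng.normal(size=(5, 8)))
        hs = patient_scores(X, [f"s{i}" for i in range(8)], n_components=2)
        Xc = X - X.mean(axis=1, keepdims=True)
        eigvals, eigvecs = np.linalg.eigh(Xc @ Xc.T)
        for got, vec in [(hs.pc1_scores, eigvecs[:, -1]), (hs.pc2_scores, eigvecs[:, -2])]:
            if vec[np.argmax(np.abs(vec))] < 0:
                vec = -vec
            np.testing.assert_allclose(got, Xc.T @ vec, atol=1e-10)

    def test_pc1_mean_zero_and_pc_orthogonality(self):
        rng = np.random.default_rng(14)
        X, _ = zscale_edges(rng.normal(size=(10, 12)))
        hs = patient_scores(X, [f"s{i}" for i in range(12)], n_components=2)
        assert abs(hs.pc1_scores.mean()) < 1e-8
        assert abs(hs.pc1_scores @ hs.pc2_scores) < 1e-8

    def test_rank_one_data_rejects_pc2(self):
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        X = np.column_stack([t * direction for t in (-1.0, 0.0, 1.0)])
        with pytest.raises(ValueError, match="rank"):
            patient_scores(X, ["a", "b", "c"], n_components=2)

    def test_collinear_samples_recover_1d_geometry(self):
        direction = np.array([1.0, -2.0, 0.5, 3.0])
        ts = np.array([-2.0, 1.0, 1.0])
        X = np.column_stack([t * direction for t in ts])
        hs = patient_scores(X, ["a", "b", "c"], n_components=1)
        centered = ts - ts.mean()
        ratio = hs.pc1_scores / centered
        np.testing.assert_allclose(ratio, ratio[0], atol=1e-10)

    def test_sign_convention_ties_scores_to_loadings(self, planted_cohort):
        matrix, collection, _, truth = planted_cohort
        pathway = truth["planted_pathway"]
        pca = PathwayPCA(genes=collection[pathway], n_components=1).fit(matrix)
        j = np.argmax(np.abs(pca.loadings_[:, 0]))
        assert pca.loadings_[j, 0] > 0


class TestClusterSubtypes:
    def _blobs(self):
        rng = np.random.default_rng(15)
        pc1 = np.concatenate([rng.normal(-8, 0.3, 12), rng.normal(8, 0.3, 12)])
        pc2 = rng.normal(0, 0.3, 24)
        return HeterogeneityScores(
            pathway="P", samples=[f"s{i}" for i in range(24)],
            pc1_scores=pc1, pc2_scores=pc2,
        )

    def test_two_separated_blobs_choose_k2(self):
        scores = self._blobs()
        labels, k, sil = cluster_subtypes(scores, k_range=range(2, 6), random_state=0)
        assert k == 2
        first_half, second_half = set(labels[:12]), set(labels[12:])
        assert len(first_half) == 1 and len(second_half) == 1
        assert first_half != second_half
        assert sil[2] == max(sil.values())

    def test_seed_determinism(self):
        scores = self._blobs()
        l1, k1, _ = cluster_subtypes(scores, random_state=3)
        l2, k2, _ = cluster_subtypes(scores, random_state=3)
        assert k1 == k2
        np.testing.assert_array_equal(l1, l2)

    def test_label_invariance_under_sample_permutation(self):
        scores = self._blobs()
        labels, _, _ = cluster_subtypes(scores, random_state=0)
        rng = np.random.default_rng(16)
        perm = rng.permutation(len(scores.samples))
        permuted = HeterogeneityScores(
            pathway="P",
            samples=[scores.samples[i] for i in perm],
            pc1_scores=scores.pc1_scores[perm],
            pc2_scores=scores.pc2_scores[perm],
        )
        plabels, _, _ = cluster_subtypes(permuted, random_state=0)
        # same partition up to relabeling
        pairs = {(a, b) for a, b in zip(labels[perm], plabels)}
        assert len(pairs) == len(set(labels))

    def test_hand_computed_silhouette_four_points(self):
        # 2 clusters: {0, 1} at x=0,1 and {2, 3} at x=10,11
        X = np.array([[0.0], [1.0], [10.0], [11.0]])
        model = SubtypeKMeans(k_range=[2], random_state=0).fit(X)
        # outer points (0, 11): a=1, b=(10+11)/2=10.5 -> s=1-1/10.5
        # inner points (1, 10): a=1, b=(9+10)/2=9.5  -> s=1-1/9.5
        expected = ((1 - 1 / 10.5) + (1 - 1 / 9.5)) / 2
        assert model.silhouettes_[2] == pytest.approx(expected, abs=1e-12)

    def test_degenerate_identical_scores_rejected(self):
        scores = HeterogeneityScores(
            pathway="P", samples=["a", "b", "c", "d"],
            pc1_scores=np.zeros(4), pc2_scores=np.zeros(4),
        )
        with pytest.raises(ValueError, match="degenerate"):
            cluster_subtypes(scores, k_range=[2])


class TestAssociateCovariates:
    def _scores(self, values):
        return HeterogeneityScores(
            pathway="P", samples=[f"s{i}" for i in range(len(values))],
            pc1_scores=np.asarray(values, dtype=float),
        )

    def _covars(self, n, **cols):
        kinds = {}
        data = {}
        for name, (kind, values) in cols.items():
            kinds[name] = kind
            data[name] = values
        return CovariateTable(
            data=pd.DataFrame(data, index=pd.Index([f"s{i}" for i in range(n)], name="sample")),
            kinds=kinds,
        )

    def test_identical_groups_give_zero_statistic(self):
        scores = self._scores([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        covars = self._covars(6, group=("categorical", ["a"] * 3 + ["b"] * 3))
        # identical score distribution in the two groups -> KW statistic ~ 0
        res = associate_covariates(scores, covars)
        assert res[0].test == "kruskal_wallis"
        assert res[0].statistic == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_value > 0.9

    def test_numerical_equal_to_scores_gives_r_one(self):
        scores = self._scores([0.5, -1.0, 2.0, 0.1, -0.6])
        covars = self._covars(5, readout=("numerical", scores.pc1_scores.tolist()))
        res = associate_covariates(scores, covars)
        assert res[0].test == "pearson"
        assert res[0].statistic == pytest.approx(1.0)

    def test_kruskal_matches_hand_rank_formula(self):
        scores = self._scores([1.0, 3.0, 5.0, 2.0, 4.0, 6.0])
        groups = ["a", "a", "a", "b", "b", "b"]
        covars = self._covars(6, group=("categorical", groups))
        res = associate_covariates(scores, covars)
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2; ranks 1..6
        ranks = {1.0: 1, 2.0: 2, 3.0: 3, 4.0: 4, 5.0: 5, 6.0: 6}
        r_a = np.mean([ranks[v] for v in [1.0, 3.0, 5.0]])
        r_b = np.mean([ranks[v] for v in [2.0, 4.0, 6.0]])
        H = 12 / (6 * 7) * (3 * (r_a - 3.5) ** 2 + 3 * (r_b - 3.5) ** 2)
        assert res[0].statistic == pytest.approx(H, abs=1e-12)

    def test_constant_covariate_skipped_and_excluded_from_bh(self):
        scores = self._scores([1.0, 2.0, 3.0, 4.0])
        covars = self._covars(
            4,
            flat=("categorical", ["x"] * 4),
            readout=("numerical", [0.9, 2.1, 3.2, 3.9]),
        )
        skip: list = []
        res = associate_covariates(scores, covars, skip_log=skip)
        assert [r.covariate for r in res] == ["readout"]
        assert ("flat", "constant after intersection") in skip
        # BH family of size 1: adjusted equals raw
        assert res[0].p_adjusted == pytest.approx(res[0].p_value)

    def test_intersection_of_samples_used(self):
        scores = self._scores([1.0, 2.0, 3.0, 4.0, 5.0])
        covars = CovariateTable(
            data=pd.DataFrame(
                {"readout": [10.0, 20.0, 30.0, -1.0]},
                index=pd.Index(["s0", "s1", "s2", "sZ"], name="sample"),
            ),
            kinds={"readout": "numerical"},
        )
        res = associate_covariates(scores, covars)
        r, _ = sps.pearsonr([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert res[0].statistic == pytest.approx(r)

    def test_too_few_shared_samples_rejected(self):
        scores = self._scores([1.0, 2.0, 3.0])
        covars = CovariateTable(
            data=pd.DataFrame({"x": [1.0]}, index=pd.Index(["s0"], name="sample")),
            kinds={"x": "numerical"},
        )
        with pytest.raises(ValueError, match="fewer than 3"):
            associate_covariates(scores, covars)

    def test_linked_covariate_detected_on_planted_cohort(self, planted_cohort):
        matrix, collection, covars, truth = planted_cohort
        pathway = truth["planted_pathway"]
        pca = PathwayPCA(genes=collection[pathway], n_components=1, pathway=pathway).fit(matrix)
        res = associate_covariates(pca.heterogeneity_scores(), covars)
        by_name = {r.covariate: r for r in res}
        # the numerical covariate was generated at |link| = 0.8 with u
        assert by_name["readout"].p_adjusted < 0.05
        assert by_name["readout"].significant


class TestGeneTargetingScores:
    def test_sum_by_definition(self, tiny_matrix):
        table = gene_targeting_scores(tiny_matrix)
        rows = [i for i, g in enumerate(tiny_matrix.genes) if g == "g2"]
        np.testing.assert_allclose(
            table.loc["g2"].to_numpy(), tiny_matrix.weights[rows].sum(axis=0)
        )

    def test_brute_force_oracle(self, tiny_matrix):
        table = gene_targeting_scores(tiny_matrix)
        for g in set(tiny_matrix.genes):
            for j, s in enumerate(tiny_matrix.samples):
                expected = sum(
                    tiny_matrix.weights[i, j]
                    for i in range(tiny_matrix.n_edges)
                    if tiny_matrix.genes[i] == g
                )
                assert table.loc[g, s] == pytest.approx(expected, abs=1e-12)

    def test_linearity(self, tiny_matrix):
        from porcupine import EdgeMatrix

        rng = np.random.default_rng(17)
        other = EdgeMatrix(
            tfs=tiny_matrix.tfs, genes=tiny_matrix.genes,
            samples=tiny_matrix.samples,
            weights=rng.normal(size=tiny_matrix.weights.shape),
        )
        combined = EdgeMatrix(
            tfs=tiny_matrix.tfs, genes=tiny_matrix.genes,
            samples=tiny_matrix.samples,
            weights=tiny_matrix.weights + other.weights,
        )
        lhs = gene_targeting_scores(combined)
        rhs = gene_targeting_scores(tiny_matrix) + gene_targeting_scores(other)
        pd.testing.assert_frame_equal(lhs, rhs)


class TestSignFlipInvariance:
    def test_top_edges_invariant_under_global_sign_flip(self):
        rng = np.random.default_rng(18)
        ids = [(f"T{i%4}", f"G{i//4}") for i in range(24)]
        loadings = _unit(rng.normal(size=24))
        a = edge_contributions(loadings, ids)
        b = edge_contributions(-loadings, ids)
        np.testing.assert_array_equal(a.top_edges, b.top_edges)
        assert a.tf_target_counts == b.tf_target_counts
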