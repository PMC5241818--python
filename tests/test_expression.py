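import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from dropcount.expression import (
    ReferenceProfileSet,
    classify_by_reference,
    cluster_marker_genes,
    compare_profiles,
    normalize,
    reduce_and_cluster,
    select_variable_genes,
)
from dropcount.synthetic_data import simulate_expression_clusters


class TestNormalize:
    def test_scale_factors_hand_arithmetic(self, matrix_factory):
        # cell totals 100 and 300 -> median 200 -> factors 2.0 and 2/3
        m = matrix_factory([[60, 200], [40, 100]])
        norm = normalize(m)
        np.testing.assert_allclose(norm.scale_factors, [2.0, 2 / 3])
        # check one entry of the log layer: ln(1 + 60 * 2.0)
        i = norm.lognorm_genes.index("G0")
        assert norm.lognorm[i, 0] == pytest.approx(np.log1p(120.0))

    def test_constant_gene_dropped_as_zero_variance(self, matrix_factory):
        # equal cell totals, so G0 stays constant after scaling
        m = matrix_factory([[5, 5], [1, 9], [8, 0]])
        norm = normalize(m)
        assert "G0" in norm.dropped_zero_variance
        assert norm.genes == ["G1", "G2"]

    def test_standardized_genes_have_zero_mean_unit_sd(self, matrix_factory):
        rng = np.random.default_rng(0)
        m = matrix_factory(rng.integers(0, 30, size=(40, 25)))
        norm = normalize(m)
        np.testing.assert_allclose(norm.standardized.mean(axis=1), 0, atol=1e-8)
        np.testing.assert_allclose(norm.standardized.std(axis=1), 1, atol=1e-8)

    def test_column_permutation_equivariance(self, matrix_factory):
        rng = np.random.default_rng(1)
        counts = rng.integers(0, 20, size=(15, 12))
        perm = rng.permutation(12)
        m1 = normalize(matrix_factory(counts))
        m2 = normalize(
            matrix_factory(counts[:, perm], barcodes=[f"BC{j}" for j in perm])
        )
        np.testing.assert_allclose(m1.standardized[:, perm], m2.standardized, atol=1e-12)

    def test_zero_total_cell_dropped(self, matrix_factory):
        m = matrix_factory([[3, 0, 5], [2, 0, 7]])
        norm = normalize(m)
        assert norm.dropped_cells == ["BC1"]
        assert len(norm.cells) == 2


class TestSelectVariableGenes:
    def test_planted_high_dispersion_genes_rank_top(self):
        # planted genes keep the background mean (so they spread across
        # bins) but carry an all-or-nothing expression pattern with a
        # far higher variance/mean ratio than their Poisson neighbours
        rng = np.random.default_rng(7)
        n_genes, n_cells = 200, 150
        counts = rng.poisson(5.0, size=(n_genes, n_cells))
        planted = rng.choice(n_genes, 10, replace=False)
        for g in planted:
            on = rng.random(n_cells) < 0.5
            counts[g] = np.where(on, 10, 0)
        genes = [f"G{i:03d}" for i in range(n_genes)]
        from conftest import make_matrix

        top = select_variable_genes(make_matrix(counts, genes=genes), n_top=20)
        assert {genes[i] for i in planted} <= set(top)

    def test_two_genes_per_bin_all_tied(self):
        # 40 genes in 20 bins put exactly 2 genes in each bin; the MAD
        # then equals each gene's deviation, so every normalised
        # dispersion is 1 and selection falls to the gene-ID tie-break.
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(40, 30))
        genes = [f"G{i:02d}" for i in range(40)]
        from conftest import make_matrix

        top = select_variable_genes(make_matrix(counts, genes=genes), n_top=40)
        assert sorted(top) == genes

    def test_small_case_matches_independent_computation(self):
        # 60 genes in 20 bins (3 per bin, so the per-bin median and MAD
        # are non-degenerate); verify against a direct reimplementation
        # of the binned normalised dispersion.
        rng = np.random.default_rng(3)
        counts = rng.integers(1, 50, size=(60, 30))
        genes = [f"G{i:02d}" for i in range(60)]
        from conftest import make_matrix

        m = make_matrix(counts, genes=genes)
        totals = counts.sum(axis=0).astype(float)
        scaled = counts.astype(float) * (np.median(totals) / totals)[None, :]
        mean, var = scaled.mean(axis=1), scaled.var(axis=1)
        disp = var / mean
        order = np.lexsort((genes, mean))
        expected_nd = np.empty(60)
        for b in range(20):
            idx = order[3 * b : 3 * b + 3]
            med = np.median(disp[idx])
            mad = max(np.median(np.abs(disp[idx] - med)), 1e-12)
            expected_nd[idx] = np.abs(disp[idx] - med) / mad
        expected = sorted(range(60), key=lambda i: (-expected_nd[i], genes[i]))
        assert select_variable_genes(m, n_top=10) == [genes[i] for i in expected[:10]]

    def test_invariant_to_gene_order(self):
        rng = np.random.default_rng(5)
        counts = rng.poisson(4.0, size=(60, 40)) + 1
        genes = [f"G{i:02d}" for i in range(60)]
        from conftest import make_matrix

        top1 = select_variable_genes(make_matrix(counts, genes=genes), n_top=15)
        perm = rng.permutation(60)
        top2 = select_variable_genes(
            make_matrix(counts[perm], genes=[genes[i] for i in perm]), n_top=15
        )
        assert top1 == top2


class TestReduceAndCluster:
    def test_two_blobs_ari_one(self):
        matrix, truth = simulate_expression_clusters(
            n_clusters=2, cells_per_cluster=60, seed=9
        )
        norm = normalize(matrix)
        res = reduce_and_cluster(norm, k=2, n_pcs=10, seed=0)
        assert adjusted_rand_score(truth.labels, res.labels) == 1.0

    def test_k1_sse_equals_total_variance(self):
        matrix, _ = simulate_expression_clusters(2, 30, seed=2)
        norm = normalize(matrix)
        res = reduce_and_cluster(norm, k=1, n_pcs=5, seed=0)
        centered = res.projections - res.projections.mean(axis=0)
        assert res.sse_by_k[1] == pytest.approx(np.sum(centered**2), rel=1e-6)

    def test_same_seed_identical_labels(self):
        matrix, _ = simulate_expression_clusters(3, 40, seed=4)
        norm = normalize(matrix)
        r1 = reduce_and_cluster(norm, k=3, seed=11)
        r2 = reduce_and_cluster(norm, k=3, seed=11)
        np.testing.assert_array_equal(r1.labels, r2.labels)

    def test_sse_non_increasing_in_k(self):
        matrix, _ = simulate_expression_clusters(3, 40, seed=6)
        norm = normalize(matrix)
        res = reduce_and_cluster(norm, k=2, seed=0, k_range=[1, 2, 3, 4])
        sses = [res.sse_by_k[k] for k in sorted(res.sse_by_k)]
        assert all(a >= b - 1e-9 for a, b in zip(sses, sses[1:]))

    def test_k_above_cells_rejected(self):
        matrix, _ = simulate_expression_clusters(1, 5, seed=0)
        with pytest.raises(ValueError, match="exceeds"):
            reduce_and_cluster(normalize(matrix), k=10, seed=0)


class TestClusterMarkers:
    def test_planted_markers_recovered_exactly(self):
        matrix, truth = simulate_expression_clusters(
            n_clusters=3, cells_per_cluster=50, markers_per_cluster=5, seed=13
        )
        norm = normalize(matrix)
        markers, dendro = cluster_marker_genes(norm, truth.labels, top_n=5)
        for c, planted in truth.markers.items():
            found = {g for g, _ in markers[c]}
            assert found == set(planted)
        assert dendro is not None and dendro.shape == (2, 4)

    def test_identical_clusters_score_zero(self, matrix_factory):
        counts = np.tile([[4], [7], [2]], (1, 20))
        m = matrix_factory(counts)
        norm = normalize(m)
        labels = [1] * 10 + [2] * 10
        markers, _ = cluster_marker_genes(norm, labels, top_n=3)
        for ranked in markers.values():
            assert all(score == pytest.approx(0.0) for _, score in ranked)

    def test_single_cluster_rejected(self, matrix_factory):
        m = matrix_factory(np.ones((3, 4), dtype=int) + np.eye(3, 4, dtype=int))
        with pytest.raises(ValueError, match=">= 2 clusters"):
            cluster_marker_genes(normalize(m), [1, 1, 1, 1])


def _reference_set():
    genes = [f"G{i}" for i in range(30)]
    rng = np.random.default_rng(17)
    helper = rng.lognormal(1, 1, 30)
    naive = helper.copy()
    naive[:3] = naive[:3] * 3  # subset population, close to helper
    nk = rng.lognormal(1, 1, 30)
    b = rng.lognormal(1, 1, 30)
    profiles = pd.DataFrame(
        {"CD4_helper": helper, "CD4_naive": naive, "NK": nk, "B": b}, index=genes
    )
    return ReferenceProfileSet(
        profiles=profiles, containment={"CD4_helper": {"CD4_naive"}}
    )


class TestClassifyByReference:
    def test_cell_equal_to_profile_gets_its_label(self, matrix_factory):
        refs = _reference_set()
        counts = np.round(refs.profiles["NK"].to_numpy() * 10).astype(int)[:, None]
        m = matrix_factory(counts, genes=list(refs.profiles.index), barcodes=["c1"])
        out = classify_by_reference(m, refs)
        assert out["label"].tolist() == ["NK"]

    def test_subset_tiebreak_reassigns_to_contained_population(self, matrix_factory):
        refs = _reference_set()
        # a cell matching CD4_helper exactly: winner helper, runner-up
        # the highly correlated CD4_naive subset -> reassigned to naive
        counts = np.round(refs.profiles["CD4_helper"].to_numpy() * 20).astype(int)[:, None]
        m = matrix_factory(counts, genes=list(refs.profiles.index), barcodes=["c1"])
        out = classify_by_reference(m, refs)
        assert out["label"].tolist() == ["CD4_naive"]

    def test_non_subset_runner_up_keeps_winner(self, matrix_factory):
        refs = ReferenceProfileSet(
            profiles=_reference_set().profiles, containment={"CD4_helper": {"B"}}
        )
        counts = np.round(refs.profiles["CD4_helper"].to_numpy() * 20).astype(int)[:, None]
        m = matrix_factory(counts, genes=list(refs.profiles.index), barcodes=["c1"])
        out = classify_by_reference(m, refs)
        # runner-up is CD4_naive, not in the containment set -> no change
        assert out["label"].tolist() == ["CD4_helper"]

    def test_constant_cell_unassigned(self, matrix_factory):
        refs = _reference_set()
        counts = np.zeros((30, 1), dtype=int)
        m = matrix_factory(counts, genes=list(refs.profiles.index), barcodes=["c1"])
        out = classify_by_reference(m, refs)
        assert out["label"].tolist() == ["unassigned"]

    def test_zero_noise_cells_classified_perfectly(self, matrix_factory):
        rng = np.random.default_rng(23)
        genes = [f"G{i}" for i in range(40)]
        pops = {p: rng.lognormal(1, 1, 40) for p in ("A", "B", "C")}
        profiles = pd.DataFrame(pops, index=genes)
        refs = ReferenceProfileSet(profiles=profiles)
        cells, labels = [], []
        for p in pops:
            for _ in range(10):
                cells.append(np.round(pops[p] * 50).astype(int))
                labels.append(p)
        m = matrix_factory(
            np.column_stack(cells), genes=genes,
            barcodes=[f"c{i}" for i in range(len(cells))],
        )
        out = classify_by_reference(m, refs)
        assert out["label"].tolist() == labels

    def test_containment_cycle_rejected(self):
        profiles = _reference_set().profiles
        with pytest.raises(ValueError, match="cycle"):
            ReferenceProfileSet(
                profiles=profiles,
                containment={"CD4_helper": {"CD4_naive"}, "CD4_naive": {"CD4_helper"}},
            )


class TestCompareProfiles:
    def test_self_comparison(self, matrix_factory):
        rng = np.random.default_rng(29)
        m = matrix_factory(rng.integers(0, 20, size=(50, 10)))
        r, up = compare_profiles(m, m)
        assert r == pytest.approx(1.0)
        # fold threshold 2 means only genes strictly doubled are listed
        assert all(False for _ in up) or up == []

    def test_exactly_doubled_genes_listed(self, matrix_factory):
        rng = np.random.default_rng(31)
        a = rng.integers(1, 20, size=(50, 10))
        b = a.copy()
        doubled = [3, 10, 25, 30, 44]
        b[doubled] = a[doubled] * 2
        genes = [f"G{i:02d}" for i in range(50)]
        r, up = compare_profiles(
            matrix_factory(a, genes=genes), matrix_factory(b, genes=genes)
        )
        assert up == [genes[i] for i in doubled]

    def test_uncorrelated_profiles_near_zero(self, matrix_factory):
        rng = np.random.default_rng(37)
        a = matrix_factory(rng.integers(0, 40, size=(400, 5)))
        b = matrix_factory(rng.integers(0, 40, size=(400, 5)))
        r, _ = compare_profiles(a, b)
        assert abs(r) < 0.2

    def test_disjoint_gene_sets_rejected(self, matrix_factory):
        a = matrix_factory([[1]], genes=["G1"])
        b = matrix_factory([[1]], genes=["G2"])
        with pytest.raises(ValueError, match="intersection"):
            compare_profiles(a, b)
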