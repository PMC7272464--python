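"""Normalization, PCA, clustering, Wilcoxon DE, cell cycle, batch, pseudobulk."""

import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats as sps
from sklearn.metrics import adjusted_rand_score

import platepool as pp
from platepool.dge import DGEMatrix
from platepool.expression import AnalysisParams, NormalizedMatrix


def _dge(array, genes=None, cells=None) -> DGEMatrix:
    array = np.asarray(array)
    genes = genes or [f"A_GENE{i:04d}" for i in range(array.shape[0])]
    cells = cells or [f"BC{i:04d}" for i in range(array.shape[1])]
    return DGEMatrix(sp.csr_matrix(array), genes, cells)


def _norm(values, genes=None, cells=None) -> NormalizedMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"A_GENE{i:04d}" for i in range(values.shape[0])]
    cells = cells or [f"BC{i:04d}" for i in range(values.shape[1])]
    return NormalizedMatrix(values, genes, cells)


class TestNormalize:
    def test_single_expressed_gene_hits_full_cpm(self):
        norm = pp.cpm_log_normalize(_dge([[10], [0]]))
        assert norm.values[0, 0] == pytest.approx(math.log2(1e6 + 1))
        assert norm.values[1, 0] == 0.0

    def test_uniform_cell_is_symmetric(self):
        norm = pp.cpm_log_normalize(_dge([[1], [1], [1], [1]]))
        assert len(set(np.round(norm.values[:, 0], 12))) == 1

    def test_inversion_identity_recovers_one_million(self, rng):
        counts = rng.integers(0, 50, size=(30, 8)) + (rng.random((30, 8)) < 0.2)
        counts[0] += 1  # no zero-total cells
        norm = pp.cpm_log_normalize(_dge(counts))
        totals = (2.0 ** norm.values - 1.0).sum(axis=0)
        np.testing.assert_allclose(totals, 1e6, rtol=1e-6)

    def test_zero_total_cell_named_in_error(self):
        with pytest.raises(ValueError, match="BC0001"):
            pp.cpm_log_normalize(_dge([[1, 0], [1, 0]]))


class TestVariableGenes:
    def test_planted_variable_gene_ranked_first(self, rng):
        values = np.tile(np.linspace(1, 5, 20)[:, None], (1, 40))
        values[7] = rng.permutation(np.r_[np.zeros(20), np.full(20, 8.0)])
        norm = _norm(values)
        assert pp.select_variable_genes(norm, 1)[0] == norm.gene_ids[7]

    def test_requesting_all_genes_returns_all(self, rng):
        norm = _norm(rng.random((12, 10)))
        assert sorted(pp.select_variable_genes(norm, 12)) == sorted(norm.gene_ids)

    def test_oversized_request_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.select_variable_genes(_norm(rng.random((5, 4))), 6)


class TestPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        values = rng.random((5, 4))  # 5 genes x 4 cells
        norm = _norm(values)
        emb = pp.run_pca(norm, AnalysisParams(n_pcs=2))
        # independent oracle: eigen-decomposition of the cell covariance
        x = values.T - values.T.mean(axis=0)
        evals, evecs = np.linalg.eigh(x.T @ x)
        order = np.argsort(evals)[::-1][:2]
        expected = x @ evecs[:, order]
        for j in range(2):
            v = evecs[:, order[j]]
            if v[np.argmax(np.abs(v))] < 0:
                expected[:, j] *= -1
        np.testing.assert_allclose(emb, expected, atol=1e-10)

    def test_planted_axis_dominates_pc1(self, rng):
        base = rng.normal(0, 0.05, size=(30, 40))
        base[0] += np.r_[np.zeros(20), np.full(20, 10.0)]  # one dominant axis
        emb = pp.run_pca(_norm(base), AnalysisParams(n_pcs=4))
        variances = emb.var(axis=0)
        assert variances[0] > variances[1:].max() * 5

    def test_rotation_invariant_explained_variance(self, rng):
        x = rng.normal(size=(10, 12))
        q, _ = np.linalg.qr(rng.normal(size=(10, 10)))
        v1 = pp.run_pca(_norm(x), AnalysisParams(n_pcs=3)).var(axis=0)
        v2 = pp.run_pca(_norm(q @ x), AnalysisParams(n_pcs=3)).var(axis=0)
        np.testing.assert_allclose(v1, v2, rtol=1e-8)

    def test_too_few_cells_rejected(self, rng):
        with pytest.raises(ValueError, match="cells"):
            pp.run_pca(_norm(rng.random((10, 4))), AnalysisParams(n_pcs=4))


class TestClustering:
    def test_two_blobs_recovered_exactly(self, rng):
        blob1 = rng.normal(0, 0.3, size=(40, 4))
        blob2 = rng.normal(6, 0.3, size=(40, 4))
        emb = np.vstack([blob1, blob2])
        labels = pp.cluster_cells(emb, resolution=1.0, seed=0)
        truth = np.r_[np.zeros(40), np.ones(40)]
        assert adjusted_rand_score(truth, labels) == 1.0
        assert set(labels) == {0, 1}

    def test_single_point_single_cluster(self):
        assert pp.cluster_cells(np.zeros((1, 4))).tolist() == [0]

    def test_identical_points_collapse_with_warning(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = pp.cluster_cells(np.ones((5, 2)), seed=0)
        assert set(labels) == {0}

    def test_deterministic_for_fixed_seed(self, rng):
        emb = rng.normal(size=(60, 4))
        a = pp.cluster_cells(emb, resolution=1.5, seed=3)
        b = pp.cluster_cells(emb, resolution=1.5, seed=3)
        assert (a == b).all()


def permutation_oracle(a, b) -> float:
    """Brute-force two-sided rank-sum permutation p-value (independent oracle)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    hits = total = 0
    for idx in combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(idx)].sum() - mu) >= observed - 1e-9:
            hits += 1
    return hits / total


class TestWilcoxonDE:
    def test_identical_groups_are_null(self, rng):
        values = rng.random((10, 8))
        norm = _norm(np.hstack([values, values]))
        a = norm.cell_barcodes[:8]
        b = norm.cell_barcodes[8:]
        res = pp.wilcoxon_de(norm, a, b)
        np.testing.assert_allclose(res.log2fc, 0.0, atol=1e-12)
        assert (res.direction == "ns").all()
        assert (res.p_value.dropna() > 0.9).all()

    @pytest.mark.parametrize("n1,n2", [(4, 4), (3, 7), (8, 8), (2, 5)])
    def test_exact_path_matches_permutation_enumeration(self, n1, n2, rng):
        for _ in range(5):
            a = np.round(rng.random(n1) * 4) / 2  # ties likely
            b = np.round(rng.random(n2) * 4) / 2
            assert pp.rank_sum_p(a, b) == pytest.approx(permutation_oracle(a, b))

    def test_asymptotic_path_tracks_scipy(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(0.8, 1, 35)
        ours = pp.rank_sum_p(a, b, exact_max_n=8)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_fdr_is_bh_monotone_and_dominates_p(self, rng):
        counts = rng.integers(0, 30, size=(60, 24)) + 1
        norm = pp.cpm_log_normalize(_dge(counts))
        res = pp.wilcoxon_de(norm, norm.cell_barcodes[:12], norm.cell_barcodes[12:])
        tested = res.dropna(subset=["p_value"]).sort_values("p_value")
        assert (tested.fdr >= tested.p_value - 1e-12).all()
        ranked_fdr = np.minimum.accumulate(tested.fdr.to_numpy()[::-1])[::-1]
        np.testing.assert_allclose(tested.fdr, ranked_fdr)

    def test_direction_rule_pure_function_of_fc_and_fdr(self, rng):
        n = 30
        strong = np.r_[np.full(n, 2.0), np.zeros(n)]
        weak = np.r_[np.full(n, 1.001), np.ones(n)]  # significant but tiny shift
        values = np.vstack([
            strong,                      # up in A
            -strong + 3,                 # down in A
            weak,                        # significant, |fc| below cutoff
            np.ones(2 * n),              # flat
        ]) + rng.normal(0, 0.01, (4, 2 * n))
        norm = _norm(values)
        res = pp.wilcoxon_de(norm, norm.cell_barcodes[:n], norm.cell_barcodes[n:])
        assert res.direction.tolist() == ["up", "down", "ns", "ns"]

    def test_empty_or_singleton_group_rejected(self, rng):
        norm = _norm(rng.random((4, 6)))
        with pytest.raises(ValueError):
            pp.wilcoxon_de(norm, [], norm.cell_barcodes[1:])
        with pytest.raises(ValueError):
            pp.wilcoxon_de(norm, norm.cell_barcodes[:1], norm.cell_barcodes[1:])


class TestCellCycle:
    def _phase_matrix(self, rng, n_cells=60):
        """Cells with planted phases: markers boosted 4x in their phase,
        suppressed in G1; baseline scales spread so expression bins hold
        non-marker genes for background matching."""
        n_genes = 400
        base = rng.random((n_genes, n_cells)) * 2
        base *= rng.lognormal(0, 0.5, n_genes)[:, None]
        s_markers = [f"A_GENE{i:04d}" for i in range(5)]
        g2m_markers = [f"A_GENE{i:04d}" for i in range(5, 10)]
        phases = np.array(["G1", "S", "G2M"])[rng.integers(0, 3, n_cells)]
        base[:5, phases == "S"] *= 4
        base[5:10, phases == "G2M"] *= 4
        base[:10, phases == "G1"] *= 0.25  # cycle genes off outside S/G2M
        return _norm(base), s_markers, g2m_markers, phases

    def test_pure_g2m_cell_called_g2m(self):
        values = np.zeros((30, 1))
        values[10:15] = 5.0
        norm = _norm(values)
        s = [f"A_GENE{i:04d}" for i in range(5)]
        g2m = [f"A_GENE{i:04d}" for i in range(10, 15)]
        res = pp.score_cell_cycle(norm, s, g2m, seed=0)
        assert res.phase.iloc[0] == "G2M"

    def test_markerless_cell_defaults_to_g1(self, rng):
        values = rng.random((40, 3)) + 1
        values[:10, 0] = 0.0  # cell 0 silent on all markers, active elsewhere
        norm = _norm(values)
        s = [f"A_GENE{i:04d}" for i in range(5)]
        g2m = [f"A_GENE{i:04d}" for i in range(5, 10)]
        res = pp.score_cell_cycle(norm, s, g2m, seed=0)
        assert res.phase.iloc[0] == "G1"

    def test_planted_phases_recovered(self, rng):
        norm, s, g2m, phases = self._phase_matrix(rng)
        res = pp.score_cell_cycle(norm, s, g2m, seed=0)
        recovery = (res.phase.to_numpy() == phases).mean()
        assert recovery >= 0.9

    def test_missing_markers_warn_and_all_missing_errors(self, rng):
        norm = _norm(rng.random((20, 4)))
        with pytest.warns(UserWarning, match="absent"):
            pp.score_cell_cycle(norm, [norm.gene_ids[0], "NOPE"], [norm.gene_ids[1]], seed=0)
        with pytest.raises(ValueError, match="marker"):
            pp.score_cell_cycle(norm, ["NOPE"], [norm.gene_ids[1]], seed=0)


class TestBatchRemoval:
    def test_additive_offset_removed_exactly(self, rng):
        base = rng.random((25, 20))
        offset = rng.normal(0, 2, size=25)
        values = base.copy()
        values[:, 10:] += offset[:, None]
        norm = _norm(values)
        batch = ["b1"] * 10 + ["b2"] * 10
        adj = pp.remove_batch_effect(norm, batch)
        m1 = adj.values[:, :10].mean(axis=1)
        m2 = adj.values[:, 10:].mean(axis=1)
        np.testing.assert_allclose(m1, m2, atol=1e-10)

    def test_single_batch_identity(self, rng):
        norm = _norm(rng.random((10, 6)))
        adj = pp.remove_batch_effect(norm, ["b"] * 6)
        np.testing.assert_array_equal(adj.values, norm.values)

    def test_condition_effect_preserved(self, rng):
        base = rng.random((30, 40))
        cond_shift = 1.5
        values = base.copy()
        condition = np.array(["ctrl"] * 20 + ["drug"] * 20)
        batch = np.array((["b1"] * 10 + ["b2"] * 10) * 2)
        values[0, condition == "drug"] += cond_shift
        values[:, batch == "b2"] += rng.normal(0, 1, 30)[:, None]
        adj = pp.remove_batch_effect(_norm(values), list(batch), list(condition))
        recovered = adj.values[0, condition == "drug"].mean() - adj.values[0, condition == "ctrl"].mean()
        assert recovered == pytest.approx(cond_shift, abs=0.05)

    def test_confounded_design_rejected(self, rng):
        norm = _norm(rng.random((5, 8)))
        batch = ["b1"] * 4 + ["b2"] * 4
        condition = ["x"] * 4 + ["y"] * 4  # perfectly aliased
        with pytest.raises(ValueError, match="confounded"):
            pp.remove_batch_effect(norm, batch, condition)


class TestPseudobulk:
    def test_identical_replicates_correlate_perfectly(self, rng):
        block = rng.random((50, 6))
        norm = _norm(np.hstack([block, block]))
        labels = ["m1"] * 6 + ["m2"] * 6
        profiles, corr = pp.pseudobulk_profiles(norm, labels)
        assert corr.loc["m1", "m2"] == pytest.approx(1.0)
        np.testing.assert_allclose(profiles.loc["m1"], profiles.loc["m2"])

    def test_independent_profiles_uncorrelated(self, rng):
        values = rng.normal(size=(5000, 2))
        profiles, corr = pp.pseudobulk_profiles(_norm(values), ["a", "b"])
        assert abs(corr.loc["a", "b"]) < 0.1

    def test_label_length_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            pp.pseudobulk_profiles(_norm(rng.random((5, 4))), ["a", "b"])


class TestHeatmapGeneSet:
    def _result(self, genes, fdrs):
        return pd.DataFrame({"gene": genes, "fdr": fdrs})

    def test_all_null_gives_empty_union(self):
        res = {"d1": self._result(["g1", "g2"], [0.5, 0.9])}
        assert pp.heatmap_gene_set(res) == []

    def test_single_hit_single_gene(self):
        res = {"d1": self._result(["g1", "g2"], [0.01, 0.9])}
        assert pp.heatmap_gene_set(res) == ["g1"]

    def test_union_matches_brute_force_over_contrasts(self, rng):
        genes = [f"g{i}" for i in range(200)]
        results = {
            d: self._result(genes, rng.random(200)) for d in ("d1", "d2", "d3")
        }
        expected = set()
        for table in results.values():
            expected |= {g for g, f in zip(table.gene, table.fdr) if f < 0.05}
        assert pp.heatmap_gene_set(results, 0.05) == sorted(expected)
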