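import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy import stats
from scipy.cluster.hierarchy import cophenet

from spacecat.containers import CountMatrix, ExpressionMatrix
from spacecat.flow import fisher_exact
from spacecat.spatial import (ModuleScoreConfig, cell_cycle_phase,
                              cluster_cell_types, composition_tests,
                              correlate_with_score, dendrogram_to_newick,
                              lognormalize, module_score, permutation_test,
                              rare_cell_power, region_score,
                              select_correlated_genes,
                              select_variable_genes)
from spacecat.synthetic import SimCountConfig, generate_counts


def make_expr(arr, genes=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    cells = [f"c{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(sp.csr_matrix(arr), genes, cells)


class TestLognormalize:
    def test_formula_and_zero_preservation(self):
        arr = np.array([[1, 0], [9999, 10]])
        counts = CountMatrix(sp.csr_matrix(arr), ["a", "b"], ["c0", "c1"])
        expr = lognormalize(counts, scale=10_000.0)
        dense = expr.to_dense()
        assert dense[0, 0] == pytest.approx(np.log(2.0))  # x=1, T=10000
        assert dense[0, 1] == 0.0

    def test_round_trip_inverse(self, default_dataset):
        counts, *_ = default_dataset
        expr = lognormalize(counts)
        totals = counts.cell_totals()
        recovered = (np.expm1(expr.to_dense()) * totals[None, :]
                     / expr.scale)
        np.testing.assert_allclose(recovered, counts.to_dense(), atol=1e-9)

    def test_zero_total_cell_named_in_error(self):
        arr = np.array([[1, 0], [2, 0]])
        counts = CountMatrix(sp.csr_matrix(arr), ["a", "b"], ["ok", "empty"])
        with pytest.raises(ValueError, match="empty"):
            lognormalize(counts)


class TestSelectVariableGenes:
    def test_strict_mean_threshold(self):
        # gene0 mean exactly 0.1, gene1 above, gene2 all-zero
        arr = np.array([[0.1, 0.1], [1.0, 2.0], [0.0, 0.0]])
        expr = make_expr(arr)
        selected = select_variable_genes(expr, min_mean=0.1)
        assert selected == ["g1"]

    def test_matches_bruteforce_mean_filter(self, default_expr):
        expr, *_ = default_expr
        selected = set(select_variable_genes(expr, min_mean=0.5))
        dense = expr.to_dense()
        expected = {g for g, row in zip(expr.genes, dense)
                    if row.mean() > 0.5}
        assert selected == expected


class TestRegionScore:
    def test_single_gene_set_equals_that_row(self, default_expr):
        expr, *_ = default_expr
        s = region_score(expr, [expr.genes[3]])
        np.testing.assert_allclose(s.to_numpy(), expr.to_dense()[3])

    def test_all_zero_set_scores_zero(self):
        expr = make_expr([[0, 0, 0], [1, 2, 3]])
        assert (region_score(expr, ["g0"]) == 0).all()

    def test_additive_over_disjoint_sets(self, default_expr):
        expr, *_ = default_expr
        a = list(expr.genes[:5])
        b = list(expr.genes[5:12])
        combined = region_score(expr, a + b)
        np.testing.assert_allclose(
            combined, region_score(expr, a) + region_score(expr, b)
        )

    def test_tracks_latent_border_proximity(self, default_expr):
        expr, _, truth = default_expr
        s = region_score(expr, truth.program_genes_up)
        r = np.corrcoef(s, truth.border_proximity)[0, 1]
        assert r > 0.8

    def test_empty_or_alien_sets_rejected(self, default_expr):
        expr, *_ = default_expr
        with pytest.raises(ValueError):
            region_score(expr, [])
        with pytest.raises(ValueError):
            region_score(expr, ["not_a_gene"])
        with pytest.warns(UserWarning):
            region_score(expr, [expr.genes[0], "not_a_gene"])


class TestCorrelateWithScore:
    def test_perfect_correlations(self):
        s = np.array([1.0, 2.0, 3.0, 4.0])
        expr = make_expr(np.vstack([s, -s + 10.0]))
        out = correlate_with_score(expr, s)
        assert out["r"].tolist() == pytest.approx([1.0, -1.0])

    def test_matches_closed_form(self, rng):
        X = rng.random((6, 10))
        s = rng.random(10)
        out = correlate_with_score(make_expr(X), s)
        for i in range(6):
            cov = np.mean((X[i] - X[i].mean()) * (s - s.mean()))
            r_hand = cov / (X[i].std() * s.std())
            assert out["r"].iloc[i] == pytest.approx(r_hand, abs=1e-12)

    def test_zero_variance_gene_flagged(self):
        expr = make_expr([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]])
        out = correlate_with_score(expr, np.array([1.0, 2.0, 3.0]))
        assert out.loc["g0", "zero_variance"]
        assert out.loc["g0", "r"] == 0.0

    def test_constant_score_rejected(self):
        expr = make_expr([[1.0, 2.0, 3.0]])
        with pytest.raises(ValueError):
            correlate_with_score(expr, np.ones(3))


class TestPermutationTest:
    def test_score_gene_hits_the_p_floor(self, rng):
        s = rng.random(40)
        expr = make_expr(np.vstack([s, rng.random(40)]))
        out = permutation_test(expr, s, n_perm=999, seed=3)
        assert out["p"].iloc[0] == pytest.approx(1 / 1000)

    def test_seeded_reproducibility(self, default_expr):
        expr, _, truth = default_expr
        s = region_score(expr, truth.program_genes_up).to_numpy()
        a = permutation_test(expr, s, n_perm=199, seed=5)
        b = permutation_test(expr, s, n_perm=199, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_too_few_permutations_rejected(self, default_expr):
        expr, _, truth = default_expr
        s = region_score(expr, truth.program_genes_up).to_numpy()
        with pytest.raises(ValueError):
            permutation_test(expr, s, n_perm=50)

    def test_null_type_i_error_and_super_uniformity(self, null_dataset):
        """Without a planted effect, non-score genes reject at ~5% and the
        p-values are compatible with Uniform(0,1)."""
        counts, _, truth = null_dataset
        expr = lognormalize(counts)
        s = region_score(expr, truth.program_genes_up).to_numpy()
        out = permutation_test(expr, s, n_perm=999, seed=9)
        non_score = ~out.index.isin(set(truth.program_genes_up))
        assert non_score.sum() >= 500
        p = out.loc[non_score, "p"].to_numpy()
        assert 0.03 <= (p < 0.05).mean() <= 0.07
        # +1 floor makes p slightly super-uniform; KS at 1% must not reject
        assert stats.kstest(p, "uniform").pvalue > 0.01


class TestSelectCorrelatedGenes:
    def test_alpha_edge_cases(self):
        result = pd.DataFrame({"r": [0.5, -0.2], "p": [0.2, 0.4]},
                              index=["a", "b"])
        assert select_correlated_genes(result, alpha=0.01) == ([], [])
        neg, pos = select_correlated_genes(result, alpha=1.0)
        assert (neg, pos) == (["b"], ["a"])

    def test_planted_program_recovery(self, default_expr):
        """Planted border program recovered with high sensitivity and
        controlled false discovery."""
        expr, _, truth = default_expr
        s = region_score(expr, truth.program_genes_up).to_numpy()
        out = permutation_test(expr, s, n_perm=999, seed=0)
        neg, pos = select_correlated_genes(out, alpha=0.05)
        up, dn = set(truth.program_genes_up), set(truth.program_genes_down)
        planted, recovered = up | dn, set(pos) | set(neg)
        jaccard = len(planted & recovered) / len(planted | recovered)
        sens = (len(up & set(pos)) + len(dn & set(neg))) / len(planted)
        fdr = len(recovered - planted) / max(len(recovered), 1)
        assert jaccard > 0.6
        assert sens > 0.9
        assert fdr < 0.15

    def test_score_ordering_shows_opposing_gradients(self, default_expr):
        """Cells ranked by score show smooth opposing program gradients."""
        expr, _, truth = default_expr
        s = region_score(expr, truth.program_genes_up)
        rank = s.rank().to_numpy()
        X = expr.to_dense()
        up_rows = expr.gene_index(truth.program_genes_up)
        dn_rows = expr.gene_index(truth.program_genes_down)
        rho_up = stats.spearmanr(rank, X[up_rows].mean(axis=0)).statistic
        rho_dn = stats.spearmanr(rank, X[dn_rows].mean(axis=0)).statistic
        assert rho_up > 0.5 and rho_dn < -0.5
        # individual planted genes are noisy but overwhelmingly signed right
        sign_up = np.mean([stats.spearmanr(rank, X[i]).statistic > 0
                           for i in up_rows])
        sign_dn = np.mean([stats.spearmanr(rank, X[i]).statistic < 0
                           for i in dn_rows])
        assert sign_up > 0.9 and sign_dn > 0.9


class TestModuleScore:
    def test_random_set_from_homogeneous_matrix_scores_near_zero(self, rng):
        arr = rng.poisson(5.0, size=(300, 80)).astype(float)
        expr = make_expr(np.log1p(arr))
        genes = list(rng.choice(expr.genes, size=20, replace=False))
        scores = module_score(expr, genes,
                              ModuleScoreConfig(ctrl_genes_per_bin=10, seed=2))
        se = scores.std() / np.sqrt(len(scores))
        assert abs(scores.mean()) < 2 * max(se, 1e-6) + 0.01

    def test_planted_module_separates_cells(self, default_expr):
        expr, _, truth = default_expr
        genes = truth.marker_genes[0]
        scores = module_score(expr, genes,
                              ModuleScoreConfig(ctrl_genes_per_bin=25, seed=1))
        is_type = (truth.cell_type == 0).to_numpy()
        p = stats.mannwhitneyu(scores[is_type], scores[~is_type]).pvalue
        assert p < 1e-3
        assert scores[is_type].mean() > scores[~is_type].mean()

    def test_seeded_determinism(self, default_expr):
        expr, _, truth = default_expr
        cfg = ModuleScoreConfig(ctrl_genes_per_bin=25, seed=4)
        a = module_score(expr, truth.marker_genes[1], cfg)
        b = module_score(expr, truth.marker_genes[1], cfg)
        pd.testing.assert_series_equal(a, b)

    def test_set_covering_matrix_rejected(self):
        expr = make_expr(np.ones((3, 4)))
        with pytest.raises(ValueError):
            module_score(expr, ["g0", "g1", "g2"])


class TestCellCyclePhase:
    def test_silent_cells_rest_in_g01(self, rng):
        arr = rng.poisson(3.0, size=(100, 30)).astype(float)
        arr[:10, :] = 0.0  # both program lists fully silent
        expr = make_expr(np.log1p(arr))
        phases = cell_cycle_phase(expr, [f"g{i}" for i in range(5)],
                                  [f"g{i}" for i in range(5, 10)],
                                  ModuleScoreConfig(n_bins=5,
                                                    ctrl_genes_per_bin=10))
        assert (phases["phase"] == "G0/1").all()

    def test_planted_programs_called_correctly(self, default_expr):
        """Cells of marker types stand in for S- and G2/M-high cells."""
        expr, _, truth = default_expr
        phases = cell_cycle_phase(expr, truth.marker_genes[1],
                                  truth.marker_genes[2],
                                  ModuleScoreConfig(ctrl_genes_per_bin=25,
                                                    seed=3))
        s_cells = (truth.cell_type == 1).to_numpy()
        g2m_cells = (truth.cell_type == 2).to_numpy()
        assert (phases.loc[s_cells, "phase"] == "S").mean() > 0.9
        assert (phases.loc[g2m_cells, "phase"] == "G2/M").mean() > 0.9

    def test_fully_missing_lists_rejected(self, default_expr):
        expr, *_ = default_expr
        with pytest.raises(ValueError):
            cell_cycle_phase(expr, ["nope1"], ["nope2"])


class TestCompositionTests:
    def test_identical_composition_is_null(self):
        table = pd.DataFrame({"A": [30, 20, 10], "B": [30, 20, 10]},
                             index=["t0", "t1", "t2"])
        out = composition_tests(table, "fisher_per_type_bh")
        assert np.allclose(out["p_adj"], 1.0)

    def test_planted_enrichment_flagged(self, rng):
        """A 3x-enriched type is detected; stable types stay null."""
        base = np.array([0.3, 0.3, 0.2, 0.1, 0.1])
        shifted = np.array([0.3 * 3, 0.3, 0.2, 0.1, 0.1])
        shifted = shifted / shifted.sum()
        table = pd.DataFrame({
            "A": rng.multinomial(500, shifted),
            "B": rng.multinomial(500, base),
        }, index=[f"t{i}" for i in range(5)])
        out = composition_tests(table, "fisher_per_type_bh")
        assert out.loc["t0", "p_adj"] < 0.05

    def test_two_by_two_reduces_to_fisher_exact(self):
        table = pd.DataFrame({"A": [12, 30], "B": [25, 9]},
                             index=["x", "y"])
        out = composition_tests(table, "fisher_per_type_bh")
        _, p_direct = fisher_exact([[12, 25], [30, 9]])
        assert out.loc["x", "p"] == pytest.approx(p_direct)

    def test_chisq_global_runs_and_warns_on_zero_margin(self):
        table = pd.DataFrame({"A": [10, 0, 20], "B": [12, 0, 18]},
                             index=["t0", "t1", "t2"])
        with pytest.warns(UserWarning):
            stat, p, dof = composition_tests(table, "chisq_global",
                                             pool_zero_margins=True)
        assert dof == 1 and 0 <= p <= 1

    def test_composition_of_default_dataset(self, default_expr):
        _, meta, _ = default_expr
        table = pd.crosstab(meta["cell_type"], meta["region_label"])
        stat, p, dof = composition_tests(table, "chisq_global")
        assert dof == (table.shape[0] - 1) * (table.shape[1] - 1)


def naive_complete_linkage(dist):
    """O(n^3) agglomeration oracle returning cophenetic distances."""
    n = dist.shape[0]
    clusters = {i: {i} for i in range(n)}
    coph = np.zeros((n, n))
    while len(clusters) > 1:
        best = None
        for a in clusters:
            for b in clusters:
                if a >= b:
                    continue
                d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
                if best is None or d < best[0]:
                    best = (d, a, b)
        d, a, b = best
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = d
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]
    return coph


class TestClusterCellTypes:
    def test_two_types_merge_at_one_minus_rho(self, default_expr):
        expr, meta, _ = default_expr
        two = np.where(meta["cell_type"].isin(["type0", "type1"]),
                       meta["cell_type"], "type0")
        z, labels = cluster_cell_types(expr, two, list(expr.genes[:100]))
        rows = expr.gene_index(list(expr.genes[:100]))
        profiles = [np.asarray(expr.matrix[rows][:, two == lbl]
                               .mean(axis=1)).ravel() for lbl in labels]
        rho = stats.spearmanr(profiles[0], profiles[1]).statistic
        assert z.shape == (1, 4)
        assert z[0, 2] == pytest.approx(1 - rho)

    def test_duplicated_profiles_merge_first_at_zero(self, rng):
        profiles = rng.random((50, 3))
        X = np.column_stack([profiles[:, 0]] * 4 + [profiles[:, 1]] * 4
                            + [profiles[:, 2]] * 4 + [profiles[:, 0]] * 4)
        expr = make_expr(X)
        clusters = np.repeat(["a", "b", "c", "a2"], 4)
        z, labels = cluster_cell_types(expr, clusters, list(expr.genes))
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        first = {labels[int(z[0, 0])], labels[int(z[0, 1])]}
        assert first == {"a", "a2"}

    def test_matches_naive_agglomeration_oracle(self, rng):
        X = rng.random((40, 15))
        expr = make_expr(X)
        clusters = np.repeat([f"t{i}" for i in range(5)], 3)
        z, labels = cluster_cell_types(expr, clusters, list(expr.genes))
        profiles = np.column_stack([
            X[:, clusters == lbl].mean(axis=1) for lbl in labels])
        rho = stats.spearmanr(profiles).statistic
        dist = 1 - rho
        np.fill_diagonal(dist, 0.0)
        coph_oracle = naive_complete_linkage(dist)
        from scipy.spatial.distance import squareform
        coph_lin = squareform(cophenet(z))
        np.testing.assert_allclose(coph_lin, coph_oracle, atol=1e-12)

    def test_zero_variance_profile_named(self):
        X = np.vstack([np.ones(6), np.arange(6, dtype=float)])
        expr = make_expr(X)
        clusters = np.array(["flat", "flat", "flat", "ok", "ok", "ok"])
        X[1, :3] = 1.0  # make 'flat' cluster constant across genes
        with pytest.raises(ValueError, match="flat"):
            cluster_cell_types(make_expr(X), clusters, ["g0", "g1"])

    def test_newick_export_contains_labels_and_lengths(self, default_expr):
        expr, meta, _ = default_expr
        z, labels = cluster_cell_types(expr, meta["cell_type"].to_numpy(),
                                       list(expr.genes[:150]))
        newick = dendrogram_to_newick(z, labels)
        assert newick.endswith(";")
        for lbl in labels:
            assert lbl in newick


class TestRareCellPower:
    def test_zero_requirement_is_certain(self):
        assert rare_cell_power(0.3, 10, 0) == 1.0

    def test_single_draw(self):
        assert rare_cell_power(0.5, 1, 1) == pytest.approx(0.5)

    def test_matches_direct_summation(self):
        f, n, k = 0.01, 500, 3
        from math import comb
        direct = sum(comb(n, i) * f ** i * (1 - f) ** (n - i)
                     for i in range(k, n + 1))
        assert rare_cell_power(f, n, k) == pytest.approx(direct, rel=1e-10)

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError):
            rare_cell_power(0.0, 10, 1)
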