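import math

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from maplink import (
    InputError,
    PairingTable,
    PreconditionError,
    SimulationConfig,
    benchmark_pairs,
    chi2_proportions,
    cross_layer_matrix,
    fdr_bh,
    group_difference,
    layerwise_benchmark,
    simulate_autocorrelated_map,
    simulate_benchmark_dataset,
    simulate_correlated_pair,
    spearman_r,
    within_region_layer_correlation,
)
from maplink.stats import _rank_corr_batch
from maplink.stats import test_correspondence as correspondence_test


def midrank_pearson(x, y):
    """Independent Spearman oracle: explicit mid-ranks + Pearson formula."""
    def midranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        ranks = [0.0] * len(v)
        i = 0
        while i < len(v):
            j = i
            while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2 + 1
            for k in range(i, j + 1):
                ranks[order[k]] = avg
            i = j + 1
        return ranks

    rx, ry = midranks(list(x)), midranks(list(y))
    mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry)
    )
    return num / den


class TestSpearman:
    def test_monotone_identity_and_reversal(self):
        assert spearman_r([1, 2, 3], [1, 4, 9]) == 1.0
        assert spearman_r([1, 2, 3], [9, 4, 1]) == -1.0

    def test_tied_data_matches_midrank_oracle(self):
        x, y = [1, 2, 2, 4], [3, 1, 4, 4]
        assert np.isclose(spearman_r(x, y), midrank_pearson(x, y), atol=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(PreconditionError):
            spearman_r([1, 1, 1], [1, 2, 3])

    def test_pairwise_complete_restriction(self):
        x = [1.0, 2.0, np.nan, 4.0, 5.0]
        y = [2.0, 1.0, 9.0, 3.0, np.nan]
        assert np.isclose(
            spearman_r(x, y), spearman_r([1, 2, 4], [2, 1, 3])
        )

    def test_batch_rank_corr_matches_scipy(self, rng):
        surr = rng.standard_normal((50, 20))
        y = rng.standard_normal(20)
        batch = _rank_corr_batch(surr, y)
        ref = [spearmanr(surr[i], y).statistic for i in range(50)]
        assert np.allclose(batch, ref, atol=1e-12)


class TestCorrespondence:
    def test_self_correspondence(self, rand30):
        _, basis = rand30
        m = simulate_autocorrelated_map(basis, 1.0, seed=5)
        res = correspondence_test(m, m, basis, n_null=200, seed=1)
        assert res.spearman_r == 1.0
        assert res.p_empirical == 1 / 201

    def test_rank_invariance_under_monotone_transform(self, rand30):
        _, basis = rand30
        m = simulate_autocorrelated_map(basis, 1.0, seed=5)
        r1 = correspondence_test(m, m, basis, n_null=200, seed=1)
        r2 = correspondence_test(m, np.exp(m), basis, n_null=200, seed=1)
        assert r1.spearman_r == r2.spearman_r
        assert r1.p_empirical == r2.p_empirical

    def test_zscoring_never_changes_r_or_p(self, rand30):
        _, basis = rand30
        a = simulate_autocorrelated_map(basis, 1.0, seed=6)
        b = simulate_correlated_pair(a, 0.5, basis, 1.0, seed=7)
        r1 = correspondence_test(a, b, basis, n_null=200, seed=2)
        r2 = correspondence_test(
            (a - a.mean()) / a.std(), (b - b.mean()) / b.std(), basis,
            n_null=200, seed=2,
        )
        assert r1.spearman_r == r2.spearman_r
        assert r1.p_empirical == r2.p_empirical

    def test_missing_regions_restrict_to_pairwise_complete(self, rand30):
        _, basis = rand30
        a = simulate_autocorrelated_map(basis, 1.0, seed=8)
        b = simulate_correlated_pair(a, 0.6, basis, 1.0, seed=9)
        a2, b2 = a.copy(), b.copy()
        a2[:4] = np.nan
        b2[4:8] = np.nan
        res = correspondence_test(a2, b2, basis, n_null=200, seed=3)
        assert res.n_regions_used == 22

    def test_p_floor_respected(self, rand30):
        _, basis = rand30
        a = simulate_autocorrelated_map(basis, 1.0, seed=10)
        res = correspondence_test(a, a, basis, n_null=500, seed=4)
        assert res.p_empirical >= 1 / 501


class TestBenchmarkPairs:
    @pytest.fixture(scope="class")
    def small_bench(self, rand30):
        parc, basis = rand30
        cfg = SimulationConfig(
            n_regions=30, n_pairs=6, effect_sizes=(0.9, 0.9, 0.9, 0.0, 0.0, 0.0),
            seed=21,
        )
        genes, receptors, pairing, truth = simulate_benchmark_dataset(
            cfg, basis=basis, parcellation=parc
        )
        return parc, basis, genes, receptors, pairing, truth

    def test_one_row_per_pairing_and_proportions(self, small_bench):
        parc, basis, genes, receptors, pairing, _ = small_bench
        out = benchmark_pairs(genes, receptors, pairing, basis, n_null=300, seed=1)
        assert len(out.table) == 6
        total = sum(v["n_tested"] for v in out.summary["by_class"].values())
        assert total == 6  # classes partition the rows
        for v in out.summary["by_class"].values():
            assert v["proportion"] == v["n_significant"] / v["n_tested"]

    def test_determinism_and_seed_dependence(self, small_bench):
        parc, basis, genes, receptors, pairing, _ = small_bench
        a = benchmark_pairs(genes, receptors, pairing, basis, n_null=300, seed=1)
        b = benchmark_pairs(genes, receptors, pairing, basis, n_null=300, seed=1)
        c = benchmark_pairs(genes, receptors, pairing, basis, n_null=300, seed=2)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert not a.table["p_empirical"].equals(c.table["p_empirical"])

    def test_fdr_rejections_subset_of_raw(self, small_bench):
        parc, basis, genes, receptors, pairing, _ = small_bench
        out = benchmark_pairs(genes, receptors, pairing, basis, n_null=300, seed=1)
        assert (out.table["significant_fdr"] <= out.table["significant"]).all()

    def test_missing_gene_reference_skipped_and_logged(self, small_bench):
        parc, basis, genes, receptors, pairing, _ = small_bench
        rows = pairing.rows + (("GHOST", "rec001", "GABA"),)
        out = benchmark_pairs(
            genes, receptors, PairingTable(rows), basis, n_null=300, seed=1
        )
        assert len(out.table) == 6
        assert any("GHOST" in s for s in out.skipped)

    def test_empty_pairing_after_checks_is_error(self, small_bench):
        parc, basis, genes, receptors, _, _ = small_bench
        ghost = PairingTable((("GHOST", "rec001", "GABA"),))
        with pytest.raises(InputError):
            benchmark_pairs(genes, receptors, ghost, basis, n_null=300, seed=1)


class TestLayerwise:
    def test_row_count_is_pairs_times_layers(self, rand30):
        parc, basis = rand30
        cfg = SimulationConfig(n_regions=30, n_pairs=4, n_layers=3, seed=31)
        layer_genes, receptors, pairing, _ = simulate_benchmark_dataset(
            cfg, basis=basis, parcellation=parc, layered=True
        )
        out = layerwise_benchmark(
            layer_genes, receptors, pairing, basis, n_null=200, seed=1
        )
        assert len(out.table) == 12
        assert set(out.summary["by_layer"]) == {"L1", "L2", "L3"}

    def test_same_matrix_for_all_layers_gives_identical_r(self, rand30):
        parc, basis = rand30
        cfg = SimulationConfig(n_regions=30, n_pairs=3, seed=32)
        genes, receptors, pairing, _ = simulate_benchmark_dataset(
            cfg, basis=basis, parcellation=parc
        )
        out = layerwise_benchmark(
            {"L1": genes, "L2": genes, "L3": genes},
            receptors, pairing, basis, n_null=200, seed=1,
        )
        for (_, _), grp in out.table.groupby(["gene", "receptor"]):
            assert grp["spearman_r"].nunique() == 1

    def test_multilayer_tallies(self, rand30):
        parc, basis = rand30
        cfg = SimulationConfig(
            n_regions=30, n_pairs=4, n_layers=3,
            effect_sizes=(0.95, 0.95, 0.0, 0.0), seed=33,
        )
        layer_genes, receptors, pairing, _ = simulate_benchmark_dataset(
            cfg, basis=basis, parcellation=parc, layered=True, active_layers=("L2",)
        )
        out = layerwise_benchmark(
            layer_genes, receptors, pairing, basis, n_null=300, seed=1
        )
        assert out.summary["pairs_significant_in_ge1_layers"] >= 2
        assert (
            out.summary["pairs_significant_in_ge2_layers"]
            <= out.summary["pairs_significant_in_ge1_layers"]
        )


class TestWithinRegionLayers:
    def test_perfect_match_exact_enumeration(self):
        res = within_region_layer_correlation(
            [1, 2, 3, 4, 5, 6], [10, 20, 30, 40, 50, 60]
        )
        assert res.spearman_r == 1.0
        assert np.isclose(res.p_empirical, 2 / 720)
        assert res.n_null == 720

    def test_antimatched_ranks(self):
        res = within_region_layer_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert res.spearman_r == -1.0

    def test_too_few_layers_error(self):
        with pytest.raises(PreconditionError):
            within_region_layer_correlation([1, 2], [3, 4])

    def test_monte_carlo_beyond_seven_layers(self, rng):
        x = rng.standard_normal(9)
        y = rng.standard_normal(9)
        res = within_region_layer_correlation(x, y, n_perm=500, seed=3)
        assert res.n_null == 500
        assert 0 < res.p_empirical <= 1


class TestCrossLayerMatrix:
    def _tables(self, rng, n_pairs=8, layers_g=3, layers_r=2):
        g = pd.DataFrame(
            rng.standard_normal((n_pairs, layers_g)),
            columns=[f"L{i+1}" for i in range(layers_g)],
        )
        r = pd.DataFrame(
            rng.standard_normal((n_pairs, layers_r)),
            columns=[f"L{i+1}" for i in range(layers_r)],
        )
        return g, r

    def test_identity_inputs_unit_diagonal(self, rng):
        g, _ = self._tables(rng, layers_g=3, layers_r=3)
        corr, _, _ = cross_layer_matrix(g, g.copy(), seed=1)
        assert np.allclose(np.diag(corr.to_numpy(float)), 1.0)

    def test_negated_column_gives_minus_one(self, rng):
        g, r = self._tables(rng)
        r["L1"] = -g["L2"]
        corr, _, _ = cross_layer_matrix(g, r, seed=1)
        assert np.isclose(corr.loc["L2", "L1"], -1.0)

    def test_matches_brute_force_loop(self, rng):
        g, r = self._tables(rng, n_pairs=6, layers_g=2, layers_r=3)
        corr, _, _ = cross_layer_matrix(g, r, seed=1)
        for la in g.columns:
            for lb in r.columns:
                assert np.isclose(
                    corr.loc[la, lb], spearman_r(g[la], r[lb]), atol=1e-12
                )

    def test_fdr_flags_shape_and_subset(self, rng):
        g, r = self._tables(rng)
        corr, pval, flags = cross_layer_matrix(g, r, alpha=0.05, seed=1)
        assert flags.shape == corr.shape
        raw_reject = pval.to_numpy(float) <= 0.05
        assert np.all(flags.to_numpy(bool) <= raw_reject)


class TestFdrBH:
    def test_single_p_unchanged(self):
        p_adj, _ = fdr_bh([0.03])
        assert p_adj[0] == 0.03

    def test_stepup_oracle_sequence(self):
        p_adj, _ = fdr_bh([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(p_adj, [0.04, 0.04, 0.04, 0.04])

    def test_all_equal_p_unchanged(self):
        p_adj, _ = fdr_bh([0.2, 0.2, 0.2])
        assert np.allclose(p_adj, 0.2)

    def test_out_of_range_p_error(self):
        with pytest.raises(InputError):
            fdr_bh([0.5, 0.0])
        with pytest.raises(InputError):
            fdr_bh([1.5])

    def test_adjusted_monotone_in_rank_order(self, rng):
        p = rng.uniform(1e-6, 1, size=40)
        p_adj, _ = fdr_bh(p)
        order = np.argsort(p)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)


class TestChi2Proportions:
    def test_equal_proportions_give_zero(self):
        chi2, p = chi2_proportions(10, 20, 5, 10)
        assert np.isclose(chi2, 0.0) and np.isclose(p, 1.0)

    def test_expected_counts_oracle(self):
        chi2, _ = chi2_proportions(30, 60, 10, 60)
        table = np.array([[30, 30], [10, 50]], dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / total
        ref = np.sum((table - expected) ** 2 / expected)
        assert np.isclose(chi2, ref, atol=1e-12)

    def test_invalid_counts_error(self):
        with pytest.raises(InputError):
            chi2_proportions(5, 4, 1, 10)

    def test_continuity_correction_toggle_reduces_statistic(self):
        raw, _ = chi2_proportions(30, 60, 10, 60)
        corrected, _ = chi2_proportions(30, 60, 10, 60, correction=True)
        assert corrected < raw


class TestGroupDifference:
    def test_identical_groups_null(self):
        t, df, d, p = group_difference([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and d == 0.0 and np.isclose(p, 1.0)

    def test_one_pooled_sd_shift_gives_d_of_one(self, rng):
        a = rng.standard_normal(50)
        sd = a.std(ddof=1)
        _, _, d, _ = group_difference(a + sd, a)
        assert np.isclose(d, 1.0)

    def test_formula_oracle(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        t, df, d, p = group_difference(a, b)
        sp = math.sqrt(((2) * a.var(ddof=1) + (2) * b.var(ddof=1)) / 4)
        t_ref = (a.mean() - b.mean()) / (sp * math.sqrt(1 / 3 + 1 / 3))
        assert df == 4
        assert np.isclose(t, t_ref, atol=1e-12)
        assert np.isclose(d, (a.mean() - b.mean()) / sp, atol=1e-12)

    def test_small_group_error(self):
        with pytest.raises(PreconditionError):
            group_difference([1.0], [1.0, 2.0])
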