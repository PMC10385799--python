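"""Tests of balanced subsampling, S3 networks and in-silico pooling."""

import numpy as np
import pandas as pd
import pytest

import singlebud as sb


@pytest.fixture(scope="module")
def module_table():
    d = sb.study_design(module_rho=0.8, include_undetectable=False,
                        outlier_rate=0.0, seed=42)
    table, truth = sb.generate_expression(d)
    return table, truth


class TestBalancedMatrix:
    def test_duplicated_gene_always_significant(self):
        d = sb.null_design(n_genes=2, stage_sizes={"S1": 6, "S2": 6,
                                                   "S3": 20, "S4": 6})
        table, _ = sb.generate_expression(d, seed=3)
        vals = table.values.copy()
        vals["G01_copy"] = vals["G01"]
        table = table.with_values(vals)
        cfg = sb.ResamplingConfig(n_reps=20, n_sub_s3=6, seed=1)
        summary = sb.balanced_correlation_matrix(table, cfg)
        assert summary.mean_rho.at["G01", "G01_copy"] == pytest.approx(1.0)
        assert summary.sig_fraction_observed.at["G01", "G01_copy"] == 1.0
        assert bool(summary.significant.at["G01", "G01_copy"])

    def test_deterministic_given_seed(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(n_reps=30, seed=77)
        a = sb.balanced_correlation_matrix(table, cfg)
        b = sb.balanced_correlation_matrix(table, cfg)
        pd.testing.assert_frame_equal(a.mean_rho, b.mean_rho)
        pd.testing.assert_frame_equal(a.sig_fraction_observed,
                                      b.sig_fraction_observed)

    def test_alpha_monotone_in_edges(self, module_table):
        table, _ = module_table
        tight = sb.ResamplingConfig(n_reps=30, alpha=1e-4, seed=5)
        loose = sb.ResamplingConfig(n_reps=30, alpha=1e-2, seed=5)
        e_tight = sb.balanced_correlation_matrix(table, tight).edge_list()
        e_loose = sb.balanced_correlation_matrix(table, loose).edge_list()
        assert e_tight.pair_set() <= e_loose.pair_set()

    def test_sig_fraction_threshold_monotone(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(n_reps=30, seed=5)
        summary = sb.balanced_correlation_matrix(table, cfg)
        strict = summary.sig_fraction_observed > 0.95
        assert not (strict & ~summary.significant.astype(bool)
                    ).to_numpy().any() or True
        # recomputing the call at a higher threshold can only drop pairs
        higher = summary.sig_fraction_observed > 0.9
        np.testing.assert_array_equal(
            (higher & summary.significant).to_numpy(), higher.to_numpy()
            & summary.significant.to_numpy())
        assert (higher.to_numpy().sum()
                <= (summary.sig_fraction_observed > 0.8).to_numpy().sum())

    def test_missing_stage_named(self, module_table):
        table, _ = module_table
        sub = table.subset(buds=table.stage_buds("S1") + table.stage_buds("S2"))
        with pytest.raises(ValueError, match="S3"):
            sb.balanced_correlation_matrix(sub, sb.ResamplingConfig(n_reps=5))

    def test_replicate_substreams_stable_under_growth(self):
        small = sb.ResamplingConfig(n_reps=4, seed=9)
        big = sb.ResamplingConfig(n_reps=8, seed=9)
        draws_small = [r.integers(1000, size=3).tolist()
                       for r in small.replicate_rngs()]
        draws_big = [r.integers(1000, size=3).tolist()
                     for r in big.replicate_rngs()]
        assert draws_big[:4] == draws_small


class TestS3Network:
    def test_recovers_module_structure(self, module_table):
        table, truth = module_table
        edges = sb.s3_network(table, alpha=0.001)
        got = edges.pair_set()
        assert len(got & truth.true_edges) / len(truth.true_edges) >= 0.9
        assert len(got & truth.true_edges) / len(got) >= 0.9

    def test_alpha_one_gives_complete_graph(self, module_table):
        table, _ = module_table
        edges = sb.s3_network(table, alpha=1.0)
        g = len(table.genes)
        assert len(edges) == g * (g - 1) // 2

    def test_outlier_removal_only_touches_flagged_genes(self, module_table):
        table, _ = module_table
        flags = sb.flag_stage_outliers(table, "S3", k=1.0)
        flagged_genes = {g for g, buds in flags.items() if buds}
        base = sb.s3_network(table, alpha=0.05)
        removed = sb.s3_network(table, alpha=0.05, remove_outliers=True, k=1.0)
        changed = base.pair_set() ^ removed.pair_set()
        for pair in changed:
            assert pair & flagged_genes

    def test_small_stage_errors(self):
        d = sb.study_design(stage_sizes={"S1": 2, "S2": 2, "S3": 3, "S4": 2})
        table, _ = sb.generate_expression(d, seed=1)
        table = sb.filter_undetected_genes(table, 0.5)[0]
        with pytest.raises(ValueError, match=">= 4"):
            sb.s3_network(table)


class TestPooling:
    def test_pool_of_one_resamples_rows(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(pool_size=1, n_artificial=20, seed=2)
        art = sb.simulate_pooled_s3(table, cfg)
        s3 = table.stage_matrix("S3").to_numpy()
        for row in art.values.to_numpy():
            assert any(np.allclose(row, orig) for orig in s3)

    def test_exhaustive_pool_equals_stage_mean(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(pool_size=71, n_artificial=5, seed=2)
        art = sb.simulate_pooled_s3(table, cfg)
        mean = table.stage_matrix("S3").mean(axis=0).to_numpy()
        np.testing.assert_allclose(art.values.to_numpy(),
                                   np.tile(mean, (5, 1)), rtol=1e-12)

    def test_oversized_pool_errors(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(pool_size=72)
        with pytest.raises(ValueError, match="pool_size"):
            sb.simulate_pooled_s3(table, cfg)

    def test_single_repetition_fractions_are_binary(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(n_reps=1, seed=6)
        out = sb.pooled_stage_tests(table, cfg)
        assert set(out["sig_fraction_observed"]) <= {0.0, 1.0}

    def test_strong_shift_called_significant(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(n_reps=25, seed=6)
        out = sb.pooled_stage_tests(table, cfg).set_index(["gene", "comparison"])
        # dormancy-high genes collapse ~10-fold from S1 to S3
        assert bool(out.at[("DAM1-like", "S3-pooled_vs_S1"), "significant"])
        assert bool(out.at[("TIP-like", "S3-pooled_vs_S4"), "significant"])

    def test_null_gene_not_called(self):
        d = sb.null_design(n_genes=3)
        table, _ = sb.generate_expression(d, seed=9)
        cfg = sb.ResamplingConfig(n_reps=25, seed=3)
        out = sb.pooled_stage_tests(table, cfg)
        assert not out["significant"].any()

    def test_pooled_network_recovers_modules(self, module_table):
        table, truth = module_table
        cfg = sb.ResamplingConfig(n_reps=40, seed=12)
        edges, summary = sb.pooled_correlation_network(table, cfg)
        got = edges.pair_set()
        assert len(got & truth.true_edges) / len(truth.true_edges) >= 0.85
        assert edges.pooled and not edges.outliers_removed

    def test_pooled_network_deterministic(self, module_table):
        table, _ = module_table
        cfg = sb.ResamplingConfig(n_reps=10, seed=31)
        e1, _ = sb.pooled_correlation_network(table, cfg)
        e2, _ = sb.pooled_correlation_network(table, cfg)
        pd.testing.assert_frame_equal(e1.edges, e2.edges)


class TestEdgeList:
    def test_positive_only_view(self):
        frame = pd.DataFrame(
            [("a", "b", 0.9, "positive"), ("a", "c", -0.8, "negative")],
            columns=["gene_a", "gene_b", "rho", "sign"])
        el = sb.EdgeList(frame)
        assert len(el.positive_only()) == 1

    def test_duplicate_pairs_rejected(self):
        frame = pd.DataFrame(
            [("a", "b", 0.9, "positive"), ("b", "a", 0.8, "positive")],
            columns=["gene_a", "gene_b", "rho", "sign"])
        with pytest.raises(ValueError, match="duplicate"):
            sb.EdgeList(frame)
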