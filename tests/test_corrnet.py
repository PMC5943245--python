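import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coexwire import corrnet
from coexwire.data_io import GeneSet
from conftest import make_matrix
import oracles


CRIT = corrnet.StrongEdgeCriteria()


class TestPairwiseCorrelations:
    def test_duplicated_gene_perfectly_correlated(self, rng):
        base = rng.standard_normal(15)
        m = make_matrix(np.vstack([base, base, rng.standard_normal(15)]))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        assert net.r.loc["G001", "G002"] == pytest.approx(1.0)
        assert net.p.loc["G001", "G002"] == 0.0

    def test_negated_gene_anticorrelated(self, rng):
        base = rng.standard_normal(15)
        m = make_matrix(np.vstack([base, -base]))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        assert net.r.loc["G001", "G002"] == pytest.approx(-1.0)

    @pytest.mark.parametrize("method,oracle", [
        ("pearson", oracles.pearson_scalar),
        ("spearman", oracles.spearman_scalar),
    ])
    def test_matches_scalar_oracle(self, rng, method, oracle):
        m = make_matrix(rng.standard_normal((5, 20)))
        net = corrnet.pairwise_correlations(m, method=method, min_pair_n=3)
        for a in range(5):
            for b in range(a + 1, 5):
                ga, gb = f"G{a + 1:03d}", f"G{b + 1:03d}"
                r_exp, p_exp = oracle(m.values.loc[ga], m.values.loc[gb])
                assert net.r.loc[ga, gb] == pytest.approx(r_exp, abs=1e-12)
                assert net.p.loc[ga, gb] == pytest.approx(p_exp, rel=1e-9)

    def test_edge_count_invariant(self, random_matrix):
        net = corrnet.pairwise_correlations(random_matrix)
        e = net.edges()
        g = net.n_genes
        assert len(e) == g * (g - 1) // 2 == net.n_pairs

    def test_missing_pairs_marked_not_fabricated(self, rng):
        vals = rng.standard_normal((3, 20))
        vals[0, 5:] = np.nan  # G001 observed on 5 samples only
        m = make_matrix(vals)
        net = corrnet.pairwise_correlations(m, min_pair_n=10)
        assert np.isnan(net.r.loc["G001", "G002"])
        assert np.isnan(net.p.loc["G001", "G002"])
        assert not np.isnan(net.r.loc["G002", "G003"])
        # the missing pair still has its slot in the edge table
        assert len(net.edges()) == 3

    def test_zero_variance_genes_excluded_with_report(self, rng):
        vals = rng.standard_normal((4, 12))
        vals[2, :] = 3.14
        m = make_matrix(vals)
        with pytest.warns(UserWarning, match="G003"):
            net = corrnet.pairwise_correlations(m)
        assert net.excluded_genes == ["G003"]
        assert "G003" not in net.genes

    def test_too_few_samples_rejected(self, rng):
        m = make_matrix(rng.standard_normal((4, 12)))
        with pytest.raises(ValueError):
            corrnet.pairwise_correlations(m, sample_ids=m.sample_ids[:2])


class TestStrongEdges:
    def _net_from_pairs(self, pairs):
        """Build a tiny network with prescribed (r, p) per pair."""
        genes = sorted({g for a, b, *_ in pairs for g in (a, b)})
        idx = pd.Index(genes, name="gene")
        r = pd.DataFrame(np.eye(len(genes)), index=idx, columns=idx)
        p = pd.DataFrame(np.zeros((len(genes), len(genes))), index=idx, columns=idx)
        n = pd.DataFrame(30, index=idx, columns=idx)
        for a, b, rv, pv in pairs:
            r.loc[a, b] = r.loc[b, a] = rv
            p.loc[a, b] = p.loc[b, a] = pv
        return corrnet.CorrelationNetwork(genes, [f"S{i}" for i in range(30)],
                                          "pearson", r, p, n)

    def test_paper_cutoff_semantics(self):
        net = self._net_from_pairs([
            ("A", "B", 0.6, 1e-4),   # kept: passes both cuts
            ("A", "C", 0.6, 0.01),   # dropped: p too large
            ("B", "C", 0.4, 1e-6),   # dropped: |r| too small
            ("A", "D", -0.7, 1e-5),  # kept: negative strong correlation
            ("B", "D", 0.5, 0.001),  # kept: boundary values are inclusive
            ("C", "D", 0.0, 1.0),
        ])
        e = corrnet.strong_edges(net, CRIT)
        assert list(map(tuple, e[["gene_a", "gene_b"]].values)) == [
            ("A", "B"), ("A", "D"), ("B", "D")
        ]

    def test_all_zero_network_empty(self):
        net = self._net_from_pairs([("A", "B", 0.0, 1.0), ("A", "C", 0.0, 1.0),
                                    ("B", "C", 0.0, 1.0)])
        assert corrnet.count_strong(net, CRIT) == 0

    def test_matches_naive_filter_loop(self, rng):
        m = make_matrix(rng.standard_normal((10, 25)))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        crit = corrnet.StrongEdgeCriteria(0.2, 0.05)
        got = corrnet.strong_edges(net, crit)
        expected = oracles.naive_strong_filter(net.edges(), 0.2, 0.05)
        assert list(map(tuple, got[["gene_a", "gene_b"]].values)) == expected
        assert corrnet.count_strong(net, crit) == len(expected)

    def test_count_strong_monotone_in_criteria(self, rng):
        m = make_matrix(rng.standard_normal((12, 20)))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        counts_r = [
            corrnet.count_strong(net, corrnet.StrongEdgeCriteria(r, 0.5))
            for r in (0.1, 0.3, 0.5, 0.7)
        ]
        assert counts_r == sorted(counts_r, reverse=True)
        counts_p = [
            corrnet.count_strong(net, corrnet.StrongEdgeCriteria(0.1, p))
            for p in (0.5, 0.1, 0.01)
        ]
        assert counts_p == sorted(counts_p, reverse=True)

    def test_identical_genes_count_all_pairs(self):
        base = np.arange(10, dtype=float)
        m = make_matrix(np.vstack([base] * 5))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        assert corrnet.count_strong(net, CRIT) == 10  # C(5,2)


class TestFastScorer:
    def test_threshold_equivalence_with_full_route(self, rng):
        for _ in range(5):
            x = rng.standard_normal((8, 15)) + rng.standard_normal((1, 15))
            m = make_matrix(x)
            net = corrnet.pairwise_correlations(m, min_pair_n=3)
            crit = corrnet.StrongEdgeCriteria(0.3, 0.05)
            assert corrnet.strong_count_complete(x, crit) == corrnet.count_strong(
                net, crit
            )

    def test_zero_variance_rows_not_counted(self):
        x = np.vstack([np.arange(10.0), np.arange(10.0), np.full(10, 2.0)])
        # constant row yields NaN correlations in the fast path, excluded
        assert corrnet.strong_count_complete(x, CRIT) == 1

    def test_r_threshold_reduces_to_r_min_at_large_n(self):
        assert corrnet.r_threshold(113, CRIT) == pytest.approx(0.5)
        assert corrnet.r_threshold(20, CRIT) > 0.5  # significance binds at small n


class TestHistogram:
    def test_bins_resolve_the_half_cut(self):
        h = corrnet.make_histogram(np.array([0.49, 0.51]))
        assert 0.5 in h.bin_edges and -0.5 in h.bin_edges
        assert h.frequencies.sum() == pytest.approx(1.0)

    def test_counts_land_in_correct_bins(self):
        h = corrnet.make_histogram(np.array([-0.99, 0.0, 0.99]), normalized=False)
        assert h.frequencies.sum() == 3


class TestRandomGenesetNull:
    def test_deterministic_under_seed(self, rng):
        m = make_matrix(rng.standard_normal((30, 25)))
        h1, c1 = corrnet.random_geneset_null(m, None, 8, 5, CRIT, seed=42,
                                             min_pair_n=3)
        h2, c2 = corrnet.random_geneset_null(m, None, 8, 5, CRIT, seed=42,
                                             min_pair_n=3)
        assert np.array_equal(c1, c2)
        assert np.array_equal(h1.frequencies, h2.frequencies)

    def test_whole_matrix_set_reproduces_own_histogram(self, rng):
        m = make_matrix(rng.standard_normal((10, 25)))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        own = corrnet.make_histogram(net.r_values())
        h, _ = corrnet.random_geneset_null(m, None, 10, 1, CRIT, seed=0,
                                           min_pair_n=3)
        assert np.allclose(h.frequencies, own.frequencies)

    def test_set_size_too_large_rejected(self, rng):
        m = make_matrix(rng.standard_normal((10, 25)))
        with pytest.raises(ValueError):
            corrnet.random_geneset_null(m, None, 11, 2, CRIT, seed=0)

    def test_type_one_error_calibration_on_noise(self):
        # at n=30 the p <= 0.001 cut implies |r| >= r_crit > 0.5, so the
        # expected strong count per 20-gene set is ~ C(20,2) * 0.001
        rng = np.random.default_rng(7)
        m = make_matrix(rng.standard_normal((60, 30)))
        _, counts = corrnet.random_geneset_null(m, None, 20, 60, CRIT, seed=1,
                                                min_pair_n=3)
        expected = 190 * 0.001
        se = np.sqrt(expected / len(counts))  # Poisson-ish Monte-Carlo SE
        assert counts.mean() <= expected + 3 * se + 0.05


class TestKSCompare:
    def test_identical_samples_d_zero(self, rng):
        s = rng.standard_normal(50)
        d, p = corrnet.ks_compare(s, s)
        assert d == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_disjoint_supports_d_one(self, rng):
        d, _ = corrnet.ks_compare(rng.uniform(-1, -0.5, 40), rng.uniform(0.5, 1, 40))
        assert d == pytest.approx(1.0)

    def test_matches_ecdf_oracle(self, rng):
        s1, s2 = rng.standard_normal(40), rng.standard_normal(60) + 0.3
        d, _ = corrnet.ks_compare(s1, s2)
        assert d == pytest.approx(oracles.ecdf_ks_statistic(s1, s2))

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            corrnet.ks_compare(np.array([]), np.array([1.0]))


class TestSubsampling:
    def test_full_size_subsample_sd_zero(self, rng):
        m = make_matrix(rng.standard_normal((8, 15)))
        full = corrnet.count_strong(
            corrnet.pairwise_correlations(m, min_pair_n=3), CRIT
        )
        s = corrnet.subsample_strong_counts(m, m.sample_ids, 15, 10, CRIT, seed=0,
                                            min_pair_n=3)
        assert s.sd_strong == 0.0
        assert s.mean_strong == full

    def test_single_subsample_flagged(self, rng):
        m = make_matrix(rng.standard_normal((8, 15)))
        s = corrnet.subsample_strong_counts(m, m.sample_ids, 10, 1, CRIT, seed=0,
                                            min_pair_n=3)
        assert not s.sd_defined and s.sd_strong == 0.0
        assert s.mean_strong == s.counts[0]

    def test_matches_independent_resampling_loop(self, rng):
        # planted correlations: one shared factor over half the genes
        factor = rng.standard_normal(40)
        vals = np.vstack(
            [0.9 * factor + 0.3 * rng.standard_normal(40) for _ in range(6)]
            + [rng.standard_normal(40) for _ in range(6)]
        )
        m = make_matrix(vals)
        seed, size, reps = 11, 20, 25
        s = corrnet.subsample_strong_counts(m, m.sample_ids, size, reps, CRIT, seed)
        # independent loop on the same seed stream and a naive per-pair count
        rng2 = np.random.default_rng(seed)
        expected = []
        for _ in range(reps):
            idx = rng2.choice(40, size=size, replace=False)
            cnt = 0
            for a in range(12):
                for b in range(a + 1, 12):
                    r, p = oracles.pearson_scalar(vals[a, idx], vals[b, idx])
                    if abs(r) >= 0.5 and p <= 0.001:
                        cnt += 1
            expected.append(cnt)
        assert list(s.counts) == expected

    def test_oversized_subsample_rejected(self, rng):
        m = make_matrix(rng.standard_normal((5, 10)))
        with pytest.raises(ValueError):
            corrnet.subsample_strong_counts(m, m.sample_ids, 11, 2, CRIT, seed=0)


class TestExports:
    def test_edge_table_and_sif(self, tmp_path, rng):
        base = rng.standard_normal(20)
        m = make_matrix(np.vstack([base, base + 0.1 * rng.standard_normal(20),
                                   rng.standard_normal(20)]))
        net = corrnet.pairwise_correlations(m, min_pair_n=3)
        corrnet.write_edge_table(net, CRIT, tmp_path / "edges.tsv")
        e = pd.read_csv(tmp_path / "edges.tsv", sep="\t", comment="#")
        assert set(e.columns) == {"gene_a", "gene_b", "r", "p", "n", "is_strong"}
        assert e["is_strong"].sum() == corrnet.count_strong(net, CRIT)
        corrnet.write_sif(net, CRIT, tmp_path / "edges.sif")
        lines = (tmp_path / "edges.sif").read_text().strip().splitlines()
        assert len(lines) == corrnet.count_strong(net, CRIT)
        assert all(len(l.split("\t")) == 3 for l in lines)
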