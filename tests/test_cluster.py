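"""Tandem pair/cluster construction, summaries and density analysis."""

import numpy as np
import pandas as pd
import pytest

from tandemscape.genome_io import GeneModel, assign_ranks
from tandemscape.homology import HomologyHit
from tandemscape.tdg_cluster import (
    build_clusters,
    build_pairs,
    cluster_summary,
    density_model,
    merge_intervals,
    windowed_density,
)


def _genes(n, chrom="chr01"):
    return assign_ranks(
        [
            GeneModel(gene_id=f"g{i}", genotype="A", chromosome=chrom,
                      start=1 + 2000 * i, end=1500 + 2000 * i, strand="+", rank=-1,
                      cds="ATGAAATAA", protein="MK", located=True)
            for i in range(n)
        ]
    )


def _hit(a, b):
    return HomologyHit(gene_a=a, gene_b=b, raw_score=600, bit_score=500,
                       bit_score_ratio=1.0, evalue=0.0, coverage_a=1.0, coverage_b=1.0)


class TestBuildPairs:
    @pytest.mark.parametrize(
        "rank_b,expected_intervening,kept",
        [(7, 1, True), (16, 10, True), (17, 11, False)],
    )
    def test_intervening_boundary(self, rank_b, expected_intervening, kept):
        genes = _genes(20)
        pairs = build_pairs([_hit("g5", f"g{rank_b}")], genes)
        if kept:
            assert len(pairs) == 1 and pairs[0].n_intervening == expected_intervening
        else:
            assert pairs == []

    def test_monotone_in_max_intervening(self):
        genes = _genes(30)
        hits = [_hit("g0", f"g{j}") for j in range(1, 30)]
        prev = -1
        for cap in range(0, 15):
            n = len(build_pairs(hits, genes, max_intervening=cap))
            assert n >= prev
            prev = n


class TestBuildClusters:
    def test_transitive_pairs_form_one_cluster(self):
        genes = _genes(5)
        pairs = build_pairs([_hit("g0", "g1"), _hit("g1", "g2")], genes)
        clusters = build_clusters(pairs, genes)
        assert len(clusters) == 1
        assert clusters[0].member_genes == ["g0", "g1", "g2"]
        assert clusters[0].size == 3
        assert all(p.cluster_id == clusters[0].cluster_id for p in pairs)

    def test_two_disjoint_planted_clusters_recovered(self, fixture_result):
        clusters_a = fixture_result.genotypes["A"].clusters
        assert len(clusters_a) == 2  # the 11-intervening homolog pair is rejected
        sizes = sorted(c.size for c in clusters_a)
        assert sizes == [2, 3]

    def test_genes_in_at_most_one_cluster(self, fixture_result):
        for res in fixture_result.genotypes.values():
            seen = [g for c in res.clusters for g in c.member_genes]
            assert len(seen) == len(set(seen))
            assert sum(c.size for c in res.clusters) == \
                res.summary["n_genes_in_clusters"]


class TestClusterSummary:
    def test_percentages_from_counts(self):
        genes = _genes(10)
        pairs = build_pairs([_hit("g0", "g1")], genes)
        clusters = build_clusters(pairs, genes)
        summary = cluster_summary(clusters, genes, pairs)
        assert summary["n_genes_in_clusters"] == 2
        assert summary["pct_genes_in_clusters"] == 20.00
        assert summary["pct_clusters_two_genes"] == 100.00
        assert summary["intervening_histogram"] == {0: 1}

    def test_empty_input(self):
        summary = cluster_summary([], _genes(5), [])
        assert summary["n_clusters"] == 0
        assert summary["pct_genes_in_clusters"] == 0.0
        assert summary["size_histogram"] == {}


class TestWindowedDensity:
    def test_single_gene_fraction(self):
        df = windowed_density(
            {"tdg": [("chr01", 100_001, 300_000)]}, {"chr01": 1_000_000}
        )
        assert len(df) == 1
        assert df.loc[0, "tdg"] == pytest.approx(0.2)

    def test_overlapping_intervals_merged(self):
        df = windowed_density(
            {"x": [("chr01", 1, 100_000), ("chr01", 50_001, 150_000)]},
            {"chr01": 1_000_000},
        )
        assert df.loc[0, "x"] == pytest.approx(0.15)
        assert merge_intervals([(1, 100_000), (50_001, 150_000)]) == [(1, 150_000)]

    def test_uniform_features_give_constant_density(self):
        intervals = [("chr01", 1 + k * 100_000, 20_000 + k * 100_000) for k in range(50)]
        df = windowed_density({"x": intervals}, {"chr01": 5_000_000})
        assert np.allclose(df["x"], 0.2)

    def test_feature_beyond_chromosome_end_errors(self):
        with pytest.raises(ValueError, match="outside"):
            windowed_density({"x": [("chr01", 1, 2_000_000)]}, {"chr01": 1_000_000})


class TestDensityModel:
    def _track(self, y, cov=None):
        df = pd.DataFrame({
            "chromosome": "chr01",
            "window_start": np.arange(len(y)) * 1_000_000,
            "window_end": (np.arange(len(y)) + 1) * 1_000_000,
            "tdg": y,
        })
        if cov is not None:
            df["genes"] = cov
        return df

    def test_zero_variance_residuals_flagged_degenerate(self):
        y = np.linspace(0.1, 0.5, 20)
        res = density_model(self._track(y, cov=y), covariate_cols=["genes"])
        assert res.degenerate
        assert res.ks_D == 1.0
        assert res.pearson_r["genes"] == pytest.approx(1.0)

    def test_equally_spaced_grid_matches_closed_form(self):
        n = 21
        y = np.linspace(0.0, 1.0, n)
        rng = np.random.default_rng(0)
        y = y[rng.permutation(n)]  # order must not matter for the KS statistic
        res = density_model(self._track(y), covariate_cols=[])
        # residuals scale back to the grid i/(n-1); closed-form one-sample KS
        grid = np.sort((y - y.mean() - (y - y.mean()).min())
                       / np.ptp(y - y.mean()))
        d_oracle = max(
            max((i + 1) / n - grid[i], grid[i] - i / n) for i in range(n)
        )
        assert res.ks_D == pytest.approx(d_oracle)
        assert res.ks_D < 0.1

    def test_concentrated_features_give_large_D(self):
        rng = np.random.default_rng(1)
        n = 100
        y = np.zeros(n)
        y[:10] = rng.uniform(0.5, 0.9, 10)  # all TDGs in 10% of windows
        cov = rng.uniform(0.2, 0.4, n)
        res = density_model(self._track(y, cov=cov), covariate_cols=["genes"])
        assert res.ks_D > 0.3

    def test_too_few_windows_errors(self):
        with pytest.raises(ValueError, match="fewer windows"):
            density_model(self._track([0.1, 0.2], cov=[0.1, 0.3]),
                          covariate_cols=["genes"])
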