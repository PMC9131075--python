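"""Cross-genotype category calls, positional profiles, correlations, fates."""

import math

import numpy as np
import pandas as pd
import pytest

from tandemscape.comparative import (
    call_fate,
    call_fates,
    categorize_clusters,
    divergence_correlations,
    positional_profile,
)
from tandemscape.genome_io import GeneModel
from tandemscape.tdg_cluster import TDGCluster


def _cluster(cid, genotype, members, chrom="chr01"):
    return TDGCluster(cluster_id=cid, genotype=genotype, chromosome=chrom,
                      member_genes=list(members))


class TestCategorize:
    def _setup(self):
        genotypes = ["A", "B", "C", "D"]
        clusters = {
            gt: [_cluster(f"{gt}:c1", gt, [f"{gt}_x1", f"{gt}_x2"])]
            for gt in genotypes
        }
        clusters["A"].append(_cluster("A:c2", "A", ["A_y1", "A_y2"]))
        clusters["A"].append(_cluster("A:c3", "A", ["A_z1", "A_z2"]))
        clusters["B"].append(_cluster("B:c3", "B", ["B_z1", "B_z2"]))
        gene_to_og = {}
        for gt in genotypes:
            gene_to_og.update({f"{gt}_x1": "OGX", f"{gt}_x2": "OGX"})
        gene_to_og.update({"A_y1": "OGY", "A_y2": "OGY"})
        gene_to_og.update({"A_z1": "OGZ", "A_z2": "OGZ", "B_z1": "OGZ", "B_z2": "OGZ"})
        return genotypes, clusters, gene_to_og

    def test_core_shared_private(self):
        genotypes, clusters, gene_to_og = self._setup()
        cats = categorize_clusters(clusters, gene_to_og, genotypes)
        by_id = {c.cluster_id: c.category for c in cats}
        assert by_id["A:c1"] == "core"  # OGX clustered in all four
        assert by_id["A:c2"] == "private"  # OGY only in A
        assert by_id["A:c3"] == "shared" and by_id["B:c3"] == "shared"

    def test_category_partition(self):
        genotypes, clusters, gene_to_og = self._setup()
        cats = categorize_clusters(clusters, gene_to_og, genotypes)
        annotated = [c for c in cats if c.category != "unset"]
        assert len(annotated) == sum(len(v) for v in clusters.values())
        counts = pd.Series([c.category for c in annotated]).value_counts()
        assert counts.sum() == len(annotated)

    def test_cluster_without_og_is_unset(self):
        clusters = {"A": [_cluster("A:c1", "A", ["orphan1", "orphan2"])]}
        (cat,) = categorize_clusters(clusters, {}, ["A"])
        assert cat.category == "unset"

    def test_planted_partition_recovered_exactly(self, small_sim):
        from tandemscape.pipeline import RunConfig, run_pipeline

        res = run_pipeline(small_sim, RunConfig(seed=5))
        truth = small_sim.truth.clusters
        detected = res.categories
        by_members = {}
        for gt, gres in res.genotypes.items():
            for c in gres.clusters:
                by_members[",".join(c.member_genes)] = c.category
        for row in truth.itertuples(index=False):
            assert by_members.get(row.members) == row.category, row


class TestPositional:
    def test_midpoint_normalisation(self):
        genes = {
            "g1": GeneModel(gene_id="g1", genotype="A", chromosome="chr01",
                            start=49_000_001, end=49_999_999, strand="+", rank=0,
                            cds="ATGTAA", protein="M"),
            "g2": GeneModel(gene_id="g2", genotype="A", chromosome="chr01",
                            start=50_000_003, end=51_000_001, strand="+", rank=1,
                            cds="ATGTAA", protein="M"),
        }
        cl = _cluster("c1", "A", ["g1", "g2"])
        prof = positional_profile([cl], {"c1": "private"}, genes,
                                 {"chr01": 100_000_000})
        assert prof["positions"]["private"][0]["position"] == pytest.approx(0.5, abs=1e-6)

    def test_planted_pericentromeric_bias_detected(self):
        rng = np.random.default_rng(0)
        genes, clusters, cats = {}, [], {}
        length = 100_000_000
        for i in range(40):
            private = i < 20
            # private near the middle (centromere), others near the arms
            pos = rng.uniform(0.42, 0.58) if private else rng.uniform(0.0, 0.15)
            if not private and rng.random() < 0.5:
                pos = 1.0 - pos
            start = int(pos * length) + 1
            gid = f"g{i}"
            genes[gid] = GeneModel(gene_id=gid, genotype="A", chromosome="chr01",
                                   start=start, end=start + 10_000, strand="+",
                                   rank=i, cds="ATGTAA", protein="M")
            cid = f"c{i}"
            clusters.append(_cluster(cid, "A", [gid]))
            cats[cid] = "private" if private else "core"
        prof = positional_profile(clusters, cats, genes, {"chr01": length},
                                  centromeres={"chr01": length // 2})
        assert prof["mannwhitney_p"] < 0.05

    def test_fallback_without_centromeres(self):
        genes = {"g1": GeneModel(gene_id="g1", genotype="A", chromosome="chr01",
                                 start=1, end=1000, strand="+", rank=0,
                                 cds="ATGTAA", protein="M")}
        prof = positional_profile([_cluster("c1", "A", ["g1"])], {"c1": "core"},
                                  genes, {"chr01": 1_000_000})
        assert prof["positions"]["core"][0]["centromere_distance"] == pytest.approx(
            abs(prof["positions"]["core"][0]["position"] - 0.5)
        )


class TestCorrelations:
    def test_identical_columns_give_r_one(self):
        vals = np.linspace(0.1, 0.9, 30)
        df = pd.DataFrame({"expr_r": vals, "ps": vals, "ks": np.linspace(2, 1, 30),
                           "omega": np.linspace(0.1, 0.4, 30)})
        out = divergence_correlations(df)
        row = out[(out.x == "expr_r") & (out.y == "ps")].iloc[0]
        assert row.r == pytest.approx(1.0)

    def test_planted_negative_coupling_recovered(self):
        rng = np.random.default_rng(1)
        ks = rng.uniform(0.1, 1.5, 500)
        ps = np.clip(0.9 - 0.3 * ks + rng.normal(0, 0.15, 500), 0, 1)
        df = pd.DataFrame({"expr_r": rng.uniform(-1, 1, 500), "ps": ps, "ks": ks,
                           "omega": rng.uniform(0, 2, 500)})
        out = divergence_correlations(df)
        row = out[(out.x == "ps") & (out.y == "ks")].iloc[0]
        assert row.r < -0.2
        assert row.p < 1e-6

    def test_shuffled_columns_near_zero(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame({c: rng.uniform(size=800)
                           for c in ("expr_r", "ps", "ks", "omega")})
        out = divergence_correlations(df)
        assert (out.r.abs() < 0.12).all()

    def test_too_few_pairs_undefined(self):
        df = pd.DataFrame({"expr_r": [0.1, 0.2], "ps": [0.3, 0.4],
                           "ks": [np.nan, np.nan], "omega": [0.5, 0.6]})
        out = divergence_correlations(df)
        assert math.isnan(out[(out.x == "ps") & (out.y == "ks")].iloc[0].r)


class TestFates:
    D1 = frozenset({"NB-ARC"})
    D2 = frozenset({"NB-ARC", "LRR"})

    @pytest.mark.parametrize(
        "diverged,omega,da,db,expected",
        [
            (True, 0.3, D1, D1, "sub_functionalization"),
            (False, 0.4, D1, D1, "genetic_redundancy"),
            (True, 1.5, D1, D2, "neo_functionalization"),
            (False, 1.5, D1, D2, "neo_functionalization"),  # rule precedence
            (True, 1.5, D1, D1, "unclassified"),
            (True, 0.3, D1, D2, "unclassified"),
        ],
    )
    def test_decision_rules(self, diverged, omega, da, db, expected):
        assert call_fate(diverged, omega, da, db).fate == expected

    def test_missing_inputs_unclassified(self):
        assert call_fate(None, 0.3, self.D1, self.D1).reason == "missing input"
        call = call_fate(True, None, self.D1, self.D1)
        assert call.fate == "unclassified"
        assert "omega" in call.reason

    def test_calls_are_exclusive_and_exhaustive(self):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(300):
            rows.append({
                "pair_id": f"p{i}", "genotype": "A",
                "expr_diverged": bool(rng.random() < 0.5),
                "omega": float(rng.uniform(0, 2)),
                "domains_a": self.D1,
                "domains_b": self.D1 if rng.random() < 0.7 else self.D2,
            })
        calls = call_fates(pd.DataFrame(rows))
        assert len(calls) == 300
        valid = {"sub_functionalization", "genetic_redundancy",
                 "neo_functionalization", "unclassified"}
        assert {c.fate for c in calls} <= valid

    def test_planted_fates_recovered(self, fixture_result, fixture_bundle):
        master = fixture_result.master.set_index(["gene_a", "gene_b"])
        for row in fixture_bundle.truth.pairs.itertuples(index=False):
            key = (row.gene_a, row.gene_b)
            if key in master.index:
                assert master.loc[key, "fate"] == row.expected_fate
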