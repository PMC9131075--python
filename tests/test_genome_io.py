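"""Input assembly, rank bookkeeping and the TE-orthogroup filter."""

import warnings

import pytest

from tandemscape import genome_io
from tandemscape.genome_io import (
    GeneModel,
    Orthogroup,
    classify_te_orthogroups,
    load_genotype,
    non_te_located_genes,
    propagate_te_flags,
    read_gene_table,
    write_gene_table,
)


def _gene(gid, start, end=None, chrom="chr01", is_te=False, located=True,
          ahrd=3, genotype="A"):
    return GeneModel(
        gene_id=gid, genotype=genotype, chromosome=chrom, start=start,
        end=end or start + 299, strand="+", rank=-1, cds="ATG" + "AAA" * 99,
        protein="M" + "K" * 99, is_te=is_te, ahrd_score=ahrd, located=located,
    )


class TestLoadGenotype:
    def test_fixture_roundtrip_counts_and_ranks(self, fixture_bundle, fixture_dir):
        gdir = fixture_dir / "A"
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            genes = load_genotype(
                gdir / "genes.gff3", gdir / "cds.fa", gdir / "protein.fa",
                gdir / "annotation.tsv", genotype="A",
            )
        assert len(genes) == len(fixture_bundle.genotypes["A"].genes)
        located = sorted(
            (g for g in genes if g.located), key=lambda g: (g.chromosome, g.start)
        )
        # ranks are a permutation of 0..n-1 per chromosome, monotone in start
        by_chrom = {}
        for g in located:
            by_chrom.setdefault(g.chromosome, []).append(g)
        for glist in by_chrom.values():
            assert [g.rank for g in glist] == list(range(len(glist)))
        # unplaced scaffold gene excluded from rank assignment
        unplaced = [g for g in genes if not g.located]
        assert unplaced and all(g.rank == -1 for g in unplaced)
        # models match what the generator built
        truth = {g.gene_id: g for g in fixture_bundle.genotypes["A"].genes}
        for g in genes:
            assert g.cds == truth[g.gene_id].cds
            assert g.protein == truth[g.gene_id].protein
            assert g.is_te == truth[g.gene_id].is_te
            assert g.pfam_domains == truth[g.gene_id].pfam_domains

    def test_missing_sequence_is_hard_error(self, fixture_dir, tmp_path):
        gdir = fixture_dir / "B"
        cds = (gdir / "cds.fa").read_text().split(">")
        trimmed = ">" + ">".join(cds[2:])  # drop the first record
        bad = tmp_path / "cds.fa"
        bad.write_text(trimmed)
        with pytest.raises(ValueError, match="missing CDS/protein"):
            load_genotype(gdir / "genes.gff3", bad, gdir / "protein.fa",
                          gdir / "annotation.tsv", genotype="B")

    def test_cds_not_multiple_of_three_excluded_with_warning(self, fixture_dir, tmp_path):
        gdir = fixture_dir / "B"
        lines = (gdir / "cds.fa").read_text().splitlines()
        # truncate the first sequence line by one base
        for i, line in enumerate(lines):
            if not line.startswith(">"):
                lines[i] = line[:-1]
                break
        bad = tmp_path / "cds.fa"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.warns(UserWarning, match="not a multiple of 3"):
            genes = load_genotype(gdir / "genes.gff3", bad, gdir / "protein.fa",
                                  gdir / "annotation.tsv", genotype="B")
        full = load_genotype(gdir / "genes.gff3", gdir / "cds.fa", gdir / "protein.fa",
                             gdir / "annotation.tsv", genotype="B")
        assert len(genes) == len(full) - 1

    def test_gene_table_roundtrip(self, fixture_bundle, tmp_path):
        genes = fixture_bundle.genotypes["A"].genes
        path = tmp_path / "genes.tsv"
        write_gene_table(genes, path)
        assert read_gene_table(path) == genes


class TestTEOrthogroups:
    def test_non_te_og(self):
        genes = [_gene(f"g{i}", 1000 * (i + 1), is_te=i < 2, ahrd=2 if i < 5 else 3)
                 for i in range(10)]
        og = Orthogroup("OG1", {"A": {g.gene_id for g in genes}})
        (out,) = classify_te_orthogroups([og], genes)
        assert out.te_gene_fraction == pytest.approx(0.2)
        assert out.mean_ahrd == pytest.approx(2.5)
        assert not out.is_te_og

    def test_exactly_30pct_te_is_te_og(self):
        genes = [_gene(f"g{i}", 1000 * (i + 1), is_te=i < 3) for i in range(10)]
        og = Orthogroup("OG1", {"A": {g.gene_id for g in genes}})
        (out,) = classify_te_orthogroups([og], genes)
        assert out.te_gene_fraction == pytest.approx(0.3)
        assert out.is_te_og  # strictly-less-than rule

    def test_low_ahrd_is_te_og(self):
        genes = [_gene(f"g{i}", 1000 * (i + 1), ahrd=[1, 1, 2, 2][i]) for i in range(4)]
        og = Orthogroup("OG1", {"A": {g.gene_id for g in genes}})
        (out,) = classify_te_orthogroups([og], genes)
        assert out.mean_ahrd == pytest.approx(1.5)
        assert out.is_te_og

    def test_unknown_gene_id_is_error(self):
        genes = [_gene("g0", 1000)]
        og = Orthogroup("OG1", {"A": {"g0", "ghost"}})
        with pytest.raises(ValueError, match="ghost"):
            classify_te_orthogroups([og], genes)

    def test_propagation_and_idempotence(self):
        genes = [_gene(f"g{i}", 1000 * (i + 1), ahrd=0) for i in range(4)]
        og = Orthogroup("OG1", {"A": {g.gene_id for g in genes}})
        classify_te_orthogroups([og], genes)
        assert og.is_te_og
        marked = propagate_te_flags(genes, [og])
        assert all(g.is_te for g in marked)
        # re-applying the classification changes nothing
        classify_te_orthogroups([og], marked)
        assert og.is_te_og
        assert propagate_te_flags(marked, [og]) == marked


class TestFiltering:
    def test_te_and_unplaced_removed_ranks_recomputed(self):
        genes = genome_io.assign_ranks(
            [_gene("g0", 1000), _gene("g1", 2000, is_te=True), _gene("g2", 3000),
             _gene("g3", 4000, located=False, chrom="chrUn"), _gene("g4", 5000)]
        )
        kept = non_te_located_genes(genes)
        assert [g.gene_id for g in kept] == ["g0", "g2", "g4"]
        assert [g.rank for g in kept] == [0, 1, 2]

    def test_all_te_gives_empty(self):
        genes = [_gene(f"g{i}", 1000 * (i + 1), is_te=True) for i in range(3)]
        assert non_te_located_genes(genes) == []

    def test_planted_te_fraction_filtered(self, small_sim):
        truth = small_sim.truth.genes
        for gt, gdata in small_sim.genotypes.items():
            sub = truth[truth.genotype == gt]
            expected = int((~sub.is_te & sub.located).sum())
            assert len(non_te_located_genes(gdata.genes)) == expected
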