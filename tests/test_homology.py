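"""Local-alignment homolog detection: statistics, thresholds, invariants."""

import numpy as np
import pytest

from tandemscape.genome_io import GeneModel, assign_ranks
from tandemscape.homology import (
    HomologyThresholds,
    ScoringParams,
    align_cds,
    same_chromosome_pairs,
    self_bit_score,
)
from tandemscape.synthetic_data import mutate_seq, random_cds, random_dna


def _gene(gid, start, cds, chrom="chr01", genotype="A"):
    return GeneModel(
        gene_id=gid, genotype=genotype, chromosome=chrom, start=start,
        end=start + len(cds) - 1, strand="+", rank=-1, cds=cds,
        protein="X" * (len(cds) // 3), located=True,
    )


class TestAlignCds:
    def test_identical_sequences_full_coverage_and_unit_bsr(self):
        rng = np.random.default_rng(1)
        seq = random_dna(rng, 300)
        stats = align_cds(seq, seq)
        assert stats.coverage_a == 1.0
        assert stats.coverage_b == 1.0
        assert stats.bit_score == pytest.approx(self_bit_score(seq))
        assert stats.bit_score / self_bit_score(seq) == pytest.approx(1.0)

    def test_unrelated_random_pair_rejected_by_evalue(self):
        rng = np.random.default_rng(2)
        a, b = random_dna(rng, 300), random_dna(rng, 300)
        stats = align_cds(a, b)
        assert stats.evalue > 1e-10

    def test_prefix_alignment_coverage(self):
        rng = np.random.default_rng(3)
        long = random_dna(rng, 300)
        short = long[:120]
        stats = align_cds(long, short)
        assert stats.coverage_b == 1.0
        assert stats.coverage_a == pytest.approx(0.4)
        assert stats.coverage_a < 0.5  # fails the coverage filter

    def test_invalid_symbols_rejected(self):
        with pytest.raises(ValueError, match="non-ACGTN"):
            align_cds("ACGTX", "ACGT")

    def test_symmetry(self):
        rng = np.random.default_rng(4)
        a = random_dna(rng, 250)
        b = mutate_seq(a, 0.05, rng)
        sab, sba = align_cds(a, b), align_cds(b, a)
        assert sab.raw_score == sba.raw_score
        assert sab.bit_score == sba.bit_score
        assert sab.coverage_a == sba.coverage_b
        assert sab.coverage_b == sba.coverage_a

    def test_score_never_increases_with_extra_mismatches(self):
        rng = np.random.default_rng(5)
        a = random_dna(rng, 200)
        b = a
        prev = align_cds(a, b).raw_score
        for rate in (0.02, 0.05, 0.10, 0.20):
            b = mutate_seq(a, rate, np.random.default_rng(50))
            score = align_cds(a, b).raw_score
            assert score <= prev
            prev = score


class TestSmithWatermanOracle:
    @staticmethod
    def _reference_sw(a, b, scoring):
        """Independent Gotoh affine-gap local alignment, score only."""
        inf = float("inf")
        n, m = len(a), len(b)
        open_cost = scoring.gap_open + scoring.gap_extend
        ext = scoring.gap_extend
        best = 0.0
        H = [[0.0] * (m + 1) for _ in range(n + 1)]
        E = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
        F = [[-inf] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
        for i in range(1, n + 1):
            for j in range(1, m + 1):
                sub = scoring.match if (a[i - 1] == b[j - 1] and a[i - 1] != "N") \
                    else scoring.mismatch
                E[i][j] = max(H[i][j - 1] - open_cost, E[i][j - 1] - ext)
                F[i][j] = max(H[i - 1][j] - open_cost, F[i - 1][j] - ext)
                H[i][j] = max(0.0, H[i - 1][j - 1] + sub, E[i][j], F[i][j])
                best = max(best, H[i][j])
        return best

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_reference_on_short_pairs(self, seed):
        rng = np.random.default_rng(seed)
        scoring = ScoringParams()
        n = int(rng.integers(10, 51))
        a = random_dna(rng, n)
        b = mutate_seq(a, float(rng.uniform(0, 0.4)), rng) if rng.random() < 0.7 \
            else random_dna(rng, int(rng.integers(10, 51)))
        assert align_cds(a, b, scoring).raw_score == pytest.approx(
            self._reference_sw(a, b, scoring)
        )


class TestSameChromosomePairs:
    def _layout(self, cds_list, chrom="chr01"):
        genes = [_gene(f"g{i}", 1 + 2000 * i, cds) for i, cds in enumerate(cds_list)]
        return assign_ranks(genes)

    def test_mutated_duplicate_three_apart_retained(self):
        rng = np.random.default_rng(10)
        anc = random_cds(rng, 150)
        cds = [anc] + [random_cds(rng, 150) for _ in range(3)] + [mutate_seq(anc, 0.02, rng)]
        genes = self._layout(cds)
        hits = same_chromosome_pairs(genes)
        assert [(h.gene_a, h.gene_b) for h in hits] == [("g0", "g4")]
        assert hits[0].bit_score_ratio >= 0.30
        assert hits[0].evalue <= 1e-10

    def test_low_bit_score_ratio_rejected(self):
        rng = np.random.default_rng(11)
        anc = random_cds(rng, 300)
        # heavy truncation: only a short identical block remains
        fragment = anc[:180] + random_dna(rng, 720)
        genes = self._layout([anc, fragment])
        hits = same_chromosome_pairs(
            genes, HomologyThresholds(evalue=1.0, bsr=0.30, coverage=0.0)
        )
        assert hits == []  # bsr ~0.2 < 0.30

    def test_different_chromosomes_never_reported(self):
        rng = np.random.default_rng(12)
        anc = random_cds(rng, 150)
        genes = assign_ranks(
            [_gene("g0", 1000, anc, chrom="chr01"), _gene("g1", 1000, anc, chrom="chr02")]
        )
        assert same_chromosome_pairs(genes) == []

    def test_result_independent_of_input_order(self):
        rng = np.random.default_rng(13)
        anc = random_cds(rng, 150)
        genes = self._layout([anc, mutate_seq(anc, 0.03, rng), random_cds(rng, 150)])
        fwd = same_chromosome_pairs(genes)
        rev = same_chromosome_pairs(list(reversed(genes)))
        assert [(h.gene_a, h.gene_b) for h in fwd] == [(h.gene_a, h.gene_b) for h in rev]

    def test_prefilter_does_not_change_accepted_pairs(self, small_sim):
        genes = [g for g in small_sim.genotypes["G1"].genes if g.located and not g.is_te]
        genes = assign_ranks(genes)
        with_pf = same_chromosome_pairs(genes, prefilter=True)
        without_pf = same_chromosome_pairs(genes, prefilter=False)
        key = lambda hits: sorted((h.gene_a, h.gene_b) for h in hits)
        assert key(with_pf) == key(without_pf)
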