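"""Same-chromosome homolog detection by local CDS alignment.

Pairwise coding sequences are compared with Smith–Waterman local alignment
(BLASTN-like scoring: match +2, mismatch −3, gap open 5, extend 2) and the raw
score is converted to a bit score and e-value with Karlin–Altschul statistics
(bits = (λS − ln K)/ln 2, E = m·n·2^(−bits), λ=0.625, K=0.41). A pair of genes
is a homologous pair when

* e-value ≤ 1e−10,
* bit score ratio ≥ 30% (pair bits over the smaller self-alignment bits, so a
  sequence against itself scores exactly 1), and
* aligned coverage of both sequences ≥ 50%.

An optional shared-k-mer prefilter skips hopeless pairs in the all-vs-all scan;
it is a pure speedup and leaves accepted pairs unchanged in practice (this is
property-tested against the unfiltered scan).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GeneModel
from .utils import validate_dna


@dataclass(frozen=True)
class ScoringParams:
    match: float = 2.0
    mismatch: float = -3.0
    gap_open: float = 5.0  # cost of the first gap position is gap_open + gap_extend
    gap_extend: float = 2.0
    lam: float = 0.625
    k: float = 0.41


@dataclass(frozen=True)
class HomologyThresholds:
    evalue: float = 1e-10
    bsr: float = 0.30
    coverage: float = 0.50


@dataclass
class AlignmentStats:
    raw_score: float
    bit_score: float
    evalue: float
    coverage_a: float
    coverage_b: float


@dataclass
class HomologyHit:
    gene_a: str  # canonical: rank_a < rank_b
    gene_b: str
    raw_score: float
    bit_score: float
    bit_score_ratio: float
    evalue: float
    coverage_a: float
    coverage_b: float


from functools import lru_cache


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    alphabet = "ACGTN"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            # N against anything (including N) counts as a mismatch
            mat[x, y] = scoring.match if (x == y and x != "N") else scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def bits_from_score(raw_score: float, scoring: ScoringParams) -> float:
    return (scoring.lam * raw_score - math.log(scoring.k)) / math.log(2.0)


def evalue_from_bits(bit_score: float, m: int, n: int) -> float:
    return m * n * 2.0 ** (-bit_score)


def align_cds(cds_a: str, cds_b: str, scoring: ScoringParams | None = None) -> AlignmentStats:
    """Best local alignment of two CDS with BLAST-style statistics.

    Coverage of each sequence is the aligned span (first to last aligned base)
    divided by its length.
    """
    scoring = scoring or ScoringParams()
    a = validate_dna(cds_a, "cds_a")
    b = validate_dna(cds_b, "cds_b")
    aligner = _aligner(scoring)
    alignments = aligner.align(a, b)
    if len(a) == 0 or len(b) == 0 or alignments.score <= 0:
        return AlignmentStats(0.0, bits_from_score(0.0, scoring), math.inf, 0.0, 0.0)
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    span_a = blocks_a[-1][1] - blocks_a[0][0]
    span_b = blocks_b[-1][1] - blocks_b[0][0]
    bits = bits_from_score(alignments.score, scoring)
    return AlignmentStats(
        raw_score=float(alignments.score),
        bit_score=bits,
        evalue=evalue_from_bits(bits, len(a), len(b)),
        coverage_a=span_a / len(a),
        coverage_b=span_b / len(b),
    )


def self_bit_score(cds: str, scoring: ScoringParams | None = None) -> float:
    """Bit score of a sequence's best local alignment with itself.

    Along the main diagonal every ACGT base scores +match and every N scores
    mismatch (N never matches), so the optimum is the best-scoring contiguous
    run — a maximum-subarray problem, solved without the quadratic DP.
    """
    scoring = scoring or ScoringParams()
    best = cur = 0.0
    for ch in cds.upper():
        cur = max(0.0, cur + (scoring.match if ch != "N" else scoring.mismatch))
        best = max(best, cur)
    return bits_from_score(best, scoring)


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def shares_kmers(kmers_a: set, kmers_b: set, min_shared: int) -> bool:
    if min_shared <= 1:
        return not kmers_a.isdisjoint(kmers_b)
    if kmers_a.isdisjoint(kmers_b):
        return False
    return len(kmers_a & kmers_b) >= min_shared


def same_chromosome_pairs(
    genes: Sequence[GeneModel],
    thresholds: HomologyThresholds | None = None,
    scoring: ScoringParams | None = None,
    prefilter: bool = True,
    prefilter_k: int = 13,
    prefilter_min_shared: int = 1,
) -> list[HomologyHit]:
    """All-vs-all homolog scan within each chromosome of each genotype.

    *genes* should already be the filtered non-TE, located set with ranks
    assigned. The result is canonical (gene_a has the smaller rank) and does
    not depend on input order.
    """
    thresholds = thresholds or HomologyThresholds()
    scoring = scoring or ScoringParams()
    by_chrom: dict = {}
    for g in genes:
        if g.located and g.rank >= 0:
            by_chrom.setdefault((g.genotype, g.chromosome), []).append(g)

    hits: list[HomologyHit] = []
    for key in sorted(by_chrom):
        glist = sorted(by_chrom[key], key=lambda g: g.rank)
        self_bits = {g.gene_id: self_bit_score(g.cds, scoring) for g in glist}
        kmers = (
            {g.gene_id: _kmer_set(g.cds, prefilter_k) for g in glist} if prefilter else None
        )
        for i in range(len(glist)):
            for j in range(i + 1, len(glist)):
                ga, gb = glist[i], glist[j]
                if prefilter and not shares_kmers(
                    kmers[ga.gene_id], kmers[gb.gene_id], prefilter_min_shared
                ):
                    continue
                stats = align_cds(ga.cds, gb.cds, scoring)
                bsr = stats.bit_score / min(self_bits[ga.gene_id], self_bits[gb.gene_id])
                if (
                    stats.evalue <= thresholds.evalue
                    and bsr >= thresholds.bsr
                    and stats.coverage_a >= thresholds.coverage
                    and stats.coverage_b >= thresholds.coverage
                ):
                    hits.append(
                        HomologyHit(
                            gene_a=ga.gene_id,
                            gene_b=gb.gene_id,
                            raw_score=stats.raw_score,
                            bit_score=stats.bit_score,
                            bit_score_ratio=bsr,
                            evalue=stats.evalue,
                            coverage_a=stats.coverage_a,
                            coverage_b=stats.coverage_b,
                        )
                    )
    return hits


def read_blast_tab(
    path,
    genes: Sequence[GeneModel],
    thresholds: HomologyThresholds | None = None,
    scoring: ScoringParams | None = None,
) -> list[HomologyHit]:
    """Accept a precomputed BLAST tabular (outfmt 6) file instead of the
    internal scan.

    Expected columns: qseqid sseqid pident length mismatch gapopen qstart qend
    sstart send evalue bitscore. Bit-score ratios are computed against internal
    self-alignment bit scores of the provided gene set; only same-chromosome,
    same-genotype pairs passing the thresholds are returned.
    """
    thresholds = thresholds or HomologyThresholds()
    scoring = scoring or ScoringParams()
    by_id = {g.gene_id: g for g in genes}
    self_bits: dict = {}
    best: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            q, s = f[0], f[1]
            if q == s or q not in by_id or s not in by_id:
                continue
            ga, gb = by_id[q], by_id[s]
            if ga.genotype != gb.genotype or ga.chromosome != gb.chromosome:
                continue
            if ga.rank > gb.rank:
                ga, gb = gb, ga
                qstart, qend, sstart, send = int(f[8]), int(f[9]), int(f[6]), int(f[7])
            else:
                qstart, qend, sstart, send = int(f[6]), int(f[7]), int(f[8]), int(f[9])
            evalue, bits = float(f[10]), float(f[11])
            for g in (ga, gb):
                if g.gene_id not in self_bits:
                    self_bits[g.gene_id] = self_bit_score(g.cds, scoring)
            bsr = bits / min(self_bits[ga.gene_id], self_bits[gb.gene_id])
            cov_a = (abs(qend - qstart) + 1) / len(ga.cds)
            cov_b = (abs(send - sstart) + 1) / len(gb.cds)
            if (
                evalue <= thresholds.evalue
                and bsr >= thresholds.bsr
                and cov_a >= thresholds.coverage
                and cov_b >= thresholds.coverage
            ):
                key = (ga.gene_id, gb.gene_id)
                hit = HomologyHit(ga.gene_id, gb.gene_id, bits, bits, bsr, evalue, cov_a, cov_b)
                if key not in best or bits > best[key].bit_score:
                    best[key] = hit
    return [best[k] for k in sorted(best)]
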