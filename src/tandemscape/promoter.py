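"""Putative promoter extraction and pairwise promoter similarity.

The putative promoter of a gene is the non-overlapping 1 kb immediately
upstream of its transcription start site on the coding strand: bases
start-1000..start-1 for a + strand gene, the reverse complement of
end+1..end+1000 for a − strand gene, truncated at the chromosome boundary and
at the nearest annotated neighbouring gene (either strand). Promoters that
contain N, or are empty after truncation, are excluded.

Promoter similarity Ps of a pair is computed from the best local
(Waterman–Eggert-style) alignment with EMBOSS-matcher-like DNA scoring
(match +5, mismatch −4, gap open 16, extend 4):

    Ps = identical aligned positions / mean(len_a, len_b)

so Ps ∈ [0, 1] and Ps(x, x) = 1. Divergence calls compare Ps with the 95%
quantile of Ps over an equal number of random non-TDG gene pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genome_io import GeneModel
from .utils import revcomp, validate_dna

PROMOTER_LEN = 1000


@dataclass(frozen=True)
class PromoterScoring:
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = 16.0
    gap_extend: float = 4.0


@dataclass
class PromoterRecord:
    gene_id: str
    seq: str | None
    start: int = 0  # 1-based inclusive, genomic (before reverse complementing)
    end: int = 0
    reason: str = ""


@dataclass
class PromoterComparison:
    pair_id: str
    gene_a: str
    gene_b: str
    ps: float
    q95_null: float
    diverged: bool | None
    promoter_len_a: int = 0
    promoter_len_b: int = 0
    reason: str = ""


def extract_promoter(
    gene: GeneModel,
    chrom_seq: str,
    neighbors: Sequence[GeneModel],
    upstream: int = PROMOTER_LEN,
) -> PromoterRecord:
    """Extract the non-overlapping upstream promoter of one gene.

    *neighbors* is the list of annotated genes on the same chromosome used for
    the non-overlap truncation (the gene itself is ignored).
    """
    others = [n for n in neighbors if n.gene_id != gene.gene_id]
    if gene.strand == "+":
        upstream_ends = [n.end for n in others if n.end < gene.start]
        lo = max([1, gene.start - upstream] + [e + 1 for e in upstream_ends])
        hi = gene.start - 1
        seq = chrom_seq[lo - 1 : hi] if hi >= lo else ""
        start, end = lo, hi
    else:
        downstream_starts = [n.start for n in others if n.start > gene.end]
        lo = gene.end + 1
        hi = min([len(chrom_seq), gene.end + upstream] + [s - 1 for s in downstream_starts])
        seq = revcomp(chrom_seq[lo - 1 : hi]) if hi >= lo else ""
        start, end = lo, hi
    if not seq:
        return PromoterRecord(gene.gene_id, None, reason="zero length after truncation")
    seq = seq.upper()
    if "N" in seq:
        return PromoterRecord(gene.gene_id, None, start, end, reason="contains N")
    return PromoterRecord(gene.gene_id, seq, start, end)


from functools import lru_cache


@lru_cache(maxsize=8)
def _aligner(scoring: PromoterScoring) -> Align.PairwiseAligner:
    alphabet = "ACGT"
    mat = substitution_matrices.Array(alphabet=alphabet, dims=2)
    for x in alphabet:
        for y in alphabet:
            mat[x, y] = scoring.match if x == y else scoring.mismatch
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -scoring.gap_open
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def promoter_similarity(
    prom_a: str, prom_b: str, scoring: PromoterScoring | None = None
) -> float:
    """Identity fraction of the best local alignment, normalised by mean length."""
    scoring = scoring or PromoterScoring()
    a = validate_dna(prom_a, "prom_a")
    b = validate_dna(prom_b, "prom_b")
    aligner = _aligner(scoring)
    alignments = aligner.align(a, b)
    if alignments.score <= 0:
        return 0.0
    aln = alignments[0]
    blocks_a, blocks_b = aln.aligned
    identical = 0
    for (sa, ea), (sb, _eb) in zip(blocks_a, blocks_b):
        for off in range(ea - sa):
            if a[sa + off] == b[sb + off]:
                identical += 1
    return identical / ((len(a) + len(b)) / 2.0)


def random_pair_null_ps(
    promoters: dict,
    tdg_gene_ids,
    n_pairs: int,
    seed: int,
    scoring: PromoterScoring | None = None,
):
    """Empirical null of Ps over random non-TDG gene pairs (seeded).

    *promoters* maps gene_id -> promoter sequence (excluded genes absent).
    Returns (sorted Ps array, q95).
    """
    eligible = sorted(g for g in promoters if g not in set(tdg_gene_ids))
    max_pairs = len(eligible) * (len(eligible) - 1) // 2
    if n_pairs < 1 or n_pairs > max_pairs:
        raise ValueError(
            f"cannot draw {n_pairs} pairs from {len(eligible)} eligible promoters"
        )
    rng = np.random.default_rng(seed)
    seen = set()
    values = []
    while len(values) < n_pairs:
        i, j = rng.choice(len(eligible), size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        values.append(promoter_similarity(promoters[eligible[key[0]]],
                                          promoters[eligible[key[1]]], scoring))
    ps = np.sort(np.array(values))
    return ps, float(np.quantile(ps, 0.95))


def call_promoter_divergence(
    pairs,
    promoters: dict,
    q95: float,
    scoring: PromoterScoring | None = None,
) -> list[PromoterComparison]:
    """Diverged/conserved promoter call per pair: diverged = Ps < q95.

    Pairs with a missing (excluded) promoter get no call.
    """
    calls = []
    for p in pairs:
        ga, gb = (p.gene_a, p.gene_b) if hasattr(p, "gene_a") else (p[0], p[1])
        pair_id = f"{ga}|{gb}"
        pa, pb = promoters.get(ga), promoters.get(gb)
        if not pa or not pb:
            calls.append(PromoterComparison(pair_id, ga, gb, math.nan, q95, None,
                                            reason="promoter excluded"))
            continue
        ps = promoter_similarity(pa, pb, scoring)
        calls.append(PromoterComparison(pair_id, ga, gb, ps, q95, ps < q95,
                                        promoter_len_a=len(pa), promoter_len_b=len(pb)))
    return calls
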