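"""Codon-aware alignment and Ka/Ks estimation for tandem duplicate pairs.

Pairs are aligned at the protein level (Needleman–Wunsch, BLOSUM62, affine
gaps) and the alignment is back-translated codon by codon; gap columns and
codons containing N are dropped. Ka and Ks are then estimated with the
Nei–Gojobori (1986) method: fractional synonymous/nonsynonymous site counts
per codon (averaged over both sequences; changes to stop codons count as
nonsynonymous so that N + S = 3 per codon exactly), observed differences
resolved by averaging over all shortest mutational pathways with
stop-crossing pathways excluded, and a Jukes–Cantor multiple-hit correction
d = −(3/4)·ln(1 − (4/3)p).

Pairs are excluded (not coerced) when Ks > 2 (synonymous saturation makes the
rate unreliable), when the JC correction is undefined (p ≥ 3/4), or when a
stop codon sits inside the reading frame. ω = Ka/Ks is flagged undefined when
Ks = 0; such pairs receive no selection class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable
from Bio.Seq import Seq

KS_MAX = 2.0

_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA = dict(_TABLE.forward_table)
for _stop in _TABLE.stop_codons:
    CODON_TO_AA[_stop] = "*"
SENSE_CODONS = sorted(c for c, aa in CODON_TO_AA.items() if aa != "*")
_BASES = "ACGT"


@dataclass
class KaKsResult:
    pair_id: str
    ka: float
    ks: float
    omega: float | None
    n_sites: float
    s_sites: float
    n_diffs: float = 0.0
    s_diffs: float = 0.0
    excluded: bool = False
    reason: str = ""
    omega_defined: bool = True


@dataclass
class SelectionClass:
    pair_id: str
    selection: str  # purifying / positive / neutral / unclassified


@lru_cache(maxsize=None)
def codon_sites(codon: str) -> tuple:
    """Fractional (synonymous, nonsynonymous) site counts of one sense codon.

    Each position contributes syn_changes/3 synonymous sites; mutations that
    create a stop codon are counted as nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1 :]
            if CODON_TO_AA[alt] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


@lru_cache(maxsize=None)
def codon_path_diffs(codon_a: str, codon_b: str) -> tuple:
    """Average (synonymous, nonsynonymous) difference counts between two codons.

    All orderings of the differing positions are enumerated; pathways passing
    through a stop codon are excluded (if every pathway does, all are kept and
    stop-creating steps count as nonsynonymous).
    """
    positions = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not positions:
        return 0.0, 0.0

    def walk(order, allow_stops):
        cur = codon_a
        syn = nonsyn = 0.0
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if CODON_TO_AA[nxt] == "*" and nxt != codon_b and not allow_stops:
                return None
            if CODON_TO_AA[nxt] == CODON_TO_AA[cur]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    paths = [r for order in itertools.permutations(positions)
             if (r := walk(order, allow_stops=False)) is not None]
    if not paths:
        paths = [walk(order, allow_stops=True) for order in itertools.permutations(positions)]
    syn = sum(p[0] for p in paths) / len(paths)
    nonsyn = sum(p[1] for p in paths) / len(paths)
    return syn, nonsyn


def jukes_cantor(p: float) -> float:
    """JC69 distance; raises ValueError at saturation (p ≥ 3/4)."""
    if p >= 0.75:
        raise ValueError("proportion of differences at or beyond JC saturation")
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - (4.0 / 3.0) * p)


def _strip_stop(cds: str) -> str:
    if len(cds) >= 3 and CODON_TO_AA.get(cds[-3:], "") == "*":
        return cds[:-3]
    return cds


@lru_cache(maxsize=1)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def align_codons(
    protein_a: str, protein_b: str, cds_a: str, cds_b: str
) -> tuple[list[str], list[str]]:
    """Global protein alignment back-translated to paired codons.

    The proteins must equal the (stop-trimmed) translations of their CDS. Gap
    columns and columns with an N-containing codon are removed.
    """
    cds_a = _strip_stop(cds_a.upper())
    cds_b = _strip_stop(cds_b.upper())
    for name, prot, cds in (("a", protein_a, cds_a), ("b", protein_b, cds_b)):
        if len(cds) != 3 * len(prot):
            raise ValueError(f"sequence {name}: CDS length does not match protein length")
        if str(Seq(cds).translate()) != prot:
            raise ValueError(f"sequence {name}: protein does not equal CDS translation")
    aln = _protein_aligner().align(protein_a, protein_b)[0]
    idx = aln.indices  # 2 x ncols, -1 marks a gap
    codons_a, codons_b = [], []
    for col in range(idx.shape[1]):
        ia, ib = int(idx[0, col]), int(idx[1, col])
        if ia < 0 or ib < 0:
            continue
        ca = cds_a[3 * ia : 3 * ia + 3]
        cb = cds_b[3 * ib : 3 * ib + 3]
        if "N" in ca or "N" in cb:
            continue
        codons_a.append(ca)
        codons_b.append(cb)
    return codons_a, codons_b


def kaks(
    codons_a: list[str], codons_b: list[str], pair_id: str = "", ks_max: float = KS_MAX
) -> KaKsResult:
    """NG86 Ka/Ks from a paired codon alignment."""
    if len(codons_a) != len(codons_b) or not codons_a:
        raise ValueError("codon alignment must be non-empty and paired")
    for ca, cb in zip(codons_a, codons_b):
        if CODON_TO_AA.get(ca) is None or CODON_TO_AA.get(cb) is None:
            raise ValueError(f"invalid codon in alignment: {ca!r}/{cb!r}")
        if CODON_TO_AA[ca] == "*" or CODON_TO_AA[cb] == "*":
            return KaKsResult(pair_id, math.nan, math.nan, None, 0.0, 0.0,
                              excluded=True, reason="internal stop codon",
                              omega_defined=False)

    s_a = sum(codon_sites(c)[0] for c in codons_a)
    s_b = sum(codon_sites(c)[0] for c in codons_b)
    n_a = sum(codon_sites(c)[1] for c in codons_a)
    n_b = sum(codon_sites(c)[1] for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = (n_a + n_b) / 2.0

    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        ds, dn = codon_path_diffs(ca, cb)
        sd += ds
        nd += dn

    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    try:
        ks = jukes_cantor(ps)
        ka = jukes_cantor(pn)
    except ValueError:
        return KaKsResult(pair_id, math.nan, math.nan, None, n_sites, s_sites,
                          n_diffs=nd, s_diffs=sd, excluded=True,
                          reason="saturation", omega_defined=False)
    if ks > ks_max:
        return KaKsResult(pair_id, ka, ks, None, n_sites, s_sites,
                          n_diffs=nd, s_diffs=sd, excluded=True,
                          reason=f"ks>{ks_max:g}", omega_defined=False)
    if ks == 0.0:
        return KaKsResult(pair_id, ka, ks, None, n_sites, s_sites,
                          n_diffs=nd, s_diffs=sd, omega_defined=False)
    return KaKsResult(pair_id, ka, ks, ka / ks, n_sites, s_sites,
                      n_diffs=nd, s_diffs=sd)


def kaks_from_sequences(
    cds_a: str, cds_b: str, pair_id: str = "", ks_max: float = KS_MAX
) -> KaKsResult:
    """Convenience wrapper: translate, align, estimate."""
    prot_a = str(Seq(_strip_stop(cds_a.upper())).translate())
    prot_b = str(Seq(_strip_stop(cds_b.upper())).translate())
    if "*" in prot_a or "*" in prot_b:
        return KaKsResult(pair_id, math.nan, math.nan, None, 0.0, 0.0,
                          excluded=True, reason="internal stop codon",
                          omega_defined=False)
    codons = align_codons(prot_a, prot_b, cds_a.upper(), cds_b.upper())
    return kaks(*codons, pair_id=pair_id, ks_max=ks_max)


def classify_selection(results) -> tuple[list[SelectionClass], dict]:
    """Strict ω comparison per pair plus genome-level proportions.

    Proportions are over non-excluded pairs with a defined ω.
    """
    classes = []
    counts = {"purifying": 0, "positive": 0, "neutral": 0, "unclassified": 0}
    for res in results:
        if res.excluded or not res.omega_defined or res.omega is None:
            label = "unclassified"
        elif res.omega < 1.0:
            label = "purifying"
        elif res.omega > 1.0:
            label = "positive"
        else:
            label = "neutral"
        counts[label] += 1
        classes.append(SelectionClass(pair_id=res.pair_id, selection=label))
    n_classified = counts["purifying"] + counts["positive"] + counts["neutral"]
    proportions = {
        key: (counts[key] / n_classified if n_classified else math.nan)
        for key in ("purifying", "positive", "neutral")
    }
    proportions["n_classified"] = n_classified
    proportions["n_unclassified"] = counts["unclassified"]
    return classes, proportions
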