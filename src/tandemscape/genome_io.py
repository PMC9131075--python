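"""Reading and validation of per-genotype inputs.

This module assembles one :class:`GeneModel` per gene from a GFF3 file plus CDS
and protein FASTAs and a per-gene annotation table, assigns within-chromosome
ranks, and applies the orthogroup-level transposon filter: an orthogroup counts
as non-TE only when fewer than 30% of its members are TE-flagged *and* its mean
AHRD quality score is at least 2; every gene of a TE orthogroup is then treated
as a TE gene downstream.

Coordinates are GFF3-style 1-based inclusive throughout. Ranks are 0-based
start-order indices among located genes of one chromosome; intervening-gene
counts downstream are taken over the non-TE, located gene set, so
:func:`non_te_located_genes` recomputes ranks after filtering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

#: chromosome names treated as "unplaced" (no usable chromosomal location)
DEFAULT_UNPLACED = frozenset({"chrUn", "chr00", "Un", "ChrUn", "scaffold_un"})

TE_FRACTION_MAX = 0.30  # strict: an OG with exactly 30% TE genes is a TE OG
MEAN_AHRD_MIN = 2.0


@dataclass
class GeneModel:
    """One annotated gene (longest isoform) of one genotype."""

    gene_id: str
    genotype: str
    chromosome: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    rank: int  # 0-based start-order index among located genes; -1 if unplaced
    cds: str
    protein: str
    is_te: bool = False
    ahrd_score: int = 0
    pfam_domains: frozenset = field(default_factory=frozenset)
    go_terms: frozenset = field(default_factory=frozenset)
    located: bool = True

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")


@dataclass
class Orthogroup:
    """A cross-genotype orthogroup with TE-filter statistics."""

    og_id: str
    members: dict  # genotype -> set of gene_ids
    te_gene_fraction: float = 0.0
    mean_ahrd: float = 0.0
    is_te_og: bool = False

    def gene_ids(self):
        for genes in self.members.values():
            yield from genes


def _read_fasta(path) -> dict:
    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def _translate_cds(cds: str) -> str:
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot


def _longest_mrna(db, gene) -> str | None:
    """Representative mRNA id: longest total CDS, ties broken lexicographically."""
    best = None
    for mrna in db.children(gene, featuretype="mRNA"):
        cds_len = sum(c.end - c.start + 1 for c in db.children(mrna, featuretype="CDS"))
        key = (-cds_len, mrna.id)
        if best is None or key < best[0]:
            best = (key, mrna.id)
    return None if best is None else best[1]


def load_genotype(
    gff3_path,
    cds_fasta,
    protein_fasta,
    annotation_tsv,
    genotype: str,
    unplaced_names: Iterable[str] = DEFAULT_UNPLACED,
) -> list[GeneModel]:
    """Assemble GeneModels for one genotype.

    The CDS and protein FASTAs are keyed by gene id and hold the longest
    isoform. Genes whose CDS length is not a multiple of 3, that contain an
    internal stop, or whose protein does not match the CDS translation are
    excluded with a warning; a gene id missing from either FASTA is a hard
    error listing the offending ids.
    """
    unplaced = set(unplaced_names)
    cds_by_id = _read_fasta(cds_fasta)
    prot_by_id = _read_fasta(protein_fasta)
    ann = read_annotation_table(annotation_tsv)

    db = gffutils.create_db(
        str(gff3_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    missing: list[str] = []
    for feat in db.features_of_type("gene"):
        gid = feat.id
        _longest_mrna(db, feat)  # representative isoform (FASTAs already hold it)
        if gid not in cds_by_id or gid not in prot_by_id:
            missing.append(gid)
            continue
        cds = cds_by_id[gid]
        if len(cds) % 3 != 0:
            warnings.warn(f"{gid}: CDS length {len(cds)} not a multiple of 3; excluded")
            continue
        prot = _translate_cds(cds)
        if "*" in prot:
            warnings.warn(f"{gid}: internal stop codon; excluded")
            continue
        if prot != prot_by_id[gid]:
            warnings.warn(f"{gid}: protein does not match CDS translation; excluded")
            continue
        a = ann.get(gid, {})
        genes.append(
            GeneModel(
                gene_id=gid,
                genotype=genotype,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                rank=-1,
                cds=cds,
                protein=prot,
                is_te=bool(a.get("te_flag", False)),
                ahrd_score=int(a.get("ahrd_stars", 0)),
                pfam_domains=frozenset(a.get("pfam", ())),
                go_terms=frozenset(a.get("go", ())),
                located=feat.seqid not in unplaced,
            )
        )
    if missing:
        raise ValueError(f"missing CDS/protein sequences for gene ids: {sorted(missing)}")
    return assign_ranks(genes)


def assign_ranks(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Assign 0-based start-order ranks per (genotype, chromosome) to located genes.

    Unplaced genes keep rank -1 and are excluded from rank assignment.
    """
    out = []
    by_chrom: dict = {}
    for g in genes:
        if g.located:
            by_chrom.setdefault((g.genotype, g.chromosome), []).append(g)
        else:
            out.append(replace(g, rank=-1))
    for key, glist in by_chrom.items():
        glist.sort(key=lambda g: (g.start, g.gene_id))
        for i, g in enumerate(glist):
            out.append(replace(g, rank=i))
    out.sort(key=lambda g: (g.genotype, g.chromosome, g.start, g.gene_id))
    return out


def read_annotation_table(path) -> dict:
    """Parse the per-gene annotation TSV (gene_id, pfam, go, ahrd_stars, te_flag)."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    ann = {}
    for row in df.itertuples(index=False):
        ann[row.gene_id] = {
            "pfam": [t for t in row.pfam.split(",") if t],
            "go": [t for t in row.go.split(",") if t],
            "ahrd_stars": int(row.ahrd_stars or 0),
            "te_flag": str(row.te_flag).strip() in {"1", "True", "true"},
        }
    return ann


def load_orthogroups(path) -> list[Orthogroup]:
    """Load the orthogroup table (og_id, genotype, gene_id; one gene per line)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    ogs: dict[str, Orthogroup] = {}
    for row in df.itertuples(index=False):
        og = ogs.setdefault(row.og_id, Orthogroup(og_id=row.og_id, members={}))
        og.members.setdefault(row.genotype, set()).add(row.gene_id)
    return [ogs[k] for k in sorted(ogs)]


def classify_te_orthogroups(
    orthogroups: Sequence[Orthogroup], genes: Sequence[GeneModel]
) -> list[Orthogroup]:
    """Set te_gene_fraction / mean_ahrd / is_te_og on each orthogroup.

    An OG is non-TE iff its TE-gene fraction is strictly below 30% and its mean
    AHRD score is >= 2; otherwise it is a TE OG. Referencing an unknown gene id
    is a hard error.
    """
    by_id = {g.gene_id: g for g in genes}
    out = []
    for og in orthogroups:
        members = [gid for gid in og.gene_ids()]
        if not members:
            raise ValueError(f"{og.og_id}: empty orthogroup")
        unknown = [gid for gid in members if gid not in by_id]
        if unknown:
            raise ValueError(f"{og.og_id}: unknown gene ids {sorted(unknown)}")
        te_frac = sum(by_id[g].is_te for g in members) / len(members)
        mean_ahrd = sum(by_id[g].ahrd_score for g in members) / len(members)
        og.te_gene_fraction = te_frac
        og.mean_ahrd = mean_ahrd
        og.is_te_og = not (te_frac < TE_FRACTION_MAX and mean_ahrd >= MEAN_AHRD_MIN)
        out.append(og)
    return out


def propagate_te_flags(
    genes: Sequence[GeneModel], orthogroups: Sequence[Orthogroup]
) -> list[GeneModel]:
    """Mark every gene belonging to a TE orthogroup as a TE gene."""
    te_genes = set()
    for og in orthogroups:
        if og.is_te_og:
            te_genes.update(og.gene_ids())
    return [replace(g, is_te=True) if g.gene_id in te_genes else g for g in genes]


def non_te_located_genes(genes: Sequence[GeneModel]) -> list[GeneModel]:
    """Restrict to non-TE genes with a known chromosomal location.

    Ranks are recomputed on the filtered set so intervening-gene counts operate
    on the analysed gene universe.
    """
    kept = [g for g in genes if not g.is_te and g.located]
    return assign_ranks(kept)


# --- gene-table TSV round trip ------------------------------------------------

_TABLE_COLS = [
    "gene_id", "genotype", "chromosome", "start", "end", "strand", "rank",
    "cds", "protein", "is_te", "ahrd_score", "pfam_domains", "go_terms", "located",
]


def write_gene_table(genes: Sequence[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "genotype": g.genotype,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "rank": g.rank,
                "cds": g.cds,
                "protein": g.protein,
                "is_te": int(g.is_te),
                "ahrd_score": g.ahrd_score,
                "pfam_domains": ",".join(sorted(g.pfam_domains)),
                "go_terms": ",".join(sorted(g.go_terms)),
                "located": int(g.located),
            }
        )
    pd.DataFrame(rows, columns=_TABLE_COLS).to_csv(path, sep="\t", index=False)


def read_gene_table(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = []
    for r in df.itertuples(index=False):
        genes.append(
            GeneModel(
                gene_id=r.gene_id,
                genotype=r.genotype,
                chromosome=r.chromosome,
                start=int(r.start),
                end=int(r.end),
                strand=r.strand,
                rank=int(r.rank),
                cds=r.cds,
                protein=r.protein,
                is_te=bool(int(r.is_te)),
                ahrd_score=int(r.ahrd_score),
                pfam_domains=frozenset(t for t in r.pfam_domains.split(",") if t),
                go_terms=frozenset(t for t in r.go_terms.split(",") if t),
                located=bool(int(r.located)),
            )
        )
    return genes
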