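"""Synthetic multi-genotype datasets with planted tandem clusters and full truth.

The generator emulates the statistical structure of a multi-genotype plant
gene complement: per genotype, chromosomes carry background genes plus planted
tandem clusters (mostly pairs) built by duplicating an ancestral CDS and
applying codon substitutions at a chosen ω, with configurable intervening-gene
counts. Cluster families are shared across genotypes through orthogroups and
carry a planted core/shared/private category. Expression profiles are
log-normal with planted pair correlation (conserved copies track each other,
diverged copies are independent); promoters descend from an ancestral 1 kb
sequence mutated at a planted per-base rate. TE genes are annotation flags
only (no repeat-sequence realism).

ω planting uses the NG86 site convention — a target count of synonymous and
nonsynonymous changes is derived from the target Ks and ω via the inverse
Jukes–Cantor map and placed by accept/reject sampling of single-nucleotide
codon changes (one change per codon, stop codons never created) — so the
planted value is exactly what the estimator defines. Everything is driven by
one seeded generator: the same seed yields a byte-identical file bundle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import GeneModel, assign_ranks
from .selection import CODON_TO_AA, SENSE_CODONS, codon_sites
from .utils import revcomp

_BASES = "ACGT"
_LOOKUP = np.frombuffer(b"ACGT", dtype=np.uint8)

PFAM_POOL = (
    "PF00931", "PF00560", "PF00201", "PF02798", "PF02519", "PF01715",
    "PF00646", "PF00954", "PF13855", "PF18052", "PF00407", "PF07714",
    "PF00069", "PF03106", "PF00067", "PF00170",
)
GO_POOL = (
    "GO:0006952", "GO:0009607", "GO:0006950", "GO:0009753", "GO:0008152",
    "GO:0009813", "GO:0016758", "GO:0004674", "GO:0005515", "GO:0003700",
)


@dataclass
class SimConfig:
    """Study conditions of the synthetic multi-genotype dataset."""

    n_genotypes: int = 4
    genotype_names: tuple | None = None  # default G1..Gn
    n_chromosomes: int = 3
    genes_per_chromosome: int = 100
    fraction_te: float = 0.10
    fraction_unplaced: float = 0.0
    unplaced_name: str = "chrUn"
    fraction_tdg: float = 0.18
    cluster_size_probs: tuple = ((2, 0.67), (3, 0.20), (4, 0.09), (5, 0.04))
    intervening_probs: tuple = ((0, 0.55), (1, 0.20), (2, 0.12), (3, 0.07), (4, 0.04), (5, 0.02))
    category_probs: tuple = (("private", 0.25), ("core", 0.30), ("shared", 0.45))
    omega_mix: tuple = ((0.3, 0.93), (1.5, 0.07))
    ks_range: tuple = (0.15, 0.45)
    n_codons_range: tuple = (200, 400)
    n_samples: int = 10
    fraction_expr_diverged: float = 0.75
    expr_noise_sd: float = 0.12
    fraction_unexpressed: float = 0.05
    promoter_len: int = 1000
    fraction_prom_diverged: float = 0.70
    prom_rate_conserved: float = 0.02
    prom_rate_diverged: float = 0.70
    intergenic_range: tuple = (1050, 1600)
    seed: int = 0

    def names(self) -> tuple:
        if self.genotype_names is not None:
            return tuple(self.genotype_names)
        return tuple(f"G{i+1}" for i in range(self.n_genotypes))


@dataclass
class GenotypeData:
    name: str
    genes: list  # GeneModel, ranks assigned
    genome: dict  # chromosome -> sequence
    tpm: pd.DataFrame  # genes x samples


@dataclass
class SyntheticTruth:
    genes: pd.DataFrame  # gene_id, genotype, chromosome, family, member, is_te, located
    pairs: pd.DataFrame  # genotype, gene_a, gene_b, family, omega, ks_target, ...
    clusters: pd.DataFrame  # family, genotype, members, category
    families: pd.DataFrame  # family, category, genotypes


@dataclass
class SyntheticBundle:
    config: SimConfig
    genotypes: dict  # name -> GenotypeData
    orthogroups: pd.DataFrame  # og_id, genotype, gene_id
    truth: SyntheticTruth


# --- sequence primitives ------------------------------------------------------


def random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return _LOOKUP[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons − 2) random sense codons + TAA."""
    body = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons - 2)]
    return "ATG" + "".join(body) + "TAA"


def _inverse_jc(d: float) -> float:
    """Proportion of differing sites that yields JC distance *d*."""
    return 0.75 * (1.0 - math.exp(-4.0 * d / 3.0))


def feasible_ks(
    ks: float, omega: float, cds: str, budget: float = 0.6
) -> float:
    """Largest target Ks ≤ *ks* whose substitution load fits the codon budget.

    One substitution per codon caps the total number of plantable changes;
    high-ω families therefore get younger (smaller-Ks) duplicates.
    """
    body = cds[:-3] if CODON_TO_AA.get(cds[-3:], "") == "*" else cds
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    s_sites = sum(codon_sites(c)[0] for c in codons)
    n_sites = 3.0 * len(codons) - s_sites
    cap = budget * (len(codons) - 1)
    while ks > 1e-3:
        needed = round(_inverse_jc(ks) * s_sites) + round(_inverse_jc(omega * ks) * n_sites)
        if needed <= cap:
            return ks
        ks *= 0.85
    return ks


def mutate_cds(cds: str, ks_target: float, omega: float, rng: np.random.Generator) -> str:
    """Apply codon substitutions hitting the target Ks and ω = Ka/Ks.

    At most one substitution per codon; the start and stop codons are left
    intact and stop codons are never created.
    """
    has_stop = CODON_TO_AA.get(cds[-3:], "") == "*"
    body = cds[:-3] if has_stop else cds
    codons = [body[i : i + 3] for i in range(0, len(body), 3)]
    s_sites = sum(codon_sites(c)[0] for c in codons)
    n_sites = 3.0 * len(codons) - s_sites
    sd = int(round(_inverse_jc(ks_target) * s_sites))
    nd = int(round(_inverse_jc(omega * ks_target) * n_sites))
    used: set = set()

    def apply(n_needed: int, want_syn: bool) -> None:
        applied = 0
        guard = 0
        while applied < n_needed:
            guard += 1
            if guard > 20000 * (n_needed + 1):
                raise RuntimeError("mutation target infeasible for this sequence")
            idx = int(rng.integers(1, len(codons)))  # keep ATG
            if idx in used:
                continue
            cod = codons[idx]
            pos = int(rng.integers(0, 3))
            base = _BASES[int(rng.integers(0, 4))]
            if base == cod[pos]:
                continue
            alt = cod[:pos] + base + cod[pos + 1 :]
            if CODON_TO_AA[alt] == "*":
                continue
            if (CODON_TO_AA[alt] == CODON_TO_AA[cod]) != want_syn:
                continue
            codons[idx] = alt
            used.add(idx)
            applied += 1

    apply(sd, True)
    apply(nd, False)
    return "".join(codons) + (cds[-3:] if has_stop else "")


def mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Per-base substitution at *rate* (always to a different base)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    for i in np.nonzero(hit)[0]:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return arr.tobytes().decode("ascii")


def _translate(cds: str) -> str:
    prot = "".join(CODON_TO_AA[cds[i : i + 3]] for i in range(0, len(cds), 3))
    return prot[:-1] if prot.endswith("*") else prot


def _draw(rng: np.random.Generator, probs: tuple):
    values = [v for v, _ in probs]
    p = np.array([w for _, w in probs], dtype=float)
    return values[int(rng.choice(len(values), p=p / p.sum()))]


# --- layout assembly ----------------------------------------------------------


def _assemble_genotype(
    name: str,
    tokens_by_chrom: Mapping[str, list],
    rng: np.random.Generator,
    intergenic_range: tuple,
    unplaced_name: str = "chrUn",
    tail: int = 2000,
) -> GenotypeData:
    """Lay tokens out on chromosomes, build genome sequence and GeneModels.

    Each token is a mutable dict with keys cds, strand, is_te, ahrd, pfam, go
    and optionally promoter (plus-strand planted upstream sequence); gene_id
    and coordinates are written back into the token.
    """
    genes = []
    genome = {}
    serial = 1
    for chrom in sorted(tokens_by_chrom):
        parts = []
        pos = 0
        for tok in tokens_by_chrom[chrom]:
            gap = int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
            filler = random_dna(rng, gap)
            prom = tok.get("promoter")
            if prom:
                if tok["strand"] != "+" or len(prom) > gap:
                    raise ValueError("planted promoters require + strand and enough gap")
                filler = filler[: gap - len(prom)] + prom
            parts.append(filler)
            pos += gap
            seq = tok["cds"] if tok["strand"] == "+" else revcomp(tok["cds"])
            start, end = pos + 1, pos + len(seq)
            parts.append(seq)
            pos = end
            gid = f"{name}g{serial:04d}"
            serial += 1
            tok.update(gene_id=gid, start=start, end=end, chromosome=chrom)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    genotype=name,
                    chromosome=chrom,
                    start=start,
                    end=end,
                    strand=tok["strand"],
                    rank=-1,
                    cds=tok["cds"],
                    protein=_translate(tok["cds"]),
                    is_te=tok.get("is_te", False),
                    ahrd_score=tok.get("ahrd", 3),
                    pfam_domains=frozenset(tok.get("pfam", ())),
                    go_terms=frozenset(tok.get("go", ())),
                    located=chrom != unplaced_name,
                )
            )
        parts.append(random_dna(rng, tail))
        genome[chrom] = "".join(parts)
    return GenotypeData(name=name, genes=assign_ranks(genes), genome=genome, tpm=None)


def _background_token(rng: np.random.Generator, cfg: SimConfig) -> dict:
    n_codons = int(rng.integers(cfg.n_codons_range[0], cfg.n_codons_range[1] + 1))
    n_dom = int(rng.integers(0, 3))
    return {
        "kind": "bg",
        "cds": random_cds(rng, n_codons),
        "strand": "+" if rng.random() < 0.5 else "-",
        "is_te": False,
        "ahrd": int(rng.integers(2, 4)),
        "pfam": set(rng.choice(PFAM_POOL, size=n_dom, replace=False)) if n_dom else set(),
        "go": set(rng.choice(GO_POOL, size=int(rng.integers(1, 3)), replace=False)),
    }


# --- main generator -----------------------------------------------------------


def simulate(config: SimConfig) -> SyntheticBundle:
    """Generate the full multi-genotype bundle plus planted ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    names = cfg.names()
    n_gt = len(names)
    G = cfg.n_chromosomes * cfg.genes_per_chromosome

    cat_probs = dict(cfg.category_probs)
    if n_gt < 3:  # "shared" needs >1 but not all; impossible below 3 genotypes
        cat_probs["core"] = cat_probs.get("core", 0.0) + cat_probs.pop("shared", 0.0)

    mean_size = sum(k * p for k, p in cfg.cluster_size_probs) / sum(
        p for _, p in cfg.cluster_size_probs
    )
    clusters_per_gt = int(round(cfg.fraction_tdg * G / mean_size))

    # --- families -------------------------------------------------------------
    families = []
    fid = 0

    def new_family(presence: tuple) -> None:
        nonlocal fid
        fid += 1
        size = _draw(rng, cfg.cluster_size_probs)
        omega = _draw(rng, cfg.omega_mix)
        n_dom = int(rng.integers(1, 3))
        base_dom = set(rng.choice(PFAM_POOL, size=n_dom, replace=False))
        extra = ""
        if omega > 1.0:  # neo-fated copies carry a novel domain
            pool = [d for d in PFAM_POOL if d not in base_dom]
            extra = str(rng.choice(pool))
        members = []
        for j in range(1, size):
            members.append(
                {
                    "ks": float(rng.uniform(*cfg.ks_range)),
                    "expr_diverged": bool(rng.random() < cfg.fraction_expr_diverged),
                    "prom_diverged": bool(rng.random() < cfg.fraction_prom_diverged),
                }
            )
        families.append(
            {
                "family": f"F{fid:04d}",
                "presence": presence,
                "size": size,
                "omega": omega,
                "n_codons": int(rng.integers(cfg.n_codons_range[0], cfg.n_codons_range[1] + 1)),
                "ancestor": None,
                "promoter": None,
                "pfam": base_dom,
                "extra_domain": extra,
                "go": set(rng.choice(GO_POOL, size=int(rng.integers(1, 3)), replace=False)),
                "members": members,
                "intervening": [
                    _draw(rng, cfg.intervening_probs) for _ in range(size - 1)
                ],
            }
        )
        families[-1]["ancestor"] = random_cds(rng, families[-1]["n_codons"])
        families[-1]["promoter"] = random_dna(rng, cfg.promoter_len)
        for m in members:
            m["ks"] = feasible_ks(m["ks"], omega, families[-1]["ancestor"])

    n_core = int(round(cat_probs.get("core", 0.0) * clusters_per_gt))
    n_private_each = int(round(cat_probs.get("private", 0.0) * clusters_per_gt))
    shared_prob = cat_probs.get("shared", 0.0)
    if shared_prob > 0 and n_gt >= 3:
        mean_subset = (2 + n_gt - 1) / 2.0
        n_shared = int(round(shared_prob * clusters_per_gt * n_gt / mean_subset))
    else:
        n_shared = 0

    for _ in range(n_core):
        new_family(tuple(names))
    for gt in names:
        for _ in range(n_private_each):
            new_family((gt,))
    for _ in range(n_shared):
        subset_size = int(rng.integers(2, n_gt))  # 2 .. n_gt-1
        subset = tuple(sorted(rng.choice(names, size=subset_size, replace=False)))
        new_family(subset)

    # categories implied by presence
    for fam in families:
        k = len(fam["presence"])
        fam["category"] = "core" if k == n_gt else ("private" if k == 1 else "shared")

    # --- per-genotype layout, sequences, expression ---------------------------
    genotype_data = {}
    og_rows = []
    truth_gene_rows = []
    truth_pair_rows = []
    truth_cluster_rows = []

    for gt in names:
        fams = [f for f in families if gt in f["presence"]]
        chrom_names = [f"chr{c+1:02d}" for c in range(cfg.n_chromosomes)]
        capacity = {c: cfg.genes_per_chromosome for c in chrom_names}
        assignment: dict = {c: [] for c in chrom_names}
        for fam in fams:
            slots = fam["size"] + sum(fam["intervening"])
            chrom = max(chrom_names, key=lambda c: capacity[c])
            if capacity[chrom] < slots:
                raise ValueError("infeasible layout: planted clusters exceed chromosome capacity")
            capacity[chrom] -= slots
            assignment[chrom].append(fam)

        tokens_by_chrom: dict = {}
        member_tokens: dict = {}  # (family, member_index) -> token
        for chrom in chrom_names:
            free_bg = capacity[chrom]
            # units: single bg tokens or whole cluster blocks; blocks are
            # inserted as atomic units so clusters can never interleave
            units: list = [[_background_token(rng, cfg)] for _ in range(free_bg)]
            for fam in assignment[chrom]:
                block = []
                for j in range(fam["size"]):
                    if j == 0:
                        cds = fam["ancestor"]
                        prom = fam["promoter"]
                    else:
                        m = fam["members"][j - 1]
                        cds = mutate_cds(fam["ancestor"], m["ks"], fam["omega"], rng)
                        rate = (
                            cfg.prom_rate_diverged
                            if m["prom_diverged"]
                            else cfg.prom_rate_conserved
                        )
                        prom = mutate_seq(fam["promoter"], rate, rng)
                    pfam = set(fam["pfam"])
                    if j > 0 and fam["extra_domain"]:
                        pfam.add(fam["extra_domain"])
                    tok = {
                        "kind": "member",
                        "family": fam["family"],
                        "member": j,
                        "cds": cds,
                        "strand": "+",
                        "promoter": prom,
                        "is_te": False,
                        "ahrd": 3,
                        "pfam": pfam,
                        "go": set(fam["go"]),
                    }
                    member_tokens[(fam["family"], j)] = tok
                    block.append(tok)
                    if j < fam["size"] - 1:
                        for _ in range(fam["intervening"][j]):
                            block.append(_background_token(rng, cfg))
                insert_at = int(rng.integers(0, len(units) + 1))
                units.insert(insert_at, block)
            tokens_by_chrom[chrom] = [tok for unit in units for tok in unit]

        # unplaced and TE flags over background genes
        n_unplaced = int(round(cfg.fraction_unplaced * G))
        if n_unplaced:
            tokens_by_chrom[cfg.unplaced_name] = [
                _background_token(rng, cfg) for _ in range(n_unplaced)
            ]
        bg_tokens = [
            t for toks in tokens_by_chrom.values() for t in toks if t["kind"] == "bg"
        ]
        n_te = int(round(cfg.fraction_te * len(bg_tokens)))
        te_idx = rng.choice(len(bg_tokens), size=n_te, replace=False) if n_te else []
        for i in te_idx:
            bg_tokens[i]["is_te"] = True
            bg_tokens[i]["ahrd"] = int(rng.integers(0, 2))
            bg_tokens[i]["pfam"] = set()

        gdata = _assemble_genotype(
            gt, tokens_by_chrom, rng, cfg.intergenic_range, cfg.unplaced_name
        )

        # expression: member 0 sets the family profile in this genotype
        n_unexpr = int(round(cfg.fraction_unexpressed * len(bg_tokens)))
        unexpr_ids = {
            bg_tokens[i]["gene_id"]
            for i in (rng.choice(len(bg_tokens), size=n_unexpr, replace=False) if n_unexpr else [])
        }
        base_pattern: dict = {}
        tpm_rows = {}
        ordered = [t for toks in tokens_by_chrom.values() for t in toks]
        ordered.sort(key=lambda t: t["gene_id"])
        for tok in ordered:
            gid = tok["gene_id"]
            if gid in unexpr_ids:
                tpm_rows[gid] = np.zeros(cfg.n_samples)
                continue
            mu = rng.normal(0.9, 0.3)
            pattern = rng.normal(mu, 0.6, size=cfg.n_samples)
            if tok["kind"] == "member":
                key = tok["family"]
                if tok["member"] == 0:
                    base_pattern[key] = pattern
                else:
                    m = next(
                        f for f in families if f["family"] == key
                    )["members"][tok["member"] - 1]
                    if not m["expr_diverged"]:
                        pattern = base_pattern[key] + rng.normal(
                            0.0, cfg.expr_noise_sd, size=cfg.n_samples
                        )
            tpm_rows[gid] = np.round(10.0 ** pattern, 3)
        gdata.tpm = pd.DataFrame.from_dict(tpm_rows, orient="index",
                                           columns=[f"S{i+1:02d}" for i in range(cfg.n_samples)])
        gdata.tpm = gdata.tpm.sort_index()
        genotype_data[gt] = gdata

        # orthogroups + truth bookkeeping
        for tok in ordered:
            gid = tok["gene_id"]
            if tok["kind"] == "member":
                og_rows.append({"og_id": f"OG_{tok['family']}", "genotype": gt, "gene_id": gid})
            else:
                og_rows.append({"og_id": f"OGS_{gid}", "genotype": gt, "gene_id": gid})
            truth_gene_rows.append(
                {
                    "gene_id": gid,
                    "genotype": gt,
                    "chromosome": tok["chromosome"],
                    "family": tok.get("family", ""),
                    "member": tok.get("member", -1),
                    "is_te": tok["is_te"],
                    "located": tok["chromosome"] != cfg.unplaced_name,
                }
            )
        for fam in fams:
            member_ids = [member_tokens[(fam["family"], j)]["gene_id"]
                          for j in range(fam["size"])]
            truth_cluster_rows.append(
                {
                    "family": fam["family"],
                    "genotype": gt,
                    "members": ",".join(member_ids),
                    "category": fam["category"],
                }
            )
            for j in range(1, fam["size"]):
                m = fam["members"][j - 1]
                domains_differ = bool(fam["extra_domain"])
                if domains_differ and fam["omega"] > 1.0:
                    expected = "neo_functionalization"
                elif m["expr_diverged"] and fam["omega"] < 1.0 and not domains_differ:
                    expected = "sub_functionalization"
                elif (not m["expr_diverged"]) and fam["omega"] < 1.0 and not domains_differ:
                    expected = "genetic_redundancy"
                else:
                    expected = "unclassified"
                truth_pair_rows.append(
                    {
                        "genotype": gt,
                        "gene_a": member_ids[0],
                        "gene_b": member_ids[j],
                        "family": fam["family"],
                        "omega": fam["omega"],
                        "ks_target": m["ks"],
                        "expr_diverged": m["expr_diverged"],
                        "prom_diverged": m["prom_diverged"],
                        "domains_differ": bool(fam["extra_domain"]),
                        "expected_fate": expected,
                    }
                )

    truth = SyntheticTruth(
        genes=pd.DataFrame(truth_gene_rows),
        pairs=pd.DataFrame(truth_pair_rows),
        clusters=pd.DataFrame(truth_cluster_rows),
        families=pd.DataFrame(
            [
                {"family": f["family"], "category": f["category"],
                 "genotypes": ",".join(f["presence"])}
                for f in families
            ]
        ),
    )
    return SyntheticBundle(
        config=cfg,
        genotypes=genotype_data,
        orthogroups=pd.DataFrame(og_rows, columns=["og_id", "genotype", "gene_id"]),
        truth=truth,
    )


# --- worked fixture -----------------------------------------------------------


def worked_fixture() -> SyntheticBundle:
    """Tiny deterministic two-genotype dataset with hand-checkable truth.

    Genotype A carries a private 3-gene cluster (family F1, ω = 0.3, diverged
    expression/promoters), a pair of identical homologs separated by 11
    intervening genes (rejected by the tandem rule), and a synonymous-only
    pair (family F2, conserved expression/promoters) that is also present in
    genotype B — making F2 a core family. Two background genes of A are
    TE-flagged and one background gene sits on the unplaced scaffold.
    """
    cfg = SimConfig(
        n_genotypes=2,
        genotype_names=("A", "B"),
        n_chromosomes=1,
        genes_per_chromosome=30,
        n_samples=6,
        fraction_unplaced=0.0,
        seed=20240401,
    )
    rng = np.random.default_rng(cfg.seed)
    anc1 = random_cds(rng, 120)
    anc2 = random_cds(rng, 100)
    anc3 = random_cds(rng, 110)
    prom1 = random_dna(rng, cfg.promoter_len)
    prom2 = random_dna(rng, cfg.promoter_len)

    f1_m1 = mutate_cds(anc1, 0.20, 0.3, rng)
    f1_m2 = mutate_cds(anc1, 0.25, 0.3, rng)
    f2_m1 = mutate_cds(anc2, 0.15, 0.0, rng)  # synonymous-only divergence
    f2_m1_b = mutate_cds(anc2, 0.15, 0.0, rng)

    def member(fam, j, cds, prom, pfam):
        return {"kind": "member", "family": fam, "member": j, "cds": cds,
                "strand": "+", "promoter": prom, "is_te": False, "ahrd": 3,
                "pfam": set(pfam), "go": {"GO:0006952"}}

    def bg(is_te=False):
        tok = _background_token(rng, cfg)
        if is_te:
            tok.update(is_te=True, ahrd=0, pfam=set())
        return tok

    tokens_a = [
        bg(), bg(is_te=True),
        member("F1", 0, anc1, prom1, {"PF00931"}),
        member("F1", 1, f1_m1, mutate_seq(prom1, 0.70, rng), {"PF00931"}),
        bg(),
        member("F1", 2, f1_m2, mutate_seq(prom1, 0.70, rng), {"PF00931"}),
        bg(), bg(is_te=True),
        {"kind": "reject", "family": "R", "member": 0, "cds": anc3, "strand": "+",
         "promoter": None, "is_te": False, "ahrd": 3, "pfam": set(), "go": {"GO:0008152"}},
        *[bg() for _ in range(11)],
        {"kind": "reject", "family": "R", "member": 1, "cds": anc3, "strand": "+",
         "promoter": None, "is_te": False, "ahrd": 3, "pfam": set(), "go": {"GO:0008152"}},
        bg(),
        member("F2", 0, anc2, prom2, {"PF00201"}),
        member("F2", 1, f2_m1, mutate_seq(prom2, 0.02, rng), {"PF00201"}),
        bg(), bg(), bg(),
    ]
    tokens_b = [
        bg(), bg(), bg(),
        member("F2", 0, anc2, prom2, {"PF00201"}),
        member("F2", 1, f2_m1_b, mutate_seq(prom2, 0.02, rng), {"PF00201"}),
        bg(), bg(), bg(), bg(),
    ]
    data_a = _assemble_genotype(
        "A", {"chr01": tokens_a, cfg.unplaced_name: [bg()]}, rng, cfg.intergenic_range,
        cfg.unplaced_name,
    )
    data_b = _assemble_genotype("B", {"chr01": tokens_b}, rng, cfg.intergenic_range,
                                cfg.unplaced_name)

    def build_tpm(tokens, extra_tokens=()):
        rows = {}
        base = {}
        for tok in list(tokens) + list(extra_tokens):
            gid = tok["gene_id"]
            mu = rng.normal(0.9, 0.3)
            pattern = rng.normal(mu, 0.6, size=cfg.n_samples)
            if tok["kind"] == "member" and tok["member"] == 0:
                base[tok["family"]] = pattern
            elif tok["kind"] == "member" and tok["family"] == "F2":
                pattern = base["F2"] + rng.normal(0.0, cfg.expr_noise_sd, cfg.n_samples)
            rows[gid] = np.round(10.0 ** pattern, 3)
        return pd.DataFrame.from_dict(rows, orient="index",
                                      columns=[f"S{i+1:02d}" for i in range(cfg.n_samples)]
                                      ).sort_index()

    tokens_a_all = tokens_a + [_find_unplaced_token(data_a)]
    data_a.tpm = build_tpm(tokens_a_all)
    data_b.tpm = build_tpm(tokens_b)

    og_rows = []
    truth_gene_rows = []
    for gt, toks in (("A", tokens_a_all), ("B", tokens_b)):
        for tok in toks:
            gid = tok["gene_id"]
            if tok["kind"] == "member":
                og_rows.append({"og_id": f"OG_{tok['family']}", "genotype": gt, "gene_id": gid})
            else:
                og_rows.append({"og_id": f"OGS_{gid}", "genotype": gt, "gene_id": gid})
            truth_gene_rows.append(
                {"gene_id": gid, "genotype": gt, "chromosome": tok["chromosome"],
                 "family": tok.get("family", "") if tok["kind"] == "member" else "",
                 "member": tok.get("member", -1) if tok["kind"] == "member" else -1,
                 "is_te": tok["is_te"],
                 "located": tok["chromosome"] != cfg.unplaced_name}
            )

    def gid_of(tokens, fam, j):
        return next(t["gene_id"] for t in tokens
                    if t.get("family") == fam and t.get("member") == j)

    truth_pairs = pd.DataFrame(
        [
            {"genotype": "A", "gene_a": gid_of(tokens_a, "F1", 0),
             "gene_b": gid_of(tokens_a, "F1", 1), "family": "F1", "omega": 0.3,
             "ks_target": 0.20, "expr_diverged": True, "prom_diverged": True,
             "domains_differ": False, "expected_fate": "sub_functionalization"},
            {"genotype": "A", "gene_a": gid_of(tokens_a, "F1", 0),
             "gene_b": gid_of(tokens_a, "F1", 2), "family": "F1", "omega": 0.3,
             "ks_target": 0.25, "expr_diverged": True, "prom_diverged": True,
             "domains_differ": False, "expected_fate": "sub_functionalization"},
            {"genotype": "A", "gene_a": gid_of(tokens_a, "F2", 0),
             "gene_b": gid_of(tokens_a, "F2", 1), "family": "F2", "omega": 0.0,
             "ks_target": 0.15, "expr_diverged": False, "prom_diverged": False,
             "domains_differ": False, "expected_fate": "genetic_redundancy"},
            {"genotype": "B", "gene_a": gid_of(tokens_b, "F2", 0),
             "gene_b": gid_of(tokens_b, "F2", 1), "family": "F2", "omega": 0.0,
             "ks_target": 0.15, "expr_diverged": False, "prom_diverged": False,
             "domains_differ": False, "expected_fate": "genetic_redundancy"},
        ]
    )
    truth_clusters = pd.DataFrame(
        [
            {"family": "F1", "genotype": "A",
             "members": ",".join(gid_of(tokens_a, "F1", j) for j in range(3)),
             "category": "private"},
            {"family": "F2", "genotype": "A",
             "members": ",".join(gid_of(tokens_a, "F2", j) for j in range(2)),
             "category": "core"},
            {"family": "F2", "genotype": "B",
             "members": ",".join(gid_of(tokens_b, "F2", j) for j in range(2)),
             "category": "core"},
        ]
    )
    truth = SyntheticTruth(
        genes=pd.DataFrame(truth_gene_rows),
        pairs=truth_pairs,
        clusters=truth_clusters,
        families=pd.DataFrame(
            [
                {"family": "F1", "category": "private", "genotypes": "A"},
                {"family": "F2", "category": "core", "genotypes": "A,B"},
            ]
        ),
    )
    return SyntheticBundle(
        config=cfg,
        genotypes={"A": data_a, "B": data_b},
        orthogroups=pd.DataFrame(og_rows, columns=["og_id", "genotype", "gene_id"]),
        truth=truth,
    )


def _find_unplaced_token(gdata: GenotypeData) -> dict:
    """Recover the token dict of the single unplaced gene via its GeneModel."""
    g = next(g for g in gdata.genes if not g.located)
    return {"kind": "bg", "gene_id": g.gene_id, "chromosome": g.chromosome,
            "is_te": g.is_te, "member": -1}


# --- file emission ------------------------------------------------------------


def _write_fasta(records: Sequence[tuple], path: Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_bundle(bundle: SyntheticBundle, out_dir) -> dict:
    """Emit the bundle as the exact formats genome_io consumes.

    Layout: ``<out>/<genotype>/{genes.gff3,genome.fa,cds.fa,protein.fa,
    annotation.tsv,tpm.tsv}`` plus ``<out>/orthogroups.tsv`` and
    ``<out>/truth/*.tsv``. Returns a path map per genotype.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for gt in sorted(bundle.genotypes):
        gdata = bundle.genotypes[gt]
        gdir = out / gt
        gdir.mkdir(exist_ok=True)
        genes = sorted(gdata.genes, key=lambda g: (g.chromosome, g.start, g.gene_id))
        with open(gdir / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for chrom in sorted(gdata.genome):
                fh.write(f"##sequence-region {chrom} 1 {len(gdata.genome[chrom])}\n")
            for g in genes:
                base = f"{g.chromosome}\ttandemscape\t"
                coords = f"\t{g.start}\t{g.end}\t.\t{g.strand}\t"
                fh.write(f"{base}gene{coords}.\tID={g.gene_id}\n")
                fh.write(f"{base}mRNA{coords}.\tID={g.gene_id}.1;Parent={g.gene_id}\n")
                fh.write(f"{base}CDS{coords}0\tID={g.gene_id}.1.cds;Parent={g.gene_id}.1\n")
        _write_fasta(sorted(gdata.genome.items()), gdir / "genome.fa")
        _write_fasta([(g.gene_id, g.cds) for g in genes], gdir / "cds.fa")
        _write_fasta([(g.gene_id, g.protein) for g in genes], gdir / "protein.fa")
        ann = pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "pfam": ",".join(sorted(g.pfam_domains)),
                    "go": ",".join(sorted(g.go_terms)),
                    "ahrd_stars": g.ahrd_score,
                    "te_flag": int(g.is_te),
                }
                for g in genes
            ]
        )
        ann.to_csv(gdir / "annotation.tsv", sep="\t", index=False)
        tpm = gdata.tpm.copy()
        tpm.index.name = "gene_id"
        tpm.to_csv(gdir / "tpm.tsv", sep="\t")
        paths[gt] = {
            "gff3": gdir / "genes.gff3",
            "genome": gdir / "genome.fa",
            "cds": gdir / "cds.fa",
            "protein": gdir / "protein.fa",
            "annotation": gdir / "annotation.tsv",
            "tpm": gdir / "tpm.tsv",
        }
    bundle.orthogroups.sort_values(["og_id", "genotype", "gene_id"]).to_csv(
        out / "orthogroups.tsv", sep="\t", index=False
    )
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    bundle.truth.genes.to_csv(tdir / "genes.tsv", sep="\t", index=False)
    bundle.truth.pairs.to_csv(tdir / "pairs.tsv", sep="\t", index=False)
    bundle.truth.clusters.to_csv(tdir / "clusters.tsv", sep="\t", index=False)
    bundle.truth.families.to_csv(tdir / "families.tsv", sep="\t", index=False)
    return paths
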