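"""End-to-end orchestration and publication-style summary tables.

``run_pipeline`` takes a bundle (a directory written by
:func:`tandemscape.synthetic_data.write_bundle`, or an in-memory
:class:`SyntheticBundle`) and runs every stage per genotype — TE-orthogroup
filter, same-chromosome homology, tandem pair/cluster calling, Ka/Ks,
expression and promoter divergence with their random-pair nulls, enrichment —
then the cross-genotype stages: core/shared/private categorisation, fate
calls, divergence correlations and differential enrichment.

All randomness (null-pair sampling) is derived from the single seed in
:class:`RunConfig`; re-running on identical inputs reproduces byte-identical
TSV outputs. Summary percentages are computed from their own counts and
rounded half-up to 2 decimals; cross-genotype "averages" are unweighted means
of per-genotype percentages, not pooled counts.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import comparative, enrichment, expression, genome_io, homology, promoter
from . import selection, synthetic_data, tdg_cluster
from .utils import derive_seed, mean_pct, pct_half_up

log = logging.getLogger("tandemscape")


@dataclass
class RunConfig:
    evalue: float = 1e-10
    bsr: float = 0.30
    coverage: float = 0.50
    max_intervening: int = 10
    tpm_cutoff: float = 0.5
    ks_max: float = 2.0
    fdr: float = 0.05
    min_term_count: int = 10
    window: int = 1_000_000
    promoter_len: int = 1000
    prefilter: bool = True
    prefilter_k: int = 13
    prefilter_min_shared: int = 1
    seed: int = 0

    def thresholds(self) -> homology.HomologyThresholds:
        return homology.HomologyThresholds(self.evalue, self.bsr, self.coverage)


@dataclass
class GenotypeResult:
    name: str
    genes: list
    filtered: list
    hits: list
    pairs: list
    clusters: list
    summary: dict
    pair_table: pd.DataFrame
    expr_summary: pd.DataFrame
    expr_q95: float
    prom_q95: float
    pfam_enrichment: pd.DataFrame
    go_enrichment: pd.DataFrame
    n_genes_before_te: int = 0
    n_genes_after_te: int = 0


@dataclass
class PipelineResult:
    config: RunConfig
    genotypes: dict
    categories: pd.DataFrame
    master: pd.DataFrame
    fates: pd.DataFrame
    fate_summary: pd.DataFrame
    correlations: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    te_report: pd.DataFrame
    differential: pd.DataFrame


def load_bundle_dir(path) -> synthetic_data.SyntheticBundle:
    """Load a bundle directory back into memory through the standard readers."""
    root = Path(path)
    genotypes = {}
    for gdir in sorted(p for p in root.iterdir() if (p / "genes.gff3").exists()):
        gt = gdir.name
        genes = genome_io.load_genotype(
            gdir / "genes.gff3", gdir / "cds.fa", gdir / "protein.fa",
            gdir / "annotation.tsv", genotype=gt,
        )
        genome = _read_fasta_dict(gdir / "genome.fa")
        tpm = pd.read_csv(gdir / "tpm.tsv", sep="\t", index_col="gene_id")
        genotypes[gt] = synthetic_data.GenotypeData(name=gt, genes=genes,
                                                    genome=genome, tpm=tpm)
    ogs = pd.read_csv(root / "orthogroups.tsv", sep="\t", dtype=str)
    return synthetic_data.SyntheticBundle(
        config=None, genotypes=genotypes, orthogroups=ogs, truth=None
    )


def _read_fasta_dict(path) -> dict:
    from Bio import SeqIO

    with open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def _orthogroups_from_table(df: pd.DataFrame) -> list:
    ogs: dict = {}
    for row in df.itertuples(index=False):
        og = ogs.setdefault(row.og_id, genome_io.Orthogroup(og_id=row.og_id, members={}))
        og.members.setdefault(row.genotype, set()).add(row.gene_id)
    return [ogs[k] for k in sorted(ogs)]


def _process_genotype(
    gt: str, gdata, orthogroups, config: RunConfig, gt_index: int
) -> GenotypeResult:
    genes = gdata.genes
    gt_ogs = [og for og in orthogroups if gt in og.members]
    if gt_ogs:
        scoped = [
            genome_io.Orthogroup(og.og_id, {gt: set(og.members[gt])}) for og in gt_ogs
        ]
        scoped = genome_io.classify_te_orthogroups(scoped, genes)
        genes = genome_io.propagate_te_flags(genes, scoped)
    filtered = genome_io.non_te_located_genes(genes)
    hits = homology.same_chromosome_pairs(
        filtered,
        thresholds=config.thresholds(),
        prefilter=config.prefilter,
        prefilter_k=config.prefilter_k,
        prefilter_min_shared=config.prefilter_min_shared,
    )
    pairs = tdg_cluster.build_pairs(hits, filtered, config.max_intervening)
    clusters = tdg_cluster.build_clusters(pairs, filtered)
    summary = tdg_cluster.cluster_summary(clusters, filtered, pairs)
    by_id = {g.gene_id: g for g in genes}

    # sequence divergence per tandem pair
    kaks_rows = {}
    for p in pairs:
        pid = f"{p.gene_a}|{p.gene_b}"
        res = selection.kaks_from_sequences(
            by_id[p.gene_a].cds, by_id[p.gene_b].cds, pair_id=pid, ks_max=config.ks_max
        )
        kaks_rows[pid] = res

    # expression divergence
    tpm = gdata.tpm
    expr_summary = expression.summarize_expression(tpm, config.tpm_cutoff)
    tdg_gene_ids = {gid for c in clusters for gid in c.member_genes}
    n_expr_pairs = sum(
        bool(expr_summary.loc[p.gene_a, "expressed"] and expr_summary.loc[p.gene_b, "expressed"])
        for p in pairs
    )
    expr_q95 = math.nan
    expr_calls = {}
    if n_expr_pairs >= 1:
        try:
            null = expression.random_pair_null(
                tpm, tdg_gene_ids, n_expr_pairs,
                seed=derive_seed(config.seed, gt_index, 1),
                tpm_cutoff=config.tpm_cutoff,
            )
            expr_q95 = null.q95
        except ValueError as exc:
            log.warning("%s: expression null unavailable (%s)", gt, exc)
    if not math.isnan(expr_q95):
        for call in expression.call_expression_divergence(
            pairs, tpm, expr_q95, config.tpm_cutoff
        ):
            expr_calls[call.pair_id] = call

    # promoter divergence
    located = [g for g in genes if g.located]
    by_chrom: dict = {}
    for g in located:
        by_chrom.setdefault(g.chromosome, []).append(g)
    promoters = {}
    for g in filtered:
        rec = promoter.extract_promoter(
            g, gdata.genome[g.chromosome], by_chrom[g.chromosome], config.promoter_len
        )
        if rec.seq:
            promoters[g.gene_id] = rec.seq
    n_prom_pairs = sum(
        p.gene_a in promoters and p.gene_b in promoters for p in pairs
    )
    prom_q95 = math.nan
    prom_calls = {}
    if n_prom_pairs >= 1:
        try:
            _, prom_q95 = promoter.random_pair_null_ps(
                promoters, tdg_gene_ids, n_prom_pairs,
                seed=derive_seed(config.seed, gt_index, 2),
            )
        except ValueError as exc:
            log.warning("%s: promoter null unavailable (%s)", gt, exc)
    if not math.isnan(prom_q95):
        for call in promoter.call_promoter_divergence(pairs, promoters, prom_q95):
            prom_calls[call.pair_id] = call

    # enrichment over the filtered background
    background = {g.gene_id for g in filtered}
    pfam_sets: dict = {}
    go_sets: dict = {}
    for g in filtered:
        for dom in g.pfam_domains:
            pfam_sets.setdefault(dom, set()).add(g.gene_id)
        for term in g.go_terms:
            go_sets.setdefault(term, set()).add(g.gene_id)
    empty = pd.DataFrame(
        columns=["term", "a", "b", "c", "d", "odds_ratio", "p",
                 "n_tdg_with_term", "fdr", "significant"]
    )
    if tdg_gene_ids and background:
        pfam_enr = (
            enrichment.fisher_enrichment(pfam_sets, tdg_gene_ids, background,
                                         config.fdr, config.min_term_count)
            if pfam_sets else empty.copy()
        )
        go_enr = (
            enrichment.fisher_enrichment(go_sets, tdg_gene_ids, background,
                                         config.fdr, config.min_term_count)
            if go_sets else empty.copy()
        )
    else:
        pfam_enr, go_enr = empty.copy(), empty.copy()

    # master pair table for this genotype
    rows = []
    for p in pairs:
        pid = f"{p.gene_a}|{p.gene_b}"
        res = kaks_rows[pid]
        ecall = expr_calls.get(pid)
        pcall = prom_calls.get(pid)
        rows.append(
            {
                "pair_id": pid,
                "genotype": gt,
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "chromosome": p.chromosome,
                "n_intervening": p.n_intervening,
                "cluster_id": p.cluster_id,
                "ka": res.ka,
                "ks": res.ks,
                "omega": res.omega if res.omega is not None else math.nan,
                "kaks_excluded": res.excluded,
                "kaks_reason": res.reason,
                "expr_r": ecall.r if ecall else math.nan,
                "expr_diverged": (
                    ecall.diverged if ecall and ecall.diverged is not None else None
                ),
                "ps": pcall.ps if pcall else math.nan,
                "prom_diverged": (
                    pcall.diverged if pcall and pcall.diverged is not None else None
                ),
                "domains_a": by_id[p.gene_a].pfam_domains,
                "domains_b": by_id[p.gene_b].pfam_domains,
            }
        )
    pair_table = pd.DataFrame(
        rows,
        columns=["pair_id", "genotype", "gene_a", "gene_b", "chromosome",
                 "n_intervening", "cluster_id", "ka", "ks", "omega",
                 "kaks_excluded", "kaks_reason", "expr_r", "expr_diverged",
                 "ps", "prom_diverged", "domains_a", "domains_b"],
    )
    return GenotypeResult(
        name=gt,
        genes=genes,
        filtered=filtered,
        hits=hits,
        pairs=pairs,
        clusters=clusters,
        summary=summary,
        pair_table=pair_table,
        expr_summary=expr_summary,
        expr_q95=expr_q95,
        prom_q95=prom_q95,
        pfam_enrichment=pfam_enr,
        go_enrichment=go_enr,
        n_genes_before_te=len(gdata.genes),
        n_genes_after_te=sum(not g.is_te for g in genes),
    )


def run_pipeline(bundle, config: RunConfig | None = None, out_dir=None) -> PipelineResult:
    """Run every stage on a bundle directory or in-memory bundle."""
    config = config or RunConfig()
    if not isinstance(bundle, synthetic_data.SyntheticBundle):
        bundle = load_bundle_dir(bundle)
    orthogroups = (
        _orthogroups_from_table(bundle.orthogroups)
        if isinstance(bundle.orthogroups, pd.DataFrame)
        else list(bundle.orthogroups)
    )
    results: dict = {}
    for i, gt in enumerate(sorted(bundle.genotypes)):
        results[gt] = _process_genotype(gt, bundle.genotypes[gt], orthogroups, config, i)

    # cross-genotype: categories via orthogroups
    gene_to_og: dict = {}
    for og in orthogroups:
        for gid in og.gene_ids():
            gene_to_og[gid] = og.og_id
    clusters_by_gt = {gt: res.clusters for gt, res in results.items()}
    cats = comparative.categorize_clusters(clusters_by_gt, gene_to_og,
                                           sorted(results))
    categories = pd.DataFrame(
        [{"cluster_id": c.cluster_id, "genotype": c.genotype, "category": c.category,
          "n_genotypes_present": len(c.genotypes_with_og_cluster)} for c in cats],
        columns=["cluster_id", "genotype", "category", "n_genotypes_present"],
    )

    master = (
        pd.concat([res.pair_table for res in results.values()], ignore_index=True)
        if results else pd.DataFrame()
    )
    if not master.empty:
        fate_calls = comparative.call_fates(master)
        master["fate"] = [f.fate for f in fate_calls]
        fates = pd.DataFrame(
            [{"pair_id": f.pair_id, "genotype": f.genotype, "fate": f.fate,
              "expression_diverged": f.expression_diverged, "omega": f.omega,
              "domains_identical": f.domains_identical, "reason": f.reason}
             for f in fate_calls]
        )
    else:
        fates = pd.DataFrame(columns=["pair_id", "genotype", "fate", "reason"])
    fate_summary = summarize_fates(fates)
    correlations = (
        comparative.divergence_correlations(master)
        if not master.empty
        else pd.DataFrame(columns=["x", "y", "r", "p", "n"])
    )

    table2 = _table2(results)
    table3 = _table3(results, categories)
    te_report = _te_report(results)
    per_gt_enr = {gt: res.pfam_enrichment for gt, res in results.items()
                  if not res.pfam_enrichment.empty}
    if len(per_gt_enr) >= 2:
        differential = enrichment.differential_enrichment(per_gt_enr)
    else:
        differential = pd.DataFrame()

    out = PipelineResult(
        config=config,
        genotypes=results,
        categories=categories,
        master=master,
        fates=fates,
        fate_summary=fate_summary,
        correlations=correlations,
        table2=table2,
        table3=table3,
        te_report=te_report,
        differential=differential,
    )
    if out_dir is not None:
        write_outputs(out, out_dir)
    return out


def summarize_fates(fates: pd.DataFrame) -> pd.DataFrame:
    """Fate proportions per genotype over eligible pairs + unweighted mean row.

    Eligible pairs are those with a complete fate input (no missing-input or
    undefined-omega reason).
    """
    fate_names = ["sub_functionalization", "genetic_redundancy",
                  "neo_functionalization", "unclassified"]
    rows = []
    genotypes = sorted(fates["genotype"].unique()) if not fates.empty else []
    for gt in genotypes:
        sub = fates[(fates["genotype"] == gt) & (fates["reason"] == "")]
        n = len(sub)
        row = {"genotype": gt, "n_eligible": n}
        for fate in fate_names:
            row[f"pct_{fate}"] = pct_half_up((sub["fate"] == fate).sum(), n)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        avg = {"genotype": "average", "n_eligible": int(df["n_eligible"].sum())}
        for fate in fate_names:
            avg[f"pct_{fate}"] = mean_pct(df[f"pct_{fate}"])
        df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return df


def _table2(results: Mapping[str, GenotypeResult]) -> pd.DataFrame:
    rows = []
    for gt in sorted(results):
        res = results[gt]
        tdg_ids = {gid for c in res.clusters for gid in c.member_genes}
        by_id = {g.gene_id: g for g in res.filtered}
        n_with_pfam = sum(bool(by_id[g].pfam_domains) for g in tdg_ids)
        expressed = res.expr_summary["expressed"]
        n_expressed = sum(bool(expressed.get(g, False)) for g in tdg_ids)
        cluster_ogs = {og for c in res.clusters for og in c.og_ids}
        rows.append(
            {
                "genotype": gt,
                "n_non_te_genes": res.n_genes_after_te,
                "n_non_te_located_genes": len(res.filtered),
                "n_clusters": res.summary["n_clusters"],
                "n_genes_in_clusters": res.summary["n_genes_in_clusters"],
                "pct_genes_in_clusters": res.summary["pct_genes_in_clusters"],
                "n_orthogroups": len(cluster_ogs),
                "pct_clusters_two_genes": res.summary["pct_clusters_two_genes"],
                "largest_cluster": res.summary["largest_cluster"],
                "pct_tdgs_with_pfam": pct_half_up(n_with_pfam, len(tdg_ids)),
                "n_pfam_enriched": int(res.pfam_enrichment["significant"].sum())
                if not res.pfam_enrichment.empty else 0,
                "pct_tdgs_expressed": pct_half_up(n_expressed, len(tdg_ids)),
            }
        )
    return pd.DataFrame(rows)


def _table3(results: Mapping[str, GenotypeResult], categories: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for gt in sorted(results):
        sub = categories[(categories["genotype"] == gt)
                         & (categories["category"] != "unset")]
        n = len(sub)
        row = {"genotype": gt, "n_clusters": n}
        for cat in ("private", "core", "shared"):
            cnt = int((sub["category"] == cat).sum())
            row[f"n_{cat}"] = cnt
            row[f"pct_{cat}"] = pct_half_up(cnt, n)
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        avg = {"genotype": "average",
               "n_clusters": int(df["n_clusters"].sum())}
        for cat in ("private", "core", "shared"):
            avg[f"n_{cat}"] = int(df[f"n_{cat}"].sum())
            avg[f"pct_{cat}"] = mean_pct(df[f"pct_{cat}"])
        df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return df


def _te_report(results: Mapping[str, GenotypeResult]) -> pd.DataFrame:
    rows = []
    for gt in sorted(results):
        res = results[gt]
        before, after = res.n_genes_before_te, res.n_genes_after_te
        rows.append({"genotype": gt, "n_genes_before": before, "n_genes_after": after,
                     "pct_te": pct_half_up(before - after, before)})
    df = pd.DataFrame(rows)
    if not df.empty:
        before = int(df["n_genes_before"].sum())
        after = int(df["n_genes_after"].sum())
        df = pd.concat(
            [df, pd.DataFrame([{"genotype": "total", "n_genes_before": before,
                                "n_genes_after": after,
                                "pct_te": pct_half_up(before - after, before)}])],
            ignore_index=True,
        )
    return df


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_outputs(result: PipelineResult, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _fmt(result.table2, out / "table2_cluster_summary.tsv")
    _fmt(result.table3, out / "table3_categories.tsv")
    _fmt(result.te_report, out / "te_filter_report.tsv")
    _fmt(result.fate_summary, out / "fate_summary.tsv")
    _fmt(result.correlations, out / "divergence_correlations.tsv")
    _fmt(result.categories, out / "cluster_categories.tsv")
    master = result.master.copy()
    if not master.empty:
        master["domains_a"] = master["domains_a"].map(lambda s: ",".join(sorted(s)))
        master["domains_b"] = master["domains_b"].map(lambda s: ",".join(sorted(s)))
    _fmt(master, out / "pair_master.tsv")
    _fmt(result.fates, out / "pair_fates.tsv")
    if not result.differential.empty:
        result.differential.to_csv(out / "differential_enrichment.tsv", sep="\t",
                                   float_format="%.6g")
    for gt, res in result.genotypes.items():
        gdir = out / gt
        gdir.mkdir(exist_ok=True)
        _fmt(res.pfam_enrichment, gdir / "pfam_enrichment.tsv")
        _fmt(res.go_enrichment, gdir / "go_enrichment.tsv")
        res.expr_summary.rename_axis("gene_id").reset_index().to_csv(
            gdir / "expression_summary.tsv", sep="\t", index=False, float_format="%.6g"
        )
        cluster_rows = [
            {"cluster_id": c.cluster_id, "chromosome": c.chromosome,
             "size": c.size, "members": ",".join(c.member_genes),
             "category": c.category}
            for c in res.clusters
        ]
        _fmt(pd.DataFrame(cluster_rows,
                          columns=["cluster_id", "chromosome", "size", "members",
                                   "category"]),
             gdir / "clusters.tsv")
        # BED export: 0-based half-open cluster spans
        by_id = {g.gene_id: g for g in res.filtered}
        bed_rows = []
        for c in res.clusters:
            members = [by_id[g] for g in c.member_genes]
            bed_rows.append((c.chromosome, min(m.start for m in members) - 1,
                             max(m.end for m in members), c.cluster_id))
        with open(gdir / "clusters.bed", "w") as fh:
            for row in bed_rows:
                fh.write("\t".join(str(x) for x in row) + "\n")
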