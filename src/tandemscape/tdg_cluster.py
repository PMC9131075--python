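"""Tandem-duplicate pair/cluster construction and genomic density analysis.

A tandemly duplicated gene (TDG) pair is a homologous same-chromosome pair
separated by at most ``max_intervening`` (default 10) retained genes, counted
over the filtered (non-TE, located) gene order. Clusters are the connected
components of the pair graph per chromosome — the minimal grouping consistent
with "a cluster is a group of pairs".

Density tracks report, per tiling window (default 1 Mb), the proportion of
bases covered by a feature class after merging overlapping intervals. The
density model regresses TDG density on covariate densities (OLS), min–max
scales the residuals to [0, 1], and tests them against Uniform(0, 1) with a
one-sample Kolmogorov–Smirnov test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome_io import GeneModel
from .homology import HomologyHit
from .utils import pct_half_up


@dataclass
class TDGPair:
    gene_a: str
    gene_b: str
    genotype: str
    chromosome: str
    n_intervening: int
    cluster_id: str | None = None


@dataclass
class TDGCluster:
    cluster_id: str
    genotype: str
    chromosome: str
    member_genes: list  # ordered by rank
    og_ids: frozenset = field(default_factory=frozenset)
    category: str = "unset"

    @property
    def size(self) -> int:
        return len(self.member_genes)


def build_pairs(
    hits: Sequence[HomologyHit],
    genes: Sequence[GeneModel],
    max_intervening: int = 10,
) -> list[TDGPair]:
    """Keep homologous pairs with at most *max_intervening* genes between them."""
    by_id = {g.gene_id: g for g in genes}
    pairs = []
    for h in hits:
        ga, gb = by_id[h.gene_a], by_id[h.gene_b]
        if ga.rank > gb.rank:
            ga, gb = gb, ga
        n_between = gb.rank - ga.rank - 1
        if n_between <= max_intervening:
            pairs.append(
                TDGPair(
                    gene_a=ga.gene_id,
                    gene_b=gb.gene_id,
                    genotype=ga.genotype,
                    chromosome=ga.chromosome,
                    n_intervening=n_between,
                )
            )
    return pairs


def build_clusters(pairs: Sequence[TDGPair], genes: Sequence[GeneModel]) -> list[TDGCluster]:
    """Connected components of the pair graph, one graph per chromosome.

    Cluster ids are deterministic: ``<genotype>:<chromosome>:c<k>`` with k
    numbering clusters by leftmost member rank. The cluster_id is also written
    back onto each pair.
    """
    rank = {g.gene_id: g.rank for g in genes}
    by_chrom: dict = {}
    for p in pairs:
        by_chrom.setdefault((p.genotype, p.chromosome), []).append(p)

    clusters: list[TDGCluster] = []
    for (genotype, chrom) in sorted(by_chrom):
        graph = nx.Graph()
        for p in by_chrom[(genotype, chrom)]:
            graph.add_edge(p.gene_a, p.gene_b)
        comps = sorted(
            (sorted(c, key=lambda gid: rank[gid]) for c in nx.connected_components(graph)),
            key=lambda members: rank[members[0]],
        )
        gene_to_cid = {}
        for k, members in enumerate(comps, start=1):
            cid = f"{genotype}:{chrom}:c{k:04d}"
            clusters.append(
                TDGCluster(cluster_id=cid, genotype=genotype, chromosome=chrom,
                           member_genes=list(members))
            )
            for gid in members:
                gene_to_cid[gid] = cid
        for p in by_chrom[(genotype, chrom)]:
            p.cluster_id = gene_to_cid[p.gene_a]
    return clusters


def cluster_summary(
    clusters: Sequence[TDGCluster],
    genes: Sequence[GeneModel],
    pairs: Sequence[TDGPair] | None = None,
) -> dict:
    """Per-genotype summary of the detected clusters.

    Percentages are over the located non-TE gene universe passed in *genes*
    and rounded half-up to 2 decimals.
    """
    n_genes = len(genes)
    clustered = sorted({gid for c in clusters for gid in c.member_genes})
    sizes = sorted(c.size for c in clusters)
    size_hist: dict[int, int] = {}
    for s in sizes:
        size_hist[s] = size_hist.get(s, 0) + 1
    intervening_hist: dict[int, int] = {}
    for p in pairs or ():
        intervening_hist[p.n_intervening] = intervening_hist.get(p.n_intervening, 0) + 1
    return {
        "n_genes": n_genes,
        "n_clusters": len(clusters),
        "n_genes_in_clusters": len(clustered),
        "pct_genes_in_clusters": pct_half_up(len(clustered), n_genes),
        "pct_clusters_two_genes": pct_half_up(size_hist.get(2, 0), len(clusters)),
        "largest_cluster": sizes[-1] if sizes else 0,
        "size_histogram": size_hist,
        "intervening_histogram": intervening_hist,
    }


# --- density ------------------------------------------------------------------


def merge_intervals(intervals: Sequence[tuple]) -> list[tuple]:
    """Union of 1-based inclusive intervals, as a sorted list."""
    ivs = sorted(intervals)
    merged: list[list] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [tuple(iv) for iv in merged]


def windowed_density(
    intervals_by_class: Mapping[str, Sequence[tuple]],
    chrom_lengths: Mapping[str, int],
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Covered-base proportion per tiling window for each feature class.

    *intervals_by_class* maps a class name to (chrom, start, end) tuples,
    1-based inclusive. Windows are half-open [k·w, (k+1)·w) in 0-based terms,
    the last one truncated to the chromosome end. A feature extending beyond
    its chromosome is an error.
    """
    rows = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        starts = np.arange(0, length, window)
        for ws in starts:
            rows.append({"chromosome": chrom, "window_start": int(ws),
                         "window_end": int(min(ws + window, length))})
    df = pd.DataFrame(rows)
    for cls, intervals in intervals_by_class.items():
        per_chrom: dict = {}
        for chrom, s, e in intervals:
            if chrom not in chrom_lengths:
                raise ValueError(f"{cls}: unknown chromosome {chrom}")
            if s < 1 or e > chrom_lengths[chrom]:
                raise ValueError(f"{cls}: interval ({s},{e}) outside {chrom}")
            per_chrom.setdefault(chrom, []).append((s, e))
        densities = []
        for row in df.itertuples(index=False):
            ws, we = row.window_start, row.window_end  # 0-based half-open
            covered = 0
            for s, e in merge_intervals(per_chrom.get(row.chromosome, [])):
                lo = max(s - 1, ws)
                hi = min(e, we)
                if hi > lo:
                    covered += hi - lo
            densities.append(covered / (we - ws))
        df[cls] = densities
    return df


@dataclass
class DensityModelResult:
    coefficients: pd.Series
    residuals: np.ndarray
    ks_D: float
    ks_p: float
    pearson_r: dict
    degenerate: bool = False


def density_model(
    track: pd.DataFrame,
    tdg_col: str = "tdg",
    covariate_cols: Sequence[str] | None = None,
) -> DensityModelResult:
    """OLS of TDG density on covariate densities + residual uniformity KS test.

    Residuals are min–max scaled to [0, 1] before the one-sample KS test
    against Uniform(0, 1). Zero-variance residuals are degenerate: D is
    reported as 1 with the flag set.
    """
    if covariate_cols is None:
        covariate_cols = [
            c for c in track.columns
            if c not in {tdg_col, "chromosome", "window_start", "window_end"}
        ]
    y = track[tdg_col].to_numpy(dtype=float)
    if len(y) < len(covariate_cols) + 2:
        raise ValueError("fewer windows than covariates + intercept")
    X = sm.add_constant(track[list(covariate_cols)].to_numpy(dtype=float), has_constant="add")
    fit = sm.OLS(y, X).fit()
    resid = fit.resid
    names = ["const", *covariate_cols]
    pearson = {
        c: float(stats.pearsonr(y, track[c].to_numpy(dtype=float))[0])
        if np.std(track[c].to_numpy(dtype=float)) > 0 and np.std(y) > 0
        else float("nan")
        for c in covariate_cols
    }
    span = resid.max() - resid.min()
    if span <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return DensityModelResult(
            coefficients=pd.Series(fit.params, index=names),
            residuals=resid,
            ks_D=1.0,
            ks_p=0.0,
            pearson_r=pearson,
            degenerate=True,
        )
    scaled = (resid - resid.min()) / span
    ks = stats.kstest(scaled, "uniform")
    return DensityModelResult(
        coefficients=pd.Series(fit.params, index=names),
        residuals=resid,
        ks_D=float(ks.statistic),
        ks_p=float(ks.pvalue),
        pearson_r=pearson,
    )
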