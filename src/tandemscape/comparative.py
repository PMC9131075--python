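"""Cross-genotype comparison of tandem clusters and duplicate-fate calls.

Clusters are linked across genotypes through orthogroups: a cluster is present
in a genotype when that genotype has a tandem cluster sharing at least one
orthogroup with it. A cluster present in every genotype is *core*, in exactly
one *private* (lineage-specific), otherwise *shared*.

Duplicate-retention fates combine three divergence axes per pair, applied in
order of precedence:

1. neo-functionalization — protein domain sets differ and ω > 1;
2. sub-functionalization — expression diverged, ω < 1, identical domains;
3. genetic redundancy — expression conserved, ω < 1, identical domains;
4. otherwise unclassified.

"Identical domains" is set equality of Pfam ids (copy number ignored).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .tdg_cluster import TDGCluster


@dataclass
class ClusterCategory:
    cluster_id: str
    genotype: str
    category: str  # core / shared / private / unset
    genotypes_with_og_cluster: frozenset = field(default_factory=frozenset)


@dataclass
class FateCall:
    pair_id: str
    genotype: str
    fate: str  # sub_functionalization / genetic_redundancy / neo_functionalization / unclassified
    expression_diverged: bool | None = None
    omega: float | None = None
    domains_identical: bool | None = None
    reason: str = ""


def categorize_clusters(
    clusters_by_genotype: Mapping[str, Sequence[TDGCluster]],
    gene_to_og: Mapping[str, str],
    genotypes: Sequence[str] | None = None,
) -> list[ClusterCategory]:
    """Core/shared/private label per cluster via orthogroup sharing.

    A cluster spanning several orthogroups is present wherever any of them is
    tandem-clustered (presence OR-ed over its OGs). Clusters with no
    OG-annotated member stay ``unset``.
    """
    genotypes = list(genotypes) if genotypes is not None else sorted(clusters_by_genotype)
    og_presence: dict = {}
    cluster_ogs: dict = {}
    for gt, clusters in clusters_by_genotype.items():
        for cl in clusters:
            ogs = {gene_to_og[g] for g in cl.member_genes if g in gene_to_og}
            cluster_ogs[cl.cluster_id] = ogs
            cl.og_ids = frozenset(ogs)
            for og in ogs:
                og_presence.setdefault(og, set()).add(gt)
    out = []
    for gt in genotypes:
        for cl in clusters_by_genotype.get(gt, ()):
            ogs = cluster_ogs[cl.cluster_id]
            if not ogs:
                cl.category = "unset"
                out.append(ClusterCategory(cl.cluster_id, gt, "unset"))
                continue
            present = set()
            for og in ogs:
                present |= og_presence[og]
            if present == set(genotypes):
                cat = "core"
            elif len(present) == 1:
                cat = "private"
            else:
                cat = "shared"
            cl.category = cat
            out.append(ClusterCategory(cl.cluster_id, gt, cat, frozenset(present)))
    return out


def positional_profile(
    clusters: Sequence[TDGCluster],
    categories: Mapping[str, str],
    genes_by_id: Mapping[str, object],
    chrom_lengths: Mapping[str, int],
    centromeres: Mapping[str, int] | None = None,
) -> dict:
    """Normalised chromosomal position per category + private-vs-rest rank test.

    The position of a cluster is its midpoint over the chromosome length; with
    centromere coordinates supplied the metric becomes the distance to the
    centromere as a fraction of chromosome length (smaller = more
    pericentromeric). Falls back to |position − 0.5| (midpoint distance) when
    no centromere map is given.
    """
    positions: dict = {"core": [], "shared": [], "private": []}
    for cl in clusters:
        cat = categories.get(cl.cluster_id, "unset")
        if cat not in positions:
            continue
        members = [genes_by_id[g] for g in cl.member_genes]
        mid = (min(m.start for m in members) + max(m.end for m in members)) / 2.0
        length = chrom_lengths[cl.chromosome]
        pos = mid / length
        if centromeres is not None and cl.chromosome in centromeres:
            metric = abs(mid - centromeres[cl.chromosome]) / length
        else:
            metric = abs(pos - 0.5)
        positions[cat].append({"cluster_id": cl.cluster_id, "position": pos,
                               "centromere_distance": metric})
    private = [p["centromere_distance"] for p in positions["private"]]
    rest = [p["centromere_distance"]
            for cat in ("core", "shared") for p in positions[cat]]
    if private and rest:
        test = stats.mannwhitneyu(private, rest, alternative="less")
        u, p = float(test.statistic), float(test.pvalue)
    else:
        u, p = math.nan, math.nan
    return {"positions": positions, "mannwhitney_u": u, "mannwhitney_p": p}


def divergence_correlations(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations across the divergence axes.

    Expects columns expr_r (expression correlation), ps (promoter similarity),
    ks and omega; reports r and two-sided p for (expr_r, ps), (ps, ks),
    (expr_r, ks) and (expr_r, omega). Fewer than 3 complete pairs leaves the
    correlation undefined (NaN).
    """
    combos = [("expr_r", "ps"), ("ps", "ks"), ("expr_r", "ks"), ("expr_r", "omega")]
    rows = []
    for x, y in combos:
        sub = pair_table[[x, y]].dropna()
        if len(sub) < 3 or sub[x].std() == 0 or sub[y].std() == 0:
            rows.append({"x": x, "y": y, "r": math.nan, "p": math.nan, "n": len(sub)})
            continue
        r, p = stats.pearsonr(sub[x], sub[y])
        rows.append({"x": x, "y": y, "r": float(r), "p": float(p), "n": len(sub)})
    return pd.DataFrame(rows)


def call_fate(
    expression_diverged: bool | None,
    omega: float | None,
    domains_a: frozenset | None,
    domains_b: frozenset | None,
    genotype: str = "",
    pair_id: str = "",
) -> FateCall:
    """Apply the fate decision rules to one pair."""
    if expression_diverged is None or domains_a is None or domains_b is None:
        return FateCall(pair_id, genotype, "unclassified",
                        expression_diverged, omega, None, reason="missing input")
    identical = set(domains_a) == set(domains_b)
    if omega is None:
        return FateCall(pair_id, genotype, "unclassified", expression_diverged,
                        None, identical, reason="omega undefined or excluded")
    if not identical and omega > 1.0:
        fate = "neo_functionalization"
    elif expression_diverged and omega < 1.0 and identical:
        fate = "sub_functionalization"
    elif not expression_diverged and omega < 1.0 and identical:
        fate = "genetic_redundancy"
    else:
        fate = "unclassified"
    return FateCall(pair_id, genotype, fate, expression_diverged, omega, identical)


def call_fates(pair_table: pd.DataFrame) -> list[FateCall]:
    """Fate call per row of a pair table.

    Expects columns pair_id, genotype, expr_diverged (nullable boolean), omega
    (NaN when undefined/excluded), domains_a, domains_b (frozensets or None).
    """
    calls = []
    for row in pair_table.itertuples(index=False):
        expr = row.expr_diverged
        if expr is not None and not isinstance(expr, bool):
            expr = None if (isinstance(expr, float) and math.isnan(expr)) else bool(expr)
        omega = row.omega
        if omega is not None and isinstance(omega, float) and math.isnan(omega):
            omega = None
        calls.append(call_fate(expr, omega, row.domains_a, row.domains_b,
                               genotype=row.genotype, pair_id=row.pair_id))
    return calls
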