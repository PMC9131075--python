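"""Term over-representation among tandem duplicates.

For each Pfam domain (or flat GO term) a 2×2 table is built over the
background gene universe — a = genes with the term among TDGs, b = with the
term among non-TDGs, c = TDGs without the term, d = non-TDGs without it — and
tested with a two-sided Fisher exact test. P-values are Benjamini–Hochberg
adjusted over all tested terms; a term is significant when FDR < 0.05 *and*
at least ``min_count`` (default 10) TDGs carry it.

GO terms are tested flat (no ontology-graph propagation); the cross-genotype
differential enrichment z-scores row-standardise per-genotype fold
enrichments of terms enriched in at least one genotype.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FDR_THRESHOLD = 0.05
MIN_TDG_WITH_TERM = 10


@dataclass
class EnrichmentResult:
    term: str
    a: int  # term ∩ TDG
    b: int  # term ∩ non-TDG
    c: int  # non-term ∩ TDG
    d: int  # non-term ∩ non-TDG
    odds_ratio: float
    p: float
    fdr: float
    significant: bool
    n_tdg_with_term: int


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def fisher_enrichment(
    term_sets: Mapping[str, set],
    tdg_genes: set,
    background_genes: set,
    fdr_threshold: float = FDR_THRESHOLD,
    min_count: int = MIN_TDG_WITH_TERM,
    alternative: str = "two-sided",
) -> pd.DataFrame:
    """Fisher exact enrichment of each term in TDGs vs the background.

    Returns a DataFrame sorted by p with the 2×2 counts, odds ratio, raw and
    BH-adjusted p, and the combined significance call.
    """
    if not background_genes:
        raise ValueError("empty background gene set")
    tdg = set(tdg_genes) & set(background_genes)
    if not set(tdg_genes) <= set(background_genes):
        raise ValueError("tdg_genes must be a subset of background_genes")
    non_tdg = set(background_genes) - tdg
    rows = []
    for term in sorted(term_sets):
        members = set(term_sets[term]) & set(background_genes)
        a = len(members & tdg)
        b = len(members & non_tdg)
        c = len(tdg) - a
        d = len(non_tdg) - b
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
        rows.append({"term": term, "a": a, "b": b, "c": c, "d": d,
                     "odds_ratio": float(odds) if math.isfinite(odds) else math.nan,
                     "p": float(p), "n_tdg_with_term": a})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(fdr=[], significant=[])
    df["fdr"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = (df["fdr"] < fdr_threshold) & (df["n_tdg_with_term"] >= min_count)
    return df.sort_values(["p", "term"], kind="stable").reset_index(drop=True)


def fold_enrichment(a: int, b: int, c: int, d: int) -> float:
    """Observed TDG share with the term over the background term frequency."""
    total = a + b + c + d
    tdg_total = a + c
    term_total = a + b
    if tdg_total == 0 or term_total == 0 or total == 0:
        return 0.0
    return (a / tdg_total) / (term_total / total)


def differential_enrichment(per_genotype: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Row-z-scored fold enrichments (terms × genotypes).

    Terms significantly enriched in at least one genotype are retained; a term
    absent from a genotype's table contributes fold 0. Rows with zero variance
    z-score to all zeros.
    """
    genotypes = sorted(per_genotype)
    if len(genotypes) < 2:
        raise ValueError("need results from at least 2 genotypes")
    keep: set = set()
    folds: dict = {}
    for gt in genotypes:
        df = per_genotype[gt]
        folds[gt] = {
            row.term: fold_enrichment(row.a, row.b, row.c, row.d)
            for row in df.itertuples(index=False)
        }
        keep.update(df.loc[df["significant"], "term"])
    terms = sorted(keep)
    mat = np.array([[folds[gt].get(t, 0.0) for gt in genotypes] for t in terms])
    if mat.size == 0:
        return pd.DataFrame(columns=genotypes)
    mean = mat.mean(axis=1, keepdims=True)
    std = mat.std(axis=1, ddof=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(std > 0, (mat - mean) / std, 0.0)
    return pd.DataFrame(z, index=terms, columns=genotypes)
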