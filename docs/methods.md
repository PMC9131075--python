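# Methods

## Scope and data model

The package analyses tandem gene duplication per genotype and compares the
results across genotypes. All coordinates are GFF3-style 1-based inclusive.
Each gene carries the CDS and protein of its longest isoform (chosen by CDS
length, ties broken by transcript id), a TE flag, an AHRD quality score
(0–3 "stars" of an automated functional annotation), Pfam domain ids and GO
terms. Genes on configured "unplaced" scaffolds keep `located=False` and are
excluded from all positional analyses.

TE filtering is done at the orthogroup level: an orthogroup is non-TE iff
strictly less than 30% of its member genes are TE-flagged **and** the mean
AHRD score of its members is ≥ 2; all genes of a TE orthogroup are treated as
TE genes downstream. Ranks (0-based start-order indices per chromosome) are
recomputed after the TE/location filter, so intervening-gene counts operate
on the analysed gene universe — the alternative (counting over all annotated
genes) is a documented config choice, not the default.

## Homology and cluster calling

All gene pairs on the same chromosome are compared by Smith–Waterman local
alignment of their CDS (match +2, mismatch −3, gap open 5, extend 2; N never
matches). Raw scores are converted with Karlin–Altschul statistics,
bits = (λS − ln K)/ln 2 with λ = 0.625, K = 0.41 (BLASTN-like), and
E = m·n·2^(−bits). This replaces an external BLAST dependency; absolute
e-values differ somewhat from NCBI BLAST (no finite-size edge corrections),
but the thresholds operate on the same scales and are configurable. A pair is
homologous when E ≤ 1e−10, bit-score ratio ≥ 0.30 and coverage of both
sequences ≥ 0.50. The *bit-score ratio* is the pair's bit score over the
smaller of the two self-alignment bit scores, so identical sequences score
exactly 1; coverage is the aligned span over the sequence length (single best
local alignment, no HSP chaining). Self-alignment scores are computed
analytically (best contiguous run of the per-base diagonal scores — a
maximum-subarray problem), which is exact under this scoring.

A homologous pair is *tandem* when at most 10 retained genes lie strictly
between the two copies. Clusters are connected components of the tandem-pair
graph per chromosome (single linkage) — the minimal grouping consistent with
a cluster being "a group of pairs". Cluster ids are deterministic
(genotype, chromosome, leftmost-member order).

An optional shared-k-mer prefilter (default k = 13, ≥ 1 shared k-mer) skips
candidate pairs with no exact 13-mer in common before aligning. At the
divergence levels that can pass the thresholds above (roughly ≤ 25%
nucleotide divergence) dozens of shared 13-mers survive in expectation, so
the filter is a pure speedup; a test compares filtered and unfiltered scans
on simulated data and requires identical accepted pairs.

All-vs-all is O(n²) per chromosome; with the prefilter a 4-genotype,
2000-genes-per-genotype dataset (10 chromosomes each) runs end to end —
generation, file round trip, homology, Ka/Ks, both divergence nulls,
enrichment, categories, fates — in a few minutes on one CPU. These are the
problem sizes used by the test suite; the method itself has no intrinsic
size limit.

## Density analysis

Feature densities (TDGs, non-TE genes, DNA/RNA TEs) are covered-base
proportions per tiling 1 Mb window (1.5 Mb available via config; tiling
rather than overlapping windows, since a step size for "sliding" would be an
extra free parameter). TDG density is regressed on the covariate densities by
OLS; the residuals are min–max scaled to [0, 1] and tested against
Uniform(0, 1) with a one-sample Kolmogorov–Smirnov test. Residuals are not
naturally on [0, 1], so the min–max scaling is a documented design choice; a
zero-variance residual vector is reported as degenerate with D = 1 rather
than crashing. Pearson correlations of TDG density with each covariate are
reported alongside.

## Ka/Ks

Tandem pairs are aligned at the protein level (Needleman–Wunsch, BLOSUM62,
gap open −10, extend −0.5) and back-translated codon by codon; gap columns
and N-containing codons are dropped. Ka and Ks follow Nei–Gojobori (1986):

* per-codon synonymous site fractions s = (synonymous single-base changes)/3
  per position, mutations creating stop codons counted as nonsynonymous, so
  N + S = 3 exactly per codon; site totals averaged over the two sequences;
* observed differences resolved by averaging over all orderings of the
  differing positions, excluding pathways that pass through a stop codon
  (when every pathway does, all pathways are kept);
* Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)p) applied to pn and ps.

NG86 with JC replaces the approximate-ML Gamma-MYN estimator used in some
published pipelines: it has no transition/transversion or gamma-rate
machinery, but preserves all downstream uses (ω thresholds, Ks as an age
axis) and admits an exact brute-force oracle, which the tests exploit over
all 61×61 sense-codon pairs. Externally computed Ka/Ks tables can be supplied
in place of the internal estimator.

Exclusions: Ks > 2 (synonymous saturation), p ≥ 3/4 (JC undefined), internal
stop codons. Ks = 0 with Ka > 0 leaves ω undefined — the pair is excluded
from selection classes rather than coerced to "positive". Selection classes
use strict comparisons (ω < 1 purifying, ω > 1 positive, ω = 1 neutral), with
proportions reported over classified pairs.

## Expression

A gene is expressed when TPM > 0.5 (strict) in at least one sample. Breadth
is the count (and %) of samples above the cutoff, level the mean TPM, and
specificity the tau index computed on linear TPM including zeros (the
log-transformed variant is a config flag): τ ∈ [0, 1], 0 for uniform
profiles, 1 for single-sample expression. Pair divergence uses Pearson r of
log10(TPM + 1) profiles; the threshold is the 95% quantile (linear
interpolation) of r over an equal number of seeded random gene pairs where
neither gene is a TDG and both are expressed, sampled without replacement
genome-wide (not matched by chromosome or distance). r < q95 ⇒ diverged. By
construction, ≈ 5% of pairs drawn from the null itself land above the
threshold; the calibration test checks this at n = 2000 within ±2 points.
Constant profiles (undefined r) are excluded with a reason.

## Promoters

The putative promoter is the non-overlapping 1 kb upstream of the TSS on the
coding strand, truncated at the chromosome edge and at the nearest annotated
gene boundary on either strand; promoters containing N, or empty after
truncation, are excluded. Similarity Ps is the number of identical aligned
positions in the best local alignment (match +5, mismatch −4, gap open 16,
extend 4 — EMBOSS-matcher-like) divided by the mean promoter length, so
Ps ∈ [0, 1] and Ps(x, x) = 1. The normalising denominator is a design choice
(alignment tools report identity over the aligned region only); since
divergence calls compare Ps with a within-run random-pair null computed the
same way, the choice cancels in the calls. Diverged ⇔ Ps < q95 of the null.

## Cross-genotype comparison

Clusters are linked through orthogroups: a cluster is present in a genotype
when that genotype has a tandem cluster sharing ≥ 1 orthogroup with it
(presence OR-ed over a cluster's orthogroups — the permissive reading;
requiring mere gene presence rather than tandem clustering in the other
genotype is the stricter alternative and is intentionally not used, since
"shared" here means the *cluster* recurs). Core = present in all genotypes,
private = exactly one, shared = otherwise; clusters with no
orthogroup-annotated member stay unset. Positional profiles use the cluster
midpoint over the chromosome length (distance to the centromere when a
centromere map is supplied, |position − 0.5| otherwise) with a one-sided
Mann–Whitney test of private vs core+shared.

Fates are decided per pair, in precedence order: (1) domain sets differ and
ω > 1 → neo-functionalization; (2) expression diverged, ω < 1, identical
domains → sub-functionalization; (3) expression conserved, ω < 1, identical
domains → genetic redundancy; (4) otherwise unclassified. "Identical
domains" is Pfam-id set equality, copy number ignored. Conflicting
combinations (e.g. diverged domains with ω < 1) are left unclassified rather
than forced into a category. Pairs missing any input (unexpressed copy,
excluded Ka/Ks) are unclassified with a reason.

Divergence-axis correlations (expression r vs Ps, Ps vs Ks, r vs Ks, r vs ω)
are pairwise-complete Pearson correlations with two-sided p-values, undefined
below 3 complete pairs.

## Enrichment

Per term (Pfam id or flat GO term), a 2×2 table over the background (all
located non-TE genes of the genotype — the more conservative background of
only-annotated genes is a config choice) is tested with a two-sided Fisher
exact test (one-sided available via config); p-values are BH-adjusted over
all tested terms and a term is significant when FDR < 0.05 and ≥ 10 TDGs
carry it. GO terms are tested flat — no ontology-graph propagation — so terms
annotated only on descendants are not aggregated upward; this understates
enrichment of broad terms and is a known gap relative to DAG-aware tools.
Differential enrichment z-scores row-standardise per-genotype fold
enrichments (a/(a+c)) / ((a+b)/n) of terms significant in ≥ 1 genotype.

## Synthetic data

The generator emulates a multi-genotype gene complement at configurable
scale. Defaults (the study conditions of the test suite): 4 genotypes,
3 chromosomes × 100 genes each, 10% TE genes, 18% of genes in tandem
clusters, cluster sizes 2:67% / 3:20% / 4:9% / 5:4%, intervening-gene counts
0–5 weighted toward 0, planted ω mix 93% at 0.3 and 7% at 1.5, target Ks
uniform on [0.15, 0.45], categories 25% private / 30% core / 45% shared,
10 expression samples with 75% of pairs planted diverged, 70% of promoters
planted diverged. These mirror the qualitative structure reported for
multi-genotype potato complements (mostly two-gene clusters, ~18% of genes
in clusters, overwhelmingly purifying selection, ~three quarters of pairs
expression-diverged, about a quarter of clusters lineage-specific).

Mechanics worth knowing:

* ω planting derives target synonymous/nonsynonymous change counts from the
  target Ks and ω via the inverse JC map and places them by accept/reject
  sampling of single-base codon changes — at most one change per codon, stop
  codons never created, start/stop codons untouched — so the planted value is
  expressed in exactly the site convention the estimator uses. Because of the
  one-change-per-codon budget, high-ω families are capped to smaller Ks
  (`feasible_ks`); gamma-rate heterogeneity across sites is not simulated.
* Cluster blocks are laid out as atomic units between background genes, so
  planted clusters never interleave and the planted intervening-gene counts
  are exact.
* Expression profiles are log-normal per gene; a conserved copy is its
  partner's log-profile plus N(0, 0.12) noise (r ≈ 0.99), a diverged copy an
  independent draw (r centred on 0, well below a typical null q95 ≈ 0.55 at
  10 samples).
* Diverged promoters are mutated at 0.70 per base. Local alignment is
  surprisingly tolerant: at a 0.35–0.5 rate the best local alignment still
  recovers 50–60% identity, far above the random-pair null (q95 ≈ 0.09 at
  1 kb); past ≈ 0.6 the alignment collapses. 0.70 puts planted-diverged
  promoters unambiguously below the null threshold. Conserved promoters
  mutate at 0.02. No indels are simulated.
* Planted promoters require + strand cluster members (the upstream gap holds
  the planted sequence); background genes get random strands. Minus-strand
  promoter extraction is unit-tested separately.
* TE genes are annotation flags with low AHRD scores in singleton
  orthogroups; no repeat sequences are simulated. Background genes get
  singleton orthogroups; cluster families get one orthogroup spanning their
  genotypes.

Everything is drawn from a single seeded NumPy generator: the same seed
yields a byte-identical file bundle, and the pipeline's null sampling derives
per-genotype sub-seeds from one run seed, so complete runs are byte-stable.

What passing tests on this generator do **not** show about real data: no
introns/UTRs or alternative isoforms, no segmental/whole-genome duplication
background, no gene conversion between duplicates, no indel or repeat
realism, no read-level expression noise, orthogroups are error-free by
construction. Recovery results are therefore upper bounds on real-data
performance; the unit under test is the analysis logic, not an annotation
pipeline.

## Numerical conventions

Percentages in summary tables are computed from their own counts and rounded
half-up to 2 decimals; cross-genotype "averages" are unweighted means of
per-genotype percentages, not pooled counts. Quantiles use NumPy's linear
interpolation. Degenerate inputs are surfaced, not silently dropped: empty
genotypes produce zero rows, zero-variance profiles and residuals carry
explicit flags/reasons, and excluded pairs keep their exclusion reason in
every output table.

## Known limitations

* E-values are Karlin–Altschul-style approximations, not NCBI-BLAST-equal;
  the thresholds are config for users who prefer external BLAST tabular
  input (`homology.read_blast_tab`).
* NG86 underestimates Ka/Ks differences that transition/transversion bias or
  site-rate variation would expose; Ks-based ages are relative, not absolute.
* Whether the published coverage threshold applies per-HSP or summed over
  HSPs is unknowable from the description; the single best local alignment
  is used.
* Flat GO enrichment (see above). Background-set composition is a config
  decision with visible effect on marginal terms.
* The random-pair nulls are genome-wide and not matched for chromosome,
  distance or GC content.
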