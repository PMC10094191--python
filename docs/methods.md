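# Methods

This note documents the statistical procedures, the conventions and edge
policies they follow, the synthetic-data model used for testing, and the
design decisions that were genuinely open.

## Codon model

Codons are held internally as RNA triplets; DNA input is converted on read
and mixing T and U within one sequence is rejected. The standard genetic
code partitions the 61 sense codons into 18 multi-codon synonymous
families (nine 2-fold, one 3-fold, five 4-fold, three 6-fold) covering 59
codons, plus the single-codon families Met (AUG) and Trp (UGG). Stop
codons are counted but excluded, together with AUG and UGG, from every
synonymous statistic; the initial AUG is counted like any other codon.
This makes a gene's *synonymous total* equal to its codon count minus
Met/Trp/stop occurrences, which is the quantity all per-gene tables report.

Sequences whose length is not a multiple of three are rejected under the
default `strict` frame policy; `trim_tail` drops the trailing 1–2 bases
explicitly. Silent trimming is deliberately not the default because frame
violations usually indicate annotation errors.

## RSCU

RSCU_i = G_ij · N_i / T_j for codon *i* of amino acid *j*. A family with
zero observations yields NaN ("undefined") for all its codons, never 0:
RSCU = 0 is reserved for a codon that is unused while its family is
observed. Undefined values propagate as missing into downstream matrices
and are imputed only where a method requires a complete table (see
correspondence analysis).

## Base composition

X3s (X ∈ {U, C, A, G}) uses the codonW "could-have" denominator: codons in
families with no X-ending synonym are excluded from the denominator.
This is the only convention consistent with the published per-gene
composition row, which the test suite locks in by enumerating the
denominators (A-capable 208, C- and U-capable 254, G-capable 191 codons of
the 300 in the reference gene) independently of the implementation.
GC3s = G/C-ending synonymous codons over all synonymous codons. Whole-CDS
GC uses every base, including the start/stop.

## ENc

Per family with n > 1 observed codons, homozygosity
F̂ = (n Σp² − 1)/(n − 1). F̂ is averaged within degeneracy classes
{2, 3, 4, 6} and ENc = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆. Edge policy
(following Wright's prescriptions, matching codonW behaviour on typical
genes): families with n ≤ 1 or F̂ ≤ 0 are excluded from their class mean; a
wholly missing 3-fold class (Ile unobserved) is imputed as (F̄₂ + F̄₄)/2; a
missing 2-, 4- or 6-fold class makes ENc undefined (raised as an error);
the result is capped at 61. Since F̂ ≤ 1 always, values never fall below 20.

## CAI, CBI, Fop

CAI is the geometric mean (computed in log space) of relative-adaptiveness
weights w over the gene's synonymous codon occurrences. The reference
weight table is an explicit input: the reference set behind published CAI
columns is generally not recoverable, so the package never bundles a
hidden default. `CAIReference.from_counts` derives weights from a
reference gene set as count/max-count per family, assigning 0.01 to
unobserved codons (the conventional floor that keeps the geometric mean
finite). Codons missing from the reference are skipped with a logged
occurrence count. CBI and Fop take a designated optimal-codon set:
Fop = N_opt/N_syn, and CBI rescales N_opt by its expectation under uniform
within-family usage, so uniform usage gives CBI = 0 exactly and exclusive
optimal usage gives 1.

## Protein indices

GRAVY is the mean Kyte–Doolittle hydropathy and aromaticity the fraction
of Phe/Tyr/Trp residues of the translated CDS (one trailing stop is
stripped; an internal stop is an error reporting the 1-based codon
position). Both are computed via Biopython's ProtParam; the tests verify
them against an independent residue-wise table lookup.

## Preferred and optimal codons

Frequency classes bin RSCU at 1.0 and 1.5 with both boundaries in the
middle bin — strict RSCU > 1.5 for "high" and strict < 1.0 for "low". The
strictness at 1.5 matters in practice: in the reference gene four codons
compute to exactly 1.50 and are excluded from the high set, which is what
makes the downstream optimal-codon intersection come out to eight members.

ΔRSCU contrasts the mean RSCU of a high-bias against a low-bias gene
group; codons with ΔRSCU > 0.08 are preferred. The grouping defaults to
ENc quantiles (lowest / highest 25% of genes by ENc, minimum two genes per
group) because the published procedure cites a high/low-expression
contrast without stating its subsets; an explicit grouping is available
and the groups used are recorded in output provenance. Undefined RSCU
values are dropped from group means per codon.

Optimal codons of a focal gene = (its high-frequency codons) ∩ (the
preferred set). Pattern similarity between two genes is the fraction of
codons, among those defined in both, falling in the same RSCU bin.

## Correspondence analysis

Classical CA of the genes × 59-codon RSCU matrix (the codonW "COA on
RSCU" mode): correspondence matrix P, row/column masses r and c,
standardized residuals S = (P − rcᵀ)/√(rcᵀ), SVD S = UΣVᵀ, principal
coordinates F = D_r^(−1/2)UΣ (genes) and G = D_c^(−1/2)VΣ (codons), inertia
fraction σ_a²/Σσ². Undefined RSCU cells are imputed with the codon's
column mean before analysis and the imputation count is kept on the
result. Singular values below 1e−12 (relative) are dropped; a table with
no variation returns a degenerate zero-axis result rather than noise axes.
Axis signs are fixed deterministically by making the codon with the
largest absolute loading positive on each axis. Zero-margin rows or
columns are rejected with the offending label named. All positive axes are
retained by default (inertia fractions sum to 1); plots and downstream
correlations use the first two.

## Clustering and correlations

Hierarchical clustering (Euclidean distance; average, Ward or complete
linkage; average is the default, and the method name is embedded in the
output since the published analysis names none) runs on rows sorted
lexicographically by gene label, which makes the dendrogram invariant to
input order and resolves distance ties deterministically. Output is a
scipy linkage matrix, flat-cluster extraction at a count or height, and
Newick with merge heights as branch lengths.

Pearson correlation panels use pairwise-complete observations with the
two-sided p from the t distribution; pairs with n < 3 or a zero-variance
variable yield NaN (flagged, not fatal). No multiple-testing correction is
applied by default, matching how such panels are conventionally reported.

## Phylogeny

Input is an aligned protein set (a translation helper is provided;
alignment construction is out of scope because the upstream procedure for
aligning heterogeneous CDS is not specified — re-deciding it silently
would manufacture irreproducibility). Complete deletion drops every
column containing a gap/missing symbol. Poisson distance d = −ln(1 − p)
with p the proportion of differing residues; p = 1 is an error naming the
pair. Neighbor joining follows Saitou–Nei with the standard Q criterion;
ties break on the lexicographically smallest pair of subtree labels (a
subtree is labelled by its smallest leaf), and negative branch-length
estimates are clamped to zero with the deficit logged. Rates are uniform
across sites and lineages homogeneous, i.e. plain Poisson correction — no
gamma variant is implemented. Bootstrap resamples the gap-free columns
with replacement (seeded integer sampling via numpy's PCG64, keyed to
column indices only, so supports are invariant to taxon order), rebuilds
the NJ tree per replicate, and reports percent recovery of each full-data
bipartition; a replicate with an undefined distance counts in the
denominator and recovers nothing, keeping supports reproducible.

## Synthetic data

The generator emulates CDS sets with controlled codon-usage structure: per
gene, amino acids are drawn i.i.d. from a fixed composition and a codon is
drawn per residue from family-level probabilities, with a start codon
prepended and a stop appended. Within each family, G/C-ending codons get
weight `gc3_bias` and A/U-ending codons `1 − gc3_bias`, sharpened by a
`concentration` exponent (∞ collapses the family onto the alphabetically
first maximal-weight codon; 0 flattens among positive-weight codons).
The default amino-acid composition mirrors the relative synonymous-family
totals of the pooled 20-gene count table, so synthetic genes exercise the
same family-size structure as the study data; the defaults (20 genes of
225 codons, i.e. 4500 synonymous codons in total) match the study's scale.
A closed-form expected GC3s is provided for law-of-large-numbers checks.

What the generator does *not* emulate: codon order structure within genes,
amino-acid composition differences between genes, and sequence evolution
along trees (clade structure for phylogeny tests is built directly at the
protein level in the tests). Passing tests on synthetic data therefore
demonstrate the statistics' correctness and sensitivity under controlled
bias, not distributional realism of any particular genome.

The published tables ship as TSV fixtures inside the package, validated on
load by SHA-256 checksum and by structural invariants (59 codons summing
to 300 for the per-gene table, 4500 for the pooled table, 20 index rows).
Two known print artifacts in the source tables are documented rather than
"corrected": the Gly row of the per-gene table prints RSCU values
inconsistent with its own counts (the counts are taken as authoritative),
and the pooled table's RSCU column is consistent with a per-gene mean of
RSCU rather than with its own pooled counts — the package exposes both
pooled RSCU and mean-of-per-gene RSCU and pins neither to that column.

## Problem sizes and tolerances

Fixture-driven checks are exact to the published precision (±0.01 at two
decimals; GC3s is compared at its published one-decimal precision, since
113/300 = 37.67 prints as 37.7). ENc on the reference counts is asserted
within ±0.5 to absorb implementation nuances in class averaging, though
the computed value (47.385) matches the printed 47.39 at two decimals.
Property tests use 150–300-codon genes, 10–25 genes per group, 10–20 seed
replicates, and 10,000–50,000 codons for convergence checks (GC3s within
2 points of its expectation; within-family frequency recovery at total
variation < 0.05) — sizes chosen to make sampling noise small relative to
the asserted effects while keeping the full suite fast. The CA oracle
(brute-force eigendecomposition) agrees to 1e−9; NJ recovers additive
matrices exactly.

## Known limitations

- CAI/CBI/Fop columns of the published index matrix are not recomputation
  targets: the reference and optimal sets behind them are not recoverable,
  so those columns are used only as printed data (e.g. in correlations).
- CA axis *contributions* reported for the original 20-gene analysis
  depend on the downloaded accessions and are not reproduced from
  fixtures; the CA implementation is instead verified against an
  independent oracle and generator ground truth.
- The NJ module consumes an existing protein alignment; producing one is
  out of scope.
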