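# Methods

This note records the models behind each `drmap` module, the defaults and
why they were chosen, what the simulators do and do not emulate, and the
numerical conventions that matter for reproducing results.

## Coordinates and interval widths

All positions are 1-based inclusive base pairs. Interval width is
`end − start` reported in Mb rounded to one decimal. This matches how such
intervals are conventionally printed (e.g. flanking markers at 5,886,143 and
16,557,950 bp give 10.7 Mb), and all region types (`LinkageRegion`,
`IBDRegion`, `GenomicRegion`) share it.

## Data model and formats

Array genotypes are unordered (unphased) allele pairs; phase is inferred
downstream, never read from input. PED/MAP is used for array genotypes
(the native dialect of array data in this field) and VCF v4.2 for sequencing
variants, with the consequence class in `INFO/CSQCLASS` and control-cohort
presence as the `INFO/INCTRLDB` flag; functional annotation itself is an
upstream concern and is consumed, not computed. Readers never silently drop
records: malformed lines raise with a line number, and exclusions are
reported. A published hair-pigment summary table (three Holstein
coat-colour groups × seven melanin assays, mean/SE/n) ships as package data.

## Two-point linkage

*Model.* In the half-sib design each progeny contributes one paternal
meiosis. At a sire-heterozygous marker the transmitted paternal allele is
deduced by Mendelian subtraction of a dam allele; when both sire alleles are
consistent the meiosis is ambiguous and excluded from n (not fractionally
weighted — the simplest convention; counts are reported per marker). Trait
transmission is read from phenotype under full penetrance with dams assumed
non-carriers, appropriate for a new and rare dominant mutation. Sire phase
is unknown and maximized per marker: r is the minimum mismatch count over
the two assignments of marker alleles to the causal/wild-type haplotypes,
so r ≤ n/2. Mendelian-inconsistent calls are excluded and reported, never
auto-corrected.

*LOD.* Evaluated at the MLE θ̂ = r/n (capped at 0.5) with the convention
0⁰ = 1, not over a θ grid: `LOD = r·log10 θ̂ + (n−r)·log10(1−θ̂) + n·log10 2`.
This is the phase-maximized two-point convention; at r = 0 it yields exactly
n·log₁₀2 (9.63 → printed 9.6 at n = 32). LOD is strictly decreasing in r
for fixed n (checked numerically to n = 64 in the tests).

*Critical region.* Bounded by the nearest scanned markers with r ≥ 1 on
each side of the maximal zero-recombinant block containing the top-LOD
marker. Ties between disjoint equal-LOD blocks resolve to the leftmost,
deterministically. A block touching the scanned end of a chromosome is
flagged open-ended rather than silently bounded.

Multipoint linkage, X-chromosome handling and genotyping-error modelling in
the LOD are out of scope.

## Allelic association

PLINK's sib-clustered DFAM statistic is not reproducible without the
original cohort's genotype data, so the scan uses a plain 1-df allelic
chi-square (continuity correction off, missing genotypes excluded),
augmented with the diagnostics that matter for this design: the fraction of
cases carrying the case-enriched allele and that allele's control
frequency. An optional permutation p-value (labels permuted within sibship
clusters) is provided for designs where the independence assumption of the
allelic test is questionable. Monomorphic markers are flagged with
chi2 = 0, p = 1. No genome-wide significance threshold is imposed; results
are ranked.

## IBD haplotype mapping

The founder-haplotype allele at each SNP is estimated as the major allele
among cases, counting both chromosomes. Conventions, all chosen to be
permissive in the same direction as the underlying "at least one copy"
carrier rule:

* a missing case genotype is carrier-satisfied (it cannot prove
  discordance); tracked separately;
* an exact frequency tie makes the marker uninformative
  (carrier-satisfied) rather than region-breaking, keeping regions
  contiguous;
* `tolerance` (default 1) interior non-carrier cases per marker are
  tolerated — a single discordant animal can reflect an unresolved
  recombination or a genotyping error;
* the run terminates at the first marker whose non-carrier count exceeds
  the tolerance or reaches `boundary_min_discordant` (default 2). The
  preference for boundaries supported by more than one discordant animal is
  additionally reported as `boundary_met_*` flags. Tolerance semantics is
  per marker; increasing the tolerance can only grow the region.

The seed marker is normally the top linkage or association marker; without
one, the midpoint of the longest qualifying run is used, and any seed inside
the same qualifying run returns the identical region. Ancestor carriage uses
the same rule: an ancestor carries the haplotype when it has ≥1 copy of the
case-major allele at at least a threshold fraction (default 1.0,
configurable — e.g. 0.9 to accept 19/21 concordance) of informative region
markers. Probabilistic (HMM) IBD, phasing and imputation are out of scope.

## Variant funnel

Stage order is fixed — region, consequence (default {missense}), proband
zygosity (default het), control-database exclusion, quality — because
reordering would make per-stage accounting incomparable across runs; stages
can only be relaxed via config. Quality is a rank key rather than a hard
filter by default: permissive variant calling deliberately keeps low-quality
calls so that true variants are not lost, and the causal candidate is
expected to surface at the top of the ranking, not via a threshold. Panel
concordance (candidate heterozygous in all known trait heterozygotes,
homozygous in none — any alternative-allele homozygote in an obligate
heterozygote disqualifies a dominant candidate) and confirmatory
resequencing are optional additional stages chained onto the same report so
the conservation invariant (every input variant appears exactly once among
survivors ∪ exclusions) spans the whole chain. Indels are counted in-region
but not scored; structural-variant calling and deleteriousness prediction
are out of scope.

## Validation statistics

* **Concordance** is exact counting with per-individual violations;
  phenotyped but ungenotyped individuals are listed as untyped, not as
  violations.
* **Segregation** uses the exact two-sided binomial test (the sum of
  probabilities of outcomes no more likely than the observed count), not a
  normal approximation — the relevant counts are small (e.g. 4 homozygotes
  among 14 offspring vs an expected 1/3). Verified against an enumeration
  oracle for all n ≤ 30.
* **Pigment chemistry**: published tables provide only mean/SE/n per group,
  so pairwise comparisons use the Welch t statistic from summary statistics,
  `t = (m₁−m₂)/√(se₁²+se₂²)`, with Welch–Satterthwaite degrees of freedom.
  The package claims consistency of the significant/non-significant pattern,
  not exact p-value reproduction (a pooled-variance test gives ≈0.10 for the
  same red-vs-red eumelanin comparison; the published value of 0.09 is
  within the uncertainty of either choice). The compact letter display
  assigns letters to maximal cliques of the non-significance graph, so two
  groups share a letter exactly when their pairwise p ≥ α. α defaults to
  0.05 everywhere and no multiple-testing correction is applied (published
  letter displays of this kind are unadjusted).

## Simulators

The generators define the study conditions the tests exercise.

*Half-sib family.* Defaults: 15 affected / 17 unaffected progeny, sire
heterozygous at 40% of markers (matching the observed ratio of
sire-heterozygous to assayed markers on a low-density bovine array), five
120 Mb chromosomes × 300 evenly spaced markers, trait locus at
3:9,479,761, penetrance 1.0, population allele frequencies uniform on
(0.1, 0.9). Crossovers follow a Haldane (no-interference) model at
1e-8 crossovers/bp/meiosis (≈1 cM/Mb); two-point analyses are insensitive
to interference, making this the simplest defensible choice. Dams are
unrelated population draws, non-carriers at the trait locus, genotyped by
default (with an option to drop them and exercise ambiguity handling). When
affected/unaffected counts are forced, paternal gametes are
rejection-sampled per progeny, which draws exactly from the conditional
gamete distribution given trait status. Truth tables (per-progeny paternal
haplotype at every marker and at the trait locus) are returned for oracle
tests; the recombinant-fraction estimator is checked unbiased against the
configured θ over 200 replicates.

*Cohort.* Defaults: 95 cases each carrying one copy of a founder haplotype
across a planted segment (3:7,906,099–10,462,387 on a 30 Mb chromosome with
400 markers) and 555 unrelated controls — the study design this models had
~55 close relatives plus 500 random animals among its controls, but only
the haplotype-sharing of cases is modelled; relatedness among controls is
not. Optional per-case exponential erosion of the segment ends emulates
recombination; optional planted discordant cases exercise the tolerance
rule. `sharp_boundaries` (default on) constructs the two markers flanking
the segment with ≥3 non-carrier cases, touching as few genotypes as
possible: the carrier rule's boundary definition presupposes multiple
discordant animals at the boundary, and without this the first marker
outside the segment can satisfy the rule by chance, making exact truth
recovery ill-posed. With it, perfect data recover the truth marker set
exactly. A `plant_segment=False` mode yields the null cohort used for
type-I calibration.

*Variant call set.* Defaults: 24 true variants (quality ~ N(180, 40),
mostly present in the control database) plus 30 false positives
(quality ~ N(25, 12), mostly absent from it) and exactly one planted causal
record — missense, heterozygous, absent from the control database, and by
construction the highest-quality call in the region. Panel genotypes for 20
known heterozygotes: the causal variant is heterozygous in all; true
population variants draw Hardy–Weinberg genotypes at a random frequency
(occasionally producing disqualifying alternative homozygotes); false
positives replicate as spurious heterozygotes at rate 0.3. Confirmatory
resequencing returns "absent" exactly for false positives.

*What passing tests do and do not show.* The simulators reproduce the
inheritance structure each method assumes — Mendelian transmission,
haplotype sharing, annotation-complete call sets. They do not model
genotyping error, linkage disequilibrium among controls, cryptic
relatedness, imperfect penetrance in the cohort, or annotation error, so
green tests certify the inference logic under its stated assumptions, not
robustness to those real-data complications.

## Problem sizes and determinism

Stochastic test batteries use 100 replicates for linkage recovery
(3 × 30-marker chromosomes), 100 for IBD recovery (95 cases, 60 controls,
150 markers), 100 for funnel recovery (default call-set mixture) and 60
null cohorts (60/60 individuals, 120 markers) for type-I calibration; the
type-I acceptance band (0.035–0.065) is four binomial standard errors
around 0.05 plus slack for the chi-square approximation at these counts.
All generators take a single integer seed through `numpy`'s `default_rng`
and are byte-reproducible; the end-to-end demo writes no timestamps and
fixed-order tables, so identical seeds produce byte-identical output trees.

## Known limitations

Two-point only (no multipoint phase reconstruction); plain allelic test
instead of a family-based association statistic; deterministic carrier-rule
IBD rather than probabilistic IBD; the funnel consumes upstream annotations
and cannot recover from annotation errors; pigment comparisons are limited
to what summary statistics support.
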