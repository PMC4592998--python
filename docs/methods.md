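# Methods

## Scope and data model

mitomk analyses aligned haploid population samples (an ingroup of n
sequences plus one or two outgroups) with gene annotations on the alignment
coordinate system. Annotation files use 1-based inclusive coordinates
(GenBank convention); all internal indexing is 0-based half-open. Gaps,
`N`, `?` and every IUPAC ambiguity code collapse to a single missing state:
downstream counting filters ambiguous data rather than interpreting it.
Genetic codes 1 (standard), 2 (vertebrate mitochondrial) and 5 (invertebrate
mitochondrial) are selectable per gene via Biopython's translation tables.
Internal stop codons in an annotated reading frame are permitted but logged,
since real mitochondrial annotations contain incomplete stop codons.

## Codon counting for MK tables

Every codon column is decomposed position by position:

* positions variable within the ingroup contribute polymorphism;
* positions fixed in the ingroup and different from the outgroup contribute
  fixed differences;
* positions both polymorphic and different from the outgroup contribute
  polymorphism only when the outgroup allele is present in the ingroup, and
  both a polymorphism and a fixed difference when it is not.

Codon pairs differing at k ∈ {1,2,3} positions are connected by k!
single-base pathways, each step classified synonymous/nonsynonymous by
translation. Pathways that traverse a stop codon at an intermediate step are
excluded; if every pathway does, all are retained with a warning (this is
unavoidable for a handful of codon pairs and affects no realistic column).
Two counting methods are provided:

* **more-inclusive** — divergence steps averaged over all usable pathways
  (fractional counts); codon columns with partial missing data kept,
  classified over the non-missing rows (minimum two);
* **less-inclusive** — divergence from the single pathway with minimal
  nonsynonymous steps (ties broken by lexicographic position order, for
  reproducibility); any codon column with missing data dropped, and
  designated high-missing sequences can be removed before counting.

Polymorphism counting is identical under both methods: with two segregating
codon states it uses the pathway average between them; with three or more
states each variable nucleotide position is counted (one polymorphism per
non-majority allele) and classified against the majority-codon background
with lexicographic tie-breaks. How columns with 3+ codon states should be
decomposed is genuinely underdetermined; this choice is documented rather
than derived. The consensus codon for divergence is the per-position
majority state.

With two outgroups, divergence is polarized to the ingroup branch: a fixed
difference is counted only where the outgroups agree with each other and
differ from the ingroup; discordant positions are excluded from divergence.

## MK summary statistics

Per-gene NI applies the +1-to-all-cells pseudocount only when a raw cell is
zero; Z* embeds the +1 by definition; summed-count NI and Z for gene sets
use raw sums with no pseudocount. These scopes are deliberate — they are
what reproduces published tables computed this way. Fisher's exact test
(two-sided, point-probability method) requires integers, so fractional
pathway-averaged counts are rounded half-away-from-zero for the test only.

NI_TG weights each gene by P_S + D_S and is computed on raw counts. Its 95%
confidence interval is a percentile bootstrap over genes (default 5000
resamples, seeded). A resample whose denominator is zero leaves the
estimator undefined; by default *any* undefined resample voids the interval,
because discarding those resamples conditions the interval on resample
composition (a set of two genes where one has P_S = D_N = 0 produces ~25%
undefined resamples, and a percentile interval over the rest would be
misleadingly tight). The tolerance is exposed as `max_undefined_frac`.

Woolf's homogeneity test adds the Haldane–Anscombe 0.5 to every cell, weights
each gene by the inverse variance of its log odds ratio, and compares the
weighted sum of squared deviations from the weighted mean log OR to χ² with
(genes − 1) degrees of freedom. Mann–Whitney comparisons use scipy's exact
method for small tie-free samples and the tie-corrected normal approximation
otherwise. Effect size is |Δmean| / RMS(SD).

## Diversity and SFS statistics

π (expected pairwise differences) is summed per column as
(n_c/(n_c−1))·(1 − Σp²) with n_c the column's non-missing sample size; a
column needs n_c ≥ 2 to count toward S. Statistics default to count units;
per-site values divide by the analysable site count. Tajima's D uses the
standard normalisation constants computed from the full ingroup n, not the
per-column n_c — appropriate for samples whose missing data is scattered and
required to reproduce per-gene values computed at fixed n. Fu & Li's D is
the outgroup-polarized form by default (derived singletons counted at
biallelic sites where the outgroup carries one of the two alleles), with
unpolarized D* also provided. Fay & Wu's H = π − θ_H is computed from the
unfolded SFS.

Folded spectra bin minor-allele counts; unfolded spectra require an outgroup
and drop sites where the outgroup base matches neither ingroup allele,
reporting them in `omitted_sites`. Sites with more than two ingroup alleles
are skipped with a log entry. Fractional synonymous/nonsynonymous site
totals (bp) follow the per-position convention: each codon position
contributes the fraction of its non-stop single-base changes that are
synonymous, evaluated on the ingroup consensus codon.

Per-site class labels for the class-specific statistics classify each
variable position against the consensus-codon background; a multi-allelic
site is labelled synonymous only if every non-majority substitution is
synonymous.

## Linkage disequilibrium and recombination tests

|D′| and r² are computed per biallelic site pair on the sequences
non-missing at both sites, with the usual sign-dependent D_max. Minor-allele
frequency cutoffs are exposed as a list (default 0, 0.05, 0.1). The
LD-vs-distance test uses Spearman's rho (robust for bounded, non-normal LD
measures) with a one-sided (negative direction) permutation p-value:
site *positions* are permuted and all pair distances recomputed, because
pairs sharing a site are not independent and an analytic null would be
wrong. Under the null where positions are exchangeable with respect to LD
(true for a nonrecombining genealogy), this permutation test is exact up to
Monte-Carlo error, and the suite verifies a ~5% rejection rate at α = 0.05
over 500 nonrecombining simulations. Distances are linear alignment-column
distances by default; circular (minimum-arc) distance is available by flag
for circular genomes. The four-gamete test counts pairs at which all four
haplotypes occur.

## Coalescent null distributions

The built-in Kingman simulator draws Exp(k(k−1)/2) waiting times and uniform
pair merges (times in coalescent units). For null p-values the simulator
conditions on the observed S (Hudson-style fixed-S): exactly S infinite-site
mutations are placed on branches with probability proportional to branch
length. Statistics are computed directly from derived-allele counts (the
derived state is known by construction, so polarized statistics need no
simulated outgroup). P-values use the (r+1)/(m+1) convention so that p = 0
is impossible; the default is 10,000 replicates.

The heterogeneity test for Δ = D_nonsyn − D_syn simulates, per replicate,
*one* genealogy shared by both mutation classes — the two classes are
physically linked on a nonrecombining molecule — drops S_syn + S_nonsyn
mutations and labels them at random. The p-value is two-sided on |Δ| by
default (sidedness is exposed), and an independent-genealogies variant is
available by flag. A vectorised batch path (per-branch descendant counts and
lengths across replicates) makes 10⁴ replicates at n = 38 take well under a
second; it is verified against the straightforward per-tree simulator and
against msprime's mean tree length in the test suite.

## Synthetic data generator

`generate_dataset` builds a codon-structured alignment from one genealogy:
a uniformly random non-stop ancestral codon sequence; Poisson(θ/2 · total
tree length) synonymous and nonsynonymous mutations, each assigned to its
own previously unused codon at a position admitting a non-stop single-base
change of the required class (infinite sites across codons, so truth counts
are exact and four-gamete violations are impossible); an outgroup that
accumulates Poisson-distributed extra substitutions per class on a single
unbroken branch, so polarization truth is exact. An optional G/C→A/T
mutation bias constrains the sampled changes, and optional missing data
masks ingroup cells uniformly.

Defaults describe the study conditions the generator emulates: n = 38
haploid sequences, 300 codons, θ_syn = 5, θ_nonsyn = 2.5 (count units,
roughly the 2:1 synonymous:nonsynonymous ratio of segregating variation in
fly mtDNA scaled to the gene length), outgroup divergence (30, 10) expected
substitutions (≈3:1 synonymous excess). The `partial_sweep` scenario
replaces the neutral genealogy with a constrained one: 95% of tips coalesce
in a recent star-like burst, two divergent lineages attach near the root,
and any remainder joins at intermediate times — the genealogical signature
of a population recovering from a cytoplasmic sweep (excess rare alleles and
excess high-frequency derived alleles; the suite verifies mean Tajima's D
and mean Fay & Wu's H are negative over 500 replicates).

What the generator does **not** emulate: recurrent mutation within a codon,
indels, selection acting forward in time, base-composition heterogeneity
along the molecule, and sequencing error beyond uniform missingness.
Passing tests therefore demonstrate correctness of the counting and
statistical machinery under the stated model, not robustness to alignment
error or to recurrent substitution at silent sites (which inflates divergence
at distant outgroups in real data).

## Numerical and design choices

* Tie-breaks are lexicographic everywhere (majority base, pathway order) so
  all outputs are deterministic; every Monte-Carlo routine takes a seed and
  is bitwise reproducible given (seed, replicate count).
* Undefined values (Tajima's D at S = 0, Z with a zero cell, NI_TG with a
  zero denominator) are NaN in memory and explicit markers in TSVs; they are
  never silently replaced.
* Overlapping gene annotations are analysed independently; a shared site
  contributes to both genes' tables, with no double-count correction.
* Test-suite problem sizes: null-machinery calibration uses 500 uniformity
  draws at 999 replicates each and 400 outer type-I replicates at 1000
  inner replicates; recombination properties use 1000 generated datasets
  (four-gamete) and 500 coalescent datasets (LD-decay rejection rate);
  parameter recovery uses 500 equilibrium and 500 partial-sweep replicates
  at the default generator configuration.

## Known limitations

* The less-inclusive tie-break among equal-D_N pathways and the
  decomposition of codon columns with 3+ segregating states are conventions;
  other reasonable conventions change fractional counts slightly.
* Fractional divergence counts arise only from pathway averaging, not from
  frequency weighting.
* The LD permutation test assumes site positions are exchangeable under the
  null; spatial mutation-rate heterogeneity would violate this.
* The coalescent null is the equilibrium constant-size model; demographic
  alternatives belong to the synthetic-data generator, not the null.
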