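# Methods

`mutload` measures mutations acquired by single stem cells during in vitro
culture and propagates those measurements into a closed-form model of
oncogenic risk. This note documents the models, the synthetic data used to
validate them, and the numerical and design choices that were genuinely
open.

## The measurement design

A clonal line is grown from one cell, cultured while mutations accumulate,
and a second single-cell step produces a subclone that is expanded for
whole-genome sequencing alongside the clone and a non-clonal reference
(biopsy/blood/bulk). Because every cell of the subclone descends from one
cell of the cultured clone, mutations acquired *between* the two clonal
steps are clonal in the subclone (VAF ≈ 0.5), absent from the reference,
and subclonal or absent in the clone. Mutations acquired *after* the
subclone step are present at low VAF and are removed by a VAF threshold.

The SBS filter chain retains subclone calls that:

1. lie in the intersection of the per-sample callable regions (depth ≥ 20,
   base and mapping quality ≥ 10 per interval);
2. have site quality > 100 and subclone depth > 20 (both strict, following
   the wording "quality > 100" and "coverage > 20");
3. are clonal in the subclone (VAF ≥ 0.3, inclusive);
4. have zero alternate reads in the reference sample;
5. are not clonal in the clone (clone VAF < 0.3);
6. are not at blacklist positions — positions variable in ≥ 3 unrelated
   individuals (recurrent artifacts / unknown SNPs) or supplied externally
   as a known-SNP list.

Indels additionally require FILTER `PASS`, genotype quality ≥ 99 in all
three samples, and per-sample depth in [10, 60]. The depth reading of
"REF and ALT read support between 10× and 60×" is deliberate: requiring
alternate support ≥ 10 in the *reference* sample would exclude every
somatic indel, so the bound is applied to total (REF+ALT) support per
sample. The subclone indel VAF rule is strict (> 0.3) where the SBS rule is
inclusive (≥ 0.3), following the letter of each rule's source.

Two thresholds that share the value 0.3 are kept as separate parameters
(`vaf_threshold` for subclone clonality, `clone_vaf_threshold` for the
clonal-in-clone exclusion). With a single shared parameter, raising the
threshold could *re-admit* records previously excluded as present in the
clone, breaking the monotonicity property the filter should satisfy
(raising the subclone VAF threshold never enlarges the retained set).

Counts are scaled to the genome as `count × genome_length /
callable_length`, divided by population doublings to give μ (mutations per
genome per population doubling), and converted to a per-year rate by
`μ × 8766 / D` with D the doubling time in hours (8766 h = 365.25 d; the
constant is fixed here so results are reproducible). Group comparisons use
classical one-way ANOVA (equal variance) for ≥ 3 groups and Student's
two-sided t-test for 2; clonality is declared when the median retained
subclone VAF lies in [0.4, 0.6].

## Spectra and signatures

Substitutions are reported on the pyrimidine strand. The 96 channels are
ordered substitution-major (C>A, C>G, C>T, T>A, T>C, T>G), then 5′ flank,
then 3′ flank, each in A,C,G,T order — the convention of the standard
reference-signature catalogs, and the order written in every signature TSV.
The seven-type spectrum splits C>T by CpG status of the 3′ flank
(C>T at NpCpG vs other); collapsing the split back to six types preserves
total C>T mass and yields the P(X→Y) used by the risk model.

De novo signatures are extracted by NMF with multiplicative updates under
the generalized Kullback–Leibler divergence (scikit-learn's `solver="mu"`,
`beta_loss="kullback-leibler"`), 10 random restarts with the best objective
kept, relative tolerance 1e-6, and an iteration cap of 1000 (200 iterations
demonstrably stop short of convergence on desk-scale mixtures; the cap is a
numerical setting, not a modelling choice). Extracted signature order is
arbitrary, so validation matches extracted to true signatures by greedy
maximum-cosine bipartite assignment. Refitting against a reference catalog
uses non-negative least squares; the reported residual is the cosine of the
reconstruction to the original profile. Signature selection keeps
signatures contributing ≥ 10% (inclusive) to at least one centroid. Sample
clustering is average-linkage agglomerative on distance 1 − cosine.
Spectrum comparisons use Pearson's chi-squared on the 2×k contingency table
of counts without continuity correction; channels empty in both samples are
dropped, and expected cells < 5 produce a logged caution rather than an
error.

## Genomic distribution and the depletion factor

For a region set R and callable set C, the expected count of a uniform
mutation process is `total × |R ∩ C| / |C|`; observed counts are compared by
a one-sided exact binomial test with the tail taken in the observed
direction (in practice the direction of interest is fixed a priori per
region — depletion for genic/CDS/promoter, enrichment for LADs — and the
type-I calibration test measures the test at a fixed direction). Region
sets may overlap one another (genic ⊇ CDS) and are tested marginally; no
multiple-testing correction is applied by default, with a Bonferroni option
behind a flag. The CDS depletion factor is defined as
`dp = observed / expected` — the multiplier on the coding mutation rate —
so a 2% depletion corresponds to dp = 0.98, the only dimensionally sensible
reading of dp as a factor in the risk formulas.

## The oncogenic-risk model

With coding fraction 0.015, depletion factor dp, rate μ, spectrum P(X→Y)
over the six substitution types, and a driver catalog of n(X→Y) activating
positions in a coding sequence of length L:

* expected activating mutations after producing N cells:
  `M_active(N) = 0.015 · dp · μ · N · Σ P(X→Y) · n(X→Y)/L` — linear in each
  of μ, dp, N and n;
* probability of at least one:
  `P(Z ≥ 1) = 1 − (Π ((L−n)/L)^P)^(0.015·dp·μ·N)`, computed as
  `−expm1(exponent · Σ P·log1p(−n/L))` to avoid underflow; any n = L with
  P > 0 short-circuits to P = 1. P ≤ min(1, M_active) always (Markov), and
  P reduces to `1 − e^(−M_active)` to first order in n/L;
* in vivo: the exponent's μ·N is replaced by
  `n_stem_cells × annual_rate × t_years` (defaults 1e8 cells, 40 SBS/yr),
  with the in vivo spectrum supplied; the equivalent exposure time solves
  `P_in_vivo(t) = P_target` by bracketed bisection to 1e-9 relative
  tolerance (the root is unique by strict monotonicity);
* cumulative coding mutations over time use `N(t) = N0 · 2^(t/D)`. An
  alternative reading counts generations of cell-cycle length mt, giving
  exponent `(mt/D)·(t/mt)` — which reduces to the same `t/D`; both modes
  are exposed and coincide.

The per-cell framing enters the formulas exactly as printed: N is "cells
produced", with no extra factor for intermediate lineage cells. The
independent Monte-Carlo oracle makes the bookkeeping explicit: synchronous
doublings from N0 to N, one new cell per division, Poisson(μ) new
genome-wide mutations per division, each coding with probability
0.015·dp and each coding mutation activating with probability
Σ P·n/L. Expected events are then μ·(N − N0), within N0/N of the closed
form — under 0.1% at the N = 2^10 scale used in validation. (Assigning
Poisson(μ) to *both* daughters of every division would double the total and
contradict the linear-in-N formula; μ is a per-lineage, per-doubling rate,
i.e. a per-division rate.)

## The synthetic generator

The generator emulates the trio design with planted truth so every
downstream stage is testable without sequence downloads. Variant classes
and true VAFs:

| class | reference | clone | subclone |
|---|---|---|---|
| germline | 0.5 / 1.0 | same | same |
| pre-clonal | 0 | 0.5 | 0.5 |
| culture (target) | 0 | 0 | 0.5 |
| post-clonal | 0 | 0 | ≤ 0.25 |
| artifact | 0 | 0 | 0.5 |

Defaults per trio — 100 germline, 20 pre-clonal, 50 culture, 30
post-clonal SBS and 5 artifact positions at 30× mean depth — chosen as a
desk-scale rendering of a genome with a few hundred culture mutations
against a large germline background. Germline sites are heterozygous with
probability 2/3. Post-clonal true VAFs follow the branching structure of
the expansion: a mutation arising in generation g after the subclone step
has cell fraction 2^−g, VAF 2^−(g+1), and generations contribute in
proportion to 2^g, so low VAFs dominate; levels are capped at
`subclonal_vaf_max` (default 0.25). Observed evidence is depth ~
Poisson(mean 30), truncated at ≥ 1, with alt reads ~ Binomial(depth, VAF);
`exact_vafs=True` fixes depth and rounds alt counts for noise-free tests.
Calls with zero alternate reads in all samples are dropped from the call
table (a caller never emits them) but stay in the truth table.

Culture mutations respect their trinucleotide context: a channel is drawn
from the requested spectrum (a seven-type spectrum spreads each type
uniformly over its 16 contexts) and a position with the matching
pyrimidine-strand context is consumed; exhausting a channel's eligible
positions is an explicit error naming the channel. How recurrent artifacts
arise is not modelled mechanistically: artifact positions are given
clonal-looking VAF in the subclone — so that the recurrence blacklist, not
the VAF filter, is what removes them — and low VAF (0.05–0.15) in ≥ 3
simulated unrelated panel individuals, exercising the "variable in at least
three unrelated individuals" rule. This artifact model is a stand-in.

Region sets are assembled from non-overlapping 500-bp tiles sampled
independently per set (so sets may overlap each other, as genic regions
contain CDS); realized fractions land within 1% of the request for
references ≥ 100 kb. Driver catalogs plant the requested number of
activating positions per substitution type inside the CDS region, with L
equal to the region length. Growth curves are X0·2^(t/D) with
multiplicative lognormal noise of a given CV, mean-corrected so the
expectation is unchanged.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real trinucleotide composition and mutation-rate
covariates (replication timing, expression), mapping and alignment error,
strand-biased damage, copy-number and structural variation, contamination,
index hopping, or biological selection during culture. Filter operating
characteristics on real genomes will differ; the synthetic results validate
the *logic and calibration* of the pipeline, not its field performance.

## Numerical choices and degenerate inputs

* Coordinates are 0-based half-open internally; VCF emission converts to
  1-based. Interval sets are merged and sorted on construction; membership
  is binary search.
* Probability products are computed as exponentials of sums of logs
  (`log1p`/`expm1`); `(1−n/L)` with n = L short-circuits to P = 1.
* The one-sided binomial p-value is the exact tail (`binom.sf/cdf`), which
  matches term-by-term enumeration to machine precision.
* Empty inputs are errors where a statistic is undefined (clonality of no
  VAFs, centroid of no profiles, cosine with a zero vector, enrichment with
  zero mutations); an empty callable set yields an empty filter result with
  a warning; an empty region–callable overlap yields a flagged "undefined"
  enrichment result.
* NMF ties between restarts resolve by objective value; restart seeds
  derive deterministically from the user seed. Clustering tie-breaks follow
  label order via scipy's deterministic linkage.
* log2(observed/expected) maps observed = 0 to −∞ rather than raising.
* Validation scales — 100–300 kb references, 50–5000 planted mutations,
  2^9–2^10-cell lineages, 4000–10000 oracle replicates — were chosen so
  statistical tolerances (3 SE bands, ±10% rate recovery, ±0.05 on dp) are
  comfortably resolvable on a single CPU.

## Known limitations

* "Base call quality > 100" is interpreted as the site-level VCF QUAL; the
  original filtering pipeline may have used a summed allele quality. The
  threshold is configurable.
* dbSNP-style known-variant filtering is a user-supplied position list; no
  database is bundled or downloaded.
* The callable autosomal genome length used for normalization is a
  configuration value, not a constant.
* The indel chain does not model multi-allelic sites or phasing; sex
  chromosomes are handled only via the contig allow-list.
* The risk model ignores selection and cell death: every produced cell is
  counted, and oncogenic clones neither expand nor die. Two-hit
  tumor-suppressor mechanisms are out of scope.
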