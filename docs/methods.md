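# Methods

This note documents the statistical procedures implemented in `epidiff`,
the parameters that control them, what the synthetic-data generator does
and does not emulate, and the numerical choices made where the underlying
procedure leaves room for interpretation.

## Differential methylation calling

The caller compares whole-genome bisulfite profiles of a mutant and its
wild-type (WT) control, separately for the three plant cytosine contexts
(CG, CHG, CHH; H = A, C or T).  The input is one table per sequencing
library of per-cytosine methylated/unmethylated read counts; cytosines on
the two strands are independent records (no CG-dinucleotide merging), and
zero-coverage cytosines are retained because they are legitimate smoothing
neighbours.

**Smoothing.**  Within each library, methylated and unmethylated counts
are smoothed independently along each (chromosome, context) track with a
Savitzky–Golay quadratic filter over 11 index-adjacent cytosines of the
same context.  "Adjacent" is index-wise, not bp-wise: a fixed-width filter
per cytosine is only well defined over track indices.  At track ends the
filter degenerates to a least-squares quadratic over the truncated
available window, which preserves exact reproduction of any polynomial of
degree ≤ 2 everywhere.  Because the filter can undershoot near sharp
spikes and counts are physically non-negative, smoothed counts are clamped
at zero.  Smoothed counts are then summed position-wise over a genotype's
libraries (each library smoothed first, per its own noise process); the
alternative of pooling raw counts before smoothing is available via
`pool_libraries=True`.  Positions covered in one library but absent from
another contribute zero counts for the missing library.

**Per-cytosine test.**  At every cytosine with non-zero smoothed coverage
in both genotypes, the rounded smoothed counts form a 2×2 table tested
with a two-sided Fisher's exact test.  A differentially methylated
cytosine (DMC) requires p ≤ 0.1 *and* an absolute smoothed-rate difference
(mutant − WT) strictly greater than 0.1; the sign assigns hyper (gain in
the mutant) or hypo.  Directionality is carried by the rate-difference
sign, so a two-sided test is used.

**Rounding.**  Wherever the procedure calls for rounding (the DMC test
inputs and the region-test averaged inputs — nowhere else), half-integers
round to the nearest even integer, the convention of `round()` in R and of
IEEE 754.  The rule is centralized in `epidiff.stats.round_counts`.

**Merging.**  Same-type DMCs chain into candidate regions when consecutive
DMCs lie within a context-specific maximum distance — 160 bp (CG), 240 bp
(CHG), 70 bp (CHH) — and no opposite-type DMC falls strictly between them.
Chaining is transitive and single-pass over position-sorted DMCs; every
DMC lands in exactly one candidate region (singletons included — the
region filters remove them).

**Region test and filters.**  For each candidate region, the smoothed
counts are averaged over *all* cytosines of the region's context inside
its span (zero-coverage cytosines contribute zeros), rounded, and tested
with Fisher's exact test; p-values are Benjamini–Hochberg-adjusted within
each context, since contexts are analysed and reported separately.
Accepted DMRs must have ≥ 5 DMCs, span ≥ 50 bp, FDR ≤ 0.05, and an
absolute region-level rate difference ≥ 0.40 (CG) or 0.20 (CHG/CHH),
where the region rates are the aggregate rates actually tested, not means
of per-DMC differences.  A DMR maps to an annotated feature when at least
one nucleotide overlaps.

This module is fully deterministic given inputs and parameters.

## Differential expression

Per-locus expression is RPKM: count / (length/10³) / (total mapped/10⁶).
Differential expression between mutant and WT is tested per replicate pair
with a two-sided Fisher's exact test on the table (locus reads vs
rest-of-library reads in each genotype) — the locus-versus-remainder
construction is the natural 2×2 reading of a count-based library
comparison.  P-values are BH-adjusted across all loci within one
replicate-pair comparison.  A locus is called up in a pair iff
log2(mutant RPKM / WT RPKM) > 2 and FDR < 0.01 (both strict; down is
symmetric), and the final call requires the identical call in every pair.
A pseudocount of one read (configurable), added to both genotypes before
RPKM conversion, keeps the log2 ratio defined at zero counts; it never
enters the Fisher test.

Genome-overview helpers: log2 ratios of mean RPKM in non-overlapping
100-kb windows tiled from position 1, each locus assigned by its midpoint
(windows with no loci or a zero mean emit NaN); and a compartment
enrichment test — a one-sample two-sided z-test of the subset's
pericentromeric-heterochromatin proportion p̂ against the background
proportion p0, z = (p̂ − p0)/√(p0(1−p0)/n).  The one-sample proportion
form is the interpretation chosen for a "z-score" on a compartment
distribution.

## Profiles and small RNAs

Methylation metaprofiles align stranded features at the 5′ or 3′ end and
average methylation in 100-bp bins from 3 kb upstream to 3 kb downstream;
upstream of a minus-strand feature is genomically downstream.  The default
bin statistic is the coverage-weighted rate (Σ meth / Σ total across
contributing cytosines), robust at low coverage; per-cytosine-rate
averaging is available (`weighted=False`).  Flanks extending past a
chromosome end yield missing values rather than truncating the opposite
flank.

Small-RNA counts are normalized to reads per million 18–26-nt mapping
reads within each library.  TE-scaled profiles use 2,000 one-nucleotide
flank bins on each side and 2,000 proportional body bins: body position j
of a TE of length L maps to bin ⌊j·2000/L⌋ (capped at the last bin), so
TEs shorter than 2,000 bp cover a subset of body bins (floor-based
assignment, no sub-bin interpolation).  Each TE contributes its per-bin
mean coverage; the profile is the mean over contributing TEs.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, at
desk scale (defaults: 2 chromosomes × 1 Mb; the central 40% of each
chromosome is pericentromeric heterochromatin):

- **Features.**  ~400 TEs placed with a 4:1 heterochromatin:euchromatin
  density ratio, ~400 protein-coding genes with the reverse bias;
  non-overlapping within each class.
- **Cytosines.**  Per-bp densities CG 0.04, CHG 0.03, CHH 0.08.  These
  keep two properties of real plant genomes that matter to the method:
  CHH sites far outnumber the symmetric contexts, and the 11-cytosine
  smoothing window spans a distance (~130–250 bp) comparable to the
  context merge gaps, so smoothing and merging interact realistically.
- **Methylomes.**  Per cytosine and library: coverage ~ Poisson(20);
  methylated count ~ beta-binomial around the compartment/context base
  rate (heterochromatin CG 0.85, CHG 0.55, CHH 0.15; euchromatin CG 0.20,
  CHG 0.05, CHH 0.03) with overdispersion ρ = 0.05, so the null behaviour
  of the caller is exercised under realistic extra-binomial noise rather
  than idealized binomial sampling.  Two replicate libraries per genotype.
  Injected intervals override the base rate to a target rate, and are
  emitted as ground truth.
- **RNA-seq.**  Negative-binomial counts around gamma-distributed
  per-locus baselines (mean 50), dispersion 0.05 — the replicate-to-
  replicate variability of isogenic plant material.  Mutant libraries
  scale injected loci by their fold change.  Library totals include a
  10⁶-read background representing the bulk of a real library that maps
  outside the desk-scale locus set; without it, a handful of strongly
  induced loci would dominate the toy library total and depress every
  RPKM ratio — a composition artifact of small locus sets that does not
  exist at genome scale.
- **Small RNAs.**  Per-library read-length totals (18–26 nt) are
  multinomial with 21-nt and 24-nt fractions of 0.15 and 0.55; within a
  size class, per-locus counts are multinomial with weights ∝ locus
  length × intensity, concentrating 24-nt siRNAs on heterochromatic TEs.

All generators are bit-reproducible: one global seed fans out through
fixed per-component child seeds (`numpy` `SeedSequence`), so adding a new
generator never shifts existing streams.

What the generator does **not** emulate: sequence composition (positions
and counts only), read-level errors and mapping ambiguity, bisulfite
conversion failure, strand-correlated CG methylation, methylation
gradients within gene bodies, and locus-dependent siRNA size mixtures.
Passing recovery/null tests therefore validates the statistical machinery
under the stated generative assumptions, not robustness to alignment or
conversion artifacts in real libraries.

## Validation conditions and problem sizes

The packaged validation (test suite and `scripts/acceptance.py`) uses:
30 injected CG hypo-DMRs (0.85 → 0.10, 300–800 bp) on a 1-Mb chromosome
at 20× coverage for recovery; 20 seeded WT-vs-WT 1-Mb runs for the
methylation null; 30 8-fold upregulated loci (baseline 50) over the
default 2×1-Mb genome for expression recovery; and 20 seeded
equal-expression runs for the expression null.  Oracle checks cover the
smoother (200 random tracks vs a brute-force local quadratic fit), the
exact test (every 2×2 table with margins ≤ 40 vs full hypergeometric
enumeration, tolerance 1e-12), BH (1,000 random vectors vs the step-up
definition), and DMC merging (an exhaustive sweep over a position grid
straddling every gap threshold, plus 6,000 random configurations, vs an
independent union-find constructor).

## Numerical choices and edge cases

- Fisher's exact p-values for tables with total ≤ 2000 are computed with
  exact integer arithmetic (binomial-coefficient weights on a common
  denominator), so probability ties — integer ties — are classified
  exactly; larger tables use `scipy.stats.fisher_exact`.  The all-zero
  table returns p = 1.
- BH adjustment delegates to `statsmodels` (`fdr_bh`).
- Cytosines with zero smoothed coverage in either genotype are skipped
  for DMC calling but still count (as zeros) in region averages.
- A candidate region whose rounded averaged counts are all zero gets
  p = 1; a region rate is undefined (NaN) at zero aggregate coverage and
  such regions never pass the rate-difference filter.
- Degenerate inputs raise: empty smoothing input, non-finite values, even
  window sizes, inverted intervals, zero-length BED records, duplicate
  cytosine records, unknown context tokens.

## Known limitations

- The per-cytosine Fisher test treats smoothed counts as if independent;
  smoothing induces correlation between neighbouring tests.  The region
  test and FDR across candidate regions absorb most of the resulting
  optimism, as the null simulations confirm, but per-DMC p-values should
  not be interpreted marginally.
- Count-based Fisher DE testing ignores biological overdispersion; the
  strict 4-fold change requirement and two-replicate intersection are the
  guards against the resulting false positives (and the null simulations
  bear this out), at some cost in sensitivity near the threshold.
- The compartment enrichment z-test uses the normal approximation; it is
  inaccurate for subsets of only a few loci.
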