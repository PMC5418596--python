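# epidiff

Differential DNA methylation, differential expression and small-RNA
profiling for plant epigenomics, at single-cytosine resolution.

`epidiff` is aimed at researchers comparing a silencing-pathway mutant
against its wild-type control with whole-genome bisulfite sequencing,
RNA-seq and small-RNA sequencing — the standard experimental triad for
deciding whether a gene-silencing phenotype works through DNA methylation
or independently of it.  It provides, as composable library functions and
a thin command-line layer:

- a **smoothed differential-methylation-region (DMR) caller**: per-library
  Savitzky–Golay quadratic smoothing of methylated/unmethylated read
  counts over 11 adjacent cytosines; per-cytosine two-sided Fisher's exact
  tests on rounded smoothed counts (DMC: p ≤ 0.1 and |rate difference| >
  0.1); context-specific merging of same-type DMCs (max gap 160/240/70 bp
  for CG/CHG/CHH, opposite-type DMCs block a merge); a region-level Fisher
  test on averaged counts with Benjamini–Hochberg FDR per context; and the
  final DMR filters (≥ 5 DMCs, ≥ 50 bp, FDR ≤ 0.05, |Δrate| ≥ 40% for CG /
  20% for CHG and CHH);
- **Fisher-exact RPKM differential expression**: per replicate pair, a
  two-sided Fisher's exact test of locus counts against the rest of the
  library, BH-adjusted; a locus is called only with log2(RPKM ratio) > 2
  (or < −2) *and* FDR < 0.01 in **every** replicate pair;
- **genome-overview statistics**: log2 expression ratios in 100-kb
  windows, and a one-sample proportion z-test,
  z = (p̂ − p0)/√(p0(1−p0)/n), for enrichment of a locus set in
  pericentromeric heterochromatin;
- **metaprofiles**: methylation around feature ends in 100-bp bins ±3 kb,
  and length-scaled TE profiles (2,000 one-nucleotide flank bins, 2,000
  proportional body bins) for 21-/24-nt siRNA coverage normalized to reads
  per million 18–26-nt mapping reads;
- a **seeded synthetic-data generator** producing genomes with a
  TE-dense, densely methylated pericentromeric compartment, beta-binomial
  bisulfite counts, negative-binomial RNA-seq counts and multinomial
  siRNA size classes, together with ground-truth tables for recovery and
  null testing.

The API follows the statsmodels convention: build a model object from
data, call `fit()`, inspect the results object.

## Worked example

Simulate a mutant methylome with 30 hypomethylated intervals injected
into pericentromeric heterochromatin (CG rate 0.85 → 0.10, 300–800 bp,
20× coverage, two replicate libraries per genotype) and call DMRs:

```python
from epidiff.simulate import preset_dmr_recovery, score_dmr_calls
from epidiff.dmr import DifferentialMethylation

data = preset_dmr_recovery(seed=1)
res = DifferentialMethylation(data["wt"], data["mut"]).fit()
print(res.summary())
```

```
Differential methylation summary
========================================
context type       DMCs    DMRs  mean len
CG      hyper       127       0       0.0
CG      hypo        781      30     605.5
CHG     hyper        38       0       0.0
CHG     hypo         41       0       0.0
CHH     hyper        96       0       0.0
CHH     hypo         93       0       0.0
total candidate regions: 353
total DMRs: 30
```

Isolated DMCs arise genome-wide from sampling noise (127 CG hyper-DMCs
here), but only the 30 injected intervals survive merging, the region
test and the filters — all called as CG hypo-DMRs:

```python
print(res.dmrs[["chrom", "start", "end", "context", "type",
                "n_dmcs", "diff", "fdr"]].head(3).to_string(index=False))
print(score_dmr_calls(res.dmrs, data["truth"]))
```

```
chrom  start    end context type  n_dmcs      diff          fdr
 chr1 303404 304060      CG hypo      20 -0.614074 1.970502e-07
 chr1 329362 329767      CG hypo      19 -0.639487 1.698889e-07
 chr1 344385 344821      CG hypo      15 -0.612498 2.505657e-07
{'n_true': 30, 'n_called': 30, 'recall': 1.0, 'precision': 1.0,
 'mean_boundary_error_bp': 33.53, 'max_boundary_error_bp': 116.0}
```

Every injected region is recovered (recall 1.0) with no spurious calls
(precision 1.0), and called boundaries sit on average 34 bp from the true
interval edges — well inside the 160-bp CG merge distance.  The same
dataset and analysis are available from the shell:

```sh
epidiff run --preset dmr-recovery --seed 1 --out results/run1
```

which chains simulation, DMR calling, differential expression,
metaprofiles and DMR/locus overlap, writing truth-scored summary tables.
See `epidiff --help` for the individual `simulate`, `call`, `de` and
`profile` commands.

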