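# splicomp

Splicing-complexity analysis for junction-count cohorts: intron-group PSI
quantification, a per-group complexity score, Dirichlet-multinomial
differential-splicing testing, complexity–expression correlation profiling,
and competitive gene-set enrichment — with a seeded synthetic-cohort
generator so the whole pipeline is testable end to end without any data
download.

## The problem

Bulk RNA-seq of tumour cohorts (the motivating setting is pre-invasive
breast lesions with a progressor / non-progressor outcome) yields spliced-read
counts per junction ("intron") per sample. Introns that share a 5′ or a 3′
splice-site endpoint represent mutually exclusive splice forms and are
grouped together. Within a group, the percent-spliced-in of intron *i* is

```
PSI(y_i) = y_i / (y_1 + y_2 + ... + y_k)
```

where *y_i* is the number of reads supporting intron *i*. The group's
splicing complexity in a sample is

```
s = 1 − (PSI_max − PSI_avg)
```

with `s = 1` when all splice forms are used evenly and `s = 1/k` when a
single form carries every read of a *k*-intron group. Averaging the defined
*s* values over well-covered groups gives each sample an aggregate
complexity score.

On top of this the package provides:

- **Differential splicing** (`splicomp.dm`): per group, sample counts are
  Dirichlet-multinomial (extra-multinomial dispersion in splicing ratios);
  a likelihood-ratio test compares one pooled concentration vector against
  per-condition vectors, `LRT ~ chi²(k)`, with BH-FDR across groups.
  Maximum likelihood uses Minka's fixed-point iteration with a
  method-of-moments start.
- **Complexity–expression profiling** (`splicomp.association`): Spearman
  correlation of each gene's log-CPM expression with aggregate *s* across
  samples, plus a read-depth confounder diagnostic (shallow samples
  systematically under-detect rare splice forms and score lower *s*; genes
  *anti*-correlated with complexity are the ones depth cannot explain).
- **Gene-set enrichment** (`splicomp.genesets`): competitive Wilcoxon
  rank-sum test of member vs non-member statistics, exact for small sets,
  normal approximation with tie/continuity corrections otherwise.
- **Contingency statistics** (`splicomp.contingency`): Pearson chi-square,
  Fisher's exact 2×2 with conditional-MLE odds ratio and exact CI, one-way
  ANOVA.
- **Synthetic cohorts** (`splicomp.sim`): seeded generator for junction
  counts with shared-endpoint group structure, planted differential groups,
  an expression matrix with genes planted to track aggregate complexity,
  sample sheets and GMT gene sets — written in every dialect the readers
  accept (generic TSV and STAR `SJ.out.tab`).

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (20 + 20 samples, 200 three-intron groups, 10% differential, 1000
genes with 5% planted to anti-correlate with complexity at rho ≈ −0.6):

```
$ python analysis/01_simulate_cohort.py --seed 1
cohort written to results/cohort
  intron groups: 200 (20 planted differential)
  genes: 1000 (50 complexity-linked)

$ python analysis/02_quantify_splicing_complexity.py
200 groups, 200 eligible for PSI
aggregate s: mean 0.700, range 0.679-0.723

$ python analysis/03_differential_splicing.py
tested 200 groups; 21 at FDR < 0.05
planted differential recovered: 19/20
false positives among null groups: 2

$ python analysis/04_complexity_expression_correlation.py
56% of genes correlate positively with complexity
planted anti-linked genes: median anti-rank 24 of 1000

$ python analysis/05_gene_set_enrichment.py
                 gene_set  n          fdr direction
PLANTED_COMPLEXITY_LINKED 25 4.440892e-15      Down

$ python analysis/06_calibration_and_power.py
type-I error at p<0.05 over 500 null groups: 0.052
power at delta-PSI 0.3 (n=20+20, FDR<0.05): 0.90
```

That is: the Dirichlet-multinomial LRT recovers 19 of 20 planted
differential groups at FDR < 0.05 with 2 false calls; the planted
anti-correlated genes concentrate at the top of the anti-correlation
ranking (median rank 24 of 1000); and the planted gene set dominates the
enrichment table as the top Down set.

The same operations are available as subcommands of the `splicomp` console
script (`simulate`, `groups`, `psi`, `complexity`, `diffsplice`,
`correlate`, `gsea`, `stats`, `run`); `splicomp run` executes the whole
pipeline from a YAML config with flag overrides and writes a run manifest.

```
$ splicomp stats chi2 "4,6,2;8,2,5;1,7,9"
X^2 = 11.79  df = 4  p = 0.01896
```

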