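# Methods

## Splice-form groups and coordinates

Internally all introns are (chrom, start, end, strand) with 0-based
half-open coordinates (BED interoperability); STAR `SJ.out.tab` input
(1-based inclusive, strand codes 0/1/2, uniquely-mapping read count in
column 7) is converted on read, and per-sample STAR files are merged by
intron key with absent entries as 0. Groups are the connected components,
computed by union-find, of the relation "shares a start or an end
coordinate on the same chromosome and strand". Grouping is
strand-stratified, with unknown strand ('.') its own stratum, so antisense
junctions never chain into chimeric groups; the alternative — ignoring
strand — was rejected because shared coordinates across strands carry no
splice-form meaning. Group ids are deterministic
(`chrom:leftmost-start:strand`), and ordering is always (chrom, leftmost
start, end) so reruns are byte-identical.

Whether group formation should chain components through both endpoints
(A–B share a donor, B–C share an acceptor ⇒ {A,B,C}) or stop at single
shared-endpoint bunches is genuinely open; chaining is implemented because
it is the transitive closure of the stated relation, and the test suite
pins it against a brute-force pairwise-closure oracle.

## PSI and the complexity score

For an eligible group (k ≥ 2 members) and sample, PSI_i = y_i / Σ_j y_j
when the group total reaches `min_group_reads` (default 10, a degeneracy
control: tiny denominators make PSI and s nearly meaningless), otherwise
missing. Singleton groups are retained in the partition but excluded from
complexity: with k = 1, s ≡ 1 carries no information.

The complexity score is s = 1 − (PSI_max − PSI_avg). PSI_avg is computed
as the mean of the PSI vector — which equals 1/k exactly for a complete
vector — rather than hard-coding 1/k, so the formula stays faithful under
any future masking convention. For a k-member group, s ∈ [1/k, 1], with
s = 1 iff PSI is uniform and s = 1/k iff one intron carries all reads;
both directions are asserted over exhaustively enumerated count vectors.

The per-sample aggregate is the arithmetic mean of defined s values over
groups defined in at least `min_sample_fraction` (default 0.5) of samples.
Mean-over-filtered-groups is the least surprising aggregation and both
knobs are explicit; median or coverage-weighted variants would be
reasonable alternatives and can be built from the exported group × sample
matrix.

## Dirichlet-multinomial differential splicing

Counts of a group in a sample are modelled as multinomial with proportions
drawn from Dirichlet(alpha); the total concentration A = Σ alpha_k
controls between-sample variability of the splicing ratios. The
log-likelihood is used in log-gamma form with the multinomial coefficient
omitted — it depends only on the data and cancels in the ratio. Maximum
likelihood is Minka's fixed-point iteration

    alpha_k ← alpha_k · Σ_j [ψ(n_jk + alpha_k) − ψ(alpha_k)]
                      / Σ_j [ψ(N_j + A) − ψ(A)]

from a method-of-moments start (mean proportions scaled by a
moment-matched precision, clamped to [1e-2, 1e6]; fallback precision k
when moments are degenerate). Convergence: max |Δ log alpha| < 1e-8, at
most 1000 iterations. Components never observed in any sample sit on the
likelihood boundary; their alpha is pinned at 1e-8 and the fit flagged.
Equidispersed (sub-Dirichlet) data drive A → ∞; the iteration then walks
toward the multinomial limit until the iteration cap, which is the correct
behaviour for a boundary MLE and is reported via the converged flag.

The two-condition test fits the null on pooled rows and the alternative
per condition: LRT = 2(ll₁ + ll₂ − ll₀), clipped at 0 (unclipped negative
values are numerical and bounded by ~1e-6 on converged fits), with p from
the chi-square upper tail at df = k (2k alternative minus k null free
parameters). Samples whose group total is below `min_group_reads` are
dropped from that group's test, not imputed; conditions with fewer than
two usable samples skip the group with a reason code. BH-FDR is applied
across tested groups. More than two conditions is an explicit error.

Calibration, measured by the suite's own null simulations (shared alpha
per group, 20 + 20 samples, Poisson(100) group depth, concentration 5,
k = 3): the empirical type-I error at p < 0.05 is close to, but slightly
above, nominal — about 0.06 across thousands of null groups. This is the
finite-sample behaviour of the chi-square asymptotics at these sample
sizes (the fits themselves are exact MLEs: refining them with a
derivative-free optimizer changes no log-likelihood beyond 1e-11). Users
drawing inferences at small n should prefer FDR thresholds over raw
p = 0.05 cutoffs, or increase samples per arm.

## Expression correlation and the depth diagnostic

Expression is normalized to log2 CPM with pseudocount 0.5:
log2((c + 0.5)/(libsize + 1) × 1e6). Spearman correlation is
rank-invariant to monotone transforms on untied data, so the normalization
mainly standardizes tie structure. Correlation of each gene with aggregate
s uses midranks; samples with missing aggregates are excluded pairwise
(minimum 4 overlapping samples), zero-variance genes get a missing rho.
The depth diagnostic is the Spearman correlation between per-sample total
junction reads and aggregate s; binomial thinning of counts demonstrably
lowers aggregate s (rare splice forms drop below detection), which is why
the anti-correlated tail of the gene profile — not the positive one — is
the biologically interesting ranking.

## Gene-set test

The competitive Wilcoxon rank-sum test compares member genes' statistics
against all non-members in the universe of genes with defined statistics.
For sets of ≤ 10 members in universes of ≤ 50 genes the exact null is
computed by dynamic programming over doubled midrank sums (exact under
ties); otherwise a normal approximation with tie correction and a 0.5
continuity correction. Two-sided p is 2·min(lower, upper) capped at 1;
direction is Up when members' mean rank exceeds non-members'. The test
makes no inter-gene correlation adjustment and is anti-conservative when
member genes are co-expressed — results on real gene sets should be read
as rankings more than as calibrated p-values. `min_set_size` defaults
to 5.

## Contingency statistics

Pearson chi-square drops zero-margin rows/columns before testing
(df = (r−1)(c−1), upper-tail p validated against an independent
incomplete-gamma series to 6 significant digits). Fisher's exact 2×2 uses
the point-probability two-sided rule with a 1 + 1e-7 relative tolerance,
the conditional-MLE odds ratio under the noncentral hypergeometric
likelihood, and a 95% CI from inverting the exact conditional test at the
2.5% tails — the convention consistent with reporting an exact CI next to
the odds ratio; degenerate tables return p = 1 with 0/∞ bounds. One-way
ANOVA handles the all-constant degenerate case explicitly (F = 0, p = 1
when between-group variation is also zero).

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the level the pipeline consumes (no read-level simulation):

- **Geometry**: groups occupy disjoint 10 kb windows on one synthetic
  chromosome; members share the window's start coordinate, so intended
  groups share a 5′ endpoint and distinct groups share nothing.
- **Junction counts**: per group, base proportions p ~ Dirichlet(2,…,2);
  alpha = concentration · p (default concentration 5 — substantial
  between-sample PSI variability); per sample, N ~ Poisson(depth 100) and
  counts ~ Multinomial(N, Dirichlet(alpha)). Differential groups shift the
  primary component's expected proportion by `effect_delta_psi` (down when
  feasible, else up; infeasible configurations are rejected).
- **Expression**: gamma-Poisson (negative-binomial) counts with common
  dispersion 0.1 and log-normal baseline means — the standard RNA-seq
  count model. Linked genes' log-means follow the normal scores of the
  realized aggregate s with latent correlation inflated by a first-order
  attenuation factor (NB measurement noise plus the Gaussian-copula
  Spearman shrinkage (6/π)·asin(r/2)), so the observed Spearman lands near
  `link_strength` in expectation (measured: planted median rho ≈ −0.61 at
  a −0.6 target, n = 60).
- **Gene sets**: one planted set drawn from the linked genes plus 19
  uniformly drawn decoys, written as GMT.

Defaults (20 samples per condition, 200 groups, 3 introns per group, depth
100, 10% differential at delta-PSI 0.3, 1000 genes with 5% linked at
rho −0.6) describe a modest bulk cohort with a two-group outcome; none are
calibrated to any real dataset. A single master seed drives labelled child
streams (proportions / counts / expression / gene sets), so adding a stage
never perturbs earlier draws and reruns are byte-identical.

What the generator does *not* emulate — and therefore what passing tests
do not establish about real data: mapping and alignment artefacts, shared
junctions between overlapping genes, GC/length biases, correlated gene
modules (co-expression makes the gene-set test anti-conservative),
batch structure, and annotation incompleteness. Passing tests show the
statistics behave as designed when their model assumptions hold.

## Problem sizes used in verification

The verification studies run at the cohort scale described above: 2000
null groups for type-I calibration, one 200-group cohort (20 planted
differential) for power, 10 replicate 60-sample cohorts for planted-gene
recovery, 8 replicates for the thinning comparison, and 500 random draws
for gene-set null uniformity — sizes at which every quantity is stable to
the first decimal while the whole suite stays fast.

## Known limitations

- Chi-square asymptotics for the DM-LRT are mildly anti-conservative at
  small n (see above); no Bartlett-type correction is applied.
- The aggregation rule for per-sample s (mean over ≥50%-covered groups) is
  a documented choice, not a claim about any published analysis.
- The gene-set test ignores inter-gene correlation.
- Junction extraction from BAM, transcript-level quantification,
  alignment, clustering and subtyping are out of scope; junction counts
  arrive pre-tabulated.
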