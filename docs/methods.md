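# Methods

## The problem

A single-nucleotide variant that replaces the G of a CpG dinucleotide
(a G→A change) removes the substrate for DNA methylation on that
chromosome. At a methylation array probe overlapping such a SNP, the
per-sample methylation level therefore separates into three classes
that track the diploid genotype: A/A hypomethylated, A/G
hemimethylated, G/G hypermethylated. `methylpop` implements the chain
of analyses that follows from this observation: infer genotypes from
the methylation distribution, estimate allele and genotype frequencies
per population, test Hardy-Weinberg equilibrium (HWE), extract variant
sites from a resequenced locus alignment, and test for balancing
selection with Tajima's D.

## Methylation model and genotype calling

Array beta-values (fraction methylated, in [0, 1]) are transformed to
M-values, M = log2(β/(1−β)), after clipping β to [ε, 1−ε] with
ε = 1e-6 so the transform stays finite at the boundaries. M-values are
approximately Gaussian within a class, which β-values are not.

The M-value distribution is modelled as a k-component univariate
Gaussian mixture (default k = 3, one component per genotype) fitted by
expectation-maximization. The EM is deterministic: means initialize at
the 10th/50th/90th data percentiles (for k = 3), weights equal,
variances at the pooled variance; convergence is declared when the
log-likelihood changes by less than 1e-8, with a cap of 500 iterations
and a variance floor of 1e-4 that prevents a component collapsing onto
a single observation. Components are reported sorted by ascending
mean. Model selection over k ∈ {1, 2, 3} by BIC is available but not
the default, since the tripartite structure is the premise of the
analysis.

Genotypes are the argmax of the posterior responsibilities. The
lowest-mean component maps to the homozygote for the CpG-abolishing
allele ("A" by default); the orientation is a flag because which
allele destroys the CpG is locus-specific. Hard M-value thresholds can
replace the mixture when the user prefers fixed cutpoints.

Two published parameterizations of the three classes ship as presets:
`paper96` (means −4.21, −0.51, 1.41; sds 1.96, 2.06, 0.97) and
`paper45` (−5.01, −0.11, 1.97; sds 0.67, 0.49, 0.36); the default is
`paper96`. A `test` preset keeps the `paper96` means but uses sds of
0.3: with the published 96-sample spreads the classes overlap
substantially, so class-assignment accuracy is only assertable in the
well-separated regime, and the test suite says so explicitly by using
this preset. Calls on real overlapping data will be less accurate than
the ≥99% the tests demonstrate.

## Population-genetic statistics

Allele frequency from counts is p = (2·n_AA + n_AG)/(2n); from
published genotype proportions it is p = f_AA + f_AG/2. Published
proportions are converted back to integer counts by multiplying by n
and rounding half away from zero.

The HWE test is the chi-square goodness of fit of the observed
genotype counts against (np², 2npq, nq²), df = 1, with **no**
continuity correction — the uncorrected statistic is the one that
matches published single-locus tables of this kind. The inbreeding
coefficient estimate F̂ = 1 − obs_het/exp_het accompanies it; positive
F̂ is a heterozygote deficit. Monomorphic samples raise an error (the
test is undefined), and populations below n = 5 are skipped with a
warning.

Tajima's D uses the classical decomposition: a1 = Σ 1/i,
a2 = Σ 1/i², b1, b2, c1, c2, e1 = c1/a1, e2 = c2/(a1²+a2), and
D = (π − S/a1)/√(e1·S + e2·S(S−1)). π is the mean number of pairwise
differences, computed per site as n0·n1/C(n,2) with missing alleles
excluded pairwise; sites with more than 20% missing calls are dropped
first, with a logged count. The minor-allele-frequency filter retains
sites with MAF **strictly greater** than the threshold (default 0.05).
Degenerate cases: S = 0 gives D = NaN with a warning rather than 0;
at n = 3 the constants e1 and e2 are exactly zero, so D is likewise
NaN; below n = 4 a reliability warning is emitted.

Two diversity modes exist because resequenced Sanger consensus data
may be unphased: the default haplotype mode (exact pairwise π on a
haplotype matrix) and an unphased-diploid mode in which the 2N allele
copies at each site are the sample and π_site = 2p(1−p)·2N/(2N−1). On
phased data expanded to haplotypes the two coincide. The mode in use
is logged.

## Variant extraction from alignments

Alignment columns and VCF positions are both 1-based. Each polymorphic
column becomes one record; the reference allele is the majority allele
with an alphabetical tie-break (deterministic under sequence
reordering, unlike first-sequence conventions). Two-base IUPAC
ambiguity codes (R, Y, S, W, K, M) are heterozygote-informative and,
in diploid mode, expand to unphased heterozygous genotypes;
three/four-base codes, N and gaps are missing. Columns with more than
two alleles are emitted multi-allelic with a warning and excluded from
downstream haplotype statistics. VCF output is minimal v4.2 with a
GT-only FORMAT column.

The pipeline decides the alignment's ploidy automatically: if any
two-base ambiguity code is present the sequences are treated as
unphased diploid consensus sequences; otherwise each sequence is a
haplotype (diploid expansion of truly haploid sequences would count
every chromosome twice and bias n). Unphased heterozygotes can never
be split into haplotypes; requesting that raises an error directing to
the unphased estimator.

## Synthetic data

The generators produce every input the pipeline consumes, with the
statistical structure the analysis assumes; all are bit-reproducible
given (seed, config) and thread a single `numpy.random.Generator`.

* **Methylation**: per-class Gaussian M-values at the preset means and
  sds, β derived by the inverse transform. What it does not emulate:
  probe noise beyond Gaussian spread, batch effects, cross-reactive
  probes, or any epigenome-wide structure — passing tests show the
  calling machinery works where the class model holds, not that the
  class model holds for arbitrary probes.
* **Genotype counts**: one multinomial draw from
  (p² + Fpq, 2pq(1−F), q² + Fpq), so a heterozygote deficit (F > 0)
  like the one the HWE test detects can be generated directly.
* **Neutral haplotypes**: a standard n-sample coalescent (epoch
  lengths exponential with rate C(k,2), time in units of 2N
  generations) with infinite-sites mutation: mutation count Poisson
  with mean θ/2 × total branch length, each mutation a unique site on
  a branch chosen proportionally to length. θ is per locus, not per
  site. Analytic checks: E[S] = θ·a1, pairwise TMRCA ~ Exp(1), site
  frequency spectrum ∝ 1/i.
* **Balanced haplotypes**: two allelic classes simulated as
  independent neutral samples, plus `k_fixed` sites fixed between
  classes. This is a structural surrogate for an old balanced
  polymorphism — it reproduces the signature Tajima's D responds to
  (deeply diverged classes at intermediate frequency inflating π) —
  not a forward model with selection coefficients. No recombination,
  demography or linkage to any real locus is modelled, and the real
  locus's six-SNP haplotype structure is not reproduced.

Simulated haplotypes can be embedded in a random monomorphic
background sequence (default 2.5 kb, matching the amplicon scale of
the motivating study design) with the two alleles written as A/G, so
the FASTA → VCF → statistics path can be exercised end to end.

## Pipeline and reporting

`run_population_scan` chains the stages: genotype calling (only when
no genotype CSV is supplied), per-population frequencies and HWE,
variant extraction, MAF filtering, Tajima's D per grouping, and a
balancing-selection flag D > 1.80 (configurable; the conventional
bound for calling a significantly positive D at this locus scale).
Grouping for D is configurable ("all" pooled, or per population)
because stratified HWE testing and pooled D estimation can coexist in
one study design. Reports are written as JSON (full precision,
`schema_version: 1`, provenance block with config and seed, no
timestamp so reruns are byte-identical) and CSV (p-values to 3
decimals). Every number in the report equals the corresponding direct
module call; the pipeline adds no arithmetic.

`compare_to_reference` merges user-supplied reference population
frequencies (e.g. public-panel values) beside the sample populations,
sorted by ascending frequency of the low-methylation allele; no test
statistic is attached deliberately, as the comparison is descriptive.

## Problem sizes in tests and the acceptance script

The simulation-based checks use: 200 replicates of the balanced
two-class sample (12+12 haplotypes, k_fixed = 16, within-class θ = 1)
for the mean-D bound; 1,000 neutral replicates (n = 20, θ = 5) for the
calibration band on mean D and mean S; 2,000 replicates (n = 10,
θ = 2) for the site-frequency-spectrum fit. The SFS check uses a
chi-square with empirical between-replicate variances because sites
within a replicate share one genealogy, which overdisperses pooled
counts relative to a multinomial.

## Known limitations

* Mixture calling assumes Gaussian classes on the M scale and exactly
  one variant under the probe; adjacent variants or aneuploidy break
  the tripartite model.
* The balanced generator is a signature surrogate, not a population
  model; its D values should not be read as predictions for any real
  locus.
* Multi-allelic columns are carried in VCF but excluded from
  haplotype statistics.
* The HWE chi-square is asymptotic; at n ≈ 24 an exact test would
  differ in the tails, but the chi-square is the estimator this
  pipeline is specified to report.
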