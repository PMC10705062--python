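# Methods

`sweepscan` implements a selective-sweep and population-structure analysis
for structured diploid populations — the kind of contrast drawn between a
set of indigenous livestock populations and a set of commercial ones. This
note records the statistical models, the numerical conventions, and the
design decisions taken where more than one reasonable choice existed.

## Data model

Everything operates on a `GenotypeMatrix`: samples × variants
alternate-allele dosages (0, 1, 2, or missing) with 1-based variant
coordinates and a population label per sample. Multi-allelic VCF records
are dropped by default — the statistics below are defined for biallelic
sites — with an opt-in `multiallelic="split"` mode that emits one
pseudo-biallelic column per alternate allele. Indels read from a VCF are
retained as generic biallelic variants but excluded from the QC and scan
stages by default (`exclude_indels=True` in `apply_qc`), keeping those
stages SNP-based. Ploidy other than 2 is an error; the X chromosome is
treated like an autosome (all individuals diploid), so X results in males
should be interpreted with that caveat.

## Quality control

The chain runs in a fixed order — chromosome restriction → individual
missingness → minor-allele frequency → Hardy–Weinberg → LD pruning — with
conventional defaults: `mind` 0.1, `maf` 0.05 (inclusive at the boundary),
HWE p-floor 1e-6, LD window/step/r² of 100/50/0.2. Per-variant missingness
(`geno`) is deliberately not part of the chain. HWE is tested on the pooled
sample, not per population.

The HWE test is the exact conditional test: given the observed allele
counts, the heterozygote count follows a hypergeometric-type distribution,
and the two-sided p-value sums the probabilities of all outcomes no more
probable than the observed one (plain formulation, no mid-p correction).
The implementation uses the standard two-sided recurrence from the
distribution's mode; the test suite checks it against an exact-rational
brute-force enumeration on all small tables.

LD r² is the squared Pearson correlation of unphased dosages over
complete pairs (no haplotype-phase EM) — deterministic and testable, though
it can diverge slightly from phase-aware implementations. The pruner is
greedy: within each window of consecutive SNPs it repeatedly removes one
member of the highest-r² offending pair (the member with fewer non-missing
calls; ties drop the larger coordinate), advances by the step, and repeats
whole passes over the surviving SNP list until a pass removes nothing. The
fixpoint iteration is what guarantees the post-hoc audit — no surviving
within-window pair above the cutoff — which a single pass over the original
list cannot.

## Population structure

**PCA** uses Patterson standardization: missing dosages are mean-imputed
per variant, columns centered and scaled by √(p̂(1−p̂)); zero-variance
columns are excluded. Scores are left singular vectors scaled by singular
values; each component's sign is fixed so its largest-magnitude score is
positive.

**Ancestry** follows the binomial admixture model
g_ij ~ Binomial(2, Σ_k q_ik f_kj), fitted by plain EM over expected
ancestral allele-copy counts. Plain EM is slower than the quasi-Newton
block relaxation used by the well-known ancestry tools but is provably
monotone in log-likelihood, which the tests assert directly. Q and F are
clamped to [1e-6, 1−1e-6] (Q renormalized) for numerical safety; default
stopping is a log-likelihood delta below 1e-4 or 500 iterations, with 5
seeded restarts keeping the best likelihood. K is selected by masked-entry
cross-validation: non-missing genotype *entries* are partitioned into five
random folds, each fold is masked (treated as missing) during a fit, and
the squared dosage error mean((g − 2Σ_k q̂f̂)²)/2 over masked entries is
averaged; deviance-style CV was considered and rejected as needlessly
coupled to the clamping constants.

**IBS** distance between two samples is 1 minus the fraction of alleles
shared by state over sites non-missing in both (per site, 2 − |dosage
difference| shared alleles of 2). **Neighbor joining** is the Saitou–Nei
algorithm with deterministic tie-breaking (smallest index pair) and
negative branch lengths clamped to zero with the deficit moved to the
sister branch so the pair's summed length is preserved. On additive
matrices NJ is consistent, and the tests require exact recovery (1e-9) of
random additive trees up to 8 leaves. IBS and NJ run on the same LD-pruned
SNP set as PCA and ancestry.

## Sweep scan

Per-site differentiation between the two contrasted groups uses the
Weir–Cockerham variance-component estimator with components a (among
populations), b (among individuals within populations), c (within
individuals):

    θ̂ = a / (a + b + c)

computed by default with the two pooled *groups* as the two populations;
a `breed_level` flag computes the r > 2 version over the constituent
populations instead. The windowed statistic is the ratio of sums
Σa / Σ(a+b+c) over the sites in a window — the standard windowed
aggregation, preferred to the mean of per-site ratios for its stability at
near-monomorphic sites.

Nucleotide diversity per site is the unbiased mean pairwise haplotype
difference 2j(m−j)/(m(m−1)) for m non-missing alleles and alternate count
j; windowed π divides the per-site sum by the window length in bp (not the
number of sites), so sparse windows read as low-diversity per bp of
sequence.

Windows are 40 kb with a 20 kb step, anchored at position 1 per
chromosome, emitted while the start is within the chromosome and truncated
at its end. On the Sus scrofa 11.1 chromosome lengths (1–18 plus X,
packaged as a `.fai` fixture) this grid has 119,595 windows.

A window is *selected* in group 1 when its F_ST reaches the empirical
upper 5% quantile AND its log2(π₁/π₂) is at or below the lower 5% quantile
(diversity lost in group 1); selected in group 2 when F_ST reaches the same
cut AND the ratio is at or above the upper 5% quantile. Quantiles are
computed with linear interpolation over windows where both statistics are
defined; windows with zero π in either group (log2 undefined) are excluded
from quantile computation and never flagged, a choice that avoids ±∞ at
the cost of silently ignoring fully monomorphic windows. Cut comparisons
are inclusive, so ties at the threshold are retained. Flagged windows
overlapping or abutting with the same direction merge into candidate
regions; both window-level flags and merged regions are reported, since
"number of selected regions" is ambiguous between the two. Genes overlap a
region when their interval shares at least 1 bp with it.

## Synthetic data

The generator draws genotypes under the Balding–Nichols model: ancestral
frequency p ~ Uniform(0.05, 0.95) per site, population frequency
p_k ~ Beta(p(1−F_k)/F_k, (1−p)(1−F_k)/F_k) for differentiation parameter
F_k, dosage ~ Binomial(2, p_k). This gives closed-form control of expected
F_ST and heterozygosity without a coalescent simulator, which is exactly
what estimator-recovery testing needs.

A sweep is an interval where the expected heterozygosity of the target
group drops by a configured factor R: the Beta parameter becomes
F_s = 1 − (1−F̄)/R, so E[2p_s(1−p_s)] = 2p(1−p)(1−F̄)/R. Crucially, all
populations of the target group *share* one frequency draw per sweep site —
the swept haplotype is common to the group. Independent per-population
draws with the same F_s would let different populations fix different
alleles, leaving the group's pooled diversity (and the between-group
contrast) far less affected; the shared draw is what makes pooled windowed
π inside the sweep ≈ background/R, which the tests verify with the
package's own π estimator.

Admixed individuals draw dosages from Binomial(2, Σ_k q_k p_k) with a known
ancestry vector, providing ground truth for the ancestry model. Sites are
independent by default — windowed F_ST/π statistics do not need linkage —
with an optional first-order copying process (`ld_copy_prob`) that
correlates adjacent sites purely to exercise the LD pruner. Missing
genotypes are injected uniformly at a configurable rate.

The standard study designs used by the tests and the acceptance script:

* *Sweep recovery*: one 5 Mb chromosome, two populations of 15 per group,
  baseline F = 0.05, one 200 kb sweep (≈11 grid windows) at 8× reduction,
  SNP density 1/400 bp (~100 sites per 40 kb window, resequencing-like).
* *Ancestry recovery*: two populations of 25 at F = 0.3, ~2,000 SNPs.
* *Default pipeline demo*: four indigenous + three commercial populations
  of 15, 5 Mb over two chromosomes, one sweep per group, a small admixed
  cohort with 50/50 ancestry.

What the generator does **not** emulate: realistic LD decay and haplotype
structure, mutation-rate heterogeneity, demographic history (bottlenecks,
migration), linked selection outside the declared sweep, genotyping error
beyond uniform missingness. Passing recovery tests therefore demonstrates
estimator and pipeline correctness under the declared model, not power on
real resequencing data.

Window-level recovery scores: a grid window is *true* for a group if it
overlaps any implanted sweep targeting that group, *called* if it overlaps
any candidate region with that direction; sensitivity is called-and-true /
true, precision is called-and-true / called (NA when nothing is called).

## Determinism

Every stochastic component takes an explicit seed (NumPy Generator);
rerunning the simulator or the pipeline with the same seed is
byte-identical. Pipeline outputs carry a header with version, config hash
and seed rather than timestamps. Quantiles, tie-breaks (LD pruning, NJ
joins, argmax) and EM restarts are all deterministic given the seed.

## Known limitations

* Windowed F_ST/π thresholds are dataset-relative quantiles; absolute
  threshold values are not comparable across datasets.
* The exact HWE p-value uses a floating recurrence; agreement with the
  rational enumeration is verified to 1e-12 only for tables up to n = 50
  (the regime the tests cover), though accuracy degrades slowly above that.
* LD pruning semantics approximate, but are not bit-compatible with, the
  widely used genotype-analysis tool (phase-unaware r², fixpoint passes).
* No relatedness filtering, sex checks or imputation; inputs are assumed
  to be unrelated individuals with called genotypes.
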