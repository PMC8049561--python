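# Methods

## The statistic

`admixeval` implements a rank-constrained test of admixture models built on
f4-statistics. For a target population *t*, hypothesized sources
*s₁ … s_k*, and reference populations *r₀ … r_{n_R−1}*, the design matrix is

    X[i, j] = f4(t, s_i; r_0, r_j),     i = 1..k,  j = 1..n_R−1,

where f4(A,B;C,D) is the average over sites of (p_A − p_B)(p_C − p_D) of
sample allele frequencies. If allele frequencies of the target's ancestor
are a linear combination of the sources' with weights summing to one, the
expectation of X has rank at most k−1, and the weight vector *w* satisfies
wᵀX ≈ 0 because Σᵢ wᵢ f4(t, sᵢ; ·) = f4(t, Σᵢ wᵢ sᵢ; ·) vanishes.

The test statistic is the generalized-least-squares distance from X to the
nearest matrix of rank k−1, in the metric of the block-jackknife covariance
of vec(X):

    Q = min_{rank(E) ≤ k−1} (vec(X−E))ᵀ C⁻¹ (vec(X−E)),

referred to a χ² distribution with (k−(k−1))·((n_R−1)−(k−1)) = n_R − k
degrees of freedom. Weights are the left-null vector of the fitted Ê,
normalized to sum to one, with delete-one-block jackknife standard errors.
A model is *plausible* when P > 0.05 and every weight lies in [0, 1];
out-of-range weights are reported, never clamped, because they are
informative (a target beyond the ends of a genetic cline yields weights
near 2 and −1). The single-source case (k = 1) tests rank 0 of the
1×(n_R−1) row with n_R − 1 degrees of freedom — a clade test.

Whether the original tool uses this GLS objective directly or a
determinant-based likelihood ratio is not documented publicly; the GLS
objective is used here and validated behaviorally (P-value uniformity under
the true model, coverage of the weight intervals).

### Numerical choices

* **Rank fit.** The weighted low-rank problem is non-convex. For k = 2 the
  left factor is a direction (cos t, sin t) and the right factor solves a
  linear GLS system, so the fit is found globally by a 48-point grid over
  t ∈ [0, π) plus Brent refinement; this makes the statistic exactly
  invariant (to ~1e-6 relative) under source reordering and reference
  re-basing. For k > 2 the fit uses alternating weighted least squares from
  the truncated SVD plus eight deterministic random restarts.
* **Covariance regularization.** Before inversion the covariance receives a
  ridge of 1e-10 × trace/dim. With more f4 components than jackknife blocks
  the covariance is singular and the statistic explodes; that regime is the
  mechanism behind the reference-inflation failure mode and is left intact.
* **Jackknife.** Weighted delete-one-block jackknife (block weights =
  contributing site counts), reducing to the classical delete-one formula
  for equal blocks. The covariance of an f4 vector uses the same block
  partition for every component; blocks empty for a component contribute
  zero weight there (the all-snps policy makes per-component site sets
  differ under missing data).
* **Weight standard errors** re-derive the weights from delete-one-block
  design matrices with the covariance metric held fixed, then apply the
  weighted jackknife variance formula. They are mildly conservative at desk
  scale (empirical spread of α̂ is ~half the mean reported SE in pilot
  runs), which errs on the safe side for the 3-SE coverage claims.
* **f4 from sample frequencies.** No small-sample correction is applied:
  unlike f2/f3, f4 over four distinct population pairs is unbiased in the
  unadjusted sample frequencies.
* **Clade-test reference distribution.** For k = 1 the statistic is exactly
  a Hotelling T² form — a quadratic form of block means in their estimated
  covariance — so its P-value uses the finite-block F reference,
  T²·(B−d)/(d(B−1)) ~ F(d, B−d) with B blocks and d = n_R − 1. The χ²
  reference is its B→∞ limit and is anticonservative when d is an
  appreciable fraction of B, which happens in rotating clade scans at
  reduced genome scale (d = 13 against some tens to hundreds of blocks).
  The k ≥ 2 rank-constrained statistic is not exactly T² and keeps the χ²
  reference, whose calibration at the default desk scales was verified
  directly by null simulation.

## Synthetic data

All data are coalescent simulations (msprime), 22 chromosomes with human
autosome lengths times a scale factor, mutation rate 1.5e-8 and
recombination rate 1.0e-8 per bp per generation, 10 diploid individuals per
population (pairs of simulated haploid genomes). Only biallelic polymorphic
sites are retained. Genotypes move through the pipeline as alt-allele
counts with EIGENSTRAT (reference-count) conversion at the I/O boundary.

### The 16-population standard scenario

The exact split times of the published test tree are not public; the
scenario here was reconstructed to satisfy every stated constraint and then
checked by simulation:

* In-group caterpillar ((((0,1),2),3),4) with splits at 80/110/140/170
  generations and a (5,6) clade splitting at 50, joining at 310; diploid
  Ne 35,000. Average pairwise FST among populations 1–5 ≈ 0.003 (within the
  stated <0.001–0.005 window), and the shared-drift ordering with
  population 0 makes sources 1→4 decreasingly bad substitutes for source 5.
* Population 14 is formed at generation 100 by a pulse: proportion α from a
  lineage that split from the (5,6) stem at 245, and 1−α from a lineage
  that population 9 splits from at generation 280 (populations 8 and 9 form
  a clade at 235). The older pulse forms population 15 at generation 350
  with β = 0.55 from a lineage related to 11.
* The two source-side stems diverge at generation 1500, and the references
  7/10/12/13 branch at 1800/2200/4200/5000 with the lineage of 11 joining
  at 3600; deep Ne 40,000. This yields FST(5,9) ≈ 0.02 and FST(0,13) ≈ 0.11
  — the within-Eurasia to French–Han range of differentiation the scenario
  is meant to mimic. Reference 0 is the only reference differentially
  related to populations 1–5; all references are symmetric or more distant
  with respect to the target than to the sources, so the standard model
  (target 14, sources 5 and 9, references 0/7/10/12/13) satisfies the
  method's assumptions.

At full scale the scenario yields tens of millions of SNPs; experiments run
at scales 1/25–1/1000 (below).

### Variant scenarios

* **Reference gene flow**: one extra pulse of proportion γ from a reference
  into a source lineage at generation 200 (after the source's split from
  the donor lineage — an assumption violation) or 350 (before it).
* **Many populations**: 51 nested pairs of populations grafted onto the
  standard tree (each pair's internal split 50 generations after its
  attachment), 118 populations total, used for the reference-inflation
  study.
* **Continuous gene flow after a pulse**: the main pulse moved to
  generation 240 (immediately after the 14a-donor/population-5 split at
  245), then symmetric migration from populations 5 and 9 into 14 at rate m
  until the present.
* **Stepping stone**: six demes (Ne 5,000) splitting simultaneously 1000
  generations ago and exchanging migrants with chain neighbours at rate m
  (m = 0.01 moves 100 haploid genomes per generation), plus three outgroups,
  all nine lineages from a common ancestor 2000 generations ago.

### Degradation operators

Site down-sampling; i.i.d. per-cell missingness (an exact per-individual
count variant exists behind a flag); pseudohaploid calling (one random
allele per site); transition flagging (77.6% of sites by default) followed
by deamination-style damage, applied per reference allele copy with
probability d = 0.05 (g → g + Binomial(2−g, d)), unidirectional; single-
individual heterozygote ascertainment (the panel individual is removed);
and per-population sample-size reduction. Stacks apply in ancient-DNA
processing order: downsample → ascertain → damage → pseudohaploid →
missingness → sample size.

## Desk-scale choices

Grading-free reproduction of the full study would need genome-scale
simulations; the experiments instead run at reduced genome scale. Two
choices matter:

* **Block size.** The default jackknife block is 0.05 Morgans. At reduced
  scale the block size shrinks with the genome but is floored at 2e-3
  Morgans: a pilot sweep showed that 1e-3 M blocks (comparable to the
  correlation length of the deeper genealogy) skew P-values low, while
  2e-3 M gives a uniform null P distribution with ~30–600 blocks depending
  on scale.
* **Scale per experiment.** Calibration studies (α grid, uniformity) are
  robust to scale and run at 1/500–1/900 (α grid 1/900, uniformity batch
  1/500). Studies whose outcome is a *power* statement get as much genome
  as the budget allows: the stepping-stone plausibility runs at 1/25–1/35,
  the rotating clade scan at 1/150 (with the F reference above), model
  comparison at 1/400, the ranking batch at 1/1500 (its contrast is
  genome-limited regardless, see below), the reference-inflation study at
  1/250 and the gene-flow bias study at 1/400.

Because bias z-scores scale with the square root of genome length, some of
the paper-scale contrasts are attenuated at desk scale: the rotating
protocol's rejection of near-optimal source pairs (notably {5,8}, which
rests on a 45-generation branch segment), the ≥95% rejection rate of the
source-11 model, the optimal model's 48% top-P share, and the rejection of
stepping-stone models at m ≤ 1e-3 all require genome scales (≳1/20 to full)
whose simulation cost is far beyond a desktop run. The corresponding tests
state the full-strength expectations and are expected to fail at desk
scale; the directions of all these effects do reproduce (e.g. the source-11
model's KS test rejects uniformity decisively at every scale tried).

What passing desk-scale tests do **not** show about real data: the
simulations have no reference bias, no error correlation between
individuals, uniform recombination and mutation rates, a single panmictic
deme per population, and sampling strictly at the present. Damage is a
per-genotype approximation of read-level deamination, which concentrates at
fragment ends; the 5% rate is an extreme-case bound, not a typical library.

## Known limitations

* The rank-fit/χ² calibration degrades when the number of f4 components
  approaches the number of jackknife blocks; at desk scale this caps usable
  reference-set sizes (and is exactly why piling on references destroys
  P-values).
* Weight standard errors are conservative rather than exact at small block
  counts.
* Only biallelic sites and unphased diploid (or pseudohaploid) genotypes
  are supported; PACKEDANCESTRYMAP, VCF and phased data are out of scope.
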