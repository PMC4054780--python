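# Methods

This note documents the models and procedures implemented in
`sweepscan`, the parameters that matter, the synthetic-data design, and
the places where a genuinely open design choice had to be made.

## Diversity estimators and window statistics

For a window with segregating sites at alternate-allele frequencies
p_i estimated from n haplotypes:

- θ_π = Σ_i 2 p_i (1 − p_i) · n/(n−1) — average pairwise
  heterozygosity with the small-sample correction; algebraically equal
  to the mean pairwise difference count over all C(n,2) haplotype
  pairs (asserted against a brute-force pairwise oracle in the tests).
- θ_f = Σ over non-fixed sites of p_i — the summed non-fixed
  frequency estimator, which down-weights low-frequency alleles and so
  stays sensitive long after a sweep has fixed.
- S_f = log(θ_f,control / θ_f,study), S_π analogous. Natural
  logarithms throughout; the literature does not fix a base and the
  choice only rescales cutoffs, which are empirical quantiles anyway.
  A window with zero study diversity but positive control diversity
  returns +∞: it is reported, flagged significant (total diversity
  loss is the strongest sweep signal), but excluded from quantile
  estimation, which an infinite value cannot anchor.
- Hudson's F_st = 1 − Σπ_w / Σπ_b, accumulated as ratio-of-sums
  across a window's sites rather than averaged per site: per-site
  ratios are unstable at low diversity. π_w is the unweighted mean of
  the two panels' corrected heterozygosities; π_b = p₁(1−p₂) + p₂(1−p₁).
- T = −log(1 − F_st) and PBS = (T_SN + T_SO − T_NO)/2. PBS may be
  negative (diversification on the control branches) and is reported
  as-is.

Windows are 50 kbp sliding at 2 kbp by default (10 kbp / 2 kbp at desk
scale, preserving the window:region ratio). Windows with fewer than 10
segregating sites (configurable) are flagged insufficient rather than
scored: a log-ratio over a near-empty window is noise. Statistics are
computed on the intersection of the panels' site universes; sites
monomorphic in every panel contribute nothing and are skipped.
Coordinates are 1-based inclusive internally and BED (0-based
half-open) at I/O boundaries.

## Variant filters

Three filters run in a fixed order, each reporting removed-site counts:

1. **Clustered rejects.** Every maximal run of ≥ 10 consecutive
   caller-rejected SNPs (within one chromosome; runs never span
   chromosomes) defines a closed removal interval; *all* sites inside
   it, clean or not, are dropped from every panel — the artifact is the
   region, not just the flagged sites. Rejected sites outside such runs
   are kept in the table (still flagged) and excluded from scan
   statistics.
2. **Coverage.** Sites with mean depth strictly above
   2 × genome-wide median (duplication) or strictly below 2 per person
   (too shallow) are removed; a site exactly at either bound is
   retained.
3. **Heterozygote excess.** The exact conditional probability of a
   genotype configuration given its allele counts,
   P(n_Aa) = n!/(n_AA! n_Aa! n_aa!) · n_A! n_a!/(2n)! · 2^{n_Aa},
   is computed in log-gamma arithmetic (exact to ~1e−12 relative error
   for n up to 10⁴). The test statistic is the one-sided upper tail —
   the sum of P over all compatible heterozygote counts ≥ the observed
   one — because "excess of heterozygotes" names a tail, not a point
   probability. Sites with P < 0.05 are removed. Panels without
   genotype counts (frequency-only input) skip this filter with a
   warning.

The filters are idempotent, and their composition is order-stable:
clusters first (they reflect calling artifacts), then coverage, then
the genotype test.

## Region prioritization

Candidate regions are unions of overlapping/abutting significant
windows (merge gap 0 by default, configurable). Four criteria then run
in order; each can only shrink the surviving set, and a region is
prioritized iff it passes all four. A criterion that cannot be
evaluated for a region (no overlapping panel or external sites) carries
the region forward flagged rather than silently passing or failing it.

- **f-frequency blocks.** For each grid frequency f = k/n
  (k = 1…n−1), sites whose study frequency lies within 1/n of f are
  selected; runs of ≥ 10 consecutive sites *within the selected
  subsequence* form blocks. "Consecutive" deliberately ignores
  intervening sites at other frequencies: post-sweep de novo singletons
  inside a swept haplotype must not fragment its block. The strict
  genome-consecutive reading is available as a switch
  (`genome_consecutive=True`). Blocks with identical member sets found
  at adjacent grid values are labeled with the grid f closest to the
  members' mean frequency; nested member sets keep only the maximal
  block.
- **Sampling threshold.** The minimum believable frequency
  differential at sample size n is the half-width of the central exact
  binomial set at the block's mean frequency whose coverage is closest
  to 95%. The guaranteed-coverage equal-tail construction overshoots
  badly at n ≈ 12–14 because of discreteness; the closest-coverage set
  reproduces the operating magnitudes this scheme is known for (~21% at
  n = 14 and intermediate frequencies, roughly doubling when the
  haplotype count halves, as on the X chromosome — callers pass the
  halved count there). Discreteness makes the threshold only
  approximately monotone in n between adjacent sample sizes.
- **Differentials.** Criterion 1 compares the block mean against the
  *closer* of the two primary controls; criterion 2 requires the
  differential to exceed the threshold against *every* additional
  panel, excluding uncovered member sites pairwise. Criterion 3 revises
  the block frequency by the sample-size-weighted average with an
  external genotyping cohort restricted to member sites the cohort
  covers (a convex combination, so the revision stays between the two
  inputs) and requires a > 10% differential against all controls.
  Criterion 4 requires ≥ 1 bp overlap with an annotated transcript
  (BED or GTF).

A one-sided Fisher exact test (hypergeometric upper tail) is provided
for downstream enrichment arithmetic, e.g. scoring experimental hits
among tested candidate genes against a screened background.

## The simulator

`SimParams` defaults are the full-scale study conditions: N_e = 1000
diploids, μ = 2.4e−7 and r = 3.784e−8 per base per generation over a
50 kbp region (θ_region = 4 N_e μ L = 48, ρ_region = 7.57), selection
coefficient s = 0.02, sample n = 100 diploids, 200 replicates (500 for
the sample-size experiment).

- **Neutral source.** Default is a coalescent sampler (msprime) of the
  whole population at exact mutation–drift equilibrium under
  infinite-sites mutation on continuous coordinates. The normative
  contract is the neutral site-frequency spectrum,
  E[#alleles at derived count i] = θ/i, verified by a
  Hotelling T² test of replicate-mean binned SFS counts against that
  expectation using the empirical between-replicate covariance. (A
  naive χ² on pooled counts is invalid here: linked sites share
  genealogies, so pooled SFS counts are far overdispersed relative to
  multinomial.) A neutral forward burn-in (≥ 10 N_e generations) is
  provided as an independent route to the same contract.
- **Splits.** Three (or more) daughter populations of 2 N_e haplotypes
  each are drawn with replacement from the source.
- **Forward evolution.** Discrete Wright–Fisher generations: parents
  drawn with probability proportional to fitness 1 : 1 + hs : 1 + s
  (aa : Aa : AA at the selected site; h = 1/2 codominance by default —
  only the homozygote fitness is fixed by the design, and the additive
  model is the sweep-literature standard, with h configurable);
  meiosis with Poisson(rL) crossovers at uniform positions; Poisson
  (μL per haplotype) infinite-sites mutations. Monomorphic columns are
  purged each generation, but positions whose derived allele *fixed*
  are recorded: when panels are aligned for cross-population
  statistics, such positions count 2N (a fixed difference). Without
  this bookkeeping F_st and PBS would be blind to the strongest sweep
  signature.
- **Selected locus.** By default a de novo single copy injected at the
  region midpoint when selection starts (midpoint maximizes symmetric
  hitchhiking); replicates that lose the allele restart from the
  initial state with fresh randomness, i.e. the experiment conditions
  on establishment, and the restart count is recorded. A
  standing-variation mode selects an existing allele nearest a given
  frequency instead.
- **Determinism.** One root seed; per-replicate coalescent seeds are
  drawn from the root generator, so every result is reproducible from
  (parameters, seed).

### Desk scaling

Experiments run at N_e = 100, L = 10 kbp with μ and r rescaled to
preserve θ_region and ρ_region, s rescaled to preserve 2 N_e s = 40,
and times rescaled in units of N_e generations (τ_desk = τ_full/10).
Under this scaling the diffusion dynamics of the sweep are preserved;
the measured median fixation time of the conditioned sweep is ~80
generations (inter-quartile ~70–100), which anchors the three regimes:
pre-fixation (τ ≈ 35, mean beneficial frequency ~0.34), near fixation
(τ ≈ 70–110, the haplotype dominates; one-third of replicates already
fixed at τ = 80), post-fixation (τ ≥ 150, ~99% fixed).

### Power estimation

Power of a statistic at the 5% false-positive rate is the fraction of
study-vs-cont1 values exceeding the top 5% of the null distribution —
the same statistic applied to the neutral pair cont1-vs-cont2 — pooled
across replicates (the per-replicate alternative is noisier and the
pooling choice is the one that makes the cutoff an estimate of a fixed
population quantity). The three-population PBS needs an outgroup in its
null too; with three simulated populations the study population takes
the null's outgroup role (under neutrality the trio is exchangeable;
under selection the study branch enters both outgroup T terms and
cancels in expectation, at the price of extra null variance). A
`null_outgroup="neutral"` mode evolves a fourth neutral population for
the null instead, which removes that contamination and measurably
strengthens PBS — the default stays with the three-population
construction this analysis design implies.

The sample-size experiment is paired: the same evolved replicates are
resampled at every sample size, so power differences between sizes
reflect sampling alone. The gold-standard "large sample" is n = 400
haplotypes at full scale; at desk scale 400 exceeds the census 2N = 200
and the gold standard becomes the census itself — exact population
frequencies, a strictly *harder* baseline, so desk-scale relative-power
numbers are conservative. With 500 paired replicates per time point the
minimum relative power of n ∈ {12, 14} across the four sampled regimes
is printed by `analysis/05_sample_size_power.py` and recomputed by
`scripts/acceptance.py`.

## What the synthetic data does and does not emulate

The generator reproduces the features the method's operating
characteristics depend on: an equilibrium neutral SFS, a common source
population with three-way divergence by drift, hitchhiking and
diversity loss around a selected locus, fixed differences, and
binomial sampling noise at small n. It does not emulate demographic
history (bottlenecks, growth, admixture), sequencing error or depth
heterogeneity beyond the filter fixtures, linkage maps with hotspots,
X-chromosome inheritance, or back-mutation (infinite sites). Passing
tests therefore demonstrate correctness of the statistics, filters,
prioritization logic and calibration machinery under the stated model
— not robustness of the scan to demographic confounding, which
cross-population designs only partially control.

## Numerical choices and degenerate inputs

- Factorials via log-gamma; probabilities re-exponentiated once.
- Window F_st is undefined (NaN) when Σπ_b = 0; T(F_st ≥ 1) = +∞.
- Quantile cutoffs use the empirical quantile of finite values only;
  +∞ windows are flagged significant directly.
- Sample sizes requested above the census are clipped to the census.
- Chromosomes shorter than one window yield a single truncated window;
  a trailing truncated window is emitted only when the uncovered tail
  is at least one step long.
- Blocks tie-broken toward more members, then lower f; identical
  member sets labeled by the closest grid frequency.
- The Wright–Fisher engine restarts a replicate (fresh randomness,
  counted) whenever the beneficial allele is lost, capping restarts at
  10⁴ before raising.

## Known limitations

- The empirical top-0.1% cutoff is a genomic-control device, not an
  error rate: with few windows (desk-scale genomes) it degenerates
  toward the per-statistic maximum.
- The null-outgroup contamination discussed above biases PBS power
  downward under strong selection in the default construction.
- Infinite-sites continuous coordinates must be snapped to integers
  for VCF/BED export; collisions are resolved by bumping to the next
  free base, which can shift positions by a few bp in dense regions.
- The prioritization operates per study population; cross-population
  intersection of prioritized regions is left to the caller.
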