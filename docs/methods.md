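# Methods

## Scope and model

`bsadesign` computes the expected outcome of a two-pool (high vs low
trait) BSA-seq experiment under a single-QTL model. The trait is a
mixture of three normal components (two for haploid-equivalent
populations), one per QTL genotype class, with unit residual variance
after standardization. All computation is in standardized units; raw
scale parameters (a, d, μ, σ_e) never enter the formulas.

Assumptions worth stating explicitly:

- one biallelic QTL, no epistasis, normal residuals;
- the pools are formed by exact phenotypic truncation of the whole
  population (design "high pool vs low pool");
- the AFD variance comes from which individuals enter the pools, not
  from sequencing: block-regression smoothing of deep-sequencing data
  removes read-resampling noise, so read depth is excluded from the
  variance model (the simulator's optional depth layer exists to show
  the depth-free limit is reached quickly);
- the threshold constant u is an input. It encodes the genome-wise
  multiple-testing correction of the upstream scan method and depends
  on genome length and marker structure, which this package does not
  model. Shipped defaults (3.93 haploid/yeast-like; 3.65/3.74/3.78 for
  F2/F3/F4 rice-like genomes) correspond to a genome-wise level of
  0.05, i.e. nominal two-tailed levels of 8.49e-5 to 2.62e-4.

## Orientation convention

The P1 homozygote mean is μ − a, so with a₀ > 0 the P1 allele is
enriched in the *low* pool and the expected AFD (H minus L, P1 allele)
is negative. Power is two-tailed and sign-agnostic; the CI formulas
use |μ_Δf|. The convention was confirmed against the pooled-truncation
simulator (sign and magnitude agree), so the mirrored convention was
not needed.

## Key parameters

| parameter | meaning | default | why |
|---|---|---|---|
| p | mean pool proportion (p_H+p_L)/2 | 0.25 | both power and CI optima sit near 0.25 across heritabilities |
| γ | pool ratio p_H/p_L | 1 | imbalance strictly hurts both criteria |
| r_d | degree of dominance d₀/a₀ | 0 | additive baseline; allowed in [−2, 2] |
| u | threshold constant | per population (see above) | genome-wise 5% level |
| n_max | bisection cap for minimum-n | 10⁷ | power has saturated far below this for any practical design |

The degree of dominance is accepted anywhere in [−2, 2]
(overdominance included); documentation examples stay in [0, 1].

## Numerical choices

- Cut points: the mixture CDF is strictly monotone, so `brentq` on
  [−12, 12] with xtol 1e-10 is exact for practical purposes; no
  tie-breaking arises.
- Apparent-recombination inversion: θ_k(θ) is strictly increasing with
  range [0, 0.5], inverted by bisection on [0, 0.5−1e-12] (tolerance
  1e-12); the RIL (k→∞) case uses the closed inverse θ = x/(2−2x).
  Apparent values ≥ 0.5 signal an unbounded interval.
- The CI border multiplier is 1.65 (hence the 0.825 factor) exactly,
  not the 95% normal quantile 1.6449, and is applied uniformly across
  generations; a generation-specific multiplier was considered and
  rejected because the downstream width is insensitive at the fourth
  decimal and a single constant keeps F₂/F₃/F₄ comparable.
- CI for F₃/F₄ inverts the selfing series θ₃ = θ(3−2θ)/2,
  θ₄ = θ[1+(1−2θ)/2+(1−2θ)²/4]; these were re-derived from
  double-heterozygote transmission under selfing and verified by the
  meiosis simulator. RIL support (k=∞ scale) is an extension beyond
  the F₂–F₄/H/DH cases and is flagged as such.
- Null power equals the nominal α identically; the negligible
  wrong-tail term of the power formula is kept so this identity is
  exact.
- Minimum-n: power is monotone in n (μ_Δf is n-free; T and σ_Δf scale
  as n^(−1/2)), so integer bisection is exact; a closed-form √n
  rearrangement serves as an independent oracle in the tests.
- Degenerate inputs: h² = 0 gives power exactly α and an infinite CI
  (reported with `finite=False`, not an error); pool proportions are
  validated at construction.

## What the simulator emulates — and what it does not

`bsadesign.simulate` draws whole populations forward: F1 gametes with
per-interval Bernoulli(θ) crossovers (no interference), k−2 further
selfing rounds for F_k (one offspring per parent, independent
meioses), phenotypes as genotype-class means plus N(0,1) noise,
truncation pooling with ⌈p·n⌉ pool sizes (phenotype ties broken by
individual index), and per-replicate regeneration of the entire
population — matching the interpretation of σ_Δf as between-experiment
variation, which the variance-ratio checks confirm empirically.
Randomness is a single `SeedSequence` spawned into one child stream
per replicate, so replicate r is identical regardless of how many
replicates are requested.

It does not emulate: genome-scale marker maps (markers are placed by
their θ to the QTL, conditionally independent given the QTL strand),
crossover interference, read-level sequencing (the depth layer is a
binomial resampling of pool frequencies), multiple or linked QTLs, or
selection-induced distortion of recombination — the analytic CI
likewise ignores the influence of phenotypic selection on the local
recombination rate, and the simulator inherits that framing. Passing
tests therefore show the closed forms are correct *within this
generative model*; they do not certify robustness to interference,
polygenic backgrounds, or non-normal residuals in real data.

A caveat on oracle granularity: at small n (e.g. 200) the analytic
truncation model ignores pool-size rounding, which shifts the
simulated AFD mean by a couple of its standard errors; comparisons at
that size are near the tolerance edge by nature, not by bug.

## Problem sizes used in validation

The simulator cross-checks run 2000 replicated experiments at six
design points (haploid and F₂; h² ∈ {0.03, 0.1}; n ∈ {200, 1500}), and
the selfing-recombination check uses 10⁶ transmitted chromosomes per
(θ, k) cell — sizes at which Monte-Carlo error is a few per mille,
small enough to resolve the formulas' predictions while keeping the
whole suite around ten seconds.

## Known limitations

- u must come from the upstream scan method; using a mismatched u
  shifts every power and CI number.
- The diploid variance treats the 2p·n pooled alleles as independent
  binomial draws; allele pairs within an individual are not truly
  independent, but the replicated simulations show no measurable
  departure from the formula at the 10% level.
- Apparent-recombination accumulation assumes selfing; F_k by random
  mating retains the F₂ single-locus structure and is out of scope.
- The CI width is an expectation, not a per-experiment guarantee.
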