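"""Forward Monte-Carlo simulator of BSA-seq experiments.

Simulates segregating populations locus-by-locus around a single QTL,
assigns phenotypes from the genotype-class means plus standard-normal
noise, forms high/low trait pools by truncation, and measures allele
frequency differences — providing an empirical check of every closed
form in the analytic modules without any external data.

Genetics: each individual carries two haplotypes (one for haploid
populations) over loci (QTL, marker_1, ..., marker_m), each marker
defined by its single-meiosis recombination rate theta to the QTL.
Gametes are formed without interference: the QTL strand is chosen
uniformly, and each marker allele follows the same strand with
probability 1 - theta.  F2 individuals are pairs of F1 gametes; F_k
(k >= 3) populations are obtained by k-2 further rounds of selfing,
one offspring per parent with two independent meioses.  One replicate
regenerates the whole population (meioses and pool membership), so the
replicate-to-replicate spread of the AFD matches the between-experiment
variance the analytic model describes.

Randomness: a root ``numpy.random.SeedSequence(seed)`` is spawned into
one child stream per replicate, so replicate r is reproducible
independently of how many replicates are requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import beta

from .afd import DesignPoint
from .genetic_model import PopulationKind, PopulationSpec


@dataclass(frozen=True)
class SimConfig:
    """Parameters of a simulated BSA-seq experiment.

    ``thetas`` are single-meiosis recombination rates from each marker
    to the QTL; the QTL itself is always locus 0 of the output.
    ``depth`` optionally resamples each pool's allele frequency
    binomially at a fixed read depth per site.
    """

    pop: str = "H"
    n: int = 1000
    a0: float = 0.0
    d0: float = 0.0
    pH: float = 0.25
    pL: float = 0.25
    thetas: tuple[float, ...] = ()
    replicates: int = 1
    seed: int = 0
    depth: int | None = None

    def __post_init__(self):
        for th in self.thetas:
            if not 0.0 <= th <= 0.5:
                raise ValueError(f"marker theta must be in [0, 0.5], got {th}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.n < 2:
            raise ValueError("population size must be >= 2")
        spec = PopulationSpec.make(self.pop)
        if spec.kind is PopulationKind.F_SELFING and spec.k is not None and spec.k > 60:
            raise ValueError("selfing generation too large to simulate explicitly")

    @property
    def pop_spec(self) -> PopulationSpec:
        return PopulationSpec.make(self.pop)

    @classmethod
    def from_design(
        cls,
        design: DesignPoint,
        thetas: tuple[float, ...] = (),
        replicates: int = 1,
        seed: int = 0,
        depth: int | None = None,
    ) -> "SimConfig":
        return cls(
            pop=design.pop.label,
            n=design.n,
            a0=design.effect.a0,
            d0=design.effect.d0,
            pH=design.pool.pH,
            pL=design.pool.pL,
            thetas=thetas,
            replicates=replicates,
            seed=seed,
            depth=depth,
        )


def _gametes(haps: np.ndarray, thetas: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent from diploid haplotypes (n, 2, L).

    Locus 0 (QTL) picks a strand uniformly; marker j recombines onto the
    other strand with probability thetas[j-1], independently per meiosis
    and per marker (no interference).
    """
    n, _, L = haps.shape
    strand = rng.integers(0, 2, size=n)
    rows = np.arange(n)
    gam = haps[rows, strand, :].copy()
    if L > 1:
        rec = rng.random(size=(n, L - 1)) < thetas[None, :]
        other = haps[rows, 1 - strand, :]
        gam[:, 1:] = np.where(rec, other[:, 1:], gam[:, 1:])
    return gam


def simulate_population(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one population: haplotypes and phenotypes.

    Returns ``(haplotypes, phenotypes)`` where haplotypes is an int8
    array of P1-allele indicators, shape (n, 2, L) for diploid
    populations or (n, 1, L) for haploid ones, with locus 0 the QTL.
    Phenotypes are genotype means (-a0 for the P1 homozygote/hemizygote,
    d0 for heterozygotes, +a0 for the P2 class) plus N(0, 1) noise.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    spec = config.pop_spec
    thetas = np.asarray(config.thetas, dtype=float)
    n, L = config.n, 1 + len(config.thetas)

    # F1 is fully heterozygous: one all-P1 and one all-P2 haplotype.
    f1 = np.zeros((n, 2, L), dtype=np.int8)
    f1[:, 0, :] = 1

    if spec.kind is PopulationKind.HAPLOID:
        haps = _gametes(f1, thetas, rng)[:, None, :]
        qtl_dose = haps[:, 0, 0].astype(float)  # 0 or 1 copies of Q
        geno_mean = np.where(qtl_dose == 1, -config.a0, config.a0)
    elif spec.kind is PopulationKind.F_SELFING:
        haps = np.stack(
            [_gametes(f1, thetas, rng), _gametes(f1, thetas, rng)], axis=1
        )
        for _ in range(spec.k - 2):
            haps = np.stack(
                [_gametes(haps, thetas, rng), _gametes(haps, thetas, rng)], axis=1
            )
        dose = haps[:, 0, 0] + haps[:, 1, 0]  # copies of Q: 0, 1, 2
        geno_mean = np.select(
            [dose == 2, dose == 1], [-config.a0, config.d0], default=config.a0
        )
    elif spec.kind in (PopulationKind.DH, PopulationKind.RIL):
        if spec.kind is PopulationKind.DH:
            gam = _gametes(f1, thetas, rng)
        else:
            # selfing to (near-)fixation, then keep one haplotype
            haps = np.stack(
                [_gametes(f1, thetas, rng), _gametes(f1, thetas, rng)], axis=1
            )
            for _ in range(40):
                haps = np.stack(
                    [_gametes(haps, thetas, rng), _gametes(haps, thetas, rng)],
                    axis=1,
                )
            gam = haps[:, 0, :]
        haps = np.stack([gam, gam], axis=1)
        dose = haps[:, 0, 0]
        geno_mean = np.where(dose == 1, -config.a0, config.a0)
    else:  # pragma: no cover
        raise ValueError(f"unsupported population: {config.pop}")

    phenotypes = geno_mean + rng.standard_normal(n)
    return haps, phenotypes


def _pool_indices(phenotypes: np.ndarray, pH: float, pL: float) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the top ceil(pH*n) and bottom ceil(pL*n) individuals.

    Phenotype ties are broken by individual index (stable sort), so the
    pools are deterministic given the phenotype vector.
    """
    n = len(phenotypes)
    nH = math.ceil(pH * n)
    nL = math.ceil(pL * n)
    if nH < 1 or nL < 1 or nH + nL > n:
        raise ValueError("pool proportions give an empty or overlapping pool")
    order = np.argsort(phenotypes, kind="stable")
    return order[n - nH:], order[:nL]


@dataclass
class SimResult:
    """Empirical AFD summaries from replicated simulated experiments.

    ``afd`` has shape (replicates, L) with locus 0 the QTL; allele
    frequencies refer to the P1 allele, so with a0 > 0 the AFD at the
    QTL is negative in expectation.
    """

    config: SimConfig
    thetas: np.ndarray
    afd: np.ndarray
    freq_H: np.ndarray
    freq_L: np.ndarray
    recomb_fraction: np.ndarray = field(default=None)

    @property
    def afd_mean(self) -> np.ndarray:
        return self.afd.mean(axis=0)

    @property
    def afd_sd(self) -> np.ndarray:
        return self.afd.std(axis=0, ddof=1)


def simulate_pools_and_afd(config: SimConfig) -> SimResult:
    """Replicated pooling experiments: per-replicate AFD at every locus.

    Each replicate draws a fresh population, truncates it into H and L
    pools and computes the pools' P1-allele frequency difference; the
    optional depth layer replaces each pool frequency by a
    Binomial(depth, f)/depth draw, mimicking finite sequencing coverage.
    """
    streams = [
        np.random.default_rng(s)
        for s in np.random.SeedSequence(config.seed).spawn(config.replicates)
    ]
    L = 1 + len(config.thetas)
    afd = np.empty((config.replicates, L))
    fH_all = np.empty((config.replicates, L))
    fL_all = np.empty((config.replicates, L))
    rec = np.zeros(L)
    ploidy = 1 if config.pop_spec.kind is PopulationKind.HAPLOID else 2
    for r, rng in enumerate(streams):
        haps, phen = simulate_population(config, rng)
        chroms = haps[:, :ploidy, :]
        rec += (chroms != chroms[:, :, :1]).mean(axis=(0, 1))
        iH, iL = _pool_indices(phen, config.pH, config.pL)
        fH = chroms[iH].mean(axis=(0, 1))
        fL = chroms[iL].mean(axis=(0, 1))
        if config.depth is not None:
            fH = rng.binomial(config.depth, fH) / config.depth
            fL = rng.binomial(config.depth, fL) / config.depth
        fH_all[r], fL_all[r] = fH, fL
        afd[r] = fH - fL
    return SimResult(
        config=config,
        thetas=np.asarray(config.thetas),
        afd=afd,
        freq_H=fH_all,
        freq_L=fL_all,
        recomb_fraction=rec / config.replicates,
    )


def recombinant_fraction(
    pop: str, theta: float, n: int, seed: int = 0
) -> float:
    """Fraction of recombinant haplotypes among a population's chromosomes.

    A haplotype is recombinant when its marker allele differs from its
    QTL allele.  With ``n`` diploid individuals this measures 2n
    transmitted chromosomes — the empirical counterpart of the apparent
    recombination rate theta_k accumulated over selfing generations.
    """
    config = SimConfig(pop=pop, n=n, thetas=(theta,), seed=seed)
    haps, _ = simulate_population(config)
    ploidy = 1 if config.pop_spec.kind is PopulationKind.HAPLOID else 2
    chroms = haps[:, :ploidy, :]
    return float((chroms[:, :, 1] != chroms[:, :, 0]).mean())


def empirical_power(
    config: SimConfig, threshold: float, confidence: float = 0.99
) -> tuple[float, tuple[float, float]]:
    """Fraction of replicates whose |AFD at the QTL| exceeds the threshold.

    Returns the point estimate and an exact (Clopper-Pearson) binomial
    confidence interval.
    """
    if config.replicates < 100:
        raise ValueError("need >= 100 replicates for a power estimate")
    result = simulate_pools_and_afd(config)
    hits = int((np.abs(result.afd[:, 0]) > threshold).sum())
    reps = config.replicates
    a = (1.0 - confidence) / 2.0
    lo = 0.0 if hits == 0 else float(beta.ppf(a, hits, reps - hits + 1))
    hi = 1.0 if hits == reps else float(beta.ppf(1.0 - a, hits + 1, reps - hits))
    return hits / reps, (lo, hi)


def marker_count_table(result: SimResult, replicate: int = 0):
    """Pool allele counts for one replicate as a tidy DataFrame.

    Columns: marker_id, theta_to_qtl, pool, allele_P1_count,
    allele_total.  Counts are reconstructed from the pool frequencies
    and pool sizes (exact when no depth layer is applied).
    """
    import pandas as pd

    config = result.config
    ploidy = 1 if config.pop_spec.kind is PopulationKind.HAPLOID else 2
    nH = math.ceil(config.pH * config.n) * ploidy
    nL = math.ceil(config.pL * config.n) * ploidy
    if config.depth is not None:
        nH = nL = config.depth
    thetas = [0.0] + list(config.thetas)
    rows = []
    for j, th in enumerate(thetas):
        marker = "QTL" if j == 0 else f"M{j}"
        for pool_name, freq, total in (
            ("H", result.freq_H[replicate, j], nH),
            ("L", result.freq_L[replicate, j], nL),
        ):
            rows.append(
                {
                    "marker_id": marker,
                    "theta_to_qtl": th,
                    "pool": pool_name,
                    "allele_P1_count": int(round(freq * total)),
                    "allele_total": total,
                }
            )
    return pd.DataFrame(rows)
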