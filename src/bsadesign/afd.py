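"""Expected allele-frequency difference (AFD) between trait pools and
the power of QTL detection.

The test statistic of pooled-sequencing QTL mapping considered here is
the difference in P1-allele frequency between the high-trait (H) and
low-trait (L) pools.  Its expectation follows from integrating the
genotype-class tails above/below the pool cut points; its sampling
variance from binomial sampling of pool allele counts (2**t alleles per
pooled individual).  Sequencing-depth noise is deliberately excluded:
block-regression smoothing removes resampling error, so pool size is
the binding source of variation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import norm

from .genetic_model import (
    PoolSpec,
    PopulationSpec,
    QTLEffectModel,
    solve_cut_points,
)

# Genome-wise 5% threshold constants u_{alpha/2} calibrated for a
# yeast-like haploid genome and rice F2/F3/F4 populations.
DEFAULT_U = {"H": 3.93, "DH": 3.93, "RIL": 3.93, "F2": 3.65, "F3": 3.74, "F4": 3.78}


@dataclass(frozen=True)
class DesignPoint:
    """A complete BSA-seq design: population, pools, QTL model, size, threshold.

    ``u`` is the two-tailed standard-normal percentile constant defining
    the AFD significance threshold; it encodes the genome-wise multiple
    testing correction and is supplied, not computed.
    """

    pop: PopulationSpec
    pool: PoolSpec
    effect: QTLEffectModel
    n: int
    u: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"population size must be >= 2, got {self.n}")
        if self.u <= 0:
            raise ValueError(f"threshold constant u must be > 0, got {self.u}")

    @classmethod
    def make(
        cls,
        pop: str | PopulationSpec,
        h2: float,
        n: int,
        p: float = 0.25,
        gamma: float = 1.0,
        r_d: float = 0.0,
        u: float | None = None,
    ) -> "DesignPoint":
        """Build a design from user-facing parameters.

        ``u`` defaults to the shipped genome-wise constant for the
        population type when available, else 3.65.
        """
        if isinstance(pop, str):
            pop = PopulationSpec.make(pop)
        if u is None:
            u = DEFAULT_U.get(pop.label, 3.65)
        effect = QTLEffectModel.from_heritability(h2, r_d, pop.b)
        return cls(pop=pop, pool=PoolSpec(p=p, gamma=gamma), effect=effect, n=n, u=u)


@dataclass(frozen=True)
class AFDStats:
    """Expected AFD moments and significance thresholds for a design."""

    mu_fH: float
    mu_fL: float
    mu_delta_f: float
    sigma_delta_f: float
    sigma_0: float
    T_plus: float
    T_minus: float
    n: int
    u: float


def expected_pool_afs(
    cut_points: tuple[float, float],
    effect: QTLEffectModel,
    pop: PopulationSpec,
    pool: PoolSpec,
) -> tuple[float, float]:
    """Expected P1-allele frequencies (mu_fH, mu_fL) in the two pools.

    The P1 homozygote class sits at -a0, so with a0 > 0 the H pool is
    depleted of the P1 allele (mu_fH < 1/2).  The same expression covers
    haploid populations, where the heterozygote weight 1-2b vanishes.
    """
    xH, xL = cut_points
    a0, d0, b = effect.a0, effect.d0, pop.b
    mu_fH = (
        1.0 - 2.0 * b * norm.cdf(xH + a0) - (1.0 - 2.0 * b) * norm.cdf(xH - d0)
    ) / (2.0 * pool.pH)
    mu_fL = (
        2.0 * b * norm.cdf(xL + a0) + (1.0 - 2.0 * b) * norm.cdf(xL - d0)
    ) / (2.0 * pool.pL)
    return float(mu_fH), float(mu_fL)


def afd_variance(
    mu_fH: float, mu_fL: float, p: float, gamma: float, n: int, t: int
) -> float:
    """Sampling variance of the AFD between pools.

    Binomial variance of each pool's allele frequency with pool allele
    counts 2**t * pH * n and 2**t * pL * n:

        sigma^2 = (1+gamma) / (2**(t+1) * p * gamma * n)
                  * [mu_fH*(1-mu_fH) + gamma*mu_fL*(1-mu_fL)]
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    return (
        (1.0 + gamma)
        / (2.0 ** (t + 1) * p * gamma * n)
        * (mu_fH * (1.0 - mu_fH) + gamma * mu_fL * (1.0 - mu_fL))
    )


def null_sd_and_threshold(
    p: float, gamma: float, n: int, t: int, u: float
) -> tuple[float, float, float]:
    """Null SD of the AFD and the two-tailed thresholds T_+/- = +/- u*sigma_0.

    Under no QTL both pool frequencies are 1/2, so the variance reduces
    to (1+gamma)**2 / (2**(t+3) * p * gamma * n).  Symmetric under
    gamma -> 1/gamma (swapping pool labels).
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    if u <= 0:
        raise ValueError("u must be > 0")
    sigma_0 = (1.0 + gamma) / math.sqrt(2.0 ** (t + 3) * p * gamma * n)
    return sigma_0, u * sigma_0, -u * sigma_0


def afd_stats(design: DesignPoint) -> AFDStats:
    """All expected-AFD quantities for a design in one pass."""
    cuts = solve_cut_points(design.pool, design.effect, design.pop)
    mu_fH, mu_fL = expected_pool_afs(cuts, design.effect, design.pop, design.pool)
    mu_delta_f = mu_fH - mu_fL
    var = afd_variance(
        mu_fH, mu_fL, design.pool.p, design.pool.gamma, design.n, design.pop.t
    )
    sigma_0, T_plus, T_minus = null_sd_and_threshold(
        design.pool.p, design.pool.gamma, design.n, design.pop.t, design.u
    )
    return AFDStats(
        mu_fH=mu_fH,
        mu_fL=mu_fL,
        mu_delta_f=mu_delta_f,
        sigma_delta_f=math.sqrt(var),
        sigma_0=sigma_0,
        T_plus=T_plus,
        T_minus=T_minus,
        n=design.n,
        u=design.u,
    )


@dataclass(frozen=True)
class PowerResult:
    """Two-tailed detection power and its two tail components."""

    power: float
    upper_tail: float
    lower_tail: float
    stats: AFDStats


def detection_power(design: DesignPoint) -> PowerResult:
    """Probability that the sampled AFD exceeds the significance threshold.

    power = 1 - Phi((T_+ - mu)/sigma) + Phi((T_- - mu)/sigma)

    with mu, sigma the expected AFD and its SD.  Under the null QTL this
    is exactly the nominal two-tailed level alpha = 2*(1 - Phi(u)); the
    negligible wrong-tail term is kept for exactness.
    """
    s = afd_stats(design)
    upper = float(norm.sf((s.T_plus - s.mu_delta_f) / s.sigma_delta_f))
    lower = float(norm.cdf((s.T_minus - s.mu_delta_f) / s.sigma_delta_f))
    power = min(max(upper + lower, 0.0), 1.0)
    return PowerResult(power=power, upper_tail=upper, lower_tail=lower, stats=s)


def alpha_from_u(u: float) -> float:
    """Nominal two-tailed significance level alpha = 2*(1 - Phi(u))."""
    if u <= 0:
        raise ValueError("u must be > 0")
    return float(2.0 * norm.sf(u))


def u_from_alpha(alpha: float) -> float:
    """Percentile constant u = Phi^-1(1 - alpha/2); inverse of alpha_from_u."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    return float(norm.isf(alpha / 2.0))
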