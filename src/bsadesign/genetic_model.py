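"""Single-QTL trait mixture model and truncation-selection cut points.

A biparental mapping population segregating for one QTL (alleles ``Q``
from parent P1, ``q`` from parent P2) has phenotypes distributed as a
mixture of normals, one component per QTL genotype class.  After
standardizing by the background standard deviation, the density is

    f(x) = b*phi(x + a0) + (1 - 2b)*phi(x - d0) + b*phi(x - a0)

where ``b`` is the frequency of each homozygote class, ``a0`` and ``d0``
are the standardized additive and dominance effects, and ``phi`` is the
standard-normal density.  The QQ class (carrying the P1 allele) sits at
``-a0`` by convention, so a positive additive effect pushes the P1
allele into the low-trait tail.

For an F_k population produced by selfing, heterozygosity halves each
generation: b = (1 - 1/2**(k-1)) / 2, so F2 has b = 1/4 and b -> 1/2 as
k -> infinity.  Permanent populations (haploid segregants, doubled
haploids, recombinant inbred lines) have only the two homozygous or
hemizygous classes, b = 1/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

from scipy.optimize import brentq
from scipy.stats import norm


class PopulationKind(str, Enum):
    """Population types supported by the design calculations."""

    F_SELFING = "Fk_selfing"  # F_k produced from F1 by repeated selfing
    HAPLOID = "H"             # haploid segregants (e.g. yeast)
    DH = "DH"                 # doubled haploids
    RIL = "RIL"               # recombinant inbred lines by selfing

    @classmethod
    def parse(cls, text: str) -> tuple["PopulationKind", int | None]:
        """Parse a user-facing label like ``F2``, ``F3``, ``H``, ``DH``, ``RIL``.

        Returns the kind and, for selfing populations, the generation k.
        """
        s = text.strip().upper()
        if s in ("H", "HAPLOID"):
            return cls.HAPLOID, None
        if s == "DH":
            return cls.DH, None
        if s == "RIL":
            return cls.RIL, None
        if s.startswith("F") and s[1:].isdigit():
            return cls.F_SELFING, int(s[1:])
        raise ValueError(f"unrecognized population type: {text!r}")


PERMANENT_KINDS = frozenset(
    {PopulationKind.HAPLOID, PopulationKind.DH, PopulationKind.RIL}
)


def population_b_t(kind: PopulationKind | str, k: int | None = None) -> tuple[float, int]:
    """Homozygote-class frequency ``b`` and ploidy exponent ``t`` for a population.

    ``t`` enters the allele-count denominators of the pool-frequency
    variance: each pooled individual contributes ``2**t`` sampled alleles
    (1 for permanent/haploid-equivalent populations, 2 for segregating
    F_k individuals).

    Parameters
    ----------
    kind
        Population type, or a label such as ``"F3"`` which carries its
        own generation number.
    k
        Selfing generation (>= 2); required for ``F_SELFING``.
    """
    if isinstance(kind, str) and not isinstance(kind, PopulationKind):
        parsed_kind, parsed_k = PopulationKind.parse(kind)
        kind = parsed_kind
        if parsed_k is not None:
            k = parsed_k
    if kind in PERMANENT_KINDS:
        return 0.5, 0
    if kind is PopulationKind.F_SELFING:
        if k is None:
            raise ValueError("selfing population requires a generation number k")
        if k < 2:
            raise ValueError(f"selfing generation must be >= 2, got k={k}")
        return (1.0 - 0.5 ** (k - 1)) / 2.0, 1
    raise ValueError(f"unknown population kind: {kind!r}")


@dataclass(frozen=True)
class PopulationSpec:
    """Population type plus its derived mixture parameters.

    Attributes
    ----------
    kind : PopulationKind
    k : int or None
        Selfing generation for F_k populations; None for permanent ones.
    b : float
        Frequency of each homozygote class; heterozygote frequency is 1-2b.
    t : int
        Ploidy exponent: 0 for permanent populations, 1 for F_k.
    """

    kind: PopulationKind
    k: int | None
    b: float
    t: int

    @classmethod
    def make(cls, kind: PopulationKind | str, k: int | None = None) -> "PopulationSpec":
        if isinstance(kind, str) and not isinstance(kind, PopulationKind):
            parsed_kind, parsed_k = PopulationKind.parse(kind)
            kind = parsed_kind
            if parsed_k is not None:
                k = parsed_k
        b, t = population_b_t(kind, k)
        if kind in PERMANENT_KINDS:
            k = None
        return cls(kind=kind, k=k, b=b, t=t)

    @property
    def label(self) -> str:
        if self.kind is PopulationKind.F_SELFING:
            return f"F{self.k}"
        return self.kind.value


def heritability_from_effects(a0: float, d0: float, b: float) -> tuple[float, float, float]:
    """Decompose standardized QTL effects into heritabilities.

    Returns ``(h2_a, h2_d, h2)`` where

        h2_a = 2*b*a0**2 / (1 + 2*b*a0**2 + 2*b*(1-2*b)*d0**2)
        h2_d = 2*b*(1-2*b)*d0**2 / (same denominator)

    and h2 = h2_a + h2_d is the fraction of phenotypic variance
    explained by the QTL.
    """
    va = 2.0 * b * a0 * a0
    vd = 2.0 * b * (1.0 - 2.0 * b) * d0 * d0
    denom = 1.0 + va + vd
    return va / denom, vd / denom, (va + vd) / denom


def effects_from_heritability(h2: float, r_d: float, b: float) -> tuple[float, float]:
    """Invert the heritability decomposition given the degree of dominance.

    With d0 = r_d * a0, the genetic variance 2*b*a0**2*(1 + (1-2b)*r_d**2)
    must equal h2/(1-h2) in residual-variance units, which pins a0 (taken
    >= 0 by orientation convention).

    Raises
    ------
    ValueError
        If ``h2`` is not in [0, 1).
    """
    if not 0.0 <= h2 < 1.0:
        raise ValueError(f"heritability must be in [0, 1), got {h2}")
    g = h2 / (1.0 - h2)
    a0 = math.sqrt(g / (2.0 * b * (1.0 + (1.0 - 2.0 * b) * r_d * r_d)))
    return a0, r_d * a0


@dataclass(frozen=True)
class QTLEffectModel:
    """Standardized effects of a single QTL and their heritability split.

    All quantities are on the scale x = (y - mu) / sigma_e, so ``a0`` and
    ``d0`` are the additive and dominance effects in units of the
    background standard deviation.  ``r_d = d0/a0`` is the degree of
    dominance (0 = purely additive, 1 = complete dominance).
    """

    a0: float
    d0: float
    r_d: float
    h2_a: float
    h2_d: float
    h2: float

    @classmethod
    def from_effects(cls, a0: float, d0: float, b: float) -> "QTLEffectModel":
        if a0 < 0:
            raise ValueError("a0 must be >= 0 (canonical orientation)")
        h2_a, h2_d, h2 = heritability_from_effects(a0, d0, b)
        r_d = d0 / a0 if a0 > 0 else 0.0
        return cls(a0=a0, d0=d0, r_d=r_d, h2_a=h2_a, h2_d=h2_d, h2=h2)

    @classmethod
    def from_heritability(cls, h2: float, r_d: float, b: float) -> "QTLEffectModel":
        a0, d0 = effects_from_heritability(h2, r_d, b)
        h2_a, h2_d, h2_tot = heritability_from_effects(a0, d0, b)
        return cls(a0=a0, d0=d0, r_d=r_d, h2_a=h2_a, h2_d=h2_d, h2=h2_tot)


def mixture_pdf(x, a0: float, d0: float, b: float):
    """Density of the standardized trait mixture."""
    return (
        b * norm.pdf(x + a0)
        + (1.0 - 2.0 * b) * norm.pdf(x - d0)
        + b * norm.pdf(x - a0)
    )


def mixture_cdf(x, a0: float, d0: float, b: float):
    """CDF of the standardized trait mixture.

    Monotone nondecreasing in x with limits 0 and 1; reduces to the
    standard-normal CDF under the null QTL (a0 = d0 = 0).
    """
    return (
        b * norm.cdf(x + a0)
        + (1.0 - 2.0 * b) * norm.cdf(x - d0)
        + b * norm.cdf(x - a0)
    )


@dataclass(frozen=True)
class PoolSpec:
    """Sizes of the high- and low-trait pools as population proportions.

    ``p`` is the mean pool proportion (p_H + p_L)/2 and ``gamma`` the
    ratio p_H/p_L, so p_H = 2*p*gamma/(1+gamma) and p_L = 2*p/(1+gamma).
    """

    p: float
    gamma: float

    def __post_init__(self):
        if not 0.0 < self.p <= 0.5:
            raise ValueError(f"pool proportion p must be in (0, 0.5], got {self.p}")
        if self.gamma <= 0:
            raise ValueError(f"pool ratio gamma must be > 0, got {self.gamma}")
        if self.pH + self.pL > 1.0 + 1e-12:
            raise ValueError("pool proportions exceed the whole population")

    @property
    def pH(self) -> float:
        return 2.0 * self.p * self.gamma / (1.0 + self.gamma)

    @property
    def pL(self) -> float:
        return 2.0 * self.p / (1.0 + self.gamma)


_CUT_BRACKET = 12.0


def solve_cut_points(
    pool: PoolSpec, effect: QTLEffectModel, pop: PopulationSpec
) -> tuple[float, float]:
    """Phenotype cut points (xH, xL) selecting the top pH and bottom pL.

    xH satisfies 1 - F(xH) = pH and xL satisfies F(xL) = pL, where F is
    the trait mixture CDF.  The CDF is strictly monotone so each root is
    unique; a bracketing solver on [-12, 12] is used.
    """
    a0, d0, b = effect.a0, effect.d0, pop.b

    def cdf(x: float) -> float:
        return float(mixture_cdf(x, a0, d0, b))

    xH = brentq(lambda x: cdf(x) - (1.0 - pool.pH), -_CUT_BRACKET, _CUT_BRACKET,
                xtol=1e-10)
    xL = brentq(lambda x: cdf(x) - pool.pL, -_CUT_BRACKET, _CUT_BRACKET,
                xtol=1e-10)
    return float(xH), float(xL)
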