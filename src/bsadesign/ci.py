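"""Expected width of the 95% confidence interval of QTL position.

Around a QTL the expected AFD decays linearly in recombination rate:
mu_dfM = (1 - 2*theta) * mu_df at a locus M with recombination theta to
the QTL.  Sliding down the expected AFD peak by 1.65 sigma locates the
CI95 border at theta = 0.825 * sigma / |mu_df| on the population's
*apparent* recombination scale.  For F3/F4 (and RILs) the apparent rate
accumulates extra meioses from selfing and must be inverted back to the
single-meiosis rate before converting to centimorgans with Kosambi's
map function D = 25 * ln((1+2theta)/(1-2theta)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .afd import AFDStats, DesignPoint, afd_stats
from .genetic_model import PopulationKind

CI_BORDER_FACTOR = 0.825  # half of the 1.65-sigma drop to the CI95 border


def afd_at_linked_locus(mu_delta_f: float, theta_pop: float) -> float:
    """Expected AFD at a locus with (apparent) recombination theta to the QTL."""
    if not 0.0 <= theta_pop <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {theta_pop}")
    return (1.0 - 2.0 * theta_pop) * mu_delta_f


def apparent_recomb(theta: float, k) -> float:
    """Apparent recombination rate accumulated by generation k of selfing.

    A recombinant haplotype can arise in any meiosis between F1 and
    F_(k-1); transmission through a shrinking double-heterozygote pool
    gives the geometric series

        theta_k = theta * sum_{i=0}^{k-2} [(1 - 2*theta)/2]**i

    so theta_2 = theta and the k -> infinity (RIL) limit is the
    classical map expansion 2*theta / (1 + 2*theta).  Pass
    ``k=math.inf`` for the RIL limit.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5], got {theta}")
    if math.isinf(k):
        return 2.0 * theta / (1.0 + 2.0 * theta)
    k = int(k)
    if k < 2:
        raise ValueError(f"generation must be >= 2, got {k}")
    r = (1.0 - 2.0 * theta) / 2.0
    return theta * sum(r**i for i in range(k - 1))


def invert_apparent_recomb(theta_k_value: float, k) -> float:
    """Single-meiosis recombination rate giving apparent rate theta_k at generation k.

    apparent_recomb is strictly increasing in theta on [0, 0.5] with
    range [0, 0.5], so the root is unique; bisection to 1e-12.
    """
    if not 0.0 <= theta_k_value < 0.5:
        raise ValueError(
            f"apparent recombination must be in [0, 0.5), got {theta_k_value}"
        )
    if theta_k_value == 0.0:
        return 0.0
    if (not math.isinf(k)) and int(k) == 2:
        return theta_k_value
    if math.isinf(k):
        # closed-form inverse of 2x/(1+2x)
        return theta_k_value / (2.0 - 2.0 * theta_k_value)
    return float(
        brentq(
            lambda th: apparent_recomb(th, k) - theta_k_value,
            0.0,
            0.5 - 1e-12,
            xtol=1e-12,
        )
    )


def kosambi_distance(theta: float) -> float:
    """Kosambi map distance in cM: D = 25 * ln((1+2theta)/(1-2theta))."""
    if not 0.0 <= theta < 0.5:
        raise ValueError(f"recombination rate must be in [0, 0.5), got {theta}")
    return 25.0 * math.log((1.0 + 2.0 * theta) / (1.0 - 2.0 * theta))


def kosambi_recomb(d_cM: float) -> float:
    """Inverse Kosambi: recombination rate at map distance d_cM."""
    if d_cM < 0:
        raise ValueError("distance must be >= 0")
    return 0.5 * math.tanh(d_cM / 50.0)


@dataclass(frozen=True)
class CIResult:
    """Expected CI95 of QTL position for a design.

    ``theta_apparent`` is the border recombination on the population's
    accumulated-meiosis scale; ``theta_real`` the single-meiosis rate;
    ``width_cM = 2 * D_cM`` spans both borders.  ``finite`` is False
    when the expected peak is too shallow to bound the interval
    (border rate >= 0.5) or the QTL is null.
    """

    theta_apparent: float
    theta_real: float
    D_cM: float
    width_cM: float
    finite: bool
    stats: AFDStats


def ci95_width(design: DesignPoint) -> CIResult:
    """Expected CI95 width in Kosambi cM for a design."""
    s = afd_stats(design)
    if s.mu_delta_f == 0.0:
        return CIResult(
            theta_apparent=math.inf,
            theta_real=math.inf,
            D_cM=math.inf,
            width_cM=math.inf,
            finite=False,
            stats=s,
        )
    theta_app = CI_BORDER_FACTOR * s.sigma_delta_f / abs(s.mu_delta_f)
    if theta_app >= 0.5:
        return CIResult(
            theta_apparent=theta_app,
            theta_real=math.inf,
            D_cM=math.inf,
            width_cM=math.inf,
            finite=False,
            stats=s,
        )
    pop = design.pop
    if pop.kind is PopulationKind.F_SELFING and pop.k is not None and pop.k > 2:
        theta_real = invert_apparent_recomb(theta_app, pop.k)
    elif pop.kind is PopulationKind.RIL:
        # extension beyond the F2-F4/H/DH cases: RIL apparent scale k=inf
        theta_real = invert_apparent_recomb(theta_app, math.inf)
    else:
        theta_real = theta_app
    D = kosambi_distance(theta_real)
    return CIResult(
        theta_apparent=theta_app,
        theta_real=theta_real,
        D_cM=D,
        width_cM=2.0 * D,
        finite=True,
        stats=s,
    )
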