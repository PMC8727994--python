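"""Design-space queries: minimum population size, best pool proportion,
and sensitivity curves of power / CI95 width over any single parameter.

All functions here are deterministic wrappers around the closed-form
power and CI engines; nothing is stochastic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .afd import DesignPoint, detection_power
from .ci import ci95_width
from .genetic_model import PoolSpec, PopulationKind, PopulationSpec, QTLEffectModel

N_MAX_DEFAULT = 10_000_000

DEFAULT_P_GRID = np.round(np.arange(0.01, 0.5 + 1e-9, 0.005), 10)
DEFAULT_GAMMA_GRID = (1.0, 1.5, 2.0, 3.0, 4.0, 8.0)


def _with_n(design: DesignPoint, n: int) -> DesignPoint:
    return replace(design, n=int(n))


@dataclass(frozen=True)
class MinNResult:
    """Smallest population size reaching a target power (or the verdict
    that the target is unreachable below ``n_max``)."""

    n_min: int | None
    target_power: float
    power_at_n_min: float | None
    attainable: bool
    power_at_n_max: float | None = None


def min_population_size(
    design: DesignPoint, target_power: float, n_max: int = N_MAX_DEFAULT
) -> MinNResult:
    """Bisect the monotone power-in-n curve for the minimum n.

    Power is nondecreasing in n (the expected AFD is n-free while the
    threshold and the AFD standard deviation both shrink as 1/sqrt(n)),
    so plain integer bisection applies.
    """
    if not 0.0 < target_power < 1.0:
        raise ValueError(f"target power must be in (0, 1), got {target_power}")
    lo, hi = 2, int(n_max)
    p_hi = detection_power(_with_n(design, hi)).power
    if p_hi < target_power:
        return MinNResult(
            n_min=None,
            target_power=target_power,
            power_at_n_min=None,
            attainable=False,
            power_at_n_max=p_hi,
        )
    if detection_power(_with_n(design, lo)).power >= target_power:
        return MinNResult(
            n_min=lo,
            target_power=target_power,
            power_at_n_min=detection_power(_with_n(design, lo)).power,
            attainable=True,
        )
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if detection_power(_with_n(design, mid)).power >= target_power:
            hi = mid
        else:
            lo = mid
    return MinNResult(
        n_min=hi,
        target_power=target_power,
        power_at_n_min=detection_power(_with_n(design, hi)).power,
        attainable=True,
    )


def _design_at_p(design: DesignPoint, p: float) -> DesignPoint:
    return replace(design, pool=PoolSpec(p=float(p), gamma=design.pool.gamma))


def optimal_pool_proportion(
    design: DesignPoint,
    grid: Sequence[float] | None = None,
    criterion: str = "ci_width",
) -> tuple[float, pd.DataFrame]:
    """Best mean pool proportion over a grid, by power or CI95 width.

    Ties (within 1e-12) are broken toward p = 0.25, the generally
    recommended proportion.  Returns the optimum and the full table.
    """
    if criterion not in ("power", "ci_width"):
        raise ValueError(f"criterion must be 'power' or 'ci_width', got {criterion!r}")
    grid = DEFAULT_P_GRID if grid is None else np.asarray(list(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("pool-proportion grid is empty")
    table = scan_curve("p", grid, design)
    if criterion == "power":
        score = table["power"].to_numpy()
        best = np.max(score)
    else:
        score = -np.where(table["finite_ci"], table["ci95_cM"], np.inf)
        best = np.max(score)
    tied = np.abs(score - best) <= 1e-12
    candidates = np.asarray(grid)[tied]
    p_star = float(candidates[np.argmin(np.abs(candidates - 0.25))])
    return p_star, table


_SCAN_VARIABLES = ("n", "p", "gamma", "r_d", "k")


def scan_curve(variable: str, grid: Sequence[float], design: DesignPoint) -> pd.DataFrame:
    """Power and CI95 width along a grid of one design parameter.

    ``variable`` is one of n, p, gamma, r_d, k (selfing generation).
    For r_d the QTL heritability is held fixed and the effects re-solved;
    for k the population structure (b, t) is rebuilt per generation.
    Returns a DataFrame with columns variable, value, power, ci95_cM,
    finite_ci.
    """
    if variable not in _SCAN_VARIABLES:
        raise ValueError(f"variable must be one of {_SCAN_VARIABLES}, got {variable!r}")
    grid = list(grid)
    if len(grid) == 0:
        raise ValueError("scan grid is empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("scan grid must be strictly increasing")

    rows = []
    for value in grid:
        d = _design_for(variable, value, design)
        pw = detection_power(d).power
        ci = ci95_width(d)
        rows.append(
            {
                "variable": variable,
                "value": value,
                "power": pw,
                "ci95_cM": ci.width_cM if ci.finite else math.inf,
                "finite_ci": ci.finite,
            }
        )
    return pd.DataFrame(rows)


def _design_for(variable: str, value, design: DesignPoint) -> DesignPoint:
    if variable == "n":
        n = int(value)
        if n < 2:
            raise ValueError(f"population size must be >= 2, got {value}")
        return _with_n(design, n)
    if variable == "p":
        return _design_at_p(design, value)
    if variable == "gamma":
        if value <= 0:
            raise ValueError(f"gamma must be > 0, got {value}")
        return replace(design, pool=PoolSpec(p=design.pool.p, gamma=float(value)))
    if variable == "r_d":
        effect = QTLEffectModel.from_heritability(
            design.effect.h2, float(value), design.pop.b
        )
        return replace(design, effect=effect)
    if variable == "k":
        pop = PopulationSpec.make(PopulationKind.F_SELFING, int(value))
        effect = QTLEffectModel.from_heritability(
            design.effect.h2, design.effect.r_d, pop.b
        )
        return replace(design, pop=pop, effect=effect)
    raise AssertionError(variable)


def curve_to_tsv(table: pd.DataFrame, path) -> None:
    """Write a scan table as TSV with a header row."""
    table.to_csv(path, sep="\t", index=False)


def curve_to_json(table: pd.DataFrame) -> list[dict]:
    """Scan table as a list of plain records (JSON-ready)."""
    return table.to_dict(orient="records")
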