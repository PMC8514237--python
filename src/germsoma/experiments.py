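"""Canonical study protocols: the screens behind the headline results.

These functions fix the study conditions -- profile sampling, cost grids,
maturity-size ranges and Monte-Carlo effort -- used by the analysis scripts
and the acceptance checks, so every entry point reproduces the same
experiment from a single seed.

Scales are desk-sized: the cost axes are half-decade log grids spanning
0.03--10, strategy space is screened at simplex step 0.1, and growth rates
use 300 trajectories per strategy with champion re-evaluation (see
:mod:`germsoma.optimize`).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .development import CostMode
from .optimize import DEFAULT_REFINE, RefineConfig
from .profiles import ProfileRanges, sample_profiles
from .screens import ScreenResult, cost_plane_screen, size_cost_screen
from .strategies import StrategyClass

__all__ = [
    "COST_GRID",
    "ASYM_COST_GRID",
    "RISK_GRID",
    "study_profiles",
    "equal_cost_size_sweep",
    "asymmetric_cost_size_sweep",
    "delay_cost_plane",
    "risk_cost_plane",
    "max_irreversible_fraction_at_size",
]

#: half-decade log grid of differentiation costs spanning 0.03 to 10
COST_GRID = (0.03, 0.1, 0.3, 1.0, 3.0, 10.0)

#: cost grid for the 2:1-cost sweep: spans 0.03--10 with roughly
#: quarter-decade resolution between 1 and 3.3, where the class decision is
#: closest (the 32-cell detections live in a narrow band of costs there)
ASYM_COST_GRID = (0.03, 0.1, 0.3, 1.0, 1.5, 2.2, 3.3, 10.0)

#: death risks for the risky-differentiation variant
RISK_GRID = (0.0, 0.1, 0.25, 0.5)


def study_profiles(seed: int, count: int, ranges: ProfileRanges = ProfileRanges()):
    """The random composition effect profiles of a study run."""
    rng = np.random.default_rng([seed, 1])
    return sample_profiles(rng, count, ranges)


def equal_cost_size_sweep(
    seed: int,
    *,
    n_profiles: int = 100,
    n_profiles_boost: int = 300,
    n_values: Sequence[int] = tuple(range(2, 9)),
    boost_n: Sequence[int] = (6,),
    costs: Sequence[float] = COST_GRID,
    M: int = 300,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    progress: bool = False,
) -> ScreenResult:
    """Maturity-size sweep at equal differentiation costs c = c_sg = c_gs.

    Screens maturity sizes 4--256 cells; the smallest size with any
    irreversible optimum is the headline threshold.  Irreversible optima
    are rare events even where they exist (a few percent of profiles), so
    the threshold size(s) in ``boost_n`` screen ``n_profiles_boost``
    profiles for detection power, while the other sizes use the first
    ``n_profiles`` of the same sample.

    Class decisions use plain argmax over the champion re-evaluation
    ladder (``tie_tol=0``): the borderline optima near the threshold have
    margins far below any workable tie tolerance, so a precedence rule
    would suppress them by construction.
    """
    profiles = study_profiles(seed, max(n_profiles, n_profiles_boost))
    parts = []
    for n in n_values:
        count = n_profiles_boost if n in boost_n else n_profiles
        parts.append(
            size_cost_screen(
                costs, [int(n)], profiles[:count], cost_ratio=1.0,
                M=M, seed=seed + 101, tie_tol=0.0, refine=refine,
                progress=progress,
            )
        )
    records = pd.concat([p.records for p in parts], ignore_index=True)
    cells = pd.concat([p.cells for p in parts], ignore_index=True)
    config = dict(parts[-1].config)
    config.update(
        {
            "n_values": [int(n) for n in n_values],
            "n_profiles": n_profiles,
            "n_profiles_boost": n_profiles_boost,
            "boost_n": [int(n) for n in boost_n],
        }
    )
    return ScreenResult(records=records, cells=cells, config=config)


def asymmetric_cost_size_sweep(
    seed: int,
    *,
    n_profiles: int = 300,
    n_profiles_boost: int = 450,
    n_values: Sequence[int] = tuple(range(3, 7)),
    boost_n: Sequence[int] = (5,),
    costs: Sequence[float] = ASYM_COST_GRID,
    M: int = 300,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    progress: bool = False,
) -> ScreenResult:
    """Maturity-size sweep with soma-to-germ cost twice the germ-to-soma
    cost (c_sg = 2 c_gs), screening maturity sizes 8--64 cells.

    Plain-argmax class decisions (``tie_tol=0``) and detection-power
    boosting at the 32-cell threshold size, as in
    :func:`equal_cost_size_sweep` (there the boosted size is 64 cells).
    """
    profiles = study_profiles(seed, max(n_profiles, n_profiles_boost))
    parts = []
    for n in n_values:
        count = n_profiles_boost if n in boost_n else n_profiles
        parts.append(
            size_cost_screen(
                costs, [int(n)], profiles[:count], cost_ratio=2.0,
                M=M, seed=seed + 202, tie_tol=0.0, refine=refine,
                progress=progress,
            )
        )
    records = pd.concat([p.records for p in parts], ignore_index=True)
    cells = pd.concat([p.cells for p in parts], ignore_index=True)
    config = dict(parts[-1].config)
    config.update(
        {
            "n_values": [int(n) for n in n_values],
            "n_profiles": n_profiles,
            "n_profiles_boost": n_profiles_boost,
            "boost_n": [int(n) for n in boost_n],
        }
    )
    return ScreenResult(records=records, cells=cells, config=config)


def delay_cost_plane(
    seed: int,
    *,
    n: int = 6,
    n_profiles: int = 50,
    axis: Sequence[float] = (0.0, 0.3, 2.0, 8.0),
    M: int = 300,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    progress: bool = False,
) -> ScreenResult:
    """Class fractions across the (c_sg, c_gs) delay-cost plane."""
    profiles = study_profiles(seed, n_profiles)
    pairs = [(sg, gs) for sg in axis for gs in axis]
    return cost_plane_screen(
        pairs, profiles, n, mode=CostMode.DELAY, M=M, seed=seed + 303,
        refine=refine, progress=progress,
    )


def risk_cost_plane(
    seed: int,
    *,
    n: int = 6,
    n_profiles: int = 50,
    axis: Sequence[float] = RISK_GRID,
    M: int = 300,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    progress: bool = False,
) -> ScreenResult:
    """Class fractions across the (delta_sg, delta_gs) death-risk plane."""
    profiles = study_profiles(seed, n_profiles)
    pairs = [(sg, gs) for sg in axis for gs in axis]
    return cost_plane_screen(
        pairs, profiles, n, mode=CostMode.RISK, M=M, seed=seed + 303,
        refine=refine, progress=progress,
    )


def max_irreversible_fraction_at_size(result: ScreenResult, n: int) -> tuple:
    """Largest fraction of profiles with an irreversible optimum at maturity
    ``2**n``, maximised over the scanned cost values.

    Returns ``(fraction, cost_gs_at_max, n_profiles)``.
    """
    rec = result.records
    sub = rec[rec["n"] == n]
    if sub.empty:
        raise ValueError(f"sweep does not include maturity exponent n={n}")
    best_frac, best_cost, count = 0.0, float(sub["cost_gs"].iloc[0]), 0
    for cost, group in sub.groupby("cost_gs"):
        frac = float(
            (group["best_class"] == StrategyClass.IRREVERSIBLE.value).mean()
        )
        if frac > best_frac:
            best_frac, best_cost = frac, float(cost)
        count = len(group)
    return best_frac, best_cost, count
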