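"""Population-level screens over random composition effect profiles.

Each screen asks, for many randomly sampled composition effect profiles and
a grid of differentiation costs (or risks), which class of developmental
strategy is growth-rate optimal, and aggregates class fractions per cost
cell.  These reproduce the qualitative experiments of the model:

* cost-plane screens: class fractions across the ``(c_sg, c_gs)`` or
  ``(delta_sg, delta_gs)`` plane;
* size--cost sweeps: the fraction of profiles promoting irreversible
  differentiation as a function of maturity size ``2**n`` and cost, and the
  smallest maturity size at which irreversible optima appear;
* differentiation-rate summaries: median and 90% band (5th--95th
  percentiles across profiles) of the cumulative differentiation rate of
  optimal strategies, per class;
* promoting-profile summaries: how the profiles whose optimum is
  irreversible differ from the full profile set.

All screens reuse one trajectory sample per maturity size across profiles
and cost values (common random numbers) and are fully deterministic given
the master seed and configuration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .development import CompositionTiming, CostMode, CostModel
from .optimize import DEFAULT_REFINE, GridOptimizer, RefineConfig
from .profiles import CompositionProfile
from .strategies import StrategyClass

__all__ = [
    "ScreenResult",
    "cost_plane_screen",
    "size_cost_screen",
    "minimal_irreversible_size",
    "irreversible_fraction_by",
    "differentiation_rate_summary",
    "promoting_profile_summary",
]

CLASS_COLUMNS = [cls.value for cls in StrategyClass]


@dataclass
class ScreenResult:
    """Per-profile optimization records plus per-cell class fractions."""

    records: pd.DataFrame
    cells: pd.DataFrame
    config: dict


def _make_costs(mode: CostMode, cost_sg: float, cost_gs: float) -> CostModel:
    if mode is CostMode.DELAY:
        return CostModel.delay(cgs=cost_gs, csg=cost_sg)
    return CostModel.risk(dgs=cost_gs, dsg=cost_sg)


def _record(result, profile_index, cost_sg, cost_gs) -> dict:
    strat = result.best_strategy
    rec = {
        "profile_index": profile_index,
        "x0": result.profile.x0,
        "x1": result.profile.x1,
        "b": result.profile.b,
        "alpha": result.profile.alpha,
        "cost_sg": cost_sg,
        "cost_gs": cost_gs,
        "n": result.n,
        "maturity_size": 2**result.n,
        "best_class": result.best_class.value,
        "best_lambda": result.best_lambda,
        "diff_rate": result.best_differentiation_rate,
        "ggg": strat.ggg,
        "ggs": strat.ggs,
        "gss": strat.gss,
        "sgg": strat.sgg,
        "sgs": strat.sgs,
        "sss": strat.sss,
    }
    for cls in StrategyClass:
        rec[f"lambda_{cls.value}"] = result.lambda_by_class[cls]
    return rec


def class_fractions(records: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Counts and fractions of optimal-strategy classes per cell.

    Fractions in each cell sum to one exactly (they are ratios of integer
    counts over the same denominator).
    """
    rows = []
    for key, group in records.groupby(list(by), sort=True):
        if not isinstance(key, tuple):
            key = (key,)
        total = len(group)
        counts = group["best_class"].value_counts()
        row = dict(zip(by, key))
        row["n_profiles"] = total
        for cls in CLASS_COLUMNS:
            c = int(counts.get(cls, 0))
            row[f"count_{cls}"] = c
            row[f"frac_{cls}"] = c / total
        rows.append(row)
    return pd.DataFrame(rows)


def _run_screen(
    cost_pairs,
    profiles,
    n_values,
    *,
    mode: CostMode,
    grid_step: float,
    M: int,
    seed: int,
    tie_tol: float,
    refine: Optional[RefineConfig],
    timing: CompositionTiming = CompositionTiming.PRE,
    progress: bool = False,
) -> pd.DataFrame:
    records = []
    for n in n_values:
        opt = GridOptimizer(
            n, grid_step=grid_step, M=M, seed=seed, tie_tol=tie_tol,
            refine=refine, timing=timing,
        )
        for ip, profile in enumerate(profiles):
            lam0 = None
            for cost_sg, cost_gs in cost_pairs:
                costs = _make_costs(mode, cost_sg, cost_gs)
                result, lam0 = opt.optimize(
                    profile, costs, lam0=lam0, return_lambdas=True
                )
                records.append(_record(result, ip, cost_sg, cost_gs))
            if progress and (ip + 1) % 20 == 0:
                print(f"  n={n}: {ip + 1}/{len(profiles)} profiles", flush=True)
    return pd.DataFrame(records)


def cost_plane_screen(
    cost_pairs: Iterable,
    profiles: Sequence[CompositionProfile],
    n: int,
    *,
    mode: CostMode = CostMode.DELAY,
    grid_step: float = 0.1,
    M: int = 300,
    seed: int = 0,
    tie_tol: float = 1e-4,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    timing: CompositionTiming = CompositionTiming.PRE,
    progress: bool = False,
) -> ScreenResult:
    """Class fractions of optimal strategies across a cost (or risk) plane.

    ``cost_pairs`` are ``(soma-to-germ, germ-to-soma)`` cost pairs in DELAY
    mode, or the corresponding death-risk pairs in RISK mode.
    """
    cost_pairs = [(float(a), float(b)) for a, b in cost_pairs]
    if not cost_pairs or not len(profiles):
        raise ValueError("need at least one cost pair and one profile")
    records = _run_screen(
        cost_pairs,
        profiles,
        [n],
        mode=mode,
        grid_step=grid_step,
        M=M,
        seed=seed,
        tie_tol=tie_tol,
        refine=refine,
        timing=timing,
        progress=progress,
    )
    cells = class_fractions(records, by=["cost_sg", "cost_gs"])
    config = {
        "screen": "cost_plane",
        "mode": mode.value,
        "n": n,
        "n_profiles": len(profiles),
        "grid_step": grid_step,
        "M": M,
        "seed": seed,
        "tie_tol": tie_tol,
        "composition_timing": timing.value,
        "cost_pairs": cost_pairs,
    }
    return ScreenResult(records=records, cells=cells, config=config)


def size_cost_screen(
    cost_gs_values: Sequence[float],
    n_values: Sequence[int],
    profiles: Sequence[CompositionProfile],
    *,
    cost_ratio: float = 1.0,
    mode: CostMode = CostMode.DELAY,
    grid_step: float = 0.1,
    M: int = 300,
    seed: int = 0,
    tie_tol: float = 1e-4,
    refine: Optional[RefineConfig] = DEFAULT_REFINE,
    timing: CompositionTiming = CompositionTiming.PRE,
    progress: bool = False,
) -> ScreenResult:
    """Sweep of maturity sizes ``2**n`` against costs with a fixed ratio
    ``c_sg = cost_ratio * c_gs``."""
    if any(int(n) < 1 for n in n_values):
        raise ValueError("maturity exponents must be >= 1")
    cost_pairs = [(cost_ratio * float(c), float(c)) for c in cost_gs_values]
    records = _run_screen(
        cost_pairs,
        profiles,
        [int(n) for n in n_values],
        mode=mode,
        grid_step=grid_step,
        M=M,
        seed=seed,
        tie_tol=tie_tol,
        refine=refine,
        timing=timing,
        progress=progress,
    )
    cells = class_fractions(records, by=["n", "cost_gs"])
    config = {
        "screen": "size_cost",
        "mode": mode.value,
        "cost_ratio": cost_ratio,
        "n_values": [int(n) for n in n_values],
        "cost_gs_values": [float(c) for c in cost_gs_values],
        "n_profiles": len(profiles),
        "grid_step": grid_step,
        "M": M,
        "seed": seed,
        "tie_tol": tie_tol,
        "composition_timing": timing.value,
    }
    return ScreenResult(records=records, cells=cells, config=config)


def irreversible_fraction_by(result: ScreenResult, by: Sequence[str]) -> pd.DataFrame:
    key = f"frac_{StrategyClass.IRREVERSIBLE.value}"
    cells = class_fractions(result.records, by=by)
    return cells[[*by, "n_profiles", key]].rename(columns={key: "frac_irreversible"})


def minimal_irreversible_size(result: ScreenResult) -> Optional[int]:
    """Smallest maturity size ``2**n`` (cells) at which any profile's optimum
    is irreversible, or None if none is."""
    rec = result.records
    hits = rec.loc[rec["best_class"] == StrategyClass.IRREVERSIBLE.value, "n"]
    if hits.empty:
        return None
    return int(2 ** hits.min())


def differentiation_rate_summary(
    records: pd.DataFrame,
    cost_col: str = "cost_gs",
) -> pd.DataFrame:
    """Median and 90% band (5th--95th percentile) of the cumulative
    differentiation rate of optimal strategies, per cost value and class.

    Classes absent at a cost value are simply missing from the table (not
    reported as zero).
    """
    rows = []
    for (cost, cls), group in records.groupby([cost_col, "best_class"], sort=True):
        rates = group["diff_rate"].to_numpy()
        rows.append(
            {
                cost_col: cost,
                "best_class": cls,
                "count": len(rates),
                "median": float(np.median(rates)),
                "q05": float(np.quantile(rates, 0.05)),
                "q95": float(np.quantile(rates, 0.95)),
            }
        )
    return pd.DataFrame(rows)


def promoting_profile_summary(
    records: pd.DataFrame,
    x_grid: Optional[np.ndarray] = None,
) -> dict:
    """Compare profiles promoting irreversible differentiation with the full
    profile set.

    Returns a dict with per-parameter summaries, pointwise ``Fcomp`` bands
    on ``x_grid`` (median and 5th--95th percentiles across profiles), the
    paired parameter records of the promoting subset, and an ``empty`` flag
    when no profile promotes irreversible differentiation.
    """
    if x_grid is None:
        x_grid = np.linspace(0.0, 1.0, 101)
    x_grid = np.asarray(x_grid, dtype=float)

    prof_cols = ["profile_index", "x0", "x1", "b", "alpha"]
    all_profiles = records[prof_cols].drop_duplicates("profile_index")
    promoting_idx = records.loc[
        records["best_class"] == StrategyClass.IRREVERSIBLE.value, "profile_index"
    ].unique()
    promoting = all_profiles[all_profiles["profile_index"].isin(promoting_idx)]

    def _param_stats(frame, label):
        out = {}
        for p in ["x0", "x1", "b", "alpha"]:
            vals = frame[p].to_numpy()
            if len(vals):
                out[p] = {
                    f"median_{label}": float(np.median(vals)),
                    f"q05_{label}": float(np.quantile(vals, 0.05)),
                    f"q95_{label}": float(np.quantile(vals, 0.95)),
                }
            else:
                out[p] = {
                    f"median_{label}": np.nan,
                    f"q05_{label}": np.nan,
                    f"q95_{label}": np.nan,
                }
        return pd.DataFrame(out).T

    params = pd.concat(
        [_param_stats(all_profiles, "all"), _param_stats(promoting, "promoting")],
        axis=1,
    )

    def _band(frame, label):
        if not len(frame):
            nancol = np.full(x_grid.shape, np.nan)
            return {f"median_{label}": nancol, f"q05_{label}": nancol, f"q95_{label}": nancol}
        curves = np.stack(
            [
                CompositionProfile(r.x0, r.x1, r.b, r.alpha)(x_grid)
                for r in frame.itertuples(index=False)
            ]
        )
        return {
            f"median_{label}": np.median(curves, axis=0),
            f"q05_{label}": np.quantile(curves, 0.05, axis=0),
            f"q95_{label}": np.quantile(curves, 0.95, axis=0),
        }

    band = pd.DataFrame({"x": x_grid})
    for label, frame in (("all", all_profiles[["x0", "x1", "b", "alpha"]]),
                         ("promoting", promoting[["x0", "x1", "b", "alpha"]])):
        for k, v in _band(frame, label).items():
            band[k] = v

    return {
        "empty": len(promoting) == 0,
        "n_profiles": len(all_profiles),
        "n_promoting": len(promoting),
        "parameters": params,
        "band": band,
        "pairs": promoting.reset_index(drop=True),
    }
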