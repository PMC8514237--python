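"""Vectorised batch simulation of developmental trajectories.

This is the numerical workhorse behind the growth-rate estimator, the
optimizer and the screens.  It simulates, for a whole array of strategies at
once, ``M`` independent developmental trajectories per strategy and stores
per-round *sufficient statistics* rather than raw outcomes:

* the soma count after each round (determines the composition effect),
* the germ-to-soma and soma-to-germ differentiation event counts per round
  (determine the delay cost factor and the survival weight),
* the final germ count (the offspring number ``G``).

From these, the trajectory time ``T`` and weight ``w = S * G`` for *any*
composition profile and cost model can be reconstructed cheaply, so one
sampled trajectory set can be reused across profiles and cost values
(common random numbers) as well as across all growth-rate evaluations during
root finding.

Two layers are provided:

* :func:`weights_times` -- direct (``float64``) reconstruction, used by the
  single-strategy estimators;
* :class:`ProfileContext` -- a per-profile ``float32`` precomputation that
  makes the per-cost reconstruction two fused multiply-adds, used by the
  grid screens.  Because trajectory times are affine in the two delay costs,
  ``T = U + cgs * VA + csg * VB`` with profile-dependent ``U, VA, VB``.

The composition effect is evaluated through per-round lookup tables: after
round ``r`` the soma count takes one of ``2**(r+1) + 1`` integer values, so
``Fcomp`` never needs to be evaluated per trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .development import CompositionTiming, CostMode, CostModel
from .profiles import CompositionProfile
from .strategies import classify_rows

__all__ = [
    "GridTrajectories",
    "sample_grid_trajectories",
    "fcomp_tables",
    "weights_times",
    "ProfileContext",
    "profile_context",
    "context_weights_times",
]


@dataclass
class GridTrajectories:
    """Per-round sufficient statistics of ``M`` trajectories per strategy."""

    strategies: np.ndarray  # (S, 6) float64
    n: int
    M: int
    soma: np.ndarray  # (n, S, M) int64: soma count after round r (int64 for fast table gathers)
    gs_events: np.ndarray  # (n, S, M) int16: germ-to-soma daughter events
    sg_events: np.ndarray  # (n, S, M) int16: soma-to-germ daughter events
    offspring: np.ndarray  # (S, M) int32: germ count at maturity
    classes: np.ndarray  # (S,) int8 strategy class codes

    @property
    def n_strategies(self) -> int:
        return self.strategies.shape[0]

    def scaled_events(self):
        """Per-round event counts divided by the post-division cell count
        (float32), cached; these are the coefficients of the costs in the
        per-round delay factor."""
        cached = getattr(self, "_scaled", None)
        if cached is None:
            n = self.n
            gs = np.empty(self.gs_events.shape, dtype=np.float32)
            sg = np.empty(self.sg_events.shape, dtype=np.float32)
            for r in range(n):
                inv = np.float32(1.0 / (1 << (r + 1)))
                np.multiply(self.gs_events[r], inv, out=gs[r], casting="unsafe")
                np.multiply(self.sg_events[r], inv, out=sg[r], casting="unsafe")
            cached = (gs, sg)
            object.__setattr__(self, "_scaled", cached)
        return cached


def sample_grid_trajectories(
    strategies: np.ndarray,
    n: int,
    M: int,
    rng: np.random.Generator,
) -> GridTrajectories:
    """Sample ``M`` trajectories of ``n`` rounds for each strategy row.

    Multinomial division outcomes are drawn as two nested binomials per
    parent type, vectorised over strategies and trajectories.
    """
    strategies = np.atleast_2d(np.asarray(strategies, dtype=float))
    if strategies.shape[1] != 6:
        raise ValueError("strategies must be an (S, 6) array")
    if n < 1 or M < 1:
        raise ValueError("need n >= 1 rounds and M >= 1 trajectories")
    if n > 14:
        raise ValueError("per-round counts are stored as int16; n > 14 unsupported")
    S = strategies.shape[0]

    p_ggg = strategies[:, 0:1]
    den_g = strategies[:, 1] + strategies[:, 2]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_g2 = np.where(den_g > 0, strategies[:, 1] / np.where(den_g > 0, den_g, 1.0), 0.0)[:, None]
    p_sgg = strategies[:, 3:4]
    den_s = strategies[:, 4] + strategies[:, 5]
    with np.errstate(invalid="ignore", divide="ignore"):
        p_s2 = np.where(den_s > 0, strategies[:, 4] / np.where(den_s > 0, den_s, 1.0), 0.0)[:, None]
    p_g2 = np.clip(p_g2, 0.0, 1.0)
    p_s2 = np.clip(p_s2, 0.0, 1.0)

    soma = np.empty((n, S, M), dtype=np.int64)
    gs_events = np.empty((n, S, M), dtype=np.int16)
    sg_events = np.empty((n, S, M), dtype=np.int16)

    g = np.ones((S, M), dtype=np.int64)
    s = np.zeros((S, M), dtype=np.int64)
    for r in range(n):
        n_gg = rng.binomial(g, p_ggg)
        rem = g - n_gg
        n_gs = rng.binomial(rem, p_g2)
        n_ss = rem - n_gs
        m_gg = rng.binomial(s, p_sgg)
        rem2 = s - m_gg
        m_gs = rng.binomial(rem2, p_s2)
        g = 2 * n_gg + n_gs + 2 * m_gg + m_gs
        s = (1 << (r + 1)) - g
        soma[r] = s
        gs_events[r] = n_gs + 2 * n_ss
        sg_events[r] = m_gs + 2 * m_gg

    return GridTrajectories(
        strategies=strategies,
        n=n,
        M=M,
        soma=soma,
        gs_events=gs_events,
        sg_events=sg_events,
        offspring=g.astype(np.int32),
        classes=classify_rows(strategies),
    )


def fcomp_tables(profile: CompositionProfile, n: int, dtype=np.float64) -> list:
    """Per-round lookup tables ``Fcomp(s / 2**(r+1))`` for all possible
    post-division soma counts ``s = 0 .. 2**(r+1)``."""
    tables = []
    for r in range(n):
        ncells = 1 << (r + 1)
        x = np.arange(ncells + 1, dtype=float) / ncells
        tables.append(profile(x).astype(dtype))
    return tables


def weights_times(
    traj: GridTrajectories,
    profile: CompositionProfile,
    costs: CostModel,
    dtype=np.float64,
    timing: CompositionTiming = CompositionTiming.PRE,
):
    """Reconstruct ``(w, T)`` per trajectory for one profile and cost model.

    ``w`` is the reproductive weight ``S * G`` (survival times offspring) and
    ``T`` the total development time.  In RISK mode the per-round delay
    factor is identically 1 and survival is carried analytically.  Under PRE
    timing round ``r`` uses the composition left by round ``r - 1`` (the
    first round always runs at ``Fcomp = 1``).
    """
    tables = fcomp_tables(profile, traj.n, dtype=dtype)
    S, M = traj.offspring.shape
    T = np.zeros((S, M), dtype=dtype)
    risky = costs.mode is CostMode.RISK
    pre = timing is CompositionTiming.PRE
    for r in range(traj.n):
        if pre:
            fc = dtype(1.0) if r == 0 else tables[r - 1][traj.soma[r - 1]]
        else:
            fc = tables[r][traj.soma[r]]
        if risky:
            T += fc
        else:
            ncells = dtype(1 << (r + 1))
            fac = 1.0 + (
                dtype(costs.cgs) * traj.gs_events[r] + dtype(costs.csg) * traj.sg_events[r]
            ) / ncells
            T += fc * fac
    w = traj.offspring.astype(dtype)
    if risky:
        w = w * _survival_weights(
            traj.gs_events.sum(0, dtype=np.int32),
            traj.sg_events.sum(0, dtype=np.int32),
            costs,
            dtype,
        )
    return w, T


def _survival_weights(tot_gs, tot_sg, costs: CostModel, dtype):
    """Analytic survival ``(1-dgs)**tot_gs * (1-dsg)**tot_sg`` per trajectory.

    Zero risks are skipped entirely so that the zero-risk model is bitwise
    identical to the zero-cost delay model under a shared trajectory set.
    """
    factor = None
    for d, tot in ((costs.dgs, tot_gs), (costs.dsg, tot_sg)):
        if d == 0.0:
            continue
        if d >= 1.0:
            f = np.where(tot > 0, dtype(0.0), dtype(1.0))
        else:
            f = np.exp(dtype(np.log1p(-d)) * tot.astype(dtype))
        factor = f if factor is None else factor * f
    if factor is None:
        return np.ones_like(tot_gs, dtype=dtype)
    return factor


@dataclass
class ProfileContext:
    """Float32 per-profile precomputation over a trajectory set.

    For any delay costs, ``T = U + cgs * VA + csg * VB``; for any risks,
    ``T = U`` and the survival exponents are ``tot_gs`` / ``tot_sg``.
    """

    traj: GridTrajectories
    U: np.ndarray  # (S, M) float32: sum of composition factors
    VA: np.ndarray  # (S, M) float32: sum of Fcomp * gs_events / N per round
    VB: np.ndarray  # (S, M) float32
    tot_gs: np.ndarray  # (S, M) int32
    tot_sg: np.ndarray  # (S, M) int32
    offspring_f: np.ndarray  # (S, M) float32


def profile_context(
    traj: GridTrajectories,
    profile: CompositionProfile,
    timing: CompositionTiming = CompositionTiming.PRE,
) -> ProfileContext:
    tables = fcomp_tables(profile, traj.n, dtype=np.float32)
    S, M = traj.offspring.shape
    U = np.zeros((S, M), dtype=np.float32)
    VA = np.zeros((S, M), dtype=np.float32)
    VB = np.zeros((S, M), dtype=np.float32)
    gs_scaled, sg_scaled = traj.scaled_events()
    tmp = np.empty((S, M), dtype=np.float32)
    pre = timing is CompositionTiming.PRE
    for r in range(traj.n):
        if pre and r == 0:
            U += np.float32(1.0)
            VA += gs_scaled[0]
            VB += sg_scaled[0]
            continue
        fc = tables[r - 1][traj.soma[r - 1]] if pre else tables[r][traj.soma[r]]
        U += fc
        np.multiply(fc, gs_scaled[r], out=tmp)
        VA += tmp
        np.multiply(fc, sg_scaled[r], out=tmp)
        VB += tmp
    return ProfileContext(
        traj=traj,
        U=U,
        VA=VA,
        VB=VB,
        tot_gs=traj.gs_events.sum(0, dtype=np.int32),
        tot_sg=traj.sg_events.sum(0, dtype=np.int32),
        offspring_f=traj.offspring.astype(np.float32),
    )


def context_weights_times(ctx: ProfileContext, costs: CostModel):
    """(w, T) in float32 from a profile context, for one cost model."""
    if costs.mode is CostMode.DELAY:
        T = ctx.U + np.float32(costs.cgs) * ctx.VA + np.float32(costs.csg) * ctx.VB
        w = ctx.offspring_f
    else:
        T = ctx.U + np.float32(0.0) * ctx.VA + np.float32(0.0) * ctx.VB
        w = ctx.offspring_f * _survival_weights(ctx.tot_gs, ctx.tot_sg, costs, np.float32)
    return w, T
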