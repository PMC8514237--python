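"""Population growth rate from stochastic developmental trajectories.

In a stationary exponentially growing population of organisms whose
development is stochastic, the growth rate ``lambda`` solves the
generalised Euler--Lotka equation

    sum_i  G_i * P_i * e**(-lambda * T_i)  =  1,

where the sum runs over developmental trajectories ``i`` with probability
``P_i``, offspring count ``G_i`` (germ cells at maturity, weighted by the
survival probability in the risky variant) and duration ``T_i``.

Two evaluation routes are implemented:

* :func:`estimate_lambda_mc` -- Monte-Carlo: sample ``M`` trajectories once
  and solve ``(1/M) * sum_j w_j * e**(-lambda*T_j) = 1``.  The same sample
  is reused for every evaluation of the left-hand side during root finding
  (common random numbers), so the estimate is deterministic given the seed
  and the left-hand side is exactly monotone in ``lambda``.
* :func:`exact_lambda` -- brute force: enumerate every trajectory with its
  exact multinomial probability (feasible for small ``n``); serves as the
  independent oracle for the Monte-Carlo route.

The left-hand side is strictly decreasing in ``lambda`` whenever some weight
is positive, so a safeguarded Newton iteration on an analytic bracket always
converges.  Negative growth rates (sub-replacement strategies) are valid
solutions; a strategy whose every trajectory has zero weight is reported as
extinct rather than given a number.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from functools import lru_cache
from math import comb
from typing import Optional

import numpy as np

from .development import CompositionTiming, CostMode, CostModel
from .engine import fcomp_tables, sample_grid_trajectories, weights_times
from .profiles import CompositionProfile
from .strategies import DevelopmentalStrategy

__all__ = [
    "GrowthStatus",
    "GrowthRateResult",
    "solve_euler_lotka",
    "estimate_lambda_mc",
    "exact_lambda",
]


class GrowthStatus(enum.Enum):
    OK = "ok"
    SUB_REPLACEMENT_NEGATIVE = "sub_replacement_negative"
    EXTINCT = "extinct"


@dataclass(frozen=True)
class GrowthRateResult:
    """A growth rate with solver diagnostics.

    ``lam`` is ``-inf`` for extinct strategies (every trajectory produced
    zero surviving offspring); otherwise the status records whether the
    population shrinks (negative rate).
    """

    lam: float
    status: GrowthStatus
    n_trajectories: int
    iterations: int
    residual: float
    bracket: tuple
    method: str
    std_error: Optional[float] = None


def solve_euler_lotka(
    weights: np.ndarray,
    times: np.ndarray,
    traj_prob: Optional[np.ndarray] = None,
    *,
    tol: float = 1e-6,
    ftol: Optional[float] = None,
    max_iter: int = 200,
    lam0: Optional[np.ndarray] = None,
    compute_residual: bool = True,
):
    """Row-wise root of ``sum_j q_j * w_j * e**(-lambda*T_j) = 1``.

    Parameters
    ----------
    weights, times : (S, M) arrays
        Per-trajectory weights ``w >= 0`` and durations ``T > 0``.
    traj_prob : optional (S, M) or (M,) array
        Trajectory probabilities ``q``; defaults to the uniform ``1/M`` of a
        Monte-Carlo sample.
    tol : float
        Absolute tolerance on ``lambda``.
    lam0 : optional (S,) array
        Warm start (e.g. the solution at a neighbouring cost value).

    Returns ``(lam, info)`` where ``lam`` is an (S,) array (``-inf`` marks
    extinct rows) and ``info`` carries iteration counts, residuals and the
    initial bracket.  The left-hand side is strictly decreasing in
    ``lambda``, so the safeguarded Newton iteration (bisection fallback on a
    bracket that always contains the root) cannot diverge.
    """
    times = np.atleast_2d(np.asarray(times))
    dtype = np.float32 if times.dtype == np.float32 else np.float64
    times = times.astype(dtype, copy=False)
    weights = np.atleast_2d(np.asarray(weights)).astype(dtype, copy=False)
    S, M = weights.shape
    if ftol is None:
        ftol = 1e-9 if dtype == np.float64 else 1e-4
    clip = 700.0 if dtype == np.float64 else 80.0

    if traj_prob is None:
        wq = weights * dtype(1.0 / M)
    else:
        wq = weights * np.asarray(traj_prob, dtype=dtype)

    sw = wq.sum(1, dtype=np.float64)
    extinct = sw <= 0.0
    positive = wq > 0
    tmin = np.where(positive, times, np.inf).min(1)
    tmin = np.where(np.isfinite(tmin), tmin, 1.0)
    tmax = np.where(positive, times, -np.inf).max(1)
    tmax = np.where(np.isfinite(tmax) & (tmax > 0), tmax, 1.0)
    del positive
    with np.errstate(divide="ignore"):
        lsw = np.log(np.maximum(sw, 1e-300))

    # Analytic bracket.  Every trajectory j bounds the root from below:
    # wq_j * e**(-lam*T_j) <= 1 at the root, so lam* >= ln(wq_j)/T_j; the
    # heaviest trajectory gives a tight bound.  From above, the row sum
    # gives lam* <= ln(sum wq)/tmin (root >= 0) or /tmax (root < 0).
    rows = np.arange(S)
    jmax = np.argmax(wq, axis=1)
    wqm = wq[rows, jmax].astype(np.float64)
    tjm = times[rows, jmax].astype(np.float64)
    lo = np.log(np.maximum(wqm, 1e-300)) / tjm
    hi = np.where(lsw >= 0.0, lsw / tmin, lsw / tmax)
    margin = 1e-6 + 1e-6 * np.maximum(np.abs(lo), np.abs(hi))
    lo = (lo - margin).astype(dtype)
    hi = (hi + margin).astype(dtype)
    bracket = (float(lo.min()) if S else np.nan, float(hi.max()) if S else np.nan)

    if lam0 is None:
        tbar = (wq * times).sum(1, dtype=np.float64) / np.maximum(sw, 1e-300)
        lam = (lsw / np.maximum(tbar, 1e-12)).astype(dtype)
    else:
        lam = np.asarray(lam0, dtype=dtype).copy()
        lam[~np.isfinite(lam)] = 0.0
    np.clip(lam, lo + dtype(1e-9), hi - dtype(1e-9), out=lam)

    conv = extinct.copy()
    iterations = 0

    def _iterate(wq_a, times_a, lam_a, lo_a, hi_a, conv_a, zbuf):
        """One safeguarded Newton step on all rows of the given views;
        returns updated (lam, lo, hi, conv)."""
        np.multiply(times_a, -lam_a[:, None], out=zbuf)
        np.clip(zbuf, -clip, clip, out=zbuf)
        np.exp(zbuf, out=zbuf)
        zbuf *= wq_a
        f = zbuf.sum(1) - 1.0
        zbuf *= times_a
        fp = zbuf.sum(1)  # = -f'(lam)
        positive = f > 0
        lo_a = np.where(positive & ~conv_a, lam_a, lo_a)
        hi_a = np.where(~positive & ~conv_a, lam_a, hi_a)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = f / fp
        done = (np.abs(step) < tol) & (np.abs(f) < ftol)
        cand = lam_a + step
        inside = (cand > lo_a) & (cand < hi_a)
        # converged rows whose (negligible) step leaves the bracket stay put;
        # unconverged ones fall back to bisection
        cand = np.where(
            inside, cand, np.where(done, lam_a, dtype(0.5) * (lo_a + hi_a))
        )
        lam_a = np.where(conv_a, lam_a, cand)
        conv_a = conv_a | done
        return lam_a, lo_a, hi_a, conv_a

    # phase 1: full-array Newton steps while most rows are unconverged
    zbuf = np.empty_like(times)
    while iterations < max_iter and not conv.all():
        if conv.mean() > 0.7 and iterations >= 2:
            break
        iterations += 1
        lam, lo, hi, conv = _iterate(wq, times, lam, lo, hi, conv, zbuf)
    del zbuf

    # phase 2: compact the stragglers and iterate on the small subset
    if not conv.all():
        idx = np.nonzero(~conv)[0]
        wq_s = np.ascontiguousarray(wq[idx])
        t_s = np.ascontiguousarray(times[idx])
        lam_s, lo_s, hi_s = lam[idx], lo[idx], hi[idx]
        conv_s = np.zeros(idx.size, dtype=bool)
        zbuf = np.empty_like(t_s)
        while iterations < max_iter and not conv_s.all():
            iterations += 1
            lam_s, lo_s, hi_s, conv_s = _iterate(
                wq_s, t_s, lam_s, lo_s, hi_s, conv_s, zbuf
            )
        lam[idx] = lam_s
        conv[idx] = conv_s

    if compute_residual:
        z = -lam[:, None] * times
        np.clip(z, -clip, clip, out=z)
        residual = np.abs((wq * np.exp(z)).sum(1) - 1.0)
        residual[extinct] = 0.0
    else:
        residual = np.full(S, np.nan)
    lam = lam.astype(float)
    lam[extinct] = -np.inf
    info = {
        "iterations": iterations,
        "residual": residual,
        "bracket": bracket,
        "extinct": extinct,
        "converged": conv,
    }
    return lam, info


def _wrap_result(lam, info, M, method, std_error=None) -> GrowthRateResult:
    lam = float(lam)
    if not np.isfinite(lam):
        status = GrowthStatus.EXTINCT
    elif lam < 0:
        status = GrowthStatus.SUB_REPLACEMENT_NEGATIVE
    else:
        status = GrowthStatus.OK
    return GrowthRateResult(
        lam=lam,
        status=status,
        n_trajectories=M,
        iterations=info["iterations"],
        residual=float(info["residual"][0]),
        bracket=info["bracket"],
        method=method,
        std_error=std_error,
    )


def estimate_lambda_mc(
    strategy: DevelopmentalStrategy,
    profile: CompositionProfile,
    costs: CostModel,
    n: int,
    M: int = 1000,
    *,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    tol: float = 1e-6,
    timing: CompositionTiming = CompositionTiming.PRE,
) -> GrowthRateResult:
    """Monte-Carlo growth rate of one strategy.

    Samples ``M`` trajectories once, then solves the Euler--Lotka equation
    over the fixed sample.  The reported standard error is the delta-method
    propagation of the sampling variance of the left-hand side through the
    root: ``se = sd(Y) / (sqrt(M) * mean(T*Y))`` with
    ``Y = w * e**(-lambda*T)``.
    """
    if M < 1:
        raise ValueError("M must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    traj = sample_grid_trajectories(strategy.as_array()[None, :], n, M, rng)
    w, T = weights_times(traj, profile, costs, dtype=np.float64, timing=timing)
    lam, info = solve_euler_lotka(w, T, tol=tol)
    std_error = None
    if np.isfinite(lam[0]):
        Y = w[0] * np.exp(np.clip(-lam[0] * T[0], -700, 700))
        denom = (T[0] * Y).mean()
        if denom > 0:
            sd = Y.std(ddof=1) if M > 1 else 0.0
            std_error = float(sd / (np.sqrt(M) * denom))
    return _wrap_result(lam[0], info, M, "monte_carlo", std_error)


@lru_cache(maxsize=4096)
def _multinomial_splits(m: int, probs: tuple):
    """All outcome count triples of ``m`` parents with positive probability,
    with their exact multinomial probabilities."""
    p1, p2, p3 = probs
    out = []
    for a in range(m + 1):
        if p1 == 0.0 and a > 0:
            continue
        for b in range(m - a + 1):
            c = m - a - b
            if (p2 == 0.0 and b > 0) or (p3 == 0.0 and c > 0):
                continue
            prob = comb(m, a) * comb(m - a, b) * p1**a * p2**b * p3**c
            if prob > 0.0:
                out.append(((a, b, c), prob))
    return tuple(out)


def exact_lambda(
    strategy: DevelopmentalStrategy,
    profile: CompositionProfile,
    costs: CostModel,
    n: int,
    *,
    cap: int = 500_000,
    tol: float = 1e-9,
    timing: CompositionTiming = CompositionTiming.PRE,
) -> GrowthRateResult:
    """Exact growth rate by full trajectory enumeration (small ``n`` only).

    Every sequence of round outcomes with positive probability is visited;
    trajectory probabilities are products of multinomial probabilities and
    sum to one.  Intended for ``n <= 3``--``4``; enumeration beyond ``cap``
    trajectories is rejected with a hint to use the Monte-Carlo estimator.
    """
    if n < 1:
        raise ValueError("need n >= 1")
    tables = fcomp_tables(profile, n, dtype=np.float64)
    risky = costs.mode is CostMode.RISK
    germ_probs = strategy.germ_probs
    soma_probs = strategy.soma_probs

    leaves_P, leaves_G, leaves_T, leaves_A, leaves_B = [], [], [], [], []

    pre = timing is CompositionTiming.PRE

    # iterative depth-first enumeration over (round, g, s, prob, T, A, B)
    stack = [(0, 1, 0, 1.0, 0.0, 0, 0)]
    while stack:
        r, g, s, prob, T, A, B = stack.pop()
        ncells = 1 << (r + 1)
        if pre:
            fc_pre = 1.0 if r == 0 else tables[r - 1][s]
        for (ngg, ngs, nss), pg in _multinomial_splits(g, germ_probs):
            for (mgg, mgs, mss), ps in _multinomial_splits(s, soma_probs):
                g2 = 2 * ngg + ngs + 2 * mgg + mgs
                s2 = ncells - g2
                a = ngs + 2 * nss
                b = mgs + 2 * mgg
                fc = fc_pre if pre else tables[r][s2]
                if risky:
                    t = fc
                else:
                    t = fc * (1.0 + (costs.cgs * a + costs.csg * b) / ncells)
                p2 = prob * pg * ps
                if r + 1 == n:
                    leaves_P.append(p2)
                    leaves_G.append(g2)
                    leaves_T.append(T + t)
                    leaves_A.append(A + a)
                    leaves_B.append(B + b)
                    if len(leaves_P) > cap:
                        raise ValueError(
                            f"exact enumeration exceeds cap={cap} trajectories; "
                            "use estimate_lambda_mc for this n"
                        )
                else:
                    stack.append((r + 1, g2, s2, p2, T + t, A + a, B + b))

    P = np.array(leaves_P, dtype=np.float64)
    G = np.array(leaves_G, dtype=np.float64)
    T = np.array(leaves_T, dtype=np.float64)
    total = P.sum()
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"enumerated trajectory probabilities sum to {total!r}")
    w = G
    if risky:
        A = np.array(leaves_A, dtype=np.float64)
        Bv = np.array(leaves_B, dtype=np.float64)
        w = G * (1.0 - costs.dgs) ** A * (1.0 - costs.dsg) ** Bv
    lam, info = solve_euler_lotka(w[None, :], T[None, :], traj_prob=P[None, :], tol=tol)
    return _wrap_result(lam[0], info, len(P), "exact")
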