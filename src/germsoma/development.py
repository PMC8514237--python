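"""Single-organism development: synchronous division rounds with stochastic
differentiation, accumulating time and (in the risky variant) survival.

An organism starts as one germ-role cell and passes through ``n`` rounds of
synchronous division, so after round ``k`` it has exactly ``2**k`` cells.  At
each round every cell independently chooses a division outcome according to
the developmental strategy; the round's duration is then

    t = Fdiff * Fcomp,

where ``Fdiff >= 1`` is the averaged differentiation cost among the cells of
the round and ``Fcomp`` is the composition effect of the organism's soma
fraction (see composition timing below).  Both factors are recomputed every
round.

Two cost mechanisms are supported:

* ``DELAY`` -- each differentiated daughter cell adds ``cgs`` (germ-to-soma)
  or ``csg`` (soma-to-germ) to the numerator of the averaged cost:
  ``Fdiff = 1 + (csg*(m_gs + 2*m_gg) + cgs*(n_gs + 2*n_ss)) / N`` with ``N``
  the post-division cell count.
* ``RISK`` -- differentiation does not slow the round (``Fdiff = 1``) but
  each differentiated daughter independently risks killing the whole
  organism; a trajectory's survival weight is the product of
  ``(1 - dgs)`` / ``(1 - dsg)`` factors over all differentiation events.

The composition effect of a round is evaluated, by default, on the
composition present at the *start* of the round (``PRE`` timing): the soma
cells produced during a division round start contributing to growth from the
following round onward, so the first round of every life cycle runs at
``Fcomp = 1``.  The alternative ``POST`` timing (daughters contribute to the
round that created them) is available as an explicit switch; it makes soma
effective one round earlier and thereby strengthens differentiation in very
small organisms.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .profiles import CompositionProfile
from .strategies import DevelopmentalStrategy

__all__ = [
    "CompositionTiming",
    "CostMode",
    "CostModel",
    "OrganismState",
    "RoundOutcome",
    "Trajectory",
    "sample_round_outcome",
    "compute_fdiff",
    "compute_round_time",
    "compute_survival",
    "simulate_trajectory",
    "trajectory_records",
]


class CostMode(enum.Enum):
    DELAY = "delay"
    RISK = "risk"


class CompositionTiming(enum.Enum):
    """Which composition enters a round's ``Fcomp``: the state before the
    round's divisions (PRE, default) or after them (POST)."""

    PRE = "pre"
    POST = "post"


@dataclass(frozen=True)
class CostModel:
    """Differentiation costs: division delays (DELAY) or death risks (RISK).

    Only the fields of the active mode are used.
    """

    mode: CostMode = CostMode.DELAY
    cgs: float = 0.0  # germ-to-soma delay cost, per differentiated daughter
    csg: float = 0.0  # soma-to-germ delay cost
    dgs: float = 0.0  # germ-to-soma death risk, per differentiated daughter
    dsg: float = 0.0  # soma-to-germ death risk

    def __post_init__(self) -> None:
        if self.mode is CostMode.DELAY:
            if self.cgs < 0 or self.csg < 0:
                raise ValueError("delay costs must be >= 0")
        else:
            if not (0.0 <= self.dgs <= 1.0 and 0.0 <= self.dsg <= 1.0):
                raise ValueError("death risks must lie in [0, 1]")

    @classmethod
    def delay(cls, cgs: float, csg: float) -> "CostModel":
        return cls(mode=CostMode.DELAY, cgs=cgs, csg=csg)

    @classmethod
    def risk(cls, dgs: float, dsg: float) -> "CostModel":
        return cls(mode=CostMode.RISK, dgs=dgs, dsg=dsg)


@dataclass(frozen=True)
class OrganismState:
    """Cell counts after round ``k`` (``g + s = 2**k``)."""

    g: int
    s: int
    k: int

    def __post_init__(self) -> None:
        if self.g < 0 or self.s < 0:
            raise ValueError("cell counts must be non-negative")
        if self.g + self.s != 2**self.k:
            raise ValueError(f"g + s must equal 2**k = {2**self.k}, got {self.g + self.s}")

    @property
    def ncells(self) -> int:
        return self.g + self.s

    @property
    def soma_fraction(self) -> float:
        return self.s / self.ncells


@dataclass(frozen=True)
class RoundOutcome:
    """Division-outcome counts of one round.

    ``n_**`` count germ-role parents by the roles of their daughters,
    ``m_**`` soma-role parents.  E.g. ``n_gs`` is the number of germ parents
    whose division produced one germ and one soma daughter.
    """

    n_gg: int
    n_gs: int
    n_ss: int
    m_gg: int
    m_gs: int
    m_ss: int

    def __post_init__(self) -> None:
        counts = (self.n_gg, self.n_gs, self.n_ss, self.m_gg, self.m_gs, self.m_ss)
        if any(c < 0 for c in counts):
            raise ValueError("outcome counts must be non-negative")

    @property
    def germ_parents(self) -> int:
        return self.n_gg + self.n_gs + self.n_ss

    @property
    def soma_parents(self) -> int:
        return self.m_gg + self.m_gs + self.m_ss

    @property
    def daughters_germ(self) -> int:
        return 2 * self.n_gg + self.n_gs + 2 * self.m_gg + self.m_gs

    @property
    def daughters_soma(self) -> int:
        return self.n_gs + 2 * self.n_ss + self.m_gs + 2 * self.m_ss

    @property
    def germ_to_soma_events(self) -> int:
        """Daughter cells of germ parents that took the soma role."""
        return self.n_gs + 2 * self.n_ss

    @property
    def soma_to_germ_events(self) -> int:
        """Daughter cells of soma parents that took the germ role."""
        return self.m_gs + 2 * self.m_gg

    def next_state(self, k_parent: int) -> OrganismState:
        return OrganismState(g=self.daughters_germ, s=self.daughters_soma, k=k_parent + 1)


@dataclass(frozen=True)
class Trajectory:
    """One realisation of organism development.

    ``T`` is the total development time, ``G`` the offspring count (germ
    cells at maturity) and ``survival`` the probability that the organism
    survived all differentiation events (1 in DELAY mode).
    """

    outcomes: Tuple[RoundOutcome, ...]
    times: Tuple[float, ...]
    T: float
    G: int
    survival: float


def trajectory_records(traj: Trajectory) -> list:
    """Per-round dump of one trajectory as flat dicts (debugging aid)."""
    rows = []
    for k, (out, t) in enumerate(zip(traj.outcomes, traj.times)):
        rows.append(
            {
                "round": k + 1,
                "n_gg": out.n_gg, "n_gs": out.n_gs, "n_ss": out.n_ss,
                "m_gg": out.m_gg, "m_gs": out.m_gs, "m_ss": out.m_ss,
                "germ": out.daughters_germ, "soma": out.daughters_soma,
                "time": t,
            }
        )
    return rows


def sample_round_outcome(
    state: OrganismState,
    strategy: DevelopmentalStrategy,
    rng: np.random.Generator,
) -> RoundOutcome:
    """Draw the division outcomes of one round: every cell independently
    chooses its outcome, so the counts are multinomial."""
    n_gg, n_gs, n_ss = rng.multinomial(state.g, strategy.germ_probs)
    m_gg, m_gs, m_ss = rng.multinomial(state.s, strategy.soma_probs)
    return RoundOutcome(
        n_gg=int(n_gg), n_gs=int(n_gs), n_ss=int(n_ss),
        m_gg=int(m_gg), m_gs=int(m_gs), m_ss=int(m_ss),
    )


def compute_fdiff(outcome: RoundOutcome, costs: CostModel) -> float:
    """Averaged differentiation cost factor of one round (DELAY mode only).

    The denominator is the post-division cell count ``N = 2 * parents``.
    """
    if costs.mode is not CostMode.DELAY:
        raise ValueError("Fdiff is defined only for delay costs (DELAY mode)")
    n_cells = 2 * (outcome.germ_parents + outcome.soma_parents)
    total = costs.csg * outcome.soma_to_germ_events + costs.cgs * outcome.germ_to_soma_events
    return 1.0 + total / n_cells


def compute_survival(outcome: RoundOutcome, costs: CostModel) -> float:
    """Probability that no differentiation event of this round killed the
    organism (RISK mode only): one independent risk per differentiated
    daughter cell."""
    if costs.mode is not CostMode.RISK:
        raise ValueError("survival is defined only for risky differentiation (RISK mode)")
    return (1.0 - costs.dgs) ** outcome.germ_to_soma_events * (
        1.0 - costs.dsg
    ) ** outcome.soma_to_germ_events


def compute_round_time(
    outcome: RoundOutcome,
    state: OrganismState,
    profile: CompositionProfile,
    costs: CostModel,
    timing: CompositionTiming = CompositionTiming.PRE,
) -> float:
    """Duration of one division round, ``Fdiff * Fcomp``.

    Under PRE timing (default) ``state`` is the organism state *before* the
    round's divisions and its composition enters ``Fcomp``; under POST
    timing ``state`` is the post-division state.  In RISK mode ``Fdiff`` is
    identically 1 (risk replaces delay).
    """
    if timing is CompositionTiming.PRE:
        consistent = (
            state.g == outcome.germ_parents and state.s == outcome.soma_parents
        )
    else:
        consistent = (
            state.g == outcome.daughters_germ and state.s == outcome.daughters_soma
        )
    if not consistent:
        raise ValueError("state inconsistent with the round outcome")
    fcomp = profile(state.soma_fraction)
    if costs.mode is CostMode.RISK:
        return fcomp
    return compute_fdiff(outcome, costs) * fcomp


def simulate_trajectory(
    strategy: DevelopmentalStrategy,
    profile: CompositionProfile,
    costs: CostModel,
    n: int,
    rng: np.random.Generator,
    timing: CompositionTiming = CompositionTiming.PRE,
) -> Trajectory:
    """Simulate one life cycle of ``n`` rounds from a single germ-role cell."""
    if n < 1:
        raise ValueError("need at least one division round")
    state = OrganismState(g=1, s=0, k=0)
    outcomes = []
    times = []
    total_time = 0.0
    survival = 1.0
    for _ in range(n):
        outcome = sample_round_outcome(state, strategy, rng)
        prev_state = state
        state = outcome.next_state(state.k)
        t = compute_round_time(
            outcome,
            prev_state if timing is CompositionTiming.PRE else state,
            profile,
            costs,
            timing,
        )
        if costs.mode is CostMode.RISK:
            survival *= compute_survival(outcome, costs)
        outcomes.append(outcome)
        times.append(t)
        total_time += t
    return Trajectory(
        outcomes=tuple(outcomes),
        times=tuple(times),
        T=total_time,
        G=state.g,
        survival=survival,
    )
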