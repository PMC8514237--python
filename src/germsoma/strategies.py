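"""Stochastic developmental strategies and their classification.

A developmental strategy is the evolvable trait of the model: six
probabilities governing the outcome of every cell division.  A dividing
germ-role cell produces two germ daughters, one germ and one soma daughter,
or two soma daughters with probabilities ``(ggg, ggs, gss)``; a dividing
soma-role cell analogously with ``(sgg, sgs, sss)``.  Each triple lives on a
2-simplex.  The strategy is static: the same probabilities apply at every
round of the life cycle.

Strategies fall into three classes:

* *no somatic differentiation* -- germ cells never produce soma (``ggg = 1``);
* *irreversible somatic differentiation* -- soma can arise from germ but can
  never produce germ (``ggg < 1`` and ``sss = 1``);
* *reversible somatic differentiation* -- both roles can produce each other
  (``ggg < 1`` and ``sss < 1``).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "DevelopmentalStrategy",
    "StrategyClass",
    "CLASS_PRECEDENCE",
    "classify",
    "classify_rows",
    "differentiation_rate",
    "differentiation_rate_rows",
    "strategy_grid",
]

#: tolerance for simplex-sum validation of externally supplied strategies
SIMPLEX_TOL = 1e-9

#: tolerance used when comparing a probability against 1 in classification of
#: non-grid (floating point) strategies; grid strategies hit 1.0 exactly
CLASSIFY_TOL = 1e-9


class StrategyClass(enum.Enum):
    """Classification of a developmental strategy."""

    NO_DIFFERENTIATION = "no_differentiation"
    REVERSIBLE = "reversible"
    IRREVERSIBLE = "irreversible"


#: Tie-break precedence used by the optimizer: when several strategies reach
#: statistically indistinguishable growth rates, the simpler class wins.  This
#: makes "irreversible differentiation is optimal" claims conservative under
#: Monte-Carlo noise.
CLASS_PRECEDENCE = {
    StrategyClass.NO_DIFFERENTIATION: 0,
    StrategyClass.REVERSIBLE: 1,
    StrategyClass.IRREVERSIBLE: 2,
}

# integer codes used in vectorised classification; order matches precedence
CLASS_CODES = {
    StrategyClass.NO_DIFFERENTIATION: 0,
    StrategyClass.REVERSIBLE: 1,
    StrategyClass.IRREVERSIBLE: 2,
}
CODE_TO_CLASS = {v: k for k, v in CLASS_CODES.items()}


@dataclass(frozen=True)
class DevelopmentalStrategy:
    """Six division-outcome probabilities ``(ggg, ggs, gss; sgg, sgs, sss)``.

    The first triple describes divisions of germ-role parents, the second
    divisions of soma-role parents.  Each triple must sum to one.
    """

    ggg: float
    ggs: float
    gss: float
    sgg: float
    sgs: float
    sss: float

    def __post_init__(self) -> None:
        probs = self.as_array()
        if np.any(probs < -SIMPLEX_TOL) or np.any(probs > 1 + SIMPLEX_TOL):
            raise ValueError(f"probabilities must lie in [0, 1], got {probs}")
        germ_sum = self.ggg + self.ggs + self.gss
        soma_sum = self.sgg + self.sgs + self.sss
        if abs(germ_sum - 1.0) > SIMPLEX_TOL or abs(soma_sum - 1.0) > SIMPLEX_TOL:
            raise ValueError(
                "division outcome probabilities must sum to 1 per parent type "
                f"(got germ sum {germ_sum!r}, soma sum {soma_sum!r})"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.ggg, self.ggs, self.gss, self.sgg, self.sgs, self.sss],
            dtype=float,
        )

    @classmethod
    def from_array(cls, values) -> "DevelopmentalStrategy":
        values = np.asarray(values, dtype=float)
        if values.shape != (6,):
            raise ValueError("expected six probabilities")
        return cls(*values.tolist())

    @classmethod
    def from_string(cls, text: str) -> "DevelopmentalStrategy":
        """Parse a comma-separated sextuple, e.g. ``"0.9,0.1,0,0,0,1"``."""
        parts = [float(p) for p in text.split(",")]
        return cls.from_array(parts)

    @property
    def germ_probs(self) -> tuple:
        return (self.ggg, self.ggs, self.gss)

    @property
    def soma_probs(self) -> tuple:
        return (self.sgg, self.sgs, self.sss)


def classify(strategy: DevelopmentalStrategy, tol: float = CLASSIFY_TOL) -> StrategyClass:
    """Classify a strategy as no-differentiation, irreversible or reversible.

    Equality with 1 is tested within ``tol``; grid-built strategies hit 1.0
    exactly, so any tolerance below the grid spacing gives exact results.
    """
    if strategy.ggg >= 1.0 - tol:
        return StrategyClass.NO_DIFFERENTIATION
    if strategy.sss >= 1.0 - tol:
        return StrategyClass.IRREVERSIBLE
    return StrategyClass.REVERSIBLE


def classify_rows(rows: np.ndarray, tol: float = CLASSIFY_TOL) -> np.ndarray:
    """Vectorised classification of an ``(S, 6)`` strategy array.

    Returns int8 codes per :data:`CLASS_CODES`.
    """
    rows = np.asarray(rows)
    codes = np.full(rows.shape[0], CLASS_CODES[StrategyClass.REVERSIBLE], dtype=np.int8)
    codes[rows[:, 5] >= 1.0 - tol] = CLASS_CODES[StrategyClass.IRREVERSIBLE]
    codes[rows[:, 0] >= 1.0 - tol] = CLASS_CODES[StrategyClass.NO_DIFFERENTIATION]
    return codes


def differentiation_rate(strategy: DevelopmentalStrategy) -> float:
    """Cumulative cell differentiation rate ``gss + ggs/2 + sgg + sgs/2``.

    The expected fraction of daughter cells whose role differs from their
    parent's, summed over the two parent types; lies in [0, 2] and is zero
    exactly when no differentiation can ever occur.
    """
    return strategy.gss + 0.5 * strategy.ggs + strategy.sgg + 0.5 * strategy.sgs


def differentiation_rate_rows(rows: np.ndarray) -> np.ndarray:
    rows = np.asarray(rows, dtype=float)
    return rows[:, 2] + 0.5 * rows[:, 1] + rows[:, 3] + 0.5 * rows[:, 4]


def _simplex_points(k: int) -> np.ndarray:
    """Lattice points of the 2-simplex with spacing 1/k, lexicographically
    ascending in (first, second) coordinate."""
    pts = []
    for i in range(k + 1):
        for j in range(k + 1 - i):
            pts.append((i / k, j / k, (k - i - j) / k))
    return np.array(pts, dtype=float)


def strategy_grid(step: float) -> np.ndarray:
    """Enumerate every strategy on the simplex-product lattice with the given
    spacing.

    ``step`` must equal ``1/k`` for an integer ``k >= 1``.  Returns an
    ``(S, 6)`` array with ``S = C(k+2, 2)**2`` rows, ordered lexicographically
    ascending by ``(ggg, ggs, gss, sgg, sgs, sss)``; the deterministic order
    fixes optimizer tie-breaking.
    """
    if step <= 0 or step > 1:
        raise ValueError("step must lie in (0, 1]")
    k = round(1.0 / step)
    if abs(1.0 / step - k) > 1e-9:
        raise ValueError(f"step must be 1/k for integer k, got {step}")
    pts = _simplex_points(k)
    m = len(pts)
    germ = np.repeat(pts, m, axis=0)
    soma = np.tile(pts, (m, 1))
    return np.hstack([germ, soma])
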