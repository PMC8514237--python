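"""Composition effect profiles: how soma-role cells shorten doubling time.

The composition effect ``Fcomp(x)`` multiplies the cell-doubling time as a
function of the soma fraction ``x = s / (s + g)``.  It is parameterised by
four numbers:

* ``x0`` -- contribution threshold: below this soma fraction, soma provides
  no benefit (``Fcomp = 1``);
* ``x1`` -- saturation threshold: above it, the benefit is maximal
  (``Fcomp = 1 - b``);
* ``b``  -- maximal benefit, the largest achievable reduction of the doubling
  time (``0 <= b < 1``; ``b = 1`` would allow a zero doubling time);
* ``alpha`` -- contribution synergy: between the thresholds the profile
  interpolates as ``1 - b + b * ((x1 - x) / (x1 - x0))**alpha``, convex
  (synergistic soma) for ``alpha > 1`` and concave (discounting) for
  ``alpha < 1``.

Random profiles stand in for "environments" in the screens: each profile is
one hypothetical way an organism could profit from vegetative cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CompositionProfile",
    "ProfileRanges",
    "DEFAULT_RANGES",
    "evaluate_fcomp",
    "sample_profile",
    "sample_profiles",
    "profiles_to_frame",
    "frame_to_profiles",
]


@dataclass(frozen=True)
class CompositionProfile:
    """Parameters ``(x0, x1, b, alpha)`` of the composition effect."""

    x0: float
    x1: float
    b: float
    alpha: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x0 <= self.x1 <= 1.0):
            raise ValueError(f"need 0 <= x0 <= x1 <= 1, got x0={self.x0}, x1={self.x1}")
        if not (0.0 <= self.b < 1.0):
            raise ValueError(f"need 0 <= b < 1, got b={self.b}")
        if not self.alpha > 0.0:
            raise ValueError(f"need alpha > 0, got alpha={self.alpha}")

    def __call__(self, x):
        return evaluate_fcomp(self, x)

    def as_tuple(self) -> tuple:
        return (self.x0, self.x1, self.b, self.alpha)


def evaluate_fcomp(profile: CompositionProfile, x):
    """Evaluate ``Fcomp`` at soma fraction(s) ``x`` in [0, 1].

    Piecewise: 1 on ``[0, x0]``; ``1 - b`` on ``[x1, 1]``;
    ``1 - b + b*((x1 - x)/(x1 - x0))**alpha`` in between.  Continuous at both
    thresholds.  When ``x0 == x1`` the first (closed) branch wins at the
    common point, so the profile is the step ``1 -> 1 - b``.
    """
    scalar = np.isscalar(x)
    x = np.asarray(x, dtype=float)
    if np.any(x < 0.0) or np.any(x > 1.0):
        raise ValueError("soma fraction x must lie in [0, 1]")
    x0, x1, b, alpha = profile.x0, profile.x1, profile.b, profile.alpha
    out = np.full(x.shape, 1.0 - b)
    out[x <= x0] = 1.0
    mid = (x > x0) & (x < x1)
    if np.any(mid):
        ratio = (x1 - x[mid]) / (x1 - x0)
        out[mid] = 1.0 - b + b * ratio**alpha
    return float(out) if scalar else out


@dataclass(frozen=True)
class ProfileRanges:
    """Sampling ranges for random composition effect profiles.

    Defaults: the two thresholds are the order statistics of two independent
    uniforms on ``[x_low, x_high]``; ``b`` is uniform on ``[b_low, b_high)``;
    ``alpha`` is log-uniform on ``[alpha_low, alpha_high]``.
    """

    x_low: float = 0.0
    x_high: float = 1.0
    b_low: float = 0.0
    b_high: float = 1.0
    alpha_low: float = 0.1
    alpha_high: float = 10.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_low < self.x_high <= 1.0):
            raise ValueError("degenerate threshold range")
        if not (0.0 <= self.b_low < self.b_high <= 1.0):
            raise ValueError("degenerate benefit range")
        if not (0.0 < self.alpha_low < self.alpha_high):
            raise ValueError("degenerate synergy range")


DEFAULT_RANGES = ProfileRanges()


def sample_profile(rng: np.random.Generator, ranges: ProfileRanges = DEFAULT_RANGES) -> CompositionProfile:
    """Draw one random profile; deterministic for a fixed generator state."""
    lo, hi = sorted(rng.uniform(ranges.x_low, ranges.x_high, size=2))
    b = rng.uniform(ranges.b_low, ranges.b_high)
    if b >= 1.0:  # uniform() upper bound is exclusive, but guard anyway
        b = np.nextafter(1.0, 0.0)
    alpha = float(np.exp(rng.uniform(np.log(ranges.alpha_low), np.log(ranges.alpha_high))))
    return CompositionProfile(x0=float(lo), x1=float(hi), b=float(b), alpha=alpha)


def sample_profiles(
    rng: np.random.Generator,
    count: int,
    ranges: ProfileRanges = DEFAULT_RANGES,
) -> list:
    if count < 1:
        raise ValueError("count must be >= 1")
    return [sample_profile(rng, ranges) for _ in range(count)]


def profiles_to_frame(profiles) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.x0, p.x1, p.b, p.alpha) for p in profiles],
        columns=["x0", "x1", "b", "alpha"],
    )


def frame_to_profiles(frame: pd.DataFrame) -> list:
    return [
        CompositionProfile(x0=row.x0, x1=row.x1, b=row.b, alpha=row.alpha)
        for row in frame.itertuples(index=False)
    ]
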