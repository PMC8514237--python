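# Methods

## Model

We model a large population of clonally developing organisms built from two
cell roles. *Germ-role* cells survive the end of the life cycle and each
founds a new organism; *soma-role* cells perform vegetative functions that
speed up growth and die at reproduction. An organism starts as a single
germ-role cell and performs `n` rounds of synchronous cell division, so it
reproduces at the maturity size `2^n`.

**Developmental strategy.** At every division the pair of daughter cells
takes one of three role combinations. A strategy is the sextuple
`D = (ggg, ggs, gss; sgg, sgs, sss)`: the probabilities of (germ,germ),
(germ,soma) and (soma,soma) daughters for a germ-role parent and a
soma-role parent respectively. The strategy is *static* (the same at every
round) and is the evolvable trait. Strategies classify as

| class | `ggg` | `sss` |
|---|---|---|
| no somatic differentiation | = 1 | irrelevant |
| irreversible somatic differentiation | < 1 | = 1 |
| reversible somatic differentiation | < 1 | < 1 |

**Round duration.** The duration of a division round is
`t = Fdiff × Fcomp`.

`Fdiff` is the differentiation cost averaged over the round's cells:
`Fdiff = 1 + [c_sg·(N_s→gs + 2 N_s→gg) + c_gs·(N_g→gs + 2 N_g→ss)] / N`,
where `N_g→gs` counts germ parents with one soma daughter, `N_g→ss` germ
parents with two (each switched daughter costs once, so a double switch
costs twice), analogously for soma parents, and `N` is the post-division
cell count. `c_gs`, `c_sg ≥ 0` are the germ-to-soma and soma-to-germ unit
costs, in units of the baseline doubling time.

`Fcomp(x) ∈ (0, 1]` is the composition effect of the soma fraction
`x = s/(g+s)`:

```
Fcomp(x) = 1                                   for 0 ≤ x ≤ x0
         = 1 − b + b·((x1 − x)/(x1 − x0))^α    for x0 < x < x1
         = 1 − b                               for x1 ≤ x ≤ 1
```

with contribution threshold `x0`, saturation threshold `x1` (`0 ≤ x0 ≤ x1 ≤ 1`),
maximal benefit `b ∈ [0, 1)` and contribution synergy `α > 0` (convex,
rapidly saturating benefit for `α > 1`). The exponent sits on the ratio:
this is the only placement that recovers the linear profile at
`(x0, x1, α) = (0, 1, 1)` and a power law at `α ≠ 1`, and makes `α` a
synergy/discounting shape parameter.

**Composition timing.** A modelling convention is required for *which*
composition enters a round's `Fcomp`: the composition present when the
round starts (PRE) or the one produced by the round's own divisions
(POST). We implement both as an explicit switch and default to **PRE**:
soma daughters begin contributing to growth in the round after the one
that created them, so the first round of every life cycle runs at
`Fcomp = 1`. Besides being the natural reading of "divide, then the new
composition applies", the choice is strongly constrained by the model's
own behaviour: under POST timing, exact trajectory enumeration shows
irreversible strategies already winning at 8–16 cells for ~1% of random
profiles at costs ≥ 3 (soma created in round one pays off immediately),
which collapses the maturity-size threshold that is the model's central
phenomenon; under PRE timing the threshold sits at 64 cells (below).

**Risky differentiation.** As an alternative cost mechanism, role
switching can carry a death risk instead of a delay: each differentiated
daughter cell independently kills the organism with probability `δ_gs`
(germ-to-soma) or `δ_sg` (soma-to-germ); `Fdiff ≡ 1`. A trajectory's
survival `S` is the product of `(1−δ)` factors over all differentiation
events, counted exactly as in `Fdiff` (a double switch counts twice).
Survival is carried as an analytic weight multiplying the offspring count,
not sampled — this is unbiased for the growth-rate equation and has lower
variance. At `δ = 0` the risky model is bitwise identical to the
zero-cost delay model under a shared random stream.

**Fitness.** Following the theory of populations with stochastic life
cycles, the population growth rate `λ` solves the generalised Euler–Lotka
equation over developmental trajectories `i`:

```
Σ_i  G_i · P_i · e^(−λ·T_i) = 1,
```

`G_i` = germ count at maturity (offspring number, weighted by survival in
the risky variant), `T_i` = summed round durations, `P_i` = trajectory
probability (a product of multinomial division-outcome probabilities).

## Numerics

**Two evaluation routes.** `exact_lambda` enumerates every trajectory with
its exact probability (zero-probability branches pruned; practical for
`n ≤ 3–4`, guarded by a trajectory cap) and is the oracle.
`estimate_lambda_mc` samples `M` trajectories once and solves the
empirical equation; the same sample is reused for every evaluation during
root finding (common random numbers), so the left-hand side is exactly
monotone and the estimate is deterministic given the seed. Its standard
error comes from the delta method:
`se(λ) = sd(Y)/(√M · mean(T·Y))` with `Y = w·e^(−λT)`.

**Root solving.** The left-hand side is strictly decreasing in `λ`, and
every trajectory `j` yields the bound `λ ≥ ln(w_j q_j)/T_j`, while the row
sum yields `λ ≤ ln(Σ w q)/T_min` (or `/T_max` for shrinking populations).
Within that analytic bracket a safeguarded Newton iteration (bisection
fallback; absolute tolerance `1e−6` on `λ`, `1e−5` in the float32 batch
path) cannot diverge. Strategies whose every sampled trajectory has zero
surviving offspring are reported extinct (`λ = −∞`), and negative roots
(sub-replacement strategies) are legitimate outputs.

**Batch engine.** Screens evaluate all `C(k+2,2)²` grid strategies at once
(4356 at the default simplex step 0.1, lexicographically ordered). Per
strategy, `M` trajectories are simulated by nested binomial draws and
reduced to per-round sufficient statistics: soma count, differentiation
event counts, final germ count. Because the trajectory time is *affine in
the two costs*, `T = U + c_gs·VA + c_sg·VB` with profile-dependent
per-trajectory sums `U, VA, VB`, one trajectory set and one per-profile
precomputation serve the whole cost axis; `Fcomp` is read from per-round
lookup tables indexed by the integer soma count. Growth rates for
neighbouring cost values warm-start the solver.

**Champion re-evaluation.** An argmax over thousands of Monte-Carlo
estimates is upward-biased, and the bias differs by class (4225 reversible
strategies vs 65 irreversible and 66 no-differentiation on the 0.1 grid),
so the raw winner is unreliable near class boundaries. The optimizer
therefore re-estimates the top 2 strategies of each class on independent
trajectory pools (`M = 3000`), escalating to `M = 20000` when the two
leading classes are within `0.01` of each other, and to `M = 150000`
(class leaders only) within `2.5e−3`. Pools are sampled lazily per
(seed, rounds, stage, strategy index) and cached, making the ladder cheap
and its results independent of evaluation order. Final class decisions in
the size sweeps are the plain argmax of these refined estimates
(`tie_tol = 0`): the borderline optima that define the maturity-size
threshold have true margins of order `1e−5`–`1e−3` (verified by exact
enumeration), far below any tie tolerance that could meaningfully be
applied. The qualitative cost-plane screens instead keep a conservative
tie rule (ties within `1e−4` resolved no-differentiation > reversible >
irreversible, then lexicographic), which is the right bias when counting
corner-region class fractions. Both knobs are exposed
(`tie_tol`, `RefineConfig`).

**Seeding.** All randomness descends from one master seed:
`default_rng([seed, n, stage])` for the grid pool, plus per-strategy
substreams for champion pools. Trajectory sets are shared across profiles
and cost values within a sweep (common random numbers): scenario results
are deterministic for a fixed configuration and mode-independent where the
models coincide (the `δ = 0` / `c = 0` bitwise equality is a test).

## Synthetic data: the profile sampler

Random composition effect profiles stand in for environments. Defaults:
`(x0, x1)` are the order statistics of two independent `U[0, 1]` draws,
`b ~ U[0, 1)`, `α` log-uniform on `[0.1, 10]` (median exactly 1). All
ranges are configurable and every screen records its sampler
configuration. The sampler covers profile space broadly and uniformly;
it does not emulate any measured distribution of real soma benefits, so
screen *fractions* (e.g. "x% of profiles promote irreversibility") are
statements about this prior over profiles, not about nature. The
threshold-type results (where irreversibility becomes possible at all) are
the robust outputs.

## Study protocols and scales

The canonical experiments (`germsoma.experiments`) run at desk scale:

* **Equal-cost size sweep** — sizes `2^2`–`2^8`, costs
  {0.03, 0.1, 0.3, 1, 3, 10} (half-decade log grid), `M = 300`,
  100 profiles per size with 300 at the 64-cell threshold size, where
  detection is a rare (~1% of profiles) event and power matters; at the
  smaller sizes the expected detection count is zero, which extra profiles
  would only confirm.
* **2:1-cost size sweep** (`c_sg = 2 c_gs`) — sizes `2^3`–`2^6`,
  300 profiles with 450 at the 32-cell threshold size, costs
  {0.03, 0.1, 0.3, 1, 1.5, 2.2, 3.3, 10}: the grid spans 0.03–10 and is
  refined to quarter-decade steps between 1 and 3.3, where margin analysis
  places the narrow band in which irreversible optima appear at 32 cells.
* **Cost/risk plane screens** — 4×4 planes ({0, 0.3, 2, 8} costs or
  {0, 0.1, 0.25, 0.5} risks), 50 profiles, maturity `2^6`.

Published analyses of this model use thousands of profiles, maturity
`2^10`, and finer cost planes; those scales are cluster-sized. At desk
scale the class-fraction estimates carry binomial noise of a few percent
and the rare-event detections (the 32-cell, ~1% result) are at the edge of
resolution — the acceptance checks treat them accordingly (binomial
confidence intervals; threshold equality).

## Known limitations

* Division is strictly synchronous; asynchronous division (each cell
  paying its own differentiation delay) is known to suppress irreversible
  differentiation and is out of scope here, though nothing in the
  trajectory representation precludes per-cell timing.
* Strategies are static; stage-dependent (dynamic) strategies are out of
  scope.
* `Fcomp` is committed to the four-parameter threshold/saturation family.
* Exact enumeration is exponential in `n`; beyond `n ≈ 4` only the
  Monte-Carlo route is available, so threshold decisions at large sizes
  are statistical, with the precision set by the champion ladder
  (standard errors of a few `1e−4`).
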