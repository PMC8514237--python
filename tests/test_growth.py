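import numpy as np
import pytest
from scipy.optimize import brentq

from germsoma.development import CompositionTiming, CostModel
from germsoma.growth import (
    GrowthStatus,
    estimate_lambda_mc,
    exact_lambda,
    solve_euler_lotka,
)
from germsoma.profiles import CompositionProfile, sample_profile
from germsoma.strategies import DevelopmentalStrategy

LN2 = np.log(2.0)
FLAT = CompositionProfile(0, 1, 0.0, 1.0)
LINEAR = CompositionProfile(0, 1, 0.5, 1.0)
NODIFF = DevelopmentalStrategy(1, 0, 0, 0, 0, 1)


class TestClosedForms:
    @pytest.mark.parametrize("n", [1, 3, 7])
    def test_no_differentiation_gives_ln2(self, n):
        """All trajectories are identical (G=2^n, T=n), so 2^n e^{-lam n}=1."""
        r = estimate_lambda_mc(
            NODIFF, LINEAR, CostModel.delay(4.0, 2.0), n=n, M=64, seed=0
        )
        assert r.lam == pytest.approx(LN2, abs=1e-9)
        assert r.status is GrowthStatus.OK
        ex = exact_lambda(NODIFF, LINEAR, CostModel.delay(4.0, 2.0), n=n)
        assert ex.lam == pytest.approx(LN2, abs=1e-9)
        assert ex.n_trajectories == 1

    def test_all_soma_is_extinct(self):
        d = DevelopmentalStrategy(0, 0, 1, 0, 0, 1)
        r = estimate_lambda_mc(d, LINEAR, CostModel.delay(0, 0), n=3, M=50, seed=0)
        assert r.status is GrowthStatus.EXTINCT
        assert r.lam == -np.inf
        ex = exact_lambda(d, LINEAR, CostModel.delay(0, 0), n=2)
        assert ex.status is GrowthStatus.EXTINCT

    def test_replacement_rate_is_zero(self):
        # forced g -> (g, s) division: G=1, T=1 => lam = 0
        d = DevelopmentalStrategy(0, 1, 0, 0, 0, 1)
        ex = exact_lambda(d, FLAT, CostModel.delay(0, 0), n=1)
        assert ex.lam == pytest.approx(0.0, abs=1e-9)

    def test_sub_replacement_negative(self):
        # G in {2, 0} with p=(0.4, 0.6): E[G]=0.8, T=1 => lam = ln 0.8 < 0
        d = DevelopmentalStrategy(0.4, 0, 0.6, 0, 0, 1)
        ex = exact_lambda(d, FLAT, CostModel.delay(0, 0), n=1)
        assert ex.lam == pytest.approx(np.log(0.8), abs=1e-9)
        assert ex.status is GrowthStatus.SUB_REPLACEMENT_NEGATIVE

    def test_risky_survival_weight(self):
        # forced single differentiation event with survival 0.9:
        # G=1, T=1, S=0.9 => lam = ln 0.9
        d = DevelopmentalStrategy(0, 1, 0, 0, 0, 1)
        ex = exact_lambda(d, FLAT, CostModel.risk(dgs=0.1, dsg=0.0), n=1)
        assert ex.lam == pytest.approx(np.log(0.9), abs=1e-9)


class TestExactEnumeration:
    def test_branching_hand_value(self):
        """g -> gg or gs with p=1/2 each, two rounds, no costs or benefits:
        every trajectory has T=2 and E[G]=1.5^2, so lam = ln(2.25)/2."""
        d = DevelopmentalStrategy(0.5, 0.5, 0, 0, 0, 1)
        ex = exact_lambda(d, FLAT, CostModel.delay(0, 0), n=2)
        assert ex.lam == pytest.approx(np.log(2.25) / 2, abs=1e-9)

    def test_against_independent_root_finder(self):
        """One round of g -> gg | gs with a composition benefit and a
        germ-to-soma cost; the two-trajectory equation is solved
        independently with scipy's brentq."""
        d = DevelopmentalStrategy(0.5, 0.5, 0, 0, 0, 1)
        ex = exact_lambda(
            d, LINEAR, CostModel.delay(cgs=1.0, csg=0.0), n=1,
            timing=CompositionTiming.POST,
        )
        # trajectories: (gg): G=2, T=1;  (gs): G=1, T=0.75*1.5=1.125
        f = lambda lam: 0.5 * 2 * np.exp(-lam) + 0.5 * np.exp(-1.125 * lam) - 1
        expected = brentq(f, -1, 2, xtol=1e-12)
        assert ex.lam == pytest.approx(expected, abs=1e-8)
        # under PRE timing the lone germ parent has x=0, so the composition
        # benefit does not yet apply: (gs) has T = 1.5 instead
        ex_pre = exact_lambda(d, LINEAR, CostModel.delay(cgs=1.0, csg=0.0), n=1)
        g = lambda lam: 0.5 * 2 * np.exp(-lam) + 0.5 * np.exp(-1.5 * lam) - 1
        assert ex_pre.lam == pytest.approx(brentq(g, -1, 2, xtol=1e-12), abs=1e-8)

    def test_probabilities_prune_but_sum_to_one(self):
        d = DevelopmentalStrategy(0.6, 0.2, 0.2, 0.1, 0.2, 0.7)
        ex = exact_lambda(d, LINEAR, CostModel.delay(0.5, 0.5), n=3)
        assert np.isfinite(ex.lam)
        assert ex.residual < 1e-9

    def test_enumeration_cap(self):
        d = DevelopmentalStrategy(0.3, 0.3, 0.4, 0.2, 0.4, 0.4)
        with pytest.raises(ValueError, match="cap"):
            exact_lambda(d, LINEAR, CostModel.delay(0, 0), n=3, cap=50)

    def test_scale_property(self):
        """Uniformly scaling every trajectory time by kappa divides the
        growth rate by kappa.  The strategy g->gs, s->gs keeps the soma
        fraction at 1/2 every round, so the benefit b scales all times."""
        d = DevelopmentalStrategy(0, 1, 0, 0, 1, 0)
        base = exact_lambda(
            d, FLAT, CostModel.delay(0, 0), n=3, timing=CompositionTiming.POST
        )
        scaled = exact_lambda(
            d, LINEAR, CostModel.delay(0, 0), n=3, timing=CompositionTiming.POST
        )
        kappa = 0.75  # Fcomp(1/2) under the linear profile
        assert scaled.lam * kappa == pytest.approx(base.lam, rel=1e-8)


class TestMonteCarloAgainstOracle:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_mc_within_three_standard_errors(self, seed):
        rng = np.random.default_rng(seed)
        probs = np.concatenate([rng.dirichlet([1, 1, 1]), rng.dirichlet([1, 1, 1])])
        d = DevelopmentalStrategy.from_array(probs)
        profile = sample_profile(rng)
        costs = CostModel.delay(*rng.uniform(0, 2, size=2))
        n = int(rng.integers(1, 4))
        ex = exact_lambda(d, profile, costs, n)
        mc = estimate_lambda_mc(d, profile, costs, n, M=20_000, rng=rng)
        if ex.status is GrowthStatus.EXTINCT:
            assert mc.status is GrowthStatus.EXTINCT
        else:
            assert mc.std_error is not None
            assert abs(mc.lam - ex.lam) < 3 * mc.std_error + 1e-6

    def test_mc_matches_oracle_in_post_timing_too(self):
        d = DevelopmentalStrategy(0.6, 0.3, 0.1, 0.2, 0.2, 0.6)
        ex = exact_lambda(
            d, LINEAR, CostModel.delay(0.5, 0.5), n=2, timing=CompositionTiming.POST
        )
        mc = estimate_lambda_mc(
            d, LINEAR, CostModel.delay(0.5, 0.5), n=2, M=20_000, seed=8,
            timing=CompositionTiming.POST,
        )
        assert abs(mc.lam - ex.lam) < 3 * mc.std_error + 1e-6

    def test_deterministic_under_seed(self):
        d = DevelopmentalStrategy(0.6, 0.3, 0.1, 0.1, 0.1, 0.8)
        a = estimate_lambda_mc(d, LINEAR, CostModel.delay(1, 1), n=4, M=500, seed=42)
        b = estimate_lambda_mc(d, LINEAR, CostModel.delay(1, 1), n=4, M=500, seed=42)
        assert a.lam == b.lam


class TestSolver:
    def test_row_wise_roots_and_extinct_rows(self):
        # row 0: w=2, T=1 => lam = ln 2; row 1: all zero weights => extinct
        w = np.array([[2.0, 2.0], [0.0, 0.0]])
        T = np.array([[1.0, 1.0], [1.0, 2.0]])
        lam, info = solve_euler_lotka(w, T, tol=1e-10)
        assert lam[0] == pytest.approx(LN2, abs=1e-9)
        assert lam[1] == -np.inf
        assert info["extinct"][1]

    def test_weighted_trajectory_probabilities(self):
        # 0.25 * 4 * e^-lam + 0.75 * 1 * e^-lam = 1 => lam = ln(1.75)
        w = np.array([[4.0, 1.0]])
        T = np.array([[1.0, 1.0]])
        q = np.array([[0.25, 0.75]])
        lam, _ = solve_euler_lotka(w, T, traj_prob=q, tol=1e-10)
        assert lam[0] == pytest.approx(np.log(1.75), abs=1e-9)

    def test_warm_start_agrees_with_cold_start(self):
        rng = np.random.default_rng(5)
        w = rng.integers(0, 20, (50, 200)).astype(float)
        T = rng.uniform(2, 10, (50, 200))
        cold, _ = solve_euler_lotka(w, T, tol=1e-8)
        warm, _ = solve_euler_lotka(w, T, tol=1e-8, lam0=cold + 0.3)
        finite = np.isfinite(cold)
        assert np.allclose(cold[finite], warm[finite], atol=1e-6)
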