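import numpy as np
import pytest

from germsoma.development import (
    CompositionTiming,
    CostModel,
    CostMode,
    OrganismState,
    RoundOutcome,
    compute_fdiff,
    compute_round_time,
    compute_survival,
    sample_round_outcome,
    simulate_trajectory,
)
from germsoma.profiles import CompositionProfile
from germsoma.strategies import DevelopmentalStrategy

FLAT = CompositionProfile(0, 1, 0.0, 1.0)  # b=0: no composition effect
LINEAR = CompositionProfile(0, 1, 0.5, 1.0)


def outcome(n_gg=0, n_gs=0, n_ss=0, m_gg=0, m_gs=0, m_ss=0):
    return RoundOutcome(n_gg, n_gs, n_ss, m_gg, m_gs, m_ss)


class TestRoundOutcomeSampling:
    def test_deterministic_strategies(self):
        rng = np.random.default_rng(0)
        out = sample_round_outcome(
            OrganismState(1, 0, 0), DevelopmentalStrategy(1, 0, 0, 0, 0, 1), rng
        )
        assert out == outcome(n_gg=1)
        out = sample_round_outcome(
            OrganismState(0, 4, 2), DevelopmentalStrategy(1, 0, 0, 0, 0, 1), rng
        )
        assert out == outcome(m_ss=4)

    def test_counts_conserve_parents(self):
        rng = np.random.default_rng(1)
        d = DevelopmentalStrategy(0.3, 0.3, 0.4, 0.2, 0.5, 0.3)
        out = sample_round_outcome(OrganismState(40, 24, 6), d, rng)
        assert out.germ_parents == 40
        assert out.soma_parents == 24
        assert out.daughters_germ + out.daughters_soma == 2 * 64

    def test_binomial_mean(self):
        """With (ggg, ggs) = (0.5, 0.5) and 64 germ parents the expected
        number of mixed divisions is 32."""
        rng = np.random.default_rng(2)
        d = DevelopmentalStrategy(0.5, 0.5, 0, 0, 0, 1)
        means = [
            sample_round_outcome(OrganismState(64, 0, 6), d, rng).n_gs
            for _ in range(3000)
        ]
        # se of the mean is 4/sqrt(3000) ~ 0.073; allow ~5 sigma
        assert abs(np.mean(means) - 32.0) < 0.4


class TestFdiff:
    def test_no_differentiation_is_free(self):
        c = CostModel.delay(cgs=3.0, csg=7.0)
        assert compute_fdiff(outcome(n_gg=5, m_ss=3), c) == 1.0

    @pytest.mark.parametrize(
        "out, cgs, csg, expected",
        [
            (outcome(n_gs=1), 1.0, 0.0, 1.5),  # one germ->gs event, N=2
            (outcome(n_ss=1), 1.0, 0.0, 2.0),  # both daughters switch, N=2
            (outcome(n_ss=1, m_gg=1), 1.0, 1.0, 2.0),  # N=4: 1+(2+2)/4
            (outcome(n_gg=2, m_gs=1, m_ss=1), 0.0, 2.0, 1.25),  # 1 + 2*1/8
        ],
    )
    def test_averaged_cost(self, out, cgs, csg, expected):
        assert compute_fdiff(out, CostModel.delay(cgs=cgs, csg=csg)) == pytest.approx(expected)

    def test_rejected_in_risk_mode(self):
        with pytest.raises(ValueError):
            compute_fdiff(outcome(n_gg=1), CostModel.risk(0.1, 0.1))


class TestSurvival:
    @pytest.mark.parametrize(
        "out, dgs, dsg, expected",
        [
            (outcome(n_gg=3, m_ss=2), 0.5, 0.5, 1.0),  # no events
            (outcome(n_gs=1), 0.1, 0.0, 0.9),  # one event
            (outcome(n_ss=1), 0.1, 0.0, 0.81),  # two daughter events
            (outcome(m_gg=1, m_gs=1), 0.0, 0.2, 0.8**3),
        ],
    )
    def test_per_event_risk(self, out, dgs, dsg, expected):
        assert compute_survival(out, CostModel.risk(dgs=dgs, dsg=dsg)) == pytest.approx(expected)

    def test_rejected_in_delay_mode(self):
        with pytest.raises(ValueError):
            compute_survival(outcome(n_gg=1), CostModel.delay(1, 1))


class TestRoundTime:
    def test_no_differentiation_all_germ(self):
        out = outcome(n_gg=1)
        t = compute_round_time(out, OrganismState(1, 0, 0), FLAT, CostModel.delay(5, 5))
        assert t == 1.0
        t = compute_round_time(
            out, OrganismState(2, 0, 1), FLAT, CostModel.delay(5, 5),
            CompositionTiming.POST,
        )
        assert t == 1.0

    def test_post_timing_composes_both_factors(self):
        # under POST timing the fresh soma daughter already shortens the
        # round that created it: Fdiff=1.5, Fcomp(0.5)=0.75
        out = outcome(n_gs=1)
        t = compute_round_time(
            out, OrganismState(1, 1, 1), LINEAR, CostModel.delay(cgs=1, csg=0),
            CompositionTiming.POST,
        )
        assert t == pytest.approx(1.5 * 0.75)

    def test_pre_timing_uses_parent_composition(self):
        # same division, PRE timing: the single germ parent has x=0, so only
        # the differentiation cost acts this round
        out = outcome(n_gs=1)
        t = compute_round_time(
            out, OrganismState(1, 0, 0), LINEAR, CostModel.delay(cgs=1, csg=0)
        )
        assert t == pytest.approx(1.5)
        # from a mixed parent state (1 germ + 1 soma): Fcomp(0.5) applies
        out2 = outcome(n_gs=1, m_ss=1)
        t2 = compute_round_time(
            out2, OrganismState(1, 1, 1), LINEAR, CostModel.delay(cgs=1, csg=0)
        )
        assert t2 == pytest.approx(0.75 * (1 + 1 / 4))

    def test_risk_mode_drops_delay_factor(self):
        out = outcome(n_gs=1)
        t = compute_round_time(
            out, OrganismState(1, 1, 1), LINEAR, CostModel.risk(0.3, 0.3),
            CompositionTiming.POST,
        )
        assert t == pytest.approx(0.75)

    def test_inconsistent_state_rejected(self):
        with pytest.raises(ValueError):
            compute_round_time(
                outcome(n_gs=1), OrganismState(2, 0, 1), LINEAR, CostModel.delay(0, 0)
            )
        with pytest.raises(ValueError):
            compute_round_time(
                outcome(n_gs=1), OrganismState(2, 0, 1), LINEAR,
                CostModel.delay(0, 0), CompositionTiming.POST,
            )

    def test_monotone_in_costs_for_fixed_outcome(self):
        out = outcome(n_gs=2, n_gg=1, m_gs=1, m_ss=4)  # 8 parents
        state = OrganismState(3, 5, 3)
        times = [
            compute_round_time(out, state, LINEAR, CostModel.delay(cgs=c, csg=0.5))
            for c in (0.0, 0.5, 1.0, 2.0)
        ]
        assert all(a <= b for a, b in zip(times, times[1:]))


class TestTrajectory:
    def test_all_germ_development(self):
        d = DevelopmentalStrategy(1, 0, 0, 0, 0, 1)
        traj = simulate_trajectory(d, LINEAR, CostModel.delay(3, 3), 10, np.random.default_rng(0))
        assert traj.G == 1024
        assert traj.T == pytest.approx(10.0)
        assert traj.survival == 1.0

    def test_all_soma_first_round_goes_extinct(self):
        d = DevelopmentalStrategy(0, 0, 1, 0, 0, 1)
        traj = simulate_trajectory(d, LINEAR, CostModel.delay(0, 0), 4, np.random.default_rng(0))
        assert traj.G == 0

    def test_forced_single_differentiation(self):
        d = DevelopmentalStrategy(0, 1, 0, 0, 0, 1)
        traj = simulate_trajectory(d, FLAT, CostModel.delay(cgs=0, csg=0), 1, np.random.default_rng(0))
        assert traj.G == 1 and traj.T == pytest.approx(1.0)

    def test_cell_count_doubles_every_round(self):
        d = DevelopmentalStrategy(0.4, 0.3, 0.3, 0.2, 0.3, 0.5)
        traj = simulate_trajectory(d, LINEAR, CostModel.delay(1, 1), 6, np.random.default_rng(3))
        for k, out in enumerate(traj.outcomes):
            assert out.germ_parents + out.soma_parents == 2**k
            assert out.daughters_germ + out.daughters_soma == 2 ** (k + 1)

    def test_zero_cost_flat_profile_gives_T_equals_n(self):
        d = DevelopmentalStrategy(0.4, 0.3, 0.3, 0.2, 0.3, 0.5)
        traj = simulate_trajectory(d, FLAT, CostModel.delay(0, 0), 7, np.random.default_rng(4))
        assert traj.T == pytest.approx(7.0)

    def test_zero_risk_matches_zero_cost_stream(self):
        """With the same generator state, the risky model at zero risk and
        the delay model at zero cost give identical trajectories."""
        d = DevelopmentalStrategy(0.5, 0.3, 0.2, 0.1, 0.4, 0.5)
        t1 = simulate_trajectory(d, LINEAR, CostModel.delay(0, 0), 6, np.random.default_rng(9))
        t2 = simulate_trajectory(d, LINEAR, CostModel.risk(0, 0), 6, np.random.default_rng(9))
        assert t1.outcomes == t2.outcomes
        assert t1.times == t2.times
        assert t1.G == t2.G and t1.survival == t2.survival == 1.0

    def test_invalid_round_count(self):
        d = DevelopmentalStrategy(1, 0, 0, 0, 0, 1)
        with pytest.raises(ValueError):
            simulate_trajectory(d, FLAT, CostModel.delay(0, 0), 0, np.random.default_rng(0))


def test_cost_model_validation():
    with pytest.raises(ValueError):
        CostModel.delay(-1, 0)
    with pytest.raises(ValueError):
        CostModel.risk(1.5, 0)
    assert CostModel.delay(1, 2).mode is CostMode.DELAY
    assert CostModel.risk(0.1, 0.2).mode is CostMode.RISK


def test_trajectory_records_roundtrip():
    from germsoma.development import trajectory_records

    d = DevelopmentalStrategy(0.5, 0.3, 0.2, 0.1, 0.2, 0.7)
    traj = simulate_trajectory(d, LINEAR, CostModel.delay(1, 1), 4, np.random.default_rng(6))
    rows = trajectory_records(traj)
    assert len(rows) == 4
    assert rows[-1]["germ"] == traj.G
    assert sum(r["time"] for r in rows) == pytest.approx(traj.T)
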