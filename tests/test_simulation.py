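"""Unit and property tests of the kinetic Monte Carlo spindle core."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from scipy.integrate import quad

from spindlesim import (SimParams, advance_timestep, check_collapse,
                        init_spindle, midzone_coordinate, neighbour_census,
                        pole_loss_probability, reorganize_lattice,
                        rescue_rate, run_simulation, sample_growth_duration,
                        wild_type_params)
from spindlesim.simulation import (GROWING, LEFT, RIGHT, SHRINKING,
                                   Microtubule, SpindleState)


def brute_force_pairs(mts):
    """Exhaustive antiparallel-pair enumeration (independent oracle)."""
    pairs = 0
    per_mt = {m.mt_id: 0 for m in mts}
    for a, b in itertools.combinations(mts, 2):
        (r1, c1), (r2, c2) = a.site, b.site
        if abs(r1 - r2) + abs(c1 - c2) == 1 and a.pole != b.pole:
            pairs += 1
            per_mt[a.mt_id] += 1
            per_mt[b.mt_id] += 1
    return per_mt, pairs


def make_state(mts, S=6.0, Lm=1.23, t=0.0, grid=(3, 3)):
    state = SpindleState(t=t, S=S, Lm=Lm, mts=mts, grid_shape=grid)
    state.refresh_census()
    return state


class TestInitialState:
    def test_chequerboard_geometry(self, rng):
        state = init_spindle(wild_type_params(), rng)
        assert len(state.mts) == 9
        assert state.S == 4.0
        assert all(m.length == 3.0 and m.state == GROWING for m in state.mts)
        assert all(m.tau_c > 0 for m in state.mts)
        by_pole = {LEFT: 0, RIGHT: 0}
        for m in state.mts:
            by_pole[m.pole] += 1
        assert sorted(by_pole.values()) == [4, 5]
        assert state.N_pairs == 12  # full 3x3 chequerboard

    def test_same_seed_identical(self):
        p = wild_type_params()
        s1 = init_spindle(p, np.random.default_rng(5))
        s2 = init_spindle(p, np.random.default_rng(5))
        assert s1.Lm == s2.Lm
        assert [(m.site, m.pole, m.tau_c) for m in s1.mts] == \
               [(m.site, m.pole, m.tau_c) for m in s2.mts]

    def test_midzone_length_distribution(self, rng):
        p = wild_type_params()
        draws = [init_spindle(p, rng).Lm for _ in range(4000)]
        assert np.mean(draws) == pytest.approx(1.23, abs=0.02)
        assert min(draws) > 0


class TestGrowthDurationSampler:
    def test_exponential_special_case(self, fixed_uniform):
        t = sample_growth_duration(1.0, 1.0, fixed_uniform([0.5]))
        assert t == pytest.approx(math.log(2), rel=1e-12)

    def test_wild_type_median_point(self, fixed_uniform):
        # numeric inversion of (1 - exp(-3.17 t))^8.53 = 0.5
        t = sample_growth_duration(3.17, 8.53, fixed_uniform([0.5]))
        assert t == pytest.approx(0.8046, abs=1e-3)

    def test_degenerate_uniform_resampled(self, fixed_uniform):
        t = sample_growth_duration(1.0, 1.0, fixed_uniform([0.0, 1.0, 0.5]))
        assert t == pytest.approx(math.log(2), rel=1e-12)

    def test_mean_matches_survival_quadrature(self, rng):
        theta, n = 3.17, 8.53
        samples = np.array([sample_growth_duration(theta, n, rng)
                            for _ in range(100_000)])
        mean_oracle, _ = quad(
            lambda t: 1.0 - (1.0 - math.exp(-theta * t)) ** n, 0, np.inf)
        assert samples.mean() == pytest.approx(mean_oracle, rel=0.01)

    def test_distribution_matches_cdf(self, rng):
        theta, n = 3.17, 8.53
        samples = [sample_growth_duration(theta, n, rng)
                   for _ in range(100_000)]
        stat = stats.kstest(
            samples, lambda t: (1.0 - np.exp(-theta * t)) ** n).statistic
        assert stat < 0.01


class TestMidzoneCoordinate:
    def make(self, S=6.0, Lm=1.0):
        mt = Microtubule(0, LEFT, (0, 0), length=S / 2.0)
        return make_state([mt], S=S, Lm=Lm), mt

    def test_center_maps_to_half(self):
        state, mt = self.make()
        assert midzone_coordinate(state, mt) == pytest.approx(0.5)

    def test_near_edge_is_zero_far_edge_is_one(self):
        state, mt = self.make()
        mt.length = state.S / 2.0 - state.Lm / 2.0  # tip at -Lm/2
        assert midzone_coordinate(state, mt) == pytest.approx(0.0)
        right = Microtubule(1, RIGHT, (0, 1),
                            length=state.S / 2.0 + state.Lm / 2.0)
        # right-pole tip at lab -Lm/2 = far edge for that orientation
        assert midzone_coordinate(state, right) == pytest.approx(1.0)

    def test_outside_midzone_is_none(self):
        state, mt = self.make()
        mt.length = 1.0
        assert midzone_coordinate(state, mt) is None


class TestRescueRate:
    def _state_with_neighbours(self, alpha, beta, x):
        # centre microtubule of a full chequerboard has 4 neighbours, N=12
        params = SimParams(alpha=alpha, beta=beta)
        state = init_spindle(params, np.random.default_rng(0))
        state.S = 6.0
        state.Lm = 1.23
        centre = next(m for m in state.mts if m.site == (1, 1))
        centre.state = SHRINKING
        centre.length = state.S / 2.0 + (x - 0.5) * state.Lm
        return state, centre, params

    def test_flat_field_closed_form(self):
        state, mt, params = self._state_with_neighbours(1.0, 1.0, 0.4)
        ctx = rescue_rate(state, mt, params)
        assert ctx.n_neighbours == 4 and ctx.N_pairs == 12
        assert ctx.rate == pytest.approx(4 * 55 / (1.23 * 12), rel=1e-9)

    def test_beta_4_2_closed_form(self):
        state, mt, params = self._state_with_neighbours(4.0, 2.0, 0.75)
        ctx = rescue_rate(state, mt, params)
        assert ctx.p_density == pytest.approx(20 * 0.75 ** 3 * 0.25, rel=1e-9)
        assert ctx.rate == pytest.approx(
            4 * 55 * 2.109375 / (1.23 * 12), rel=1e-6)

    def test_no_neighbours_no_rescue(self):
        mt = Microtubule(0, LEFT, (0, 0), length=3.0, state=SHRINKING)
        state = make_state([mt], S=6.0)
        assert rescue_rate(state, mt, SimParams()).rate == 0.0

    def test_uniform_variant_rate(self):
        mts = [Microtubule(0, LEFT, (0, 0), length=3.0, state=SHRINKING),
               Microtubule(1, RIGHT, (0, 1), length=5.0)]
        state = make_state(mts, S=6.0)
        params = SimParams(variant="uniform", R=34.0)
        ctx = rescue_rate(state, mts[0], params)
        assert ctx.rate == pytest.approx(34.0 / (2 * 8.0))


class TestNeighbourCensus:
    def test_full_board_counts(self, rng):
        state = init_spindle(wild_type_params(), rng)
        counts, n_pairs = neighbour_census(state)
        by_site = {m.site: counts[m.mt_id] for m in state.mts}
        assert by_site[(1, 1)] == 4
        assert by_site[(0, 0)] == 2
        assert n_pairs == 12
        assert sum(counts.values()) == 2 * n_pairs

    def test_removing_centre_decrements_edges(self, rng):
        state = init_spindle(wild_type_params(), rng)
        before, _ = neighbour_census(state)
        edge_ids = [m.mt_id for m in state.mts
                    if m.site in {(0, 1), (1, 0), (1, 2), (2, 1)}]
        state.mts = [m for m in state.mts if m.site != (1, 1)]
        after, _ = neighbour_census(state)
        for mt_id in edge_ids:
            assert after[mt_id] == before[mt_id] - 1

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 3), st.integers(0, 3),
                              st.booleans()),
                    min_size=0, max_size=16, unique_by=lambda t: t[:2]))
    def test_matches_exhaustive_enumeration(self, occupancy):
        mts = [Microtubule(i, LEFT if left else RIGHT, (r, c), length=1.0)
               for i, (r, c, left) in enumerate(occupancy)]
        state = make_state(mts, grid=(4, 4))
        counts, n_pairs = neighbour_census(state)
        oracle_counts, oracle_pairs = brute_force_pairs(mts)
        assert counts == oracle_counts
        assert n_pairs == oracle_pairs


class TestReorganizeLattice:
    def test_identity_when_no_improving_move(self, rng):
        state = init_spindle(wild_type_params(), rng)
        assert reorganize_lattice(state) == []

    def test_corner_moves_into_vacated_centre(self, rng):
        state = init_spindle(wild_type_params(), rng)
        centre = next(m for m in state.mts if m.site == (1, 1))
        state.mts.remove(centre)
        state.refresh_census()
        moves = reorganize_lattice(state)
        assert moves, "an improving move exists"
        mt_id, old, new = moves[0]
        moved = next(m for m in state.mts if m.mt_id == mt_id)
        # a same-orientation corner microtubule takes the centre (gain 4-2)
        assert new == (1, 1)
        assert moved.pole == centre.pole
        assert old in {(0, 0), (0, 2), (2, 0), (2, 2)}

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 2), st.integers(0, 2),
                              st.booleans()),
                    min_size=1, max_size=8, unique_by=lambda t: t[:2]))
    def test_never_decreases_pairs_and_converges(self, occupancy):
        mts = [Microtubule(i, LEFT if left else RIGHT, (r, c), length=1.0)
               for i, (r, c, left) in enumerate(occupancy)]
        state = make_state(mts)
        before = state.N_pairs
        reorganize_lattice(state)
        assert state.N_pairs >= before
        # converged: no further improving move
        assert reorganize_lattice(state) == []


class TestAdvanceTimestep:
    def test_pole_kinematics_exact(self, rng):
        params = wild_type_params()
        state = init_spindle(params, rng)
        advance_timestep(state, params, rng, step_index=1)
        assert state.S == 4.0 + 2 * 0.35 * 0.01

    def test_zero_rate_never_rescues(self, rng):
        params = wild_type_params(R=0.0)
        mts = [Microtubule(0, LEFT, (0, 0), length=3.0, state=SHRINKING),
               Microtubule(1, RIGHT, (0, 1), length=3.5)]
        state = make_state(mts, S=4.0)
        for i in range(50):
            events = advance_timestep(state, params, rng, step_index=i + 1)
            assert not any(e.kind == "rescue" for e in events)

    def test_rescue_frequency_matches_rate(self):
        # hold a shrinking microtubule at constant rate r and count
        # per-step rescues against the Bernoulli probability 1-exp(-r h)
        params = SimParams(alpha=1.0, beta=1.0, v_d=1e-9, v_s=1e-9)
        rng = np.random.default_rng(77)
        n_trials, n_resc = 100_000, 0
        state = init_spindle(params, rng)
        state.S, state.Lm = 6.0, 1.23
        centre = next(m for m in state.mts if m.site == (1, 1))
        r = rescue_rate(state, centre, params)
        for _ in range(n_trials):
            centre.state = SHRINKING
            centre.length = state.S / 2.0  # tip at centre, x = 0.5
            events = advance_timestep(state, params, rng)
            state.t, state.S = 0.0, 6.0  # freeze geometry
            if any(e.kind == "rescue" and e.mt_id == centre.mt_id
                   for e in events):
                n_resc += 1
        rate = 4 * 55 / (1.23 * 12)
        p_expected = 1.0 - math.exp(-rate * params.h)
        se = math.sqrt(p_expected * (1 - p_expected) / n_trials)
        assert n_resc / n_trials == pytest.approx(p_expected, abs=4 * se)

    def test_tip_clipped_at_pole_then_catastrophe(self, rng):
        params = wild_type_params()
        mts = [Microtubule(0, LEFT, (0, 0), length=3.99, tau_c=10.0),
               Microtubule(1, RIGHT, (0, 1), length=3.0, tau_c=10.0)]
        state = make_state(mts, S=4.0)
        for i in range(1, 10):
            events = advance_timestep(state, params, rng, step_index=i)
            assert mts[0].length <= state.S
            if any(e.kind == "catastrophe" and e.mt_id == 0 for e in events):
                assert mts[0].state == SHRINKING
                break
        else:
            pytest.fail("tip never reached the opposite pole")


class TestCollapse:
    def test_overlap_rules(self):
        a = Microtubule(0, LEFT, (0, 0), length=3.5)
        b = Microtubule(1, RIGHT, (0, 1), length=3.0)
        assert not check_collapse(make_state([a, b], S=6.0))
        a.length = 2.9
        assert check_collapse(make_state([a, b], S=6.0))

    def test_empty_pole_collapses(self):
        b = Microtubule(1, RIGHT, (0, 1), length=5.0)
        assert check_collapse(make_state([b], S=6.0))


class TestRunSimulation:
    def test_bit_identical_event_logs(self, wt_params):
        t1 = run_simulation(wt_params, seed=42)
        t2 = run_simulation(wt_params, seed=42)
        assert [(e.kind, e.t, e.mt_id, e.pos_signed) for e in t1.events] == \
               [(e.kind, e.t, e.mt_id, e.pos_signed) for e in t2.events]
        assert np.array_equal(t1.spindle_length, t2.spindle_length)

    def test_no_rescue_budget_always_collapses(self):
        params = wild_type_params(R=0.0)
        for seed in range(5):
            assert run_simulation(params, seed).collapsed

    def test_rescues_confined_to_midzone_and_lengths_bounded(self, wt_params):
        traj = run_simulation(wt_params, seed=3)
        for e in traj.events:
            if e.kind == "rescue":
                assert abs(e.pos_signed) <= traj.Lm / 2 + 1e-12
        for snap, S in zip(traj.mt_snapshots, traj.spindle_length):
            for _id, _pole, length, _state in snap:
                assert 0.0 <= length <= S + 1e-12

    def test_exact_elongation_kinematics(self, wt_params):
        traj = run_simulation(wt_params, seed=9)
        expected = 4.0 + 2 * 0.35 * traj.times
        assert np.array_equal(traj.spindle_length, expected)


class TestRescueBudgetConservation:
    @pytest.mark.parametrize("alpha,beta", [(1.0, 1.0), (4.0, 2.0),
                                            (12.0, 2.0)])
    def test_midzone_integral_is_2R(self, alpha, beta, rng):
        params = SimParams(alpha=alpha, beta=beta)
        state = init_spindle(params, rng)
        state.S = 7.0
        # integrate r over all tip positions in the midzone for each MT
        total = 0.0
        for mt in state.mts:
            def r_of_tip(q, mt=mt):
                mt.length = state.S / 2.0 + q
                return rescue_rate(state, mt, params).rate
            val, _ = quad(r_of_tip, -state.Lm / 2, state.Lm / 2,
                          limit=200, epsabs=1e-12, epsrel=1e-10)
            total += val
        assert total == pytest.approx(2 * params.R, rel=1e-6)

    def test_uniform_integral_is_half_R(self, rng):
        params = SimParams(variant="uniform", R=34.0)
        state = init_spindle(params, rng)
        # r is constant R/(2 Lt); integrating over every microtubule's
        # length gives R/2
        Lt = state.polymer()
        total = sum(rescue_rate(state, m, params).rate * m.length
                    for m in state.mts)
        assert Lt > 0
        assert total == pytest.approx(params.R / 2, rel=1e-9)


def test_pole_loss_enumeration_matches_closed_form():
    # enumeration over all 2^9 outcomes reproduces p^4 + p^5
    assert pole_loss_probability(4, 5, 0.5) == pytest.approx(
        1 / 2 ** 4 + 1 / 2 ** 5, rel=1e-12)
    assert pole_loss_probability(3, 3, 0.3) == pytest.approx(
        2 * 0.3 ** 3, rel=1e-9)
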