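import numpy as np
import pytest
from scipy import stats as sps

from cryptoswarm import (
    InfluenceNetwork,
    SearchParams,
    build_network,
    cost,
    init_population,
    run_search,
    run_trial,
    update_agent,
)
from cryptoswarm.dynamics import _spawn_streams, count_change_events

from conftest import DONALD_SOLUTION


class TestSearchParams:
    def test_valid(self):
        SearchParams(N=10, p=0.5, K=9, seed=0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(N=0),
            dict(N=5, p=-0.1),
            dict(N=5, p=1.5),
            dict(N=5, p=0.5, K=0),  # p > 0 needs K >= 1
            dict(N=1, p=0.5, K=1),  # p > 0 needs N >= 2
            dict(N=5, p=0.0, K=5),  # K > N-1
            dict(N=5, max_trials=0),
            dict(N=5, move_kind="teleport"),
        ],
    )
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            SearchParams(**kwargs)


class TestUpdateAgent:
    def test_p0_always_moves(self, small3, rng):
        net = build_network(4, 0, rng)
        state = init_population(small3, 4, rng)
        params = SearchParams(N=4, p=0.0, K=0, seed=0)
        outcomes = {update_agent(i, small3, net, state, params, rng)
                    for i in range(4) for _ in range(5)}
        assert outcomes == {"moved"}

    def test_cheaper_target_wastes(self, donald, rng):
        net = InfluenceNetwork(np.array([[1], [0]]))
        state = init_population(donald, 2, rng)
        state.assignments[0] = donald.assignment_from_map(DONALD_SOLUTION)
        state.refresh_cost(donald, 0)
        assert state.costs[0] == 0 < state.costs[1]
        params = SearchParams(N=2, p=1.0, K=1, seed=0)
        before = state.assignments[0].copy()
        assert update_agent(0, donald, net, state, params, rng) == "wasted"
        assert np.array_equal(state.assignments[0], before)

    def test_identical_to_model_wastes(self, donald, rng):
        net = InfluenceNetwork(np.array([[1], [0]]))
        state = init_population(donald, 2, rng)
        state.assignments[1] = state.assignments[0].copy()
        state.refresh_cost(donald, 1)
        params = SearchParams(N=2, p=1.0, K=1, seed=0)
        assert update_agent(0, donald, net, state, params, rng) == "wasted"

    def test_imitation_copies_and_keeps_cache_coherent(self, donald, rng):
        net = InfluenceNetwork(np.array([[1], [0]]))
        state = init_population(donald, 2, rng)
        state.assignments[1] = donald.assignment_from_map(DONALD_SOLUTION)
        state.refresh_cost(donald, 1)
        params = SearchParams(N=2, p=1.0, K=1, seed=0)
        out = update_agent(0, donald, net, state, params, rng)
        assert out == "imitated"
        assert state.costs[0] == cost(donald, state.assignments[0])

    def test_equal_cost_different_string_copies(self, donald, rng):
        # strict-inequality abort rule: equal costs proceed to copy
        net = InfluenceNetwork(np.array([[1], [0]]))
        state = init_population(donald, 2, rng)
        # same cost by construction: mirrored assignment of the other agent
        state.assignments[1] = np.roll(state.assignments[0], 1)
        state.costs[0] = state.costs[1] = 42  # fake equal cached costs
        params = SearchParams(N=2, p=1.0, K=1, seed=0)
        before = state.assignments[0].copy()
        assert update_agent(0, donald, net, state, params, rng) == "imitated"
        assert not np.array_equal(state.assignments[0], before)


class TestRunTrial:
    def test_every_agent_updated_once(self, small3, rng):
        net = build_network(6, 5, rng)
        state = init_population(small3, 6, rng)
        params = SearchParams(N=6, p=0.5, K=5, seed=0)
        tally = run_trial(small3, net, state, params, rng)
        assert sum(tally.values()) == 6
        assert state.trial_index == 1

    def test_p0_trial_is_independent_moves(self, small3, rng):
        net = build_network(5, 0, rng)
        state = init_population(small3, 5, rng)
        before = state.assignments.copy()
        params = SearchParams(N=5, p=0.0, K=0, seed=0)
        tally = run_trial(small3, net, state, params, rng)
        assert tally == {"moved": 5, "imitated": 0, "wasted": 0}
        for i in range(5):
            assert 1 <= (before[i] != state.assignments[i]).sum() <= 2

    def test_cache_coherent_after_many_trials(self, small3, rng):
        net = build_network(5, 4, rng)
        state = init_population(small3, 5, rng)
        params = SearchParams(N=5, p=0.7, K=4, seed=0)
        for _ in range(30):
            run_trial(small3, net, state, params, rng)
        for i in range(5):
            assert state.costs[i] == cost(small3, state.assignments[i])


class TestChangeEvents:
    def test_worked_example(self):
        # trace (5,5,5,3,3,9,9,9,9) over t*=9 with initial minimum 5
        trace = [5, 5, 5, 3, 3, 9, 9, 9, 9]
        events = count_change_events(5, trace)
        assert events == 2
        assert 9 / events == 4.5  # stasis M

    def test_counts_increases_and_decreases(self):
        assert count_change_events(4, [3, 4, 4, 5, 0]) == 4

    def test_no_changes(self):
        assert count_change_events(7, [7, 7, 7]) == 0


class TestRunSearchPython:
    def test_reproducible_and_cost_identity(self, small3):
        params = SearchParams(N=4, p=0.5, K=3, seed=11, max_trials=100_000)
        r1 = run_search(small3, params, engine="python")
        r2 = run_search(small3, params, engine="python")
        assert r1 == r2
        assert r1.total_cost == 4 * r1.t_star
        assert r1.rescaled_cost == pytest.approx(r1.total_cost / 720)
        assert not r1.capped

    def test_trace_consistent_with_result(self, small3):
        params = SearchParams(N=4, p=0.5, K=3, seed=5, max_trials=100_000)
        result, trace = run_search(small3, params, engine="python",
                                   return_trace=True)
        assert len(trace) == result.t_star
        assert trace[-1] == 0
        # recompute events from the initial population minimum
        net_rng, init_rng, _ = _spawn_streams(params.seed)
        build_network(params.N, params.K, net_rng)
        state0 = init_population(small3, params.N, init_rng)
        assert count_change_events(state0.min_cost(), trace) == result.n_change_events
        expected_m = (result.t_star / result.n_change_events
                      if result.n_change_events else float(result.t_star))
        assert result.stasis_m == pytest.approx(expected_m)

    def test_capped_run_reported(self, donald):
        params = SearchParams(N=4, p=0.0, K=0, seed=0, max_trials=5)
        r = run_search(donald, params, engine="python")
        assert r.capped and r.t_star == 5

    def test_min_cost_can_rise_without_elitism(self, small3):
        params = SearchParams(N=3, p=0.0, K=0, seed=2, max_trials=100_000)
        _, trace = run_search(small3, params, engine="python", return_trace=True)
        diffs = np.diff(np.asarray(trace))
        assert (diffs > 0).any()  # the population minimum rose at least once


class TestRunSearchNumba:
    def test_reproducible(self, small3):
        params = SearchParams(N=4, p=0.5, K=3, seed=11, max_trials=100_000)
        assert run_search(small3, params) == run_search(small3, params)

    def test_seeds_differ(self, small3):
        p1 = SearchParams(N=4, p=0.5, K=3, seed=1, max_trials=100_000)
        p2 = SearchParams(N=4, p=0.5, K=3, seed=2, max_trials=100_000)
        assert run_search(small3, p1) != run_search(small3, p2)

    def test_trace_and_change_events_consistent(self, small3):
        params = SearchParams(N=5, p=0.4, K=4, seed=9, max_trials=100_000)
        result, trace = run_search(small3, params, return_trace=True)
        assert len(trace) == result.t_star
        assert trace[-1] == 0
        net_rng, init_rng, _ = _spawn_streams(params.seed)
        build_network(params.N, params.K, net_rng)
        state0 = init_population(small3, params.N, init_rng)
        assert count_change_events(state0.min_cost(), trace) == result.n_change_events

    def test_update_conservation(self, small3):
        params = SearchParams(N=6, p=0.6, K=5, seed=3, max_trials=100_000)
        r = run_search(small3, params)
        assert r.total_cost == 6 * r.t_star
        assert 0 <= r.wasted_updates + r.n_imitations <= r.total_cost

    def test_capped_run_reported(self, donald):
        r = run_search(donald, SearchParams(N=4, seed=0, max_trials=5))
        assert r.capped and r.t_star == 5

    def test_unknown_engine(self, small3):
        with pytest.raises(ValueError, match="engine"):
            run_search(small3, SearchParams(N=2), engine="fortran")

    def test_engines_statistically_equivalent(self, small3):
        """Numba and Python engines implement the same process: two-sample
        KS on t* from matched parameter sets."""
        params = [SearchParams(N=4, p=0.5, K=3, seed=s, max_trials=10**6)
                  for s in range(120)]
        t_nb = [run_search(small3, p).t_star for p in params]
        t_py = [run_search(small3, p, engine="python").t_star for p in params]
        stat = sps.ks_2samp(t_nb, t_py)
        assert stat.pvalue > 1e-3

    def test_engines_equivalent_independent_search(self, small3):
        params = [SearchParams(N=3, p=0.0, K=0, seed=s, max_trials=10**6)
                  for s in range(120)]
        t_nb = [run_search(small3, p).t_star for p in params]
        t_py = [run_search(small3, p, engine="python").t_star for p in params]
        assert sps.ks_2samp(t_nb, t_py).pvalue > 1e-3


class TestGlobalMoveBaselineOracle:
    def test_survival_matches_closed_form(self, unique4):
        """p=0 with global moves: P(t* > t) = (1 - 1/5040)^(N t) exactly."""
        N, runs = 3, 500
        samples = np.array([
            run_search(
                unique4,
                SearchParams(N=N, p=0.0, K=0, seed=s, move_kind="global",
                             max_trials=10**7),
            ).t_star
            for s in range(runs)
        ])
        q = (1 - 1 / 5040) ** N

        def cdf(t):
            return 1 - q ** np.floor(np.maximum(t, 0))

        grid = np.unique(samples)
        emp = np.searchsorted(np.sort(samples), grid, side="right") / runs
        d = np.max(np.abs(emp - cdf(grid)))
        assert d < 1.63 / np.sqrt(runs)  # KS 1% critical value (conservative)


class TestImitationConvergence:
    def test_frozen_model_absorbs_population(self, donald, rng):
        """p=1 with a hub model at the solution: everyone converges within
        L-1 = 9 trials and the hub never moves."""
        N = 6
        infl = np.zeros((N, 1), dtype=np.int64)
        infl[0, 0] = 1  # the hub watches agent 1 but is always cheaper
        net = InfluenceNetwork(infl)
        state = init_population(donald, N, rng)
        solution = donald.assignment_from_map(DONALD_SOLUTION)
        state.assignments[0] = solution
        state.refresh_cost(donald, 0)
        params = SearchParams(N=N, p=1.0, K=1, seed=0)
        for _ in range(9):
            run_trial(donald, net, state, params, rng)
        for i in range(N):
            assert np.array_equal(state.assignments[i], solution)

    def test_initial_solution_halts_after_first_trial(self, donald, rng):
        """A zero-cost string present at trial 0 survives a p=1 trial (its
        update is always wasted), so the end-of-trial check halts at t*=1."""
        N = 4
        net = build_network(N, N - 1, rng)
        state = init_population(donald, N, rng)
        state.assignments[2] = donald.assignment_from_map(DONALD_SOLUTION)
        state.refresh_cost(donald, 2)
        params = SearchParams(N=N, p=1.0, K=N - 1, seed=0)
        run_trial(donald, net, state, params, rng)
        assert state.min_cost() == 0 and state.trial_index == 1
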