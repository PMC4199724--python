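"""Search dynamics: trials of asynchronous agent updates until a solution.

One *trial* updates all N agents once, in a freshly drawn random order.  Each
update is either an imitation attempt (probability ``p``) or a random move
(probability ``1 - p``; the local elementary move, or the global redraw for
the baseline variant).  An imitation attempt first selects the agent's model
(its minimum-cost influencer); the attempt is *wasted* — nothing changes —
when the target's cost is strictly lower than the model's or the two strings
are identical.  Model selection reads cached costs, so models can change
several times within a trial; the process is asynchronous, not parallel.

The search halts at the first end-of-trial check that finds a zero-cost
agent, so the computational cost is exactly ``N * t_star`` agent updates.
A *change event* is a trial whose end-of-trial population minimum cost
differs (up or down) from the previous trial's; the stasis statistic
``M = t_star / n_change_events`` is the mean number of trials between
consecutive change events.

Seed discipline: ``SeedSequence(seed)`` is split into three children, used
in order for (1) network construction, (2) initial assignments, (3) all
within-search randomness (update order, move/imitation coin, move choices,
tie-breaks).  A seed therefore fully determines a run for a given engine.

Two engines produce statistically identical dynamics: ``"numba"`` (default,
a compiled inner loop) and ``"python"`` (the readable reference used for
contract tests).  Their random streams differ, so per-seed trajectories are
engine-specific; equivalence is checked distributionally in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np

from . import _kernels
from .moves import elementary_move, global_move, imitate
from .population import (
    InfluenceNetwork,
    PopulationState,
    build_network,
    init_population,
    select_model,
)
from .puzzle import Puzzle

__all__ = [
    "SearchParams",
    "SearchResult",
    "UpdateOutcome",
    "update_agent",
    "run_trial",
    "run_search",
    "count_change_events",
]


def count_change_events(initial_min: int, per_trial_mins) -> int:
    """Number of trials whose end-of-trial population minimum differs (up or
    down) from the previous trial's, starting the comparison at the initial
    (trial-0) minimum."""
    changes = 0
    prev = initial_min
    for m in per_trial_mins:
        if m != prev:
            changes += 1
            prev = m
    return changes

UpdateOutcome = Literal["moved", "imitated", "wasted"]
_OUTCOMES = ("moved", "imitated", "wasted")


@dataclass(frozen=True)
class SearchParams:
    """Parameters of one search run."""

    N: int
    p: float = 0.0
    K: int = 0
    seed: int = 0
    max_trials: int | None = None  # default: 100 * |S| / N, see run_search
    move_kind: Literal["elementary", "global"] = "elementary"

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError("N must be >= 1")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.p > 0 and (self.K < 1 or self.N < 2):
            raise ValueError("p > 0 requires K >= 1 and N >= 2")
        if not 0 <= self.K <= self.N - 1:
            raise ValueError("K must satisfy 0 <= K <= N-1")
        if self.move_kind not in ("elementary", "global"):
            raise ValueError(f"unknown move_kind: {self.move_kind}")
        if self.max_trials is not None and self.max_trials < 1:
            raise ValueError("max_trials must be positive")


@dataclass(frozen=True)
class SearchResult:
    """Outcome of one search run.

    ``total_cost`` is always ``N * t_star`` agent updates; ``rescaled_cost``
    divides by the state-space size 10!/(10-L)!.  ``stasis_m`` is
    ``t_star / n_change_events`` (or ``t_star`` when no change event
    occurred).  ``capped`` flags runs stopped at ``max_trials`` without a
    solution.
    """

    t_star: int
    total_cost: int
    rescaled_cost: float
    n_change_events: int
    stasis_m: float
    wasted_updates: int
    n_imitations: int
    capped: bool
    seed: int
    params: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def default_max_trials(pz: Puzzle, N: int) -> int:
    """Cap far beyond the exponential scale of typical searches."""
    return max(1000, int(100 * pz.space_size / N))


def update_agent(
    agent: int,
    pz: Puzzle,
    net: InfluenceNetwork,
    state: PopulationState,
    params: SearchParams,
    rng: np.random.Generator,
) -> UpdateOutcome:
    """Update one agent in place and return the outcome tag.

    With probability ``p``: select the model; abort (``"wasted"``) if the
    target is strictly cheaper than the model or identical to it, else copy
    one differing pairing (``"imitated"``).  Otherwise perform the random
    move of ``params.move_kind`` (``"moved"``).  The cached cost is kept
    coherent.
    """
    if params.p > 0 and rng.random() < params.p:
        model, model_cost = select_model(agent, net, state, rng)
        if state.costs[agent] < model_cost:
            return "wasted"
        target = state.assignments[agent]
        model_a = state.assignments[model]
        if np.array_equal(target, model_a):
            return "wasted"
        state.assignments[agent] = imitate(target, model_a, rng)
        state.refresh_cost(pz, agent)
        return "imitated"
    if params.move_kind == "global":
        state.assignments[agent] = global_move(pz, rng)
    else:
        state.assignments[agent] = elementary_move(state.assignments[agent], rng)
    state.refresh_cost(pz, agent)
    return "moved"


def run_trial(
    pz: Puzzle,
    net: InfluenceNetwork,
    state: PopulationState,
    params: SearchParams,
    rng: np.random.Generator,
) -> dict[UpdateOutcome, int]:
    """Update every agent once, in a uniformly random order, then advance the
    trial index.  Returns the tally of update outcomes."""
    tally = {o: 0 for o in _OUTCOMES}
    for agent in rng.permutation(state.n_agents):
        tally[update_agent(int(agent), pz, net, state, params, rng)] += 1
    state.trial_index += 1
    return tally


def _spawn_streams(seed: int):
    net_ss, init_ss, dyn_ss = np.random.SeedSequence(seed).spawn(3)
    return (
        np.random.default_rng(net_ss),
        np.random.default_rng(init_ss),
        dyn_ss,
    )


def run_search(
    pz: Puzzle,
    params: SearchParams,
    engine: Literal["numba", "python"] = "numba",
    return_trace: bool = False,
) -> SearchResult | tuple[SearchResult, np.ndarray]:
    """Run a full search from a fresh network and population.

    Halting is checked only at trial end, so a solution found mid-trial still
    completes its trial and ``t_star`` counts that full trial.  If
    ``max_trials`` is reached the run is returned with ``capped=True`` rather
    than raising.

    With ``return_trace=True`` also returns the per-trial population minimum
    cost series (length ``t_star``).
    """
    net_rng, init_rng, dyn_ss = _spawn_streams(params.seed)
    net = build_network(params.N, params.K, net_rng)
    state = init_population(pz, params.N, init_rng)
    max_trials = (
        params.max_trials
        if params.max_trials is not None
        else default_max_trials(pz, params.N)
    )

    if engine == "numba":
        lead_idx = np.flatnonzero(pz._lead_mask).astype(np.int64)
        kernel_seed = int(dyn_ss.generate_state(1, dtype=np.uint32)[0])
        t_star, changes, wasted, n_imit, capped, trace = _kernels.search_kernel(
            pz._coefs,
            lead_idx,
            int(pz.penalty_cost),
            state.assignments,
            net.influencers,
            float(params.p),
            params.move_kind == "global",
            int(max_trials),
            kernel_seed,
            return_trace,
        )
    elif engine == "python":
        dyn_rng = np.random.default_rng(dyn_ss)
        prev_min = state.min_cost()
        trace_list: list[int] = []
        wasted = n_imit = changes = 0
        capped = True
        t_star = max_trials
        for t in range(1, max_trials + 1):
            tally = run_trial(pz, net, state, params, dyn_rng)
            wasted += tally["wasted"]
            n_imit += tally["imitated"]
            cur_min = state.min_cost()
            if return_trace:
                trace_list.append(cur_min)
            if cur_min != prev_min:
                changes += 1
                prev_min = cur_min
            if cur_min == 0:
                t_star, capped = t, False
                break
        trace = np.asarray(trace_list, dtype=np.int64)
    else:
        raise ValueError(f"unknown engine: {engine}")

    result = SearchResult(
        t_star=int(t_star),
        total_cost=int(t_star) * params.N,
        rescaled_cost=int(t_star) * params.N / pz.space_size,
        n_change_events=int(changes),
        stasis_m=(int(t_star) / changes) if changes else float(t_star),
        wasted_updates=int(wasted),
        n_imitations=int(n_imit),
        capped=bool(capped),
        seed=params.seed,
        params={
            "N": params.N,
            "p": params.p,
            "K": params.K,
            "max_trials": int(max_trials),
            "move_kind": params.move_kind,
            "puzzle": pz.text,
        },
    )
    if return_trace:
        return result, trace
    return result
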