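"""Influence networks, agent populations, and model-string selection.

Every agent carries one assignment with a cached cost.  Each agent observes a
fixed list of K distinct other agents (its influencers), sampled without
replacement at build time and never rewired; links are unidirectional.  The
model of an agent is the minimum-cost assignment among its influencers at the
moment of its update, with ties broken uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .puzzle import Puzzle, cost, random_assignment

__all__ = [
    "InfluenceNetwork",
    "PopulationState",
    "build_network",
    "init_population",
    "select_model",
]


@dataclass(frozen=True)
class InfluenceNetwork:
    """Fixed per-agent influencer lists: ``influencers[i]`` are the K agents
    agent ``i`` can observe (never including ``i`` itself)."""

    influencers: np.ndarray  # int64[N, K]

    @property
    def n_agents(self) -> int:
        return self.influencers.shape[0]

    @property
    def k(self) -> int:
        return self.influencers.shape[1]

    def dump(self, path: str | Path) -> None:
        """Write the network as an edge list, one ``agent influencer`` pair
        per line."""
        with open(path, "w") as fh:
            for i in range(self.n_agents):
                for j in self.influencers[i]:
                    fh.write(f"{i} {int(j)}\n")

    @classmethod
    def load(cls, path: str | Path) -> "InfluenceNetwork":
        edges: dict[int, list[int]] = {}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                i, j = map(int, line.split())
                edges.setdefault(i, []).append(j)
        n = max(edges) + 1
        ks = {len(v) for v in edges.values()}
        if len(edges) != n or len(ks) != 1:
            raise ValueError("edge list does not describe a fixed-out-degree network")
        k = ks.pop()
        arr = np.empty((n, k), dtype=np.int64)
        for i, lst in edges.items():
            arr[i] = lst
        return cls(arr)


@dataclass
class PopulationState:
    """N agent assignments with cached costs and the current trial index."""

    assignments: np.ndarray  # int64[N, L]
    costs: np.ndarray  # int64[N]
    trial_index: int = 0

    @property
    def n_agents(self) -> int:
        return self.assignments.shape[0]

    def min_cost(self) -> int:
        return int(self.costs.min())

    def refresh_cost(self, pz: Puzzle, agent: int) -> None:
        self.costs[agent] = cost(pz, self.assignments[agent])


def build_network(N: int, K: int, rng: np.random.Generator) -> InfluenceNetwork:
    """Sample each agent's K influencers uniformly without replacement from
    the other N-1 agents.  K = N-1 is the fully connected system."""
    if N < 1:
        raise ValueError("need at least one agent")
    if not 0 <= K <= N - 1:
        raise ValueError(f"K must satisfy 0 <= K <= N-1, got K={K}, N={N}")
    net = np.empty((N, K), dtype=np.int64)
    for i in range(N):
        others = np.concatenate([np.arange(i), np.arange(i + 1, N)])
        net[i] = rng.choice(others, size=K, replace=False)
    return InfluenceNetwork(net)


def init_population(pz: Puzzle, N: int, rng: np.random.Generator) -> PopulationState:
    """N independent uniform random assignments with cached costs, at trial 0."""
    assignments = np.stack([random_assignment(pz, rng) for _ in range(N)])
    costs = np.array([cost(pz, a) for a in assignments], dtype=np.int64)
    return PopulationState(assignments=assignments, costs=costs, trial_index=0)


def select_model(
    agent: int,
    net: InfluenceNetwork,
    state: PopulationState,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Return ``(model_index, model_cost)``: a minimum-cost influencer of
    ``agent``, ties broken uniformly at random.

    Reads the cached costs, so it automatically reflects every update already
    applied within the current trial.
    """
    infl = net.influencers[agent]
    if infl.size == 0:
        raise ValueError("agent has no influencers")
    c = state.costs[infl]
    lowest = c.min()
    candidates = infl[c == lowest]
    model = int(candidates[rng.integers(candidates.size)])
    return model, int(lowest)
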