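# cryptoswarm

Agent-based simulation of collective problem solving by imitative learning.
A group of `N` agents searches the permutation space of letter-to-digit
assignments of a cryptarithmetic puzzle (the classic 10-letter instance
`DONALD+GERALD=ROBERT` by default, with 10! = 3,628,800 states).  At every
trial each agent, in random order, either

* performs a **local random move** (swap the digits of two random letters),
  with probability `1 - p`, or
* **imitates** the best-performing agent among its `K` fixed random
  influencers, with probability `p`: it copies one letter-digit pairing in
  which it differs from that model, unless it is already cheaper than the
  model (or identical to it), in which case the update is wasted.

The search halts when any agent reaches cost zero; the computational cost of
a run is `N * t*` agent updates.  Cooperation at a well-chosen `(N, p)` cuts
the mean cost roughly thirtyfold relative to independent search (`p = 0`),
while oversized or over-imitative groups perform far worse than independent
agents — the package reproduces these cost distributions, the speed-up, and
the leader-stasis statistics.

## Command line

```bash
# one search: JSON result record (t*, cost, stasis statistic, ...)
cryptoswarm run --puzzle DONALD+GERALD=ROBERT -N 20 -p 0.5 -K 19 --seed 1

# per-trial minimum-cost trace
cryptoswarm run -N 10 -p 0.3 -K 9 --seed 2 --trace trace.csv

# independent-search baseline with global (whole-string) redraws
cryptoswarm run -N 10 --move global --seed 3

# random 10-letter puzzle with a unique solution (verified exhaustively)
cryptoswarm generate-puzzle --seed 7

# (N, p, K) grid sweep from a YAML config -> tidy CSV + metadata
cryptoswarm sweep --config sweep.yaml --outdir out/

# figure-style experiments (fig1..fig8) at reduced replicate counts
cryptoswarm figure --which fig2 --scale 0.1 --outdir figures/
```

A sweep config is a YAML file:

```yaml
puzzle: DONALD+GERALD=ROBERT
N_grid: [5, 10, 20]
p_grid: [0.0, 0.3, 0.5, 0.7]
K_grid: [full]        # "full" means K = N - 1
replicates: 200
seed: 1
```

## Library

```python
from cryptoswarm import parse_puzzle, SearchParams, run_search, summarize

pz = parse_puzzle("DONALD+GERALD=ROBERT")
result = run_search(pz, SearchParams(N=20, p=0.5, K=19, seed=1))
print(result.rescaled_cost, result.stasis_m)
```

Modules map one-to-one onto the model's parts: `puzzle` (parsing, cost
function, exhaustive solution counting, random unique-solution puzzle
generation), `moves` (elementary/global/imitation operators), `population`
(influence networks, model selection), `dynamics` (trial loop and halting;
a numba kernel plus a pure-Python reference engine), `stats` (cost and
stasis summaries, exponential fits), `experiments` (sweeps, optimum
finding, figure reproductions).

Seeds fully determine runs: `SeedSequence(seed)` is split into network /
initialization / dynamics streams, and sweeps derive per-run seeds from
`(base_seed, cell_index, replicate_index)`.

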