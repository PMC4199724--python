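"""Parameter sweeps, optimum finding and figure-style reproductions.

All sweeps derive per-run seeds deterministically from
``SeedSequence((base_seed, cell_index, replicate_index))``, so a (config,
seed) pair reproduces a table exactly.  Replicate counts default to 10^3 per
cell and can be scaled down for desk-scale runs; standard errors are always
reported so reduced replicates stay interpretable.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import SearchParams, SearchResult, run_search
from .puzzle import DONALD_GERALD_ROBERT, Puzzle, generate_random_puzzle, parse_puzzle
from .stats import stasis_distribution, summarize

__all__ = [
    "SweepConfig",
    "run_replicates",
    "run_sweep",
    "find_optimum",
    "reproduce_figure",
    "FIGURE_IDS",
]

#: Default grids; endpoint guard at p = 0.99 because the p -> 1 limit makes
#: the cost diverge (the elementary move is then never chosen).
DEFAULT_P_GRID = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.99)
DEFAULT_N_GRID = (2, 5, 10, 20, 50, 100, 200)
DEFAULT_K_GRID = ("full",)
DEFAULT_REPLICATES = 1000


def _seed_for(base_seed: int, cell_index: int, replicate: int) -> int:
    ss = np.random.SeedSequence((int(base_seed), int(cell_index), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint64)[0] & 0x7FFFFFFFFFFFFFFF)


def run_replicates(
    pz: Puzzle,
    N: int,
    p: float,
    K: int,
    replicates: int,
    base_seed: int,
    cell_index: int = 0,
    max_trials: int | None = None,
    move_kind: str = "elementary",
) -> list[SearchResult]:
    """Run ``replicates`` independent searches of one parameter cell."""
    out = []
    for rep in range(replicates):
        params = SearchParams(
            N=N,
            p=p,
            K=K,
            seed=_seed_for(base_seed, cell_index, rep),
            max_trials=max_trials,
            move_kind=move_kind,
        )
        out.append(run_search(pz, params))
    return out


@dataclass(frozen=True)
class SweepConfig:
    """Grid over (N, p, K) with replicates per cell.

    ``puzzle`` is a ``WORD+WORD=WORD`` expression.  ``K_grid`` entries may be
    integers or the token ``"full"`` meaning K = N - 1.
    """

    puzzle: str = DONALD_GERALD_ROBERT
    N_grid: tuple[int, ...] = DEFAULT_N_GRID
    p_grid: tuple[float, ...] = DEFAULT_P_GRID
    K_grid: tuple[int | str, ...] = DEFAULT_K_GRID
    replicates: int = DEFAULT_REPLICATES
    seed: int = 0
    max_trials: int | None = None
    move_kind: str = "elementary"
    workers: int = 1

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("N_grid", "p_grid", "K_grid"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def cells(self) -> list[tuple[int, int, float, int]]:
        """Enumerate (cell_index, N, p, K) with ``"full"`` resolved to N-1."""
        out = []
        idx = 0
        for N in self.N_grid:
            for p in self.p_grid:
                for K in self.K_grid:
                    k = N - 1 if K == "full" else int(K)
                    out.append((idx, int(N), float(p), k))
                    idx += 1
        return out


def _run_cell(pz: Puzzle, cfg: SweepConfig, cell) -> dict:
    idx, N, p, K = cell
    results = run_replicates(
        pz,
        N=N,
        p=p,
        K=K if p > 0 else min(K, N - 1),
        replicates=cfg.replicates,
        base_seed=cfg.seed,
        cell_index=idx,
        max_trials=cfg.max_trials,
        move_kind=cfg.move_kind,
    )
    s = summarize(results)
    return {
        "N": N,
        "p": p,
        "K": K,
        "n_runs": s.n_runs,
        "mean_rescaled": s.mean_rescaled,
        "std_rescaled": s.std_rescaled,
        "ratio_std_mean": s.ratio_std_mean,
        "sem": s.sem_rescaled,
        "capped": s.capped_runs,
    }


def run_sweep(cfg: SweepConfig) -> pd.DataFrame:
    """Run every grid cell and aggregate into a tidy table."""
    pz = parse_puzzle(cfg.puzzle)
    cells = cfg.cells()
    for _, N, p, K in cells:
        # fail fast on invalid cells before burning compute
        SearchParams(N=N, p=p, K=K if p > 0 else min(K, N - 1), seed=0)
    if cfg.workers > 1:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=cfg.workers)(
            delayed(_run_cell)(pz, cfg, cell) for cell in cells
        )
    else:
        rows = [_run_cell(pz, cfg, cell) for cell in cells]
    return pd.DataFrame(rows)


def find_optimum(table: pd.DataFrame) -> dict:
    """Grid cell of minimal mean rescaled cost and its speed-up over the
    p = 0 baseline (pooled over the baseline cells, weighted by run count)."""
    baseline = table[table["p"] == 0.0]
    if baseline.empty:
        raise ValueError("table has no p = 0 baseline cell")
    base_mean = float(
        np.average(baseline["mean_rescaled"], weights=baseline["n_runs"])
    )
    best = table.loc[table["mean_rescaled"].idxmin()]
    return {
        "N": int(best["N"]),
        "p": float(best["p"]),
        "K": int(best["K"]),
        "min_mean_cost": float(best["mean_rescaled"]),
        "baseline_mean_cost": base_mean,
        "speedup_vs_independent": base_mean / float(best["mean_rescaled"]),
    }


# ---------------------------------------------------------------------------
# figure-style reproductions (reduced replicates; grids are package defaults,
# not digitized from any plot)
# ---------------------------------------------------------------------------

FIGURE_IDS = (
    "fig1",
    "fig2",
    "fig3",
    "fig4",
    "fig5",
    "fig6",
    "fig7",
    "fig8",
)


def _reps(scale: float, base: int = DEFAULT_REPLICATES) -> int:
    return max(10, int(round(base * scale)))


def _log_hist(values: np.ndarray, n_bins: int = 25) -> pd.DataFrame:
    """Probability histogram with logarithmic binning (costs span decades)."""
    lo, hi = values.min(), values.max()
    if lo <= 0 or lo == hi:
        edges = np.linspace(lo, hi + 1e-12, n_bins + 1)
    else:
        edges = np.geomspace(lo, hi * (1 + 1e-9), n_bins + 1)
    counts, edges = np.histogram(values, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "probability": counts / counts.sum(),
        }
    )


def _save(
    outdir: Path, name: str, table: pd.DataFrame, meta: dict
) -> dict[str, Path]:
    outdir.mkdir(parents=True, exist_ok=True)
    csv = outdir / f"{name}.csv"
    table.to_csv(csv, index=False)
    meta_path = outdir / f"{name}.meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, default=str))
    return {"csv": csv, "meta": meta_path}


def _plot_sweep(table: pd.DataFrame, by: str, x: str, path: Path, xlabel: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for key, grp in table.groupby(by):
        ax.errorbar(
            grp[x], grp["mean_rescaled"], yerr=grp["sem"], marker="o",
            label=f"{by}={key}",
        )
    ax.set_yscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("mean rescaled cost")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _plot_hist(
    tables: dict[str, pd.DataFrame], path: Path, xlabel: str, logx: bool = False
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, tb in tables.items():
        centers = 0.5 * (tb["bin_left"] + tb["bin_right"])
        ax.plot(centers, tb["probability"], marker="o", ls="none", label=label)
    ax.set_yscale("log")
    if logx:
        ax.set_xscale("log")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("probability")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def reproduce_figure(
    which: str,
    scale: float = 1.0,
    outdir: str | Path = "figures",
    seed: int = 0,
    puzzle: str | None = None,
) -> dict[str, Path]:
    """Recreate one figure-style experiment at ``scale`` times the default
    replicate count.  Writes the underlying table(s) as CSV, a JSON metadata
    sidecar, and a rendered PNG; returns the paths."""
    if which not in FIGURE_IDS:
        raise ValueError(f"unknown figure id {which!r}; known: {FIGURE_IDS}")
    outdir = Path(outdir)
    pz_text = puzzle or DONALD_GERALD_ROBERT
    t0 = time.time()
    meta = {"figure": which, "scale": scale, "seed": seed, "puzzle": pz_text}

    if which == "fig1":
        # independent-search cost distributions for several N
        reps = _reps(scale)
        pz = parse_puzzle(pz_text)
        tables = {}
        rows = []
        for i, N in enumerate((2, 5, 10)):
            res = run_replicates(pz, N, 0.0, 0, reps, seed, cell_index=i)
            vals = np.array([r.rescaled_cost for r in res])
            tb = _log_hist(vals)
            tb.insert(0, "N", N)
            tables[f"N={N}"] = tb
            rows.append(tb)
        table = pd.concat(rows, ignore_index=True)
        paths = _save(outdir, which, table, meta | {"replicates": reps})
        _plot_hist(tables, outdir / f"{which}.png", "rescaled cost", logx=False)
    elif which == "fig2":
        cfg = SweepConfig(
            puzzle=pz_text,
            N_grid=(5, 10, 20, 50),
            p_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
            K_grid=("full",),
            replicates=_reps(scale),
            seed=seed,
        )
        table = run_sweep(cfg)
        paths = _save(outdir, which, table, meta | {"config": asdict(cfg)})
        _plot_sweep(table, "N", "p", outdir / f"{which}.png", "imitation probability p")
    elif which == "fig3":
        # cost distribution in the rising-cost regime (large p), with its
        # exponential tail
        reps = _reps(scale)
        pz = parse_puzzle(pz_text)
        res = run_replicates(pz, 10, 0.9, 9, reps, seed)
        vals = np.array([r.rescaled_cost for r in res if not r.capped])
        table = _log_hist(vals)
        paths = _save(
            outdir, which, table,
            meta | {"replicates": reps, "N": 10, "p": 0.9,
                    "mean_rescaled": float(vals.mean())},
        )
        _plot_hist({"N=10, p=0.9": table}, outdir / f"{which}.png",
                   "rescaled cost", logx=True)
    elif which == "fig4":
        cfg = SweepConfig(
            puzzle=pz_text,
            N_grid=(2, 5, 10, 20, 50, 100),
            p_grid=(0.0, 0.1, 0.3, 0.5),
            K_grid=("full",),
            replicates=_reps(scale),
            seed=seed,
        )
        table = run_sweep(cfg)
        paths = _save(outdir, which, table, meta | {"config": asdict(cfg)})
        _plot_sweep(table, "p", "N", outdir / f"{which}.png", "number of agents N")
    elif which == "fig5":
        # stasis-duration distributions: low- vs high-cost regime at equal p
        reps = _reps(scale, base=200)
        pz = parse_puzzle(pz_text)
        tables = {}
        rows = []
        for i, N in enumerate((20, 200)):
            res = run_replicates(pz, N, 0.5, N - 1, reps, seed, cell_index=i)
            tb = stasis_distribution(res, bins=20)
            tb.insert(0, "N", N)
            tables[f"N={N}"] = tb
            rows.append(tb)
        table = pd.concat(rows, ignore_index=True)
        paths = _save(outdir, which, table, meta | {"replicates": reps, "p": 0.5})
        _plot_hist(tables, outdir / f"{which}.png", "stasis duration M", logx=True)
    elif which == "fig6":
        cfg = SweepConfig(
            puzzle=pz_text,
            N_grid=(50,),
            p_grid=(0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
            K_grid=(2, 5, 10, "full"),
            replicates=_reps(scale),
            seed=seed,
        )
        table = run_sweep(cfg)
        paths = _save(outdir, which, table, meta | {"config": asdict(cfg)})
        _plot_sweep(table, "K", "p", outdir / f"{which}.png", "imitation probability p")
    elif which == "fig7":
        cfg = SweepConfig(
            puzzle=pz_text,
            N_grid=(50,),
            p_grid=(0.1, 0.3, 0.5, 0.8),
            K_grid=(1, 2, 5, 10, 25, "full"),
            replicates=_reps(scale),
            seed=seed,
        )
        table = run_sweep(cfg)
        paths = _save(outdir, which, table, meta | {"config": asdict(cfg)})
        _plot_sweep(table, "p", "K", outdir / f"{which}.png", "influencers K")
    elif which == "fig8":
        # the alphametic instance vs four random unique-solution puzzles
        puzzles = {"alphametic": pz_text}
        gen_rng = np.random.default_rng(np.random.SeedSequence((seed, 8)))
        for i in range(4):
            puzzles[f"random{i + 1}"] = generate_random_puzzle(6, gen_rng).text
        rows = []
        for j, (label, text) in enumerate(puzzles.items()):
            cfg = SweepConfig(
                puzzle=text,
                N_grid=(10,),
                p_grid=(0.0, 0.2, 0.4, 0.6, 0.8),
                K_grid=("full",),
                replicates=_reps(scale),
                seed=seed + j,
            )
            tb = run_sweep(cfg)
            tb.insert(0, "puzzle", label)
            tb.insert(1, "expression", text)
            rows.append(tb)
        table = pd.concat(rows, ignore_index=True)
        paths = _save(outdir, which, table, meta | {"puzzles": puzzles})
        _plot_sweep(table, "puzzle", "p", outdir / f"{which}.png",
                    "imitation probability p")

    meta_path = paths["meta"]
    meta_out = json.loads(meta_path.read_text())
    meta_out["elapsed_seconds"] = round(time.time() - t0, 2)
    meta_path.write_text(json.dumps(meta_out, indent=2, default=str))
    paths["png"] = outdir / f"{which}.png"
    return paths
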