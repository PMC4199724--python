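"""Summary statistics over collections of search results.

The headline quantities: moments of the rescaled computational cost, the
std-to-mean ratio (equal to 1 for an exponential distribution), the
maximum-likelihood exponential rate (1/mean), stasis-duration histograms,
and a straight-line fit of log-probability against cost for the large-cost
tail of a distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dynamics import SearchResult

__all__ = ["SummaryStats", "summarize", "stasis_distribution", "tail_fit"]


@dataclass(frozen=True)
class SummaryStats:
    n_runs: int
    mean_rescaled: float
    std_rescaled: float
    ratio_std_mean: float
    exp_rate: float
    sem_rescaled: float
    capped_runs: int

    def to_dict(self) -> dict:
        return asdict(self)


def _rescaled(results: Sequence[SearchResult], space_size: int | None) -> np.ndarray:
    if space_size is None:
        return np.array([r.rescaled_cost for r in results], dtype=float)
    return np.array([r.total_cost / space_size for r in results], dtype=float)


def summarize(
    results: Iterable[SearchResult], space_size: int | None = None
) -> SummaryStats:
    """Moments of the rescaled cost over a set of runs sharing parameters.

    Capped runs are excluded from the moments and counted in
    ``capped_runs``.  The exponential fit is by maximum likelihood, for which
    the rate is simply 1/mean.  ``space_size`` optionally re-derives the
    rescaled costs from ``total_cost`` (useful when aggregating runs made on
    puzzles with fewer than 10 letters).
    """
    results = list(results)
    used = [r for r in results if not r.capped]
    n_capped = len(results) - len(used)
    if len(used) < 2:
        raise ValueError(
            f"need at least 2 uncapped runs to summarize, got {len(used)} "
            f"({n_capped} capped)"
        )
    x = _rescaled(used, space_size)
    mean = float(x.mean())
    std = float(x.std(ddof=1))
    return SummaryStats(
        n_runs=len(used),
        mean_rescaled=mean,
        std_rescaled=std,
        ratio_std_mean=std / mean if mean > 0 else 0.0,
        exp_rate=1.0 / mean,
        sem_rescaled=std / np.sqrt(len(used)),
        capped_runs=n_capped,
    )


def stasis_distribution(
    results: Iterable[SearchResult],
    bins: int | Sequence[float] | str = "auto",
) -> pd.DataFrame:
    """Normalized histogram of the per-search stasis statistic M.

    Each search contributes its single ``stasis_m`` value.  Returns a tidy
    frame with columns ``bin_left``, ``bin_right``, ``probability`` whose
    probabilities sum to 1.
    """
    values = np.array([r.stasis_m for r in results], dtype=float)
    if values.size == 0:
        raise ValueError("no results to histogram")
    counts, edges = np.histogram(values, bins=bins)
    probs = counts / counts.sum()
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "probability": probs}
    )


def tail_fit(
    histogram: pd.DataFrame, threshold: float
) -> tuple[float, float]:
    """Exponential fit ``P(C) = amplitude * exp(-rate * C)`` of the
    large-cost tail of a cost histogram.

    Least-squares line fit of log-probability against bin center, restricted
    to bins with centers above ``threshold`` and nonzero mass.  Requires at
    least 5 such bins.
    """
    centers = 0.5 * (histogram["bin_left"].to_numpy() + histogram["bin_right"].to_numpy())
    probs = histogram["probability"].to_numpy(dtype=float)
    mask = (centers > threshold) & (probs > 0)
    if mask.sum() < 5:
        raise ValueError(
            f"need >= 5 nonzero bins above threshold {threshold}, got {int(mask.sum())}"
        )
    slope, intercept = np.polyfit(centers[mask], np.log(probs[mask]), 1)
    return float(np.exp(intercept)), float(-slope)
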