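"""State-transition operators on assignments.

Three operators, all pure (the input array is never modified):

* :func:`elementary_move` — the local move: swap the digits of two random
  letters (equivalently, on alphabets smaller than 10 letters, reassign one
  letter to a random new digit); accepted unconditionally, with no cost test.
* :func:`global_move` — redraw the whole assignment uniformly at random, the
  baseline variant used to calibrate the independent search.
* :func:`imitate` — copy one differing letter-digit pairing from a model
  assignment, implemented as a transposition so injectivity is preserved and
  the Hamming distance to the model strictly decreases (by 1 or 2).
"""

from __future__ import annotations

import numpy as np

from .puzzle import Assignment, Puzzle

__all__ = ["elementary_move", "global_move", "imitate", "hamming"]


def hamming(a: Assignment, b: Assignment) -> int:
    """Number of letter positions where two assignments disagree."""
    return int(np.sum(np.asarray(a) != np.asarray(b)))


def elementary_move(a: Assignment, rng: np.random.Generator) -> Assignment:
    """Local random move: reassign one letter to a new digit.

    A letter position ``i`` and a digit ``d != a[i]`` are chosen uniformly.
    If ``d`` is held by another letter the two letters exchange digits; on a
    full 10-letter alphabet this is exactly a uniform swap of two distinct
    letter positions.  When the alphabet has fewer than 10 letters ``d`` may
    be currently unused, in which case only position ``i`` changes — this
    keeps the move ergodic over all injective maps on small alphabets.
    """
    L = len(a)
    if L < 2:
        raise ValueError("elementary move needs at least 2 letters")
    out = np.array(a, dtype=np.int64)
    i = int(rng.integers(L))
    d = int(rng.integers(9))
    if d >= out[i]:
        d += 1
    holder = np.flatnonzero(out == d)
    if holder.size:
        out[holder[0]] = out[i]
    out[i] = d
    return out


def global_move(pz: Puzzle, rng: np.random.Generator) -> Assignment:
    """Uniformly random injective assignment, independent of the current
    state (penalized leading-zero states are part of the draw)."""
    return rng.permutation(10)[: pz.n_letters].astype(np.int64)


def imitate(
    target: Assignment, model: Assignment, rng: np.random.Generator
) -> Assignment:
    """Assimilate one letter-digit pairing of ``model`` into ``target``.

    A position ``q`` is chosen uniformly among those where the two disagree;
    the output holds ``model[q]`` at ``q`` and, if ``model[q]`` already
    occurred in the target, the displaced digit is written where ``model[q]``
    used to sit (a transposition).  The Hamming distance to the model drops
    by 2 when the swap fixes both positions, else by 1.
    """
    target = np.asarray(target, dtype=np.int64)
    model = np.asarray(model, dtype=np.int64)
    diff = np.flatnonzero(target != model)
    if diff.size == 0:
        raise ValueError("target is identical to model; nothing to imitate")
    q = int(rng.choice(diff))
    out = target.copy()
    dm, dt = int(model[q]), int(target[q])
    holder = np.flatnonzero(target == dm)
    if holder.size:
        out[holder[0]] = dt
    out[q] = dm
    return out
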