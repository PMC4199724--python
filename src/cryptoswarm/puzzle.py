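"""Cryptarithmetic (alphametic) puzzles and their cost landscape.

A puzzle is a single-line sum ``WORD+WORD=WORD`` over uppercase letters.  A
state of the search is an :class:`Assignment`: an injective map from the
puzzle's letters to the digits 0-9, stored as a digit sequence indexed by
letter position.  The cost of an assignment is the absolute violation of the
sum, ``|value(result) - value(operand1) - value(operand2)|``, except that
assignments placing digit 0 on the first letter of any word receive a large
penalty cost (they break the no-leading-zero rule but are kept in the state
space as very poor states).

The classic 10-letter instance ``DONALD+GERALD=ROBERT`` has exactly one
zero-cost state among the 10! = 3,628,800 injective assignments; this is
verified by exhaustive enumeration (:func:`count_solutions`), not assumed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from ._kernels import count_zero_cost_kernel

__all__ = [
    "Puzzle",
    "Assignment",
    "DONALD_GERALD_ROBERT",
    "parse_puzzle",
    "word_value",
    "cost",
    "is_solution",
    "count_solutions",
    "generate_random_puzzle",
    "random_assignment",
    "PuzzleGenerationError",
]

#: Penalty charged to leading-zero assignments.  Must exceed the maximum
#: attainable valid cost; for base-10 words of length <= W any valid cost is
#: below 2 * 10**W, so 10**7 covers words up to 6 letters.
DEFAULT_PENALTY = 10**7

_PUZZLE_RE = re.compile(r"^([A-Z]+)\+([A-Z]+)=([A-Z]+)$")

#: The alphametic instance used throughout: its first and second operands
#: share the final trigram "ALD", and it has a unique solution.
DONALD_GERALD_ROBERT = "DONALD+GERALD=ROBERT"

Assignment = np.ndarray
"""An injective letter->digit map: ``digits[i]`` is the digit of letter ``i``
in the puzzle's alphabet order.  For a 10-letter puzzle this is a permutation
of 0..9."""


class PuzzleGenerationError(RuntimeError):
    """Raised when rejection sampling fails to produce a unique-solution puzzle."""


@dataclass(frozen=True)
class Puzzle:
    """A cryptarithmetic sum ``operand1 + operand2 = result``.

    Attributes
    ----------
    operand1, operand2, result
        The three uppercase words.
    alphabet
        Distinct letters in first-occurrence order scanning operand1,
        operand2, result.
    leading_letters
        First letters of the three words (1-3 distinct members).
    penalty_cost
        Cost charged to assignments that put 0 on a leading letter.
    """

    operand1: str
    operand2: str
    result: str
    alphabet: tuple[str, ...]
    leading_letters: frozenset[str]
    penalty_cost: int = DEFAULT_PENALTY

    # derived, cached arrays used by the evaluation kernels
    _coefs: np.ndarray = field(default=None, repr=False, compare=False)
    _lead_mask: np.ndarray = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        L = len(self.alphabet)
        if not 2 <= L <= 10:
            raise ValueError(f"alphabet must have 2-10 letters, got {L}")
        index = {ch: i for i, ch in enumerate(self.alphabet)}
        coefs = np.zeros(L, dtype=np.int64)
        for word, sign in ((self.result, 1), (self.operand1, -1), (self.operand2, -1)):
            for pos, ch in enumerate(word):
                coefs[index[ch]] += sign * 10 ** (len(word) - 1 - pos)
        lead = np.zeros(L, dtype=np.bool_)
        for ch in self.leading_letters:
            lead[index[ch]] = True
        object.__setattr__(self, "_coefs", coefs)
        object.__setattr__(self, "_lead_mask", lead)
        max_valid = 2 * 10 ** max(len(self.operand1), len(self.operand2), len(self.result))
        if self.penalty_cost <= max_valid:
            raise ValueError(
                f"penalty_cost={self.penalty_cost} does not exceed the maximum "
                f"valid cost bound {max_valid}"
            )

    @property
    def n_letters(self) -> int:
        return len(self.alphabet)

    @property
    def space_size(self) -> int:
        """Number of injective letter->digit maps, 10!/(10-L)!."""
        L = self.n_letters
        return math.factorial(10) // math.factorial(10 - L)

    @property
    def text(self) -> str:
        return f"{self.operand1}+{self.operand2}={self.result}"

    def letter_index(self, letter: str) -> int:
        return self.alphabet.index(letter)

    def assignment_from_map(self, mapping: dict[str, int]) -> Assignment:
        """Build an Assignment array from an explicit letter->digit dict."""
        digits = np.array([mapping[ch] for ch in self.alphabet], dtype=np.int64)
        _validate_assignment(self, digits)
        return digits


def parse_puzzle(text: str, penalty_cost: int = DEFAULT_PENALTY) -> Puzzle:
    """Parse a ``WORD+WORD=WORD`` expression into a :class:`Puzzle`.

    The alphabet is the distinct letters in first-occurrence order; leading
    letters are the first letters of the three words.  Surrounding whitespace
    is ignored.
    """
    stripped = text.strip()
    m = _PUZZLE_RE.match(stripped)
    if m is None:
        raise ValueError(f"malformed puzzle expression: {text!r}")
    op1, op2, res = m.groups()
    alphabet: list[str] = []
    for ch in op1 + op2 + res:
        if ch not in alphabet:
            alphabet.append(ch)
    if len(alphabet) > 10:
        raise ValueError(
            f"puzzle has {len(alphabet)} distinct letters; at most 10 allowed"
        )
    return Puzzle(
        operand1=op1,
        operand2=op2,
        result=res,
        alphabet=tuple(alphabet),
        leading_letters=frozenset({op1[0], op2[0], res[0]}),
        penalty_cost=penalty_cost,
    )


def _validate_assignment(pz: Puzzle, a: Assignment) -> None:
    a = np.asarray(a)
    if a.shape != (pz.n_letters,):
        raise ValueError(
            f"assignment has shape {a.shape}, expected ({pz.n_letters},)"
        )
    if len(set(a.tolist())) != pz.n_letters or a.min() < 0 or a.max() > 9:
        raise ValueError(f"assignment is not an injective map into 0..9: {a}")


def word_value(word: str, a: Assignment, pz: Puzzle) -> int:
    """Base-10 integer value of ``word`` under assignment ``a``."""
    value = 0
    index = {ch: i for i, ch in enumerate(pz.alphabet)}
    for ch in word:
        if ch not in index:
            raise ValueError(f"letter {ch!r} not in puzzle alphabet")
        value = value * 10 + int(a[index[ch]])
    return value


def cost(pz: Puzzle, a: Assignment) -> int:
    """Cost of assignment ``a``: the penalty if any leading letter holds digit
    0, otherwise ``|value(result) - value(op1) - value(op2)|``.  Zero exactly
    at a solution."""
    a = np.asarray(a, dtype=np.int64)
    if bool(np.any(a[pz._lead_mask] == 0)):
        return int(pz.penalty_cost)
    return int(abs(int(pz._coefs @ a)))


def is_solution(pz: Puzzle, a: Assignment) -> bool:
    return cost(pz, a) == 0


def count_solutions(pz: Puzzle, limit: int | None = None) -> int:
    """Count zero-cost assignments by exhaustive enumeration of all
    10!/(10-L)! injective letter->digit maps.

    Parameters
    ----------
    limit
        Optional early-exit bound: stop as soon as this many solutions are
        found (useful for uniqueness screening, where only 0/1/2+ matters).
    """
    cap = pz.space_size + 1 if limit is None else int(limit)
    return int(count_zero_cost_kernel(pz._coefs, pz._lead_mask, cap))


def random_assignment(pz: Puzzle, rng: np.random.Generator) -> Assignment:
    """Uniformly random injective assignment for ``pz``."""
    return rng.permutation(10)[: pz.n_letters].astype(np.int64)


def _letterize(digit_strings: list[str]) -> list[str]:
    """Replace digits by letters A.. in first-occurrence order."""
    mapping: dict[str, str] = {}
    letters = "ABCDEFGHIJ"
    out = []
    for s in digit_strings:
        word = []
        for d in s:
            if d not in mapping:
                mapping[d] = letters[len(mapping)]
            word.append(mapping[d])
        out.append("".join(word))
    return out


def generate_random_puzzle(
    word_len: int = 6,
    rng_seed: int | np.random.Generator = 0,
    max_rejects: int = 100_000,
    penalty_cost: int = DEFAULT_PENALTY,
) -> Puzzle:
    """Generate a random 10-letter puzzle with a unique solution.

    Draws two random ``word_len``-digit operands (no leading zeros), forms
    their sum, and keeps the instance only if the sum also has ``word_len``
    digits, all 10 digits occur across the three numbers, and exhaustive
    enumeration confirms exactly one solution.  Construction from a concrete
    sum guarantees at least one solution before the uniqueness screen.

    Deterministic for a fixed integer seed.  Raises
    :class:`PuzzleGenerationError` after ``max_rejects`` failed draws.
    """
    if word_len < 4:
        raise ValueError("word_len must be >= 4 to fit 10 distinct digits")
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    lo, hi = 10 ** (word_len - 1), 10**word_len
    for _ in range(max_rejects):
        a = int(rng.integers(lo, hi))
        b = int(rng.integers(lo, hi))
        s = a + b
        if s >= hi:  # result must have word_len digits too
            continue
        strings = [str(a), str(b), str(s)]
        if len(set("".join(strings))) != 10:
            continue
        words = _letterize(strings)
        pz = parse_puzzle(f"{words[0]}+{words[1]}={words[2]}", penalty_cost=penalty_cost)
        if count_solutions(pz, limit=2) == 1:
            return pz
    raise PuzzleGenerationError(
        f"no unique-solution puzzle found in {max_rejects} draws"
    )
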