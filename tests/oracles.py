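"""Independent oracles used by the tests.

Everything here is deliberately written without the package's evaluation
code paths: costs via plain Python string/integer arithmetic, solution
counting via itertools enumeration, and column-wise carry addition as a
second, structurally different correctness check.
"""

from __future__ import annotations

import itertools
from math import factorial


def oracle_cost(op1: str, op2: str, res: str, mapping: dict[str, int],
                penalty: int = 10**7) -> int:
    """Cost by direct string substitution and integer arithmetic."""
    for word in (op1, op2, res):
        if mapping[word[0]] == 0:
            return penalty

    def val(word: str) -> int:
        return int("".join(str(mapping[ch]) for ch in word))

    return abs(val(res) - val(op1) - val(op2))


def oracle_count_solutions(op1: str, op2: str, res: str) -> int:
    """Count solutions by enumerating all injective letter->digit maps."""
    letters = []
    for ch in op1 + op2 + res:
        if ch not in letters:
            letters.append(ch)
    count = 0
    for digits in itertools.permutations(range(10), len(letters)):
        mapping = dict(zip(letters, digits))
        if oracle_cost(op1, op2, res, mapping) == 0:
            count += 1
    return count


def columnwise_is_solution(op1: str, op2: str, res: str,
                           mapping: dict[str, int]) -> bool:
    """Check the sum digit column by digit column, propagating carries —
    a different mechanism from integer arithmetic."""
    for word in (op1, op2, res):
        if mapping[word[0]] == 0:
            return False
    a = [mapping[ch] for ch in reversed(op1)]
    b = [mapping[ch] for ch in reversed(op2)]
    r = [mapping[ch] for ch in reversed(res)]
    carry = 0
    for i in range(len(r)):
        da = a[i] if i < len(a) else 0
        db = b[i] if i < len(b) else 0
        s = da + db + carry
        if s % 10 != r[i]:
            return False
        carry = s // 10
    return carry == 0 and len(r) >= max(len(a), len(b))


def oracle_count_solutions_columnwise(op1: str, op2: str, res: str) -> int:
    letters = []
    for ch in op1 + op2 + res:
        if ch not in letters:
            letters.append(ch)
    count = 0
    for digits in itertools.permutations(range(10), len(letters)):
        if columnwise_is_solution(op1, op2, res, dict(zip(letters, digits))):
            count += 1
    return count


def injective_space_size(n_letters: int) -> int:
    return factorial(10) // factorial(10 - n_letters)
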