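"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written from the definitions, without
reusing any code path from the package under test.
"""

from __future__ import annotations

import math
from typing import Sequence


def levenshtein_dp_table(a: str, b: str) -> int:
    """Full-table unit-cost edit distance, straight from the recurrence."""
    m, n = len(a), len(b)
    table = [[0] * (n + 1) for _ in range(m + 1)]
    for i in range(m + 1):
        table[i][0] = i
    for j in range(n + 1):
        table[0][j] = j
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            table[i][j] = min(
                table[i - 1][j] + 1,
                table[i][j - 1] + 1,
                table[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
            )
    return table[m][n]


def dtw_by_path_enumeration(s1: Sequence[str], s2: Sequence[str]) -> float:
    """Minimum cumulative cost over all monotone warping paths.

    Enumerates every path from cell (1,1) to (m,n) built from diagonal,
    down, and right steps, summing the word cost of each visited cell;
    feasible for sequences of up to ~4 words.
    """
    m, n = len(s1), len(s2)
    cost = [[levenshtein_dp_table(s1[i], s2[j]) for j in range(n)] for i in range(m)]

    best = math.inf

    def walk(i: int, j: int, total: float) -> None:
        nonlocal best
        total += cost[i][j]
        if total >= best:
            return
        if i == m - 1 and j == n - 1:
            best = total
            return
        if i + 1 < m and j + 1 < n:
            walk(i + 1, j + 1, total)
        if i + 1 < m:
            walk(i + 1, j, total)
        if j + 1 < n:
            walk(i, j + 1, total)

    walk(0, 0, 0.0)
    return best


def entropy_bits(labels: Sequence[int]) -> float:
    """Shannon entropy in bits, from the definition."""
    n = len(labels)
    total = 0.0
    for value in set(labels):
        p = sum(1 for x in labels if x == value) / n
        total -= p * math.log2(p)
    return total


def information_gain_longhand(feature: Sequence, labels: Sequence[int]) -> float:
    """H(y) - sum_v p(v) H(y | f = v), computed longhand."""
    n = len(labels)
    gain = entropy_bits(labels)
    for value in set(feature):
        subset = [y for x, y in zip(feature, labels) if x == value]
        gain -= len(subset) / n * entropy_bits(subset)
    return gain


def f1_score_by_counting(predicted: Sequence[bool], gold: Sequence[bool]) -> float:
    tp = sum(p and g for p, g in zip(predicted, gold))
    fp = sum(p and not g for p, g in zip(predicted, gold))
    fn = sum(g and not p for p, g in zip(predicted, gold))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else 0.0


def best_cutoff_exhaustive(probs: Sequence[float], gold: Sequence[bool]) -> float:
    """Max F1 over every threshold on the same 0.01 grid (value only)."""
    best = -1.0
    for step in range(101):
        t = step / 100.0
        predicted = [p >= t for p in probs]
        best = max(best, f1_score_by_counting(predicted, gold))
    return best
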