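"""Independent brute-force oracles used by the tests."""

from __future__ import annotations

import itertools


def brute_force_max_weight_matching(weights: dict[tuple[int, int], float],
                                    allow_empty: bool = True) -> float:
    """Exhaustively enumerate all matchings and return the max total weight.

    ``weights`` maps unordered pairs (i, j), i < j, to real weights.  Feasible
    matchings use each node at most once.
    """
    pairs = sorted(weights)

    def rec(idx: int, used: frozenset) -> float:
        if idx == len(pairs):
            return 0.0
        i, j = pairs[idx]
        best = rec(idx + 1, used)  # skip this pair
        if i not in used and j not in used:
            take = weights[(i, j)] + rec(idx + 1, used | {i, j})
            best = max(best, take)
        return best

    best = rec(0, frozenset())
    if not allow_empty and best == 0.0 and pairs:
        best = max(weights.values())
    return best


def brute_force_bipartite_matching(sim) -> tuple[int, float]:
    """Best (count at max weight) one-to-one assignment between two node sets,
    by exhaustive enumeration over injective mappings (small inputs only)."""
    import numpy as np

    sim = np.asarray(sim, dtype=float)
    a, b = sim.shape
    best_w = 0.0
    best_k = 0
    cols = range(b)
    for k in range(1, min(a, b) + 1):
        for rows in itertools.combinations(range(a), k):
            for perm in itertools.permutations(cols, k):
                w = sum(sim[r, c] for r, c in zip(rows, perm))
                if w > best_w + 1e-12:
                    best_w, best_k = w, k
    return best_k, best_w
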