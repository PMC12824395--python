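"""Independent oracles and instance factories shared by the test suite."""

from __future__ import annotations

import itertools

import numpy as np

from medseq.ssa_core import (
    CostMatrix,
    dissimilarity_matrix,
    transition_rates,
    trate_costs,
)
from medseq.states import TREATMENT_STATES
from medseq.synthetic_registry import DEFAULT_ARCHETYPES


def brute_force_edit_distance(a, b, costs: CostMatrix) -> float:
    """Plain recursion over every edit script (no memoisation): the
    independent oracle for optimal matching on short sequences."""
    alpha = costs.alphabet

    def rec(x, y):
        if not x:
            return costs.indel * len(y)
        if not y:
            return costs.indel * len(x)
        return min(
            rec(x[1:], y[1:]) + costs.sub[alpha.index(x[0]), alpha.index(y[0])],
            rec(x[1:], y) + costs.indel,
            rec(x, y[1:]) + costs.indel,
        )

    return rec(tuple(a), tuple(b))


def exhaustive_pam_objective(D: np.ndarray, w: np.ndarray, k: int) -> float:
    """Global minimum of the weighted k-medoids loss by enumerating every
    medoid subset."""
    return min(
        float((D[:, list(m)].min(axis=1) * w).sum())
        for m in itertools.combinations(range(len(w)), k)
    )


def archetype_instance(seed: int, noise: float = 0.05):
    """A small cluster-structured sequence set: k archetypes, light
    per-period noise. Returns (dissimilarity, true_k)."""
    rng = np.random.default_rng(seed)
    arch = list(DEFAULT_ARCHETYPES.values())
    k = int(rng.integers(2, 4))
    chosen = rng.choice(len(arch), size=k, replace=False)
    n = int(rng.integers(max(5, 2 * k), 9))
    rows = []
    for i in range(n):
        seq = list(arch[chosen[i % k]])
        for t in range(len(seq)):
            if rng.random() < noise:
                seq[t] = TREATMENT_STATES[rng.integers(0, len(TREATMENT_STATES))]
        rows.append(seq)
    seqs = np.array(rows, dtype=object)
    dissim = dissimilarity_matrix(seqs, trate_costs(transition_rates(seqs)))
    return dissim, k
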