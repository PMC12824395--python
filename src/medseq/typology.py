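"""Medication-use typologies: weighted clustering of the OM dissimilarity.

Clusters are fitted on unique sequences carrying multiplicity weights,
which is exactly equivalent to clustering the fully expanded multiset of
person-level sequences. Three methods are offered — hierarchical Ward,
partitioning around medoids (PAM), and PAM initialised from the Ward
partition — and the number of typologies is selected by maximising the
weighted average silhouette width (ASW) over a range of k.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ssa_core import DissimilarityMatrix
from .states import (
    AD_MONO,
    ANTIPSYCH,
    AUGMENT,
    CENSORED,
    LACK,
    LI_AUGMENT,
    LITHIUM,
    MOOD_STAB,
)

log = logging.getLogger(__name__)

METHODS = ("pam", "ward_then_pam", "ward")

#: Typology names by the dominant state of the cluster medoid.
TYPOLOGY_NAMES = {
    LACK: "treatment failure",
    AD_MONO: "persistent antidepressant-monotherapy",
    MOOD_STAB: "persistent mood-stabilizers",
    ANTIPSYCH: "persistent antipsychotics",
    LITHIUM: "persistent lithium",
    AUGMENT: "persistent augmentation",
    LI_AUGMENT: "persistent lithium with augmentation",
}


@dataclass(frozen=True)
class ClusterSolution:
    method: str
    k: int
    labels: np.ndarray  # per unique sequence, 1..k
    medoids: np.ndarray | None  # unique-sequence indices (PAM variants)
    silhouettes: np.ndarray
    asw: float

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.min() < 1 or lab.max() > self.k:
            raise ValueError("labels must lie in 1..k")
        if len(np.unique(lab)) != self.k:
            raise ValueError("every cluster must be non-empty")


# ---------------------------------------------------------------------------
# Ward (weighted Lance–Williams on squared dissimilarities, ward.D2 style)
# ---------------------------------------------------------------------------


def _ward_merges(D: np.ndarray, w: np.ndarray) -> list[tuple[int, int]]:
    """Full agglomeration schedule as (keep, drop) index pairs.

    Inter-cluster cost is initialised to 2 w_i w_j / (w_i + w_j) * d_ij^2
    and updated with the Ward Lance–Williams recurrence, which makes the
    weighted run identical to agglomerating the expanded multiset.
    Ties break toward the lowest (i, j) pair.
    """
    n = len(w)
    sizes = w.astype(float).copy()
    with np.errstate(invalid="ignore"):
        M = (2.0 * np.outer(sizes, sizes) / np.add.outer(sizes, sizes)) * D**2
    np.fill_diagonal(M, np.inf)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int]] = []
    for _ in range(n - 1):
        flat = np.argmin(M)
        i, j = divmod(int(flat), n)
        if i > j:
            i, j = j, i
        si, sj, sk = sizes[i], sizes[j], sizes
        dij = M[i, j]
        with np.errstate(invalid="ignore"):
            new = ((si + sk) * M[i] + (sj + sk) * M[j] - sk * dij) / (si + sj + sk)
        M[i, :] = new
        M[:, i] = new
        M[i, i] = np.inf
        M[j, :] = np.inf
        M[:, j] = np.inf
        sizes[i] = si + sj
        active[j] = False
        merges.append((i, j))
    return merges


def _cut_merges(merges: list[tuple[int, int]], n: int, k: int) -> np.ndarray:
    """Replay the first n - k merges; return labels 1..k (order of first
    appearance)."""
    parent = np.arange(n)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in merges[: n - k]:
        parent[find(j)] = find(i)
    roots = np.array([find(x) for x in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    # relabel by first appearance for determinism
    order = {}
    out = np.empty(n, dtype=np.int64)
    for idx, lab in enumerate(labels):
        if lab not in order:
            order[lab] = len(order) + 1
        out[idx] = order[lab]
    return out


def ward_cluster(dissim: DissimilarityMatrix, k: int) -> ClusterSolution:
    """Weighted hierarchical Ward clustering cut at k clusters."""
    n = dissim.n_unique
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    merges = _ward_merges(dissim.matrix, dissim.weights)
    labels = _cut_merges(merges, n, k)
    sil, asw = silhouette(dissim, labels)
    return ClusterSolution("ward", k, labels, None, sil, asw)


# ---------------------------------------------------------------------------
# PAM (weighted BUILD + steepest-descent SWAP)
# ---------------------------------------------------------------------------


def _weighted_medoid(D: np.ndarray, w: np.ndarray, members: np.ndarray) -> int:
    costs = (D[np.ix_(members, members)] * w[members]).sum(axis=1)
    return int(members[int(np.argmin(costs))])


def _pam_build(D: np.ndarray, w: np.ndarray, k: int) -> list[int]:
    n = len(w)
    first = int(np.argmin((D * w).sum(axis=1)))
    medoids = [first]
    dn = D[:, first].copy()
    while len(medoids) < k:
        # gain of adding candidate h: sum of per-point cost reductions
        gain = (np.maximum(dn[None, :] - D, 0.0) * w).sum(axis=1)
        gain[medoids] = -np.inf
        h = int(np.argmax(gain))
        medoids.append(h)
        dn = np.minimum(dn, D[:, h])
    return medoids


def pam_cluster(
    dissim: DissimilarityMatrix,
    k: int,
    init: np.ndarray | None = None,
    max_iter: int = 200,
) -> ClusterSolution:
    """Weighted partitioning around medoids.

    Greedy deterministic BUILD seeding followed by steepest-descent
    single swaps; the weighted objective (sum of each sequence's
    multiplicity times its distance to the nearest medoid) never
    increases. When ``init`` labels are given (the Ward hybrid), BUILD
    is replaced by extracting each initial cluster's weighted medoid.
    """
    D, w = dissim.matrix, dissim.weights
    n = dissim.n_unique
    if not 2 <= k <= n:
        raise ValueError(f"k={k} outside 2..{n}")
    method = "pam"
    if init is None:
        medoids = _pam_build(D, w, k)
    else:
        method = "ward_then_pam"
        init = np.asarray(init)
        uniq = np.unique(init)
        if len(uniq) != k:
            raise ValueError("init labels must form exactly k clusters")
        medoids = [_weighted_medoid(D, w, np.flatnonzero(init == c)) for c in uniq]

    medoids = list(dict.fromkeys(medoids))
    if len(medoids) < k:  # duplicate medoids from degenerate init
        extra = [i for i in np.argsort((D * w).sum(axis=1)) if i not in medoids]
        medoids += [int(e) for e in extra[: k - len(medoids)]]

    Dm = D[:, medoids]
    for _ in range(max_iter):
        order = np.argsort(Dm, axis=1, kind="stable")
        nearest = order[:, 0]
        dn1 = Dm[np.arange(n), nearest]
        dn2 = Dm[np.arange(n), order[:, 1]]
        best_delta, best_swap = -1e-9, None
        td = float((dn1 * w).sum())
        for mi in range(k):
            base = np.where(nearest == mi, dn2, dn1)
            cand = np.minimum(base[None, :], D)  # (h, j)
            tds = (cand * w).sum(axis=1)
            tds[medoids] = np.inf
            h = int(np.argmin(tds))
            delta = float(tds[h]) - td
            if delta < best_delta:
                best_delta, best_swap = delta, (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
        Dm = D[:, medoids]

    medoids_arr = np.array(sorted(medoids), dtype=np.int64)
    labels = np.argmin(D[:, medoids_arr], axis=1)
    # medoids label their own cluster even under distance ties
    for ci, m in enumerate(medoids_arr):
        labels[m] = ci
    labels = labels + 1
    sil, asw = silhouette(dissim, labels)
    return ClusterSolution(method, k, labels, medoids_arr, sil, asw)


def pam_objective(dissim: DissimilarityMatrix, medoids) -> float:
    """Weighted total distance to the nearest medoid (the PAM loss)."""
    Dm = dissim.matrix[:, list(medoids)]
    return float((Dm.min(axis=1) * dissim.weights).sum())


# ---------------------------------------------------------------------------
# Silhouette
# ---------------------------------------------------------------------------


def silhouette(
    dissim: DissimilarityMatrix, labels: np.ndarray
) -> tuple[np.ndarray, float]:
    """Weighted silhouettes s(i) = (b - a) / max(a, b) and their mean.

    Weighted so the result equals the classic silhouette of the expanded
    multiset: the within-cluster mean a(i) divides by (cluster weight -
    1), counting the other copies of i at distance zero; singleton
    clusters get s = 0 by convention, as does the degenerate a = b = 0
    case.
    """
    D, w = dissim.matrix, np.asarray(dissim.weights, dtype=float)
    labels = np.asarray(labels)
    clusters = np.unique(labels)
    cw = {c: w[labels == c].sum() for c in clusters}
    n = len(labels)
    s = np.zeros(n)
    sums = {c: D[:, labels == c] @ w[labels == c] for c in clusters}
    for i in range(n):
        c = labels[i]
        if cw[c] <= 1:
            continue
        a = sums[c][i] / (cw[c] - 1)
        b = min(sums[c2][i] / cw[c2] for c2 in clusters if c2 != c)
        m = max(a, b)
        s[i] = 0.0 if m == 0 else (b - a) / m
    asw = float((s * w).sum() / w.sum())
    return s, asw


# ---------------------------------------------------------------------------
# Model selection and naming
# ---------------------------------------------------------------------------


def select_typologies(
    dissim: DissimilarityMatrix,
    k_range=range(2, 16),
    methods: tuple[str, ...] = METHODS,
) -> tuple[ClusterSolution, pd.DataFrame]:
    """Fit every (method, k) and return the highest-ASW solution.

    Ties break toward smaller k, then method order pam > ward_then_pam >
    ward. The ASW table lists every fitted combination.
    """
    ward_merges = None
    if "ward" in methods or "ward_then_pam" in methods:
        ward_merges = _ward_merges(dissim.matrix, dissim.weights)
    rows = []
    best: ClusterSolution | None = None
    for k in k_range:
        if k > dissim.n_unique:
            continue
        for method in sorted(methods, key=METHODS.index):
            if method == "pam":
                sol = pam_cluster(dissim, k)
            elif method == "ward":
                labels = _cut_merges(ward_merges, dissim.n_unique, k)
                sil, asw = silhouette(dissim, labels)
                sol = ClusterSolution("ward", k, labels, None, sil, asw)
            elif method == "ward_then_pam":
                init = _cut_merges(ward_merges, dissim.n_unique, k)
                sol = pam_cluster(dissim, k, init=init)
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append((method, k, sol.asw))
            if best is None or sol.asw > best.asw:
                best = sol
    if best is None:
        raise ValueError("no (method, k) combination could be fitted")
    table = pd.DataFrame(rows, columns=["method", "k", "asw"])
    if best.asw < 0.25:
        log.warning("low ASW (%.3f): little cluster structure in the data", best.asw)
    return best, table


def cluster_medoids(dissim: DissimilarityMatrix, labels: np.ndarray) -> dict[int, int]:
    """Weighted medoid (unique-sequence index) of each cluster."""
    labels = np.asarray(labels)
    return {
        int(c): _weighted_medoid(dissim.matrix, dissim.weights, np.flatnonzero(labels == c))
        for c in np.unique(labels)
    }


def name_typologies(
    solution: ClusterSolution, dissim: DissimilarityMatrix
) -> dict[int, str]:
    """Label each cluster by the dominant state of its medoid sequence.

    A medoid dominated by the censoring symbol, or with a tied modal
    state, is left "unclassified" with a warning.
    """
    if solution.medoids is not None:
        med = {c + 1: int(m) for c, m in enumerate(solution.medoids)}
    else:
        med = cluster_medoids(dissim, solution.labels)
    names: dict[int, str] = {}
    for c in sorted(np.unique(solution.labels)):
        seq = dissim.sequences[med[int(c)]]
        counts = np.bincount(seq, minlength=len(dissim.alphabet))
        top = counts.max()
        modal = np.flatnonzero(counts == top)
        state = dissim.alphabet[int(modal[0])]
        if len(modal) > 1 or state == CENSORED or state not in TYPOLOGY_NAMES:
            warnings.warn(f"cluster {c}: ambiguous medoid, left unclassified")
            names[int(c)] = "unclassified"
        else:
            names[int(c)] = TYPOLOGY_NAMES[state]
    return names
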