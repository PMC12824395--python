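"""Sequence-analysis kernel.

Transition rates between states, transition-rate (TRATE) substitution
costs, optimal-matching edit distances, transversal and longitudinal
entropy, a complexity index, and time-in-state summaries with log-linear
group contrasts. Sequences are categorical strings of equal length over
the 8-symbol alphabet (7 treatment states + censoring).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import ALPHABET, CENSORED


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition probabilities with raw counts.

    ``observed[i]`` is False when state i never occurs as an origin
    (positions 1..L-1); its probability row is all zero rather than NaN.
    """

    probs: np.ndarray
    counts: np.ndarray
    alphabet: tuple[str, ...] = ALPHABET

    @property
    def observed(self) -> np.ndarray:
        return self.counts.sum(axis=1) > 0

    def leave_probability(self) -> np.ndarray:
        """1 - p(i -> i): likelihood of leaving state i per period."""
        return np.where(self.observed, 1.0 - np.diag(self.probs), np.nan)

    def destination_shares(self) -> np.ndarray:
        """Off-diagonal row mass renormalised: where transitions lead."""
        off = self.probs.copy()
        np.fill_diagonal(off, 0.0)
        tot = off.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(tot > 0, off / tot, 0.0)
        return out


@dataclass(frozen=True)
class CostMatrix:
    """Symmetric substitution costs plus a single indel cost."""

    sub: np.ndarray
    indel: float
    alphabet: tuple[str, ...] = ALPHABET

    def __post_init__(self) -> None:
        s = np.asarray(self.sub, dtype=float)
        if s.shape != (len(self.alphabet), len(self.alphabet)):
            raise ValueError("substitution matrix shape does not match alphabet")
        if not np.allclose(s, s.T):
            raise ValueError("substitution matrix must be symmetric")
        if np.diag(s).any():
            raise ValueError("substitution matrix must have zero diagonal")
        if self.indel <= 0:
            raise ValueError("indel cost must be positive")


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Pairwise OM distances over unique sequences with multiplicities."""

    matrix: np.ndarray
    weights: np.ndarray
    sequences: np.ndarray  # (n_unique, L) state indices, lexicographic order
    alphabet: tuple[str, ...] = ALPHABET

    @property
    def n_unique(self) -> int:
        return len(self.weights)


def _encode(sequences, alphabet: tuple[str, ...]) -> np.ndarray:
    """Sequences (array, DataFrame s1.., or list of symbol lists) -> int array."""
    if isinstance(sequences, pd.DataFrame):
        cols = [c for c in sequences.columns if c.startswith("s") and c[1:].isdigit()]
        cols.sort(key=lambda c: int(c[1:]))
        sequences = sequences[cols].to_numpy()
    arr = np.asarray(sequences)
    if arr.dtype.kind in "iu":
        return arr.astype(np.int64)
    idx = {s: i for i, s in enumerate(alphabet)}
    try:
        return np.vectorize(idx.__getitem__, otypes=[np.int64])(arr)
    except KeyError as e:
        raise ValueError(f"symbol outside alphabet: {e.args[0]!r}") from None


def transition_rates(
    sequences,
    weights=None,
    alphabet: tuple[str, ...] = ALPHABET,
) -> TransitionMatrix:
    """Pooled lag-1 transition rates across sequences.

    p(i -> j) = weighted #(s_t = i, s_{t+1} = j) / weighted #(s_t = i,
    t < L), positions pooled over all sequences. Rows for states never
    observed as an origin are zero and flagged via ``observed``.
    """
    arr = _encode(sequences, alphabet)
    if arr.ndim != 2 or len(arr) == 0:
        raise ValueError("need a non-empty 2-D sequence array")
    n_states = len(alphabet)
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, dtype=float)
    counts = np.zeros((n_states, n_states))
    src = arr[:, :-1].ravel()
    dst = arr[:, 1:].ravel()
    wrep = np.repeat(w, arr.shape[1] - 1)
    np.add.at(counts, (src, dst), wrep)
    row = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        probs = np.where(row > 0, counts / row, 0.0)
    return TransitionMatrix(probs=probs, counts=counts, alphabet=alphabet)


def trate_costs(
    rates: TransitionMatrix, cval: float = 2.0, indel: float | None = None
) -> CostMatrix:
    """Transition-rate substitution costs.

    cost(i, j) = cval - p(i -> j) - p(j -> i) for i != j (floored at 0),
    zero diagonal; states that are rarely interchanged are expensive to
    substitute. Indel defaults to cval / 2.
    """
    p = rates.probs
    sub = cval - p - p.T
    np.fill_diagonal(sub, 0.0)
    sub = np.maximum(sub, 0.0)
    return CostMatrix(
        sub=sub,
        indel=cval / 2.0 if indel is None else indel,
        alphabet=rates.alphabet,
    )


def om_distance(a, b, costs: CostMatrix) -> float:
    """Optimal-matching distance between two sequences.

    Needleman–Wunsch style dynamic programme: the cheapest series of
    substitutions, insertions and deletions transforming ``a`` into
    ``b``. Sequences may differ in length and are given as symbol lists
    or index arrays over ``costs.alphabet``.
    """
    sa = _encode(np.asarray(a, dtype=object).reshape(1, -1), costs.alphabet)[0]
    sb = _encode(np.asarray(b, dtype=object).reshape(1, -1), costs.alphabet)[0]
    la, lb = len(sa), len(sb)
    D = np.empty((la + 1, lb + 1))
    D[:, 0] = np.arange(la + 1) * costs.indel
    D[0, :] = np.arange(lb + 1) * costs.indel
    for i in range(1, la + 1):
        for j in range(1, lb + 1):
            D[i, j] = min(
                D[i - 1, j - 1] + costs.sub[sa[i - 1], sb[j - 1]],
                D[i - 1, j] + costs.indel,
                D[i, j - 1] + costs.indel,
            )
    return float(D[la, lb])


def _om_pairwise(seqs: np.ndarray, costs: CostMatrix, block: int = 200_000) -> np.ndarray:
    """All-pairs OM distances for equal-length encoded sequences.

    Runs the DP with the pair axis vectorised, two rolling DP rows at a
    time, in blocks to bound memory.
    """
    n, L = seqs.shape
    out = np.zeros((n, n))
    ii, jj = np.triu_indices(n, k=1)
    indel = costs.indel
    sub = costs.sub
    for lo in range(0, len(ii), block):
        bi, bj = ii[lo : lo + block], jj[lo : lo + block]
        A, B = seqs[bi], seqs[bj]  # (p, L)
        p = len(bi)
        prev = np.tile(np.arange(L + 1) * indel, (p, 1))
        cur = np.empty((p, L + 1))
        for i in range(1, L + 1):
            cur[:, 0] = i * indel
            subrow = sub[A[:, i - 1][:, None], B]  # (p, L)
            for j in range(1, L + 1):
                cur[:, j] = np.minimum(
                    prev[:, j - 1] + subrow[:, j - 1],
                    np.minimum(prev[:, j], cur[:, j - 1]) + indel,
                )
            prev, cur = cur, prev
        d = prev[:, L]
        out[bi, bj] = d
        out[bj, bi] = d
    return out


def dissimilarity_matrix(
    sequences,
    costs: CostMatrix,
    weights=None,
) -> DissimilarityMatrix:
    """Weighted OM dissimilarity matrix over unique sequences.

    Identical sequences are pooled into a single row whose weight is
    their multiplicity (or summed input weight); rows are ordered
    lexicographically by state index so the result is independent of
    input order.
    """
    arr = _encode(sequences, costs.alphabet)
    if len(arr) < 1:
        raise ValueError("need at least one sequence")
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, dtype=float)
    uniq, inv = np.unique(arr, axis=0, return_inverse=True)
    uw = np.zeros(len(uniq))
    np.add.at(uw, inv, w)
    mat = _om_pairwise(uniq, costs)
    return DissimilarityMatrix(
        matrix=mat, weights=uw, sequences=uniq, alphabet=costs.alphabet
    )


def unique_index(sequences, dissim: DissimilarityMatrix) -> np.ndarray:
    """Map each input sequence to its row in ``dissim.sequences``."""
    arr = _encode(sequences, dissim.alphabet)
    lookup = {tuple(row): i for i, row in enumerate(dissim.sequences)}
    return np.array([lookup[tuple(r)] for r in arr], dtype=np.int64)


def _entropy(p: np.ndarray, norm_states: int) -> float:
    p = p[p > 0]
    if len(p) == 0:
        return 0.0
    return float(-(p * np.log(p)).sum() / np.log(norm_states))


def transversal_entropy(
    sequences,
    weights=None,
    alphabet: tuple[str, ...] = ALPHABET,
    norm_states: int | None = None,
) -> np.ndarray:
    """Normalised Shannon entropy of the state distribution per period.

    0 when everyone shares the same state, 1 for a uniform spread over
    the ``norm_states`` alphabet (defaults to the full alphabet size).
    """
    arr = _encode(sequences, alphabet)
    ns = len(alphabet) if norm_states is None else norm_states
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, dtype=float)
    out = np.empty(arr.shape[1])
    for t in range(arr.shape[1]):
        dist = np.bincount(arr[:, t], weights=w, minlength=len(alphabet)).astype(float)
        out[t] = _entropy(dist / dist.sum(), ns)
    return out


def longitudinal_entropy(
    sequence, alphabet: tuple[str, ...] = ALPHABET, norm_states: int | None = None
) -> float:
    """Normalised entropy of the within-sequence state distribution."""
    arr = _encode(np.asarray(sequence, dtype=object).reshape(1, -1), alphabet)[0]
    ns = len(alphabet) if norm_states is None else norm_states
    dist = np.bincount(arr, minlength=len(alphabet)).astype(float)
    return _entropy(dist / dist.sum(), ns)


def complexity_index(
    sequence, alphabet: tuple[str, ...] = ALPHABET, norm_states: int | None = None
) -> float:
    """Geometric mean of transition density and longitudinal entropy.

    sqrt((#transitions / (L - 1)) * normalised entropy); 0 for a
    constant sequence, approaching 1 for maximally volatile ones.
    """
    arr = _encode(np.asarray(sequence, dtype=object).reshape(1, -1), alphabet)[0]
    if len(arr) < 2:
        return 0.0
    trans = float((arr[1:] != arr[:-1]).mean())
    ent = longitudinal_entropy(sequence, alphabet, norm_states)
    return float(np.sqrt(trans * ent))


def mean_time_in_states(
    sequences,
    group_labels,
    weights=None,
    alphabet: tuple[str, ...] = ALPHABET,
) -> pd.DataFrame:
    """Mean periods and share of follow-up per group and state.

    Shares of the seven treatment states are computed over non-censored
    periods, so they sum to 1 within each group; the censored share is
    reported separately against the full 12-period grid.

    Returns a tidy frame with columns ``group, state, mean_periods,
    proportion``.
    """
    arr = _encode(sequences, alphabet)
    groups = np.asarray(group_labels)
    w = np.ones(len(arr)) if weights is None else np.asarray(weights, dtype=float)
    cens_idx = alphabet.index(CENSORED) if CENSORED in alphabet else -1
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        sub, ws = arr[sel], w[sel]
        counts = np.zeros(len(alphabet))
        for s in range(len(alphabet)):
            counts[s] = ((sub == s) * ws[:, None]).sum()
        total = counts.sum()
        noncens = total - (counts[cens_idx] if cens_idx >= 0 else 0.0)
        for s, name in enumerate(alphabet):
            if s == cens_idx:
                prop = counts[s] / total if total else np.nan
            else:
                prop = counts[s] / noncens if noncens else np.nan
            rows.append((g, name, counts[s] / ws.sum(), prop))
    return pd.DataFrame(rows, columns=["group", "state", "mean_periods", "proportion"])


def time_in_state_contrast(
    sequences,
    group_labels,
    reference_group: str,
    alphabet: tuple[str, ...] = ALPHABET,
    robust: bool = False,
) -> pd.DataFrame:
    """Log-linear (Poisson) contrasts of time in state between groups.

    For each state, person-level period counts are regressed on group
    indicators with an offset for the person's observed (non-censored)
    periods; exponentiated coefficients are rate ratios vs the
    reference group.

    Returns columns ``state, group, rate_ratio, ci_low, ci_high,
    p_value``.
    """
    import statsmodels.api as sm

    arr = _encode(sequences, alphabet)
    groups = pd.Series(np.asarray(group_labels), name="group")
    cens_idx = alphabet.index(CENSORED) if CENSORED in alphabet else -1
    observed = (arr != cens_idx).sum(axis=1).astype(float)
    ok = observed > 0
    levels = [g for g in pd.unique(groups) if g != reference_group]
    design = pd.get_dummies(
        pd.Categorical(groups, categories=[reference_group] + levels),
        drop_first=True,
        dtype=float,
    )
    X = sm.add_constant(design.to_numpy())
    rows = []
    for s, name in enumerate(alphabet):
        if s == cens_idx:
            continue
        y = (arr == s).sum(axis=1).astype(float)
        model = sm.GLM(
            y[ok],
            X[ok],
            family=sm.families.Poisson(),
            offset=np.log(observed[ok]),
        )
        try:
            fit = model.fit(cov_type="HC1" if robust else "nonrobust")
        except Exception:
            continue
        for i, g in enumerate(levels, start=1):
            coef, se = fit.params[i], fit.bse[i]
            rows.append(
                (
                    name,
                    g,
                    float(np.exp(coef)),
                    float(np.exp(coef - 1.959964 * se)),
                    float(np.exp(coef + 1.959964 * se)),
                    float(fit.pvalues[i]),
                )
            )
    return pd.DataFrame(
        rows, columns=["state", "group", "rate_ratio", "ci_low", "ci_high", "p_value"]
    )
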