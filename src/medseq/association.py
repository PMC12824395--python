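"""Multinomial logistic regression of typology membership.

Associations between cluster membership and population group (plus
covariates) are estimated by maximum-likelihood softmax regression with
the largest typology as the reference outcome. Reported effects are
odds ratios with Wald 95% confidence intervals; predicted probabilities
are marginally standardized (g-computation): every person's factor is
set to each level in turn and the model-predicted category
probabilities are averaged over the sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

Z975 = 1.959964


@dataclass(frozen=True)
class RegressionResult:
    """Fitted multinomial model with its design metadata.

    ``coef`` is (K-1, P) over non-reference outcome categories x terms;
    the reference category's coefficients are identically zero.
    """

    outcome_categories: tuple[str, ...]  # reference first
    terms: tuple[str, ...]  # "const" then dummy columns
    coef: np.ndarray
    se: np.ndarray
    pvalues: np.ndarray
    cov: np.ndarray
    factor_levels: dict[str, tuple[str, ...]]  # reference level first
    n: int
    llf: float
    converged: bool

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        """Per-row category probabilities (columns in outcome order)."""
        X = _design_matrix(data, self.factor_levels)
        eta = np.column_stack([np.zeros(len(X)), X @ self.coef.T])
        eta -= eta.max(axis=1, keepdims=True)
        p = np.exp(eta)
        return p / p.sum(axis=1, keepdims=True)


def _level_order(
    series: pd.Series, reference: str | None
) -> tuple[str, ...]:
    counts = series.value_counts()
    ref = counts.index[0] if reference is None else reference
    if ref not in counts.index:
        raise ValueError(f"reference level {ref!r} not present in {series.name!r}")
    others = sorted(str(v) for v in counts.index if v != ref)
    return (str(ref), *others)


def _design_matrix(
    data: pd.DataFrame, factor_levels: dict[str, tuple[str, ...]]
) -> np.ndarray:
    cols = [np.ones(len(data))]
    for factor, levels in factor_levels.items():
        vals = data[factor].astype(str)
        unknown = set(vals) - set(levels)
        if unknown:
            raise ValueError(f"unseen levels in {factor!r}: {sorted(unknown)}")
        for lv in levels[1:]:
            cols.append((vals == lv).to_numpy(dtype=float))
    return np.column_stack(cols)


def _term_names(factor_levels: dict[str, tuple[str, ...]]) -> tuple[str, ...]:
    names = ["const"]
    for factor, levels in factor_levels.items():
        names += [f"{factor}[{lv}]" for lv in levels[1:]]
    return tuple(names)


def fit_multinomial(
    outcome,
    design: pd.DataFrame,
    reference_outcome: str | None = None,
    reference_levels: dict[str, str] | None = None,
    maxiter: int = 200,
) -> RegressionResult:
    """Fit a multinomial logit of ``outcome`` on categorical factors.

    Parameters
    ----------
    outcome
        Category labels (e.g. typology names), one per person.
    design
        Frame of categorical predictors; every column is dummy-coded
        against its reference level.
    reference_outcome
        Reference category; defaults to the most frequent outcome.
    reference_levels
        Per-factor reference level; defaults to each factor's most
        frequent level.

    Raises
    ------
    ValueError
        On a rank-deficient design (naming the offending column) or
        failed convergence.
    """
    import statsmodels.api as sm

    y = pd.Series(outcome).astype(str).reset_index(drop=True)
    design = design.reset_index(drop=True)
    out_levels = _level_order(y.rename("outcome"), reference_outcome)
    if len(out_levels) < 2:
        raise ValueError("need at least two outcome categories")
    refs = reference_levels or {}
    factor_levels = {
        c: _level_order(design[c].astype(str), refs.get(c)) for c in design.columns
    }
    X = _design_matrix(design, factor_levels)
    terms = _term_names(factor_levels)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        for j in range(1, X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) < j + 1:
                raise ValueError(f"design is rank deficient at column {terms[j]!r}")
        raise ValueError("design is rank deficient")

    codes = y.map({lv: i for i, lv in enumerate(out_levels)}).to_numpy()
    model = sm.MNLogit(codes, X)
    start = np.zeros(X.shape[1] * (len(out_levels) - 1))
    import warnings as _warnings

    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            fit = model.fit(method="newton", start_params=start, maxiter=maxiter, disp=0)
            if not fit.mle_retvals.get("converged", False):
                # Newton stalls under quasi-separation; BFGS from zero is
                # the deterministic fallback before giving up.
                fit = model.fit(
                    method="bfgs", start_params=start, maxiter=5 * maxiter, disp=0
                )
    except np.linalg.LinAlgError:
        raise ValueError(
            "multinomial fit is degenerate (singular information matrix); "
            "check for separation or empty outcome x level cells"
        ) from None
    if not fit.mle_retvals.get("converged", False):
        raise ValueError(
            "multinomial fit did not converge "
            f"(iterations={fit.mle_retvals.get('iterations')}); "
            "check for separation or empty cells"
        )
    # statsmodels stores params as (P, K-1)
    coef = np.asarray(fit.params).T
    if np.abs(coef).max() > 10:
        j = int(np.argmax(np.abs(coef).max(axis=0)))
        raise ValueError(
            f"separation detected: coefficient for {terms[j]!r} diverged "
            "(an outcome category is empty in some predictor cell)"
        )
    se = np.asarray(fit.bse).T
    pv = np.asarray(fit.pvalues).T
    return RegressionResult(
        outcome_categories=out_levels,
        terms=terms,
        coef=coef,
        se=se,
        pvalues=pv,
        cov=np.asarray(fit.cov_params()),
        factor_levels=factor_levels,
        n=len(y),
        llf=float(fit.llf),
        converged=True,
    )


def odds_ratios(result: RegressionResult) -> pd.DataFrame:
    """Effect table: OR with Wald 95% CI per (typology, predictor level).

    Reference outcome and reference predictor levels appear as marked
    rows with OR 1 and no interval.
    """
    rows = []
    with np.errstate(over="ignore"):  # quasi-separated cells give huge CIs
        for ci, cat in enumerate(result.outcome_categories[1:]):
            for factor, levels in result.factor_levels.items():
                rows.append((cat, factor, levels[0], 1.0, np.nan, np.nan, np.nan, True))
                for lv in levels[1:]:
                    j = result.terms.index(f"{factor}[{lv}]")
                    b, s = result.coef[ci, j], result.se[ci, j]
                    rows.append(
                        (
                            cat,
                            factor,
                            lv,
                            float(np.exp(b)),
                            float(np.exp(b - Z975 * s)),
                            float(np.exp(b + Z975 * s)),
                            float(result.pvalues[ci, j]),
                            False,
                        )
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "typology",
            "factor",
            "level",
            "odds_ratio",
            "ci_low",
            "ci_high",
            "p_value",
            "is_reference",
        ],
    )


def fitted_probabilities(
    result: RegressionResult,
    data: pd.DataFrame,
    factor: str,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Marginally standardized typology probabilities by factor level.

    For each level of ``factor``, every person's value is set to that
    level and predicted probabilities are averaged — over the whole
    sample, or within each level of ``stratify_by``. Probabilities sum
    to 1 across typologies within each (stratum, level) row set.
    """
    if factor not in result.factor_levels:
        raise ValueError(f"{factor!r} was not a model factor")
    strata = (
        [("all", data)]
        if stratify_by is None
        else [(str(g), d) for g, d in data.groupby(data[stratify_by].astype(str))]
    )
    rows = []
    for stratum, frame in strata:
        for lv in result.factor_levels[factor]:
            mod = frame.copy()
            mod[factor] = lv
            probs = result.predict(mod).mean(axis=0)
            for cat, p in zip(result.outcome_categories, probs):
                rows.append((stratum, factor, lv, cat, float(p)))
    return pd.DataFrame(
        rows, columns=["stratum", "factor", "level", "typology", "probability"]
    )
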