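"""Confounder-adjusted logistic modelling of rare substitutions.

A binomial logistic regression classifies substitutions as rare vs common
from six potential confounders (conservation, codon degeneracy, GC content,
sequencing depth, recombination rate, protein disorder) plus their
interactions. The alternative model adds the binary PTM-region indicator and
its interactions. PTM significance is the likelihood-ratio (deviance) test
of alternative vs null; individual predictors are ranked by the deviance
lost when the predictor and every interaction containing it are deleted.
A marginality-respecting backward step procedure (AIC criterion) discards
uninformative terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

CONFOUNDERS = (
    "conservation",
    "codon_degeneracy",
    "gc_content",
    "read_depth",
    "recomb_rate",
    "in_disorder",
)
PTM_TERM = "in_ptm_region"
CONTINUOUS = ("conservation", "codon_degeneracy", "gc_content", "read_depth", "recomb_rate")
MIN_ROWS_PER_CLASS = 50

Term = frozenset


@dataclass
class FittedModel:
    terms: list[Term]
    result: object  # statsmodels GLMResults
    factors: tuple[str, ...]

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    @property
    def llf(self) -> float:
        return float(self.result.llf)

    @property
    def aic(self) -> float:
        return float(self.result.aic)

    def coef(self, term: Term) -> float:
        return float(self.result.params[_term_name(term)])


def _term_name(term: Term) -> str:
    return ":".join(sorted(term))


def build_feature_table(subs: pd.DataFrame, include_depth: bool | None = None) -> pd.DataFrame:
    """Assemble the regression table from an annotated substitution frame.

    Continuous predictors are standardised (mean 0, sd 1) before interaction
    construction; binary flags become 0/1. When read depth is absent (or
    *include_depth* is False) the depth term is omitted entirely, as for
    cohorts without per-variant depth.
    """
    df = subs[subs["is_nonsyn"]].copy()
    if include_depth is None:
        include_depth = "read_depth" in df.columns and df["read_depth"].notna().all()
    out = pd.DataFrame({"is_rare": df["is_rare"].astype(int).to_numpy()})
    for col in CONTINUOUS:
        if col == "read_depth" and not include_depth:
            continue
        x = df[col].astype(float).to_numpy()
        sd = x.std()
        out[col] = (x - x.mean()) / sd if sd > 0 else x - x.mean()
    out["in_disorder"] = df["in_disorder"].astype(int).to_numpy()
    out[PTM_TERM] = df["in_ptm_region"].astype(int).to_numpy()
    return out


def model_terms(
    factors: Sequence[str], max_interaction_order: int = 2, with_ptm: bool = False
) -> list[Term]:
    """All main-effect and interaction terms up to the given order."""
    pool = list(factors) + ([PTM_TERM] if with_ptm else [])
    terms = []
    for order in range(1, max_interaction_order + 1):
        for combo in combinations(pool, order):
            terms.append(Term(combo))
    return terms


def _design(table: pd.DataFrame, terms: Sequence[Term]) -> pd.DataFrame:
    X = pd.DataFrame(index=table.index)
    X["Intercept"] = 1.0
    for term in terms:
        col = np.ones(len(table))
        for f in sorted(term):
            col = col * table[f].to_numpy()
        X[_term_name(term)] = col
    return X


def fit_glm(table: pd.DataFrame, terms: Sequence[Term]) -> FittedModel:
    """Fit the binomial logistic model with the given term list."""
    n_rare = int(table["is_rare"].sum())
    n_common = len(table) - n_rare
    if min(n_rare, n_common) < MIN_ROWS_PER_CLASS:
        raise ValueError(
            f"need >= {MIN_ROWS_PER_CLASS} rows per response class, "
            f"got rare={n_rare}, common={n_common}"
        )
    # drop constant columns (e.g. a PTM flag that never varies): their
    # coefficients are inestimable and they contribute nothing
    terms = [t for t in terms if table[list(t)].prod(axis=1).nunique() > 1]
    X = _design(table, terms)
    model = sm.GLM(table["is_rare"].to_numpy(), X, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(maxiter=200)
    if not result.converged:
        raise RuntimeError(
            "logistic fit did not converge; offending terms: "
            + ", ".join(_term_name(t) for t in terms)
        )
    factors = tuple(sorted({f for t in terms for f in t}))
    return FittedModel(list(terms), result, factors)


def fit_models(
    table: pd.DataFrame, max_interaction_order: int = 2
) -> tuple[FittedModel, FittedModel]:
    """Fit the null (confounders only) and alternative (+PTM) models."""
    factors = [f for f in CONFOUNDERS if f in table.columns]
    null_fit = fit_glm(table, model_terms(factors, max_interaction_order))
    alt_fit = fit_glm(table, model_terms(factors, max_interaction_order, with_ptm=True))
    return null_fit, alt_fit


def lrt(null_fit: FittedModel, alt_fit: FittedModel) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested fits: (delta deviance, df, p)."""
    delta = null_fit.deviance - alt_fit.deviance
    df = len(alt_fit.terms) - len(null_fit.terms)
    if df < 0 or not set(null_fit.terms) <= set(alt_fit.terms):
        raise ValueError("models are not nested (null terms must be a subset of alternative)")
    if df == 0:
        return max(delta, 0.0), 0, 1.0
    return max(delta, 0.0), df, float(stats.chi2.sf(max(delta, 0.0), df))


def chi2_p(delta_deviance: float, df: int) -> float:
    if df <= 0:
        raise ValueError(f"degrees of freedom must be positive, got {df}")
    return float(stats.chi2.sf(delta_deviance, df))


def backward_select(table: pd.DataFrame, fit: FittedModel) -> FittedModel:
    """AIC backward elimination respecting marginality.

    Only terms not contained in a retained higher-order term are candidates;
    the removal improving AIC the most is applied, until no removal helps.
    """
    current = fit
    while True:
        terms = current.terms
        candidates = [
            t for t in terms if not any(t < other for other in terms)
        ]
        best: FittedModel | None = None
        for t in candidates:
            reduced = [u for u in terms if u != t]
            if not reduced:
                continue
            trial = fit_glm(table, reduced)
            if trial.aic < current.aic - 1e-9 and (best is None or trial.aic < best.aic):
                best = trial
        if best is None:
            return current
        current = best


def deviance_rank(
    table: pd.DataFrame, null_fit: FittedModel, alt_fit: FittedModel
) -> pd.DataFrame:
    """Rank predictors by the deviance lost on deleting each factor.

    For every factor (the PTM indicator included), the factor's main effect
    and all interactions containing it are deleted from the alternative
    model and the chi-square deviance difference is taken; the PTM row is by
    construction the alternative-vs-null likelihood-ratio test. Effect signs
    come from the main-effect coefficients.
    """
    rows = []
    for factor in alt_fit.factors:
        reduced_terms = [t for t in alt_fit.terms if factor not in t]
        reduced = fit_glm(table, reduced_terms)
        delta = reduced.deviance - alt_fit.deviance
        df = len(alt_fit.terms) - len(reduced.terms)
        main = Term([factor])
        sign = "+" if (main in alt_fit.terms and alt_fit.coef(main) > 0) else "-"
        rows.append(
            {
                "term": factor,
                "delta_deviance": max(delta, 0.0),
                "df": df,
                "p": float(stats.chi2.sf(max(delta, 0.0), df)) if df > 0 else 1.0,
                "effect_sign": sign,
            }
        )
    out = pd.DataFrame(rows).sort_values("delta_deviance", ascending=False, kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
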