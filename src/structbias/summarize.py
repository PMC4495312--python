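"""Summary surfaces: mean bias, eta-squared partitions, marginal means,
and proportions of unbiased cells.

The design has four crossed factors — sample size n, population effect
size rho2_yy, multicollinearity rho_xx, and predictor count k — giving
15 ANOVA terms (4 main effects, 6 two-way, 4 three-way and 1 four-way
interaction).  Eta-squared for a term is its sum of squares divided by
the *record-level* total sum of squares, so replicate noise sits in the
denominator; this is why the explained totals are small percentages even
when the design drives essentially all systematic variation in bias.

Per-predictor records are reduced to a per-sample average across
predictors by default: the predictors are exchangeable by construction,
so averaging leaves mean bias untouched while matching the per-sample
record the summary tables describe.  ``predictor="first"`` instead
keeps predictor 1, preserving the sampling variance of a single
predictor's coefficient (larger SDs, same means).

Sums of squares use the classical balanced-factorial decomposition on
cell means (inclusion–exclusion of marginal means).  Exclusion of
undefined replicates can break exact balance; the decomposition then
weights cells equally using the harmonic-mean cell count, behind an
explicit opt-in flag.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .population import (
    K_LEVELS,
    N_LEVELS,
    RHO2_YY_LEVELS,
    RHO_XX_LEVELS,
    ParameterError,
)
from .simulation import BIAS_COLUMNS

__all__ = [
    "FACTORS",
    "ETA_TERMS",
    "SummaryTables",
    "select_predictor",
    "mean_bias",
    "eta_squared",
    "eta_table",
    "marginal_means",
    "proportion_unbiased",
    "summarize_records",
]

#: design factors in the order the eta-squared table is printed
FACTORS = ("n", "rho2_yy", "rho_xx", "k")

FACTOR_LEVELS = {
    "n": N_LEVELS,
    "rho2_yy": RHO2_YY_LEVELS,
    "rho_xx": RHO_XX_LEVELS,
    "k": K_LEVELS,
}


def _terms(factors: tuple[str, ...]) -> list[tuple[str, ...]]:
    out = []
    for size in range(1, len(factors) + 1):
        out.extend(itertools.combinations(factors, size))
    return out


#: the 15 ANOVA terms, main effects first, then interactions by order
ETA_TERMS = tuple(":".join(t) for t in _terms(FACTORS))


def select_predictor(records: pd.DataFrame, predictor="mean") -> pd.DataFrame:
    """Reduce per-predictor records to one row per replicate.

    ``predictor="mean"`` (the parity choice) averages the per-predictor
    statistics within each replicate, ``"first"`` keeps predictor 1,
    ``"all"`` keeps every row, and an integer selects that predictor.
    """
    if predictor == "all":
        return records
    if predictor == "first":
        predictor = 1
    if predictor == "mean":
        keys = ["cell_id", "rep", "k", "rho2_yy", "rho_xx", "n"]
        out = records.groupby(keys, as_index=False)[list(BIAS_COLUMNS)].mean()
        out["r2s_undefined"] = (
            records.groupby(keys)["r2s_undefined"].any().to_numpy()
        )
        return out
    return records[records["predictor"] == int(predictor)].reset_index(drop=True)


def mean_bias(records: pd.DataFrame, predictor="mean") -> pd.DataFrame:
    """Record-level mean and SD (n-1 denominator) of each bias statistic.

    Pooled across cells; in a balanced design the pooled record mean
    equals the mean of cell means.  Undefined structure-coefficient
    entries are excluded from their own statistics only.
    """
    if records.empty:
        raise ParameterError("no records")
    df = select_predictor(records, predictor)
    rows = {}
    for col in BIAS_COLUMNS:
        vals = df[col].dropna()
        if vals.empty:
            rows[col] = {"mean": np.nan, "sd": np.nan, "n_records": 0}
        else:
            rows[col] = {
                "mean": vals.mean(),
                "sd": vals.std(ddof=1),
                "n_records": int(vals.size),
            }
    return pd.DataFrame(rows).T.rename_axis("statistic")


def _factorial_ss(
    df: pd.DataFrame,
    factors: tuple[str, ...],
    response: str,
    allow_imbalance: bool,
) -> tuple[dict[str, float], float, float]:
    """Sums of squares for every factorial term of a (near-)balanced design.

    Returns (per-term SS, within-cell SS, total SS about the grand mean).
    Balanced path is exact classical ANOVA; the near-balanced path
    weights cells equally with the harmonic-mean cell count.
    """
    y = df[response].to_numpy()
    counts = df.groupby(list(factors), observed=True)[response].count()
    levels = [np.unique(df[f]) for f in factors]
    n_cells_expected = int(np.prod([len(l) for l in levels]))
    if len(counts) != n_cells_expected or (counts == 0).any():
        raise ParameterError(
            f"records do not cover the full {n_cells_expected}-cell factorial"
        )
    balanced = counts.nunique() == 1
    if not balanced and not allow_imbalance:
        raise ParameterError(
            "unbalanced cell counts "
            f"(min {counts.min()}, max {counts.max()}); pass "
            "allow_imbalance=True to use the equal-cell-weight decomposition"
        )
    n_h = len(counts) / (1.0 / counts).sum()  # harmonic mean cell count

    if len(factors) == 1:
        full_index = pd.Index(levels[0], name=factors[0])
    else:
        full_index = pd.MultiIndex.from_product(levels, names=factors)
    cell_means = (
        df.groupby(list(factors), observed=True)[response]
        .mean()
        .reindex(full_index)
    )
    A = cell_means.to_numpy().reshape([len(l) for l in levels])

    axes = {f: i for i, f in enumerate(factors)}
    # marginal means of the cell-mean array for every subset of factors
    marg: dict[tuple[str, ...], np.ndarray] = {}
    for term in [()] + _terms(factors):
        other = tuple(axes[f] for f in factors if f not in term)
        marg[term] = A.mean(axis=other, keepdims=True) if other else A

    ss_terms: dict[str, float] = {}
    for term in _terms(factors):
        effect = np.zeros_like(marg[term])
        for sub in itertools.chain.from_iterable(
            itertools.combinations(term, r) for r in range(len(term) + 1)
        ):
            sign = (-1) ** (len(term) - len(sub))
            effect = effect + sign * marg[sub]
        # each distinct effect value recurs once per cell it spans
        ss_terms[":".join(term)] = n_h * float(
            np.sum(np.broadcast_to(effect, A.shape) ** 2)
        )

    fitted = cell_means.reindex(
        df.set_index(list(factors)).index
    ).to_numpy()
    ss_within = float(np.sum((y - fitted) ** 2))
    if balanced:
        ss_total = float(np.sum((y - y.mean()) ** 2))
    else:
        ss_total = sum(ss_terms.values()) + ss_within
    return ss_terms, ss_within, ss_total


def eta_squared(
    records: pd.DataFrame,
    response: str,
    predictor="mean",
    allow_imbalance: bool = False,
) -> pd.Series:
    """Eta-squared of each of the 15 design terms for one bias statistic.

    Computed on per-replicate records so within-cell (sampling) variance
    is part of the total.  A constant response yields all zeros by
    convention.  Undefined entries are dropped first; if that unbalances
    the design, ``allow_imbalance`` selects the equal-cell-weight
    decomposition.
    """
    df = select_predictor(records, predictor).dropna(subset=[response])
    if df.empty:
        raise ParameterError(f"all records undefined for {response}")
    ss_terms, _, ss_total = _factorial_ss(
        df, FACTORS, response, allow_imbalance
    )
    if ss_total == 0.0:
        return pd.Series(0.0, index=list(ETA_TERMS), name=response)
    out = pd.Series(
        {name: ss / ss_total for name, ss in ss_terms.items()}, name=response
    )
    return out.reindex(list(ETA_TERMS))


def eta_table(
    records: pd.DataFrame, predictor="mean", allow_imbalance: bool = False
) -> pd.DataFrame:
    """15-term eta-squared table for all six bias statistics, plus totals."""
    cols = {
        col: eta_squared(records, col, predictor, allow_imbalance)
        for col in BIAS_COLUMNS
    }
    table = pd.DataFrame(cols)
    table.loc["total_explained"] = table.sum()
    return table.rename_axis("term")


def marginal_means(records: pd.DataFrame, predictor="mean") -> pd.DataFrame:
    """Mean bias per design cell for each statistic, one row per cell.

    In the balanced design these equal the ANOVA estimated marginal
    means.  Row order is fixed (k, rho2_yy, rho_xx, n) regardless of
    record order.
    """
    if records.empty:
        raise ParameterError("no records")
    df = select_predictor(records, predictor)
    out = (
        df.groupby(["k", "rho2_yy", "rho_xx", "n"], observed=True)[
            list(BIAS_COLUMNS)
        ]
        .mean()
        .reset_index()
        .sort_values(["k", "rho2_yy", "rho_xx", "n"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def proportion_unbiased(
    marginal: pd.DataFrame, threshold: float = 0.01
) -> pd.DataFrame:
    """Share of design cells with |mean bias| <= threshold, by main-effect level.

    One row per (factor, level); six statistic columns plus 2-decimal
    parity columns rounded half-up is left to the report layer — values
    here are exact fractions.
    """
    rows = []
    for factor in FACTORS:
        for level in FACTOR_LEVELS[factor]:
            sub = marginal[marginal[factor] == level]
            row = {"factor": factor, "level": level, "n_cells": len(sub)}
            for col in BIAS_COLUMNS:
                row[col] = float(
                    (sub[col].abs() <= threshold).mean()
                ) if len(sub) else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SummaryTables:
    """Bundle of the study's summary surfaces for one set of records."""

    mean_sd: pd.DataFrame
    eta2: pd.DataFrame
    marginal: pd.DataFrame
    proportions: pd.DataFrame
    threshold: float = 0.01


def summarize_records(
    records: pd.DataFrame,
    predictor="mean",
    threshold: float = 0.01,
    allow_imbalance: bool = False,
) -> SummaryTables:
    """All summary tables from a set of bias records."""
    marginal = marginal_means(records, predictor)
    return SummaryTables(
        mean_sd=mean_bias(records, predictor),
        eta2=eta_table(records, predictor, allow_imbalance),
        marginal=marginal,
        proportions=proportion_unbiased(marginal, threshold),
        threshold=threshold,
    )
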