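"""Equicorrelated multivariate-normal population designs.

A population condition is defined by three quantities: the number of
predictors ``k``, the population squared multiple correlation ``rho2_yy``
(the proportion of outcome variance the predictor set explains), and a
common pairwise predictor intercorrelation ``rho_xx`` (compound-symmetric
multicollinearity).  All predictors carry the same validity coefficient
``rho_xy`` with the outcome, chosen so that the implied multiple
correlation equals ``rho2_yy``.

Under compound symmetry the predictor correlation block is
``(1 - rho_xx) I + rho_xx J``, whose action on the constant vector gives
the closed forms used throughout:

    rho2_xy        = rho2_yy * (1 + (k - 1) rho_xx) / k
    rho2_structure = rho2_xy / rho2_yy = (1 + (k - 1) rho_xx) / k

where ``rho2_structure`` is the squared population structure coefficient —
the squared correlation between any one predictor and the model's predicted
outcome scores.

The study grid crosses rho2_yy in {0.2, 0.5, 0.8}, rho_xx in
{0.1, 0.3, 0.5}, sample size n in {20, 40, 60, 100, 200} and k in
{2, 4, 8}: 135 design cells over 27 distinct populations.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "ParameterError",
    "PopulationSpec",
    "PopulationParams",
    "DesignCell",
    "solve_validity",
    "population_parameters",
    "design_grid",
    "table1",
    "round_half_up",
    "RHO2_YY_LEVELS",
    "RHO_XX_LEVELS",
    "N_LEVELS",
    "K_LEVELS",
]

RHO2_YY_LEVELS: tuple[float, ...] = (0.2, 0.5, 0.8)
RHO_XX_LEVELS: tuple[float, ...] = (0.1, 0.3, 0.5)
N_LEVELS: tuple[int, ...] = (20, 40, 60, 100, 200)
K_LEVELS: tuple[int, ...] = (2, 4, 8)

#: smallest admissible eigenvalue of a population correlation matrix;
#: anything below is treated as an error, not a warning.
PD_EIGENVALUE_TOL = 1e-10


class ParameterError(ValueError):
    """An infeasible or out-of-bounds population/design parameter."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up, matching printed-table conventions.

    Binary-float bankers rounding misrounds exact midpoints such as 0.475
    or 0.2125; table parity therefore goes through :class:`~decimal.Decimal`
    on the shortest repr of the float.
    """
    x = float(x)
    if not np.isfinite(x):
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PopulationSpec:
    """One population condition (k, rho2_yy, rho_xx).

    ``rho_xx`` is ignored for k = 1.  The predictor block must be positive
    definite, i.e. ``rho_xx > -1/(k-1)`` for k > 1.
    """

    k: int
    rho2_yy: float
    rho_xx: float = 0.0

    def __post_init__(self) -> None:
        if int(self.k) != self.k or self.k < 1:
            raise ParameterError(f"k must be an integer >= 1, got {self.k}")
        if not 0.0 <= self.rho2_yy < 1.0:
            raise ParameterError(
                f"rho2_yy must lie in [0, 1), got {self.rho2_yy}"
            )
        if self.k > 1:
            lo = -1.0 / (self.k - 1)
            if not lo < self.rho_xx < 1.0:
                raise ParameterError(
                    f"rho_xx must lie in ({lo:.4g}, 1) for k={self.k} "
                    f"(positive-definite predictor block), got {self.rho_xx}"
                )


@dataclass(frozen=True)
class PopulationParams:
    """Analytic truth for one population condition.

    ``corr`` is the (k+1) x (k+1) joint correlation matrix with the
    predictors in columns 0..k-1 and the outcome in the last column.
    """

    spec: PopulationSpec
    rho_xy: float
    rho2_xy: float
    rho2_structure: float
    corr: np.ndarray = field(repr=False)

    @property
    def k(self) -> int:
        return self.spec.k


@dataclass(frozen=True)
class DesignCell:
    """One simulation design cell: a population condition plus a sample size."""

    spec: PopulationSpec
    n: int
    cell_id: int

    def __post_init__(self) -> None:
        # n > k + 3 keeps the shrinkage denominators N-p-1 and N-p-2.3
        # positive for every p <= k.
        if self.n <= self.spec.k + 3:
            raise ParameterError(
                f"n must exceed k + 3 (got n={self.n}, k={self.spec.k})"
            )


def _structure_factor(k: int, rho_xx: float) -> float:
    return (1.0 + (k - 1) * rho_xx) / k


def solve_validity(spec: PopulationSpec) -> float:
    """Common validity coefficient implied by an equicorrelated design.

    Returns the nonnegative ``rho_xy`` such that k equally valid,
    equicorrelated predictors yield a squared multiple correlation of
    ``spec.rho2_yy``.  Raises :class:`ParameterError` if the implied
    squared validity exceeds 1 or the predictor block is not positive
    definite.
    """
    factor = _structure_factor(spec.k, spec.rho_xx)
    if factor <= 0:
        raise ParameterError(
            f"predictor block not positive definite: 1+(k-1)rho_xx = {factor}"
        )
    rho2_xy = spec.rho2_yy * factor
    if rho2_xy > 1.0:
        raise ParameterError(
            f"implied squared validity {rho2_xy:.6g} exceeds 1"
        )
    return float(np.sqrt(rho2_xy))


def _assemble_corr(spec: PopulationSpec, rho_xy: float) -> np.ndarray:
    k = spec.k
    m = k + 1
    corr = np.empty((m, m))
    corr[:k, :k] = spec.rho_xx
    np.fill_diagonal(corr, 1.0)
    corr[:k, k] = rho_xy
    corr[k, :k] = rho_xy
    corr[k, k] = 1.0
    return corr


def population_parameters(spec: PopulationSpec) -> PopulationParams:
    """Analytic parameters and joint correlation matrix for a condition.

    Validates positive definiteness (smallest eigenvalue above
    ``PD_EIGENVALUE_TOL``) and that the squared multiple correlation
    recomputed from the assembled matrix round-trips to ``spec.rho2_yy``.
    """
    rho_xy = solve_validity(spec)
    # computed directly, not by squaring the root: sqrt-then-square drifts
    # off exact binary values (0.375 -> 0.37499...) and breaks printed parity
    rho2_xy = spec.rho2_yy * _structure_factor(spec.k, spec.rho_xx)
    rho2_structure = _structure_factor(spec.k, spec.rho_xx)
    corr = _assemble_corr(spec, rho_xy)

    eigmin = float(np.linalg.eigvalsh(corr)[0])
    if eigmin <= PD_EIGENVALUE_TOL:
        raise ParameterError(
            f"joint correlation matrix is not positive definite "
            f"(smallest eigenvalue {eigmin:.3g})"
        )
    k = spec.k
    r = corr[:k, k]
    r2_roundtrip = float(r @ np.linalg.solve(corr[:k, :k], r))
    if abs(r2_roundtrip - spec.rho2_yy) > 1e-12:
        raise ParameterError(
            f"round-trip R^2 {r2_roundtrip!r} differs from rho2_yy "
            f"{spec.rho2_yy!r}"
        )
    return PopulationParams(
        spec=spec,
        rho_xy=rho_xy,
        rho2_xy=rho2_xy,
        rho2_structure=rho2_structure,
        corr=corr,
    )


def design_grid() -> list[DesignCell]:
    """The full 135-cell grid, ordered lexicographically by (k, rho2_yy, rho_xx, n).

    ``cell_id`` is the ordinal position in this enumeration and is stable
    across runs; it keys the per-cell random streams.
    """
    cells = []
    combos = itertools.product(K_LEVELS, RHO2_YY_LEVELS, RHO_XX_LEVELS, N_LEVELS)
    for cell_id, (k, rho2_yy, rho_xx, n) in enumerate(combos):
        spec = PopulationSpec(k=k, rho2_yy=rho2_yy, rho_xx=rho_xx)
        cells.append(DesignCell(spec=spec, n=n, cell_id=cell_id))
    return cells


def table1() -> pd.DataFrame:
    """Analytic population parameters for the 27 study conditions.

    Columns carry full precision plus 2-decimal half-up-rounded parity
    columns; rows are ordered (k, rho_xx, rho2_yy) as conventionally
    printed.
    """
    rows = []
    for k, rho_xx, rho2_yy in itertools.product(
        K_LEVELS, RHO_XX_LEVELS, RHO2_YY_LEVELS
    ):
        params = population_parameters(
            PopulationSpec(k=k, rho2_yy=rho2_yy, rho_xx=rho_xx)
        )
        rows.append(
            {
                "k": k,
                "rho2_yy": rho2_yy,
                "rho_xx": rho_xx,
                "rho2_xy": params.rho2_xy,
                "rho2_structure": params.rho2_structure,
                "rho2_xy_2dp": round_half_up(params.rho2_xy),
                "rho2_structure_2dp": round_half_up(params.rho2_structure),
            }
        )
    return pd.DataFrame(rows)
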