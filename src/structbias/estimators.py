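"""Uncorrected regression interpretation coefficients from sample data.

Everything is computed on the sample Pearson correlation matrix (n-1
denominator): standardized beta weights solve the normal equations
``R_xx beta = r_xy``, the squared multiple correlation is
``R2 = r_xy' beta``, and the squared structure coefficient of predictor j
is ``r2_xy[j] / R2`` — identically the squared correlation between
predictor j and the fitted outcome scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .population import ParameterError

__all__ = [
    "DegenerateSampleError",
    "UndefinedRatioError",
    "Sample",
    "SampleEstimates",
    "regression_estimates",
    "structure_from_validity",
    "batch_regression_stats",
]

#: sample R^2 below this is treated as zero; structure coefficients are
#: then undefined (0/0) and reported as NaN, never silently dropped.
R2_DEFINED_TOL = 1e-12


class DegenerateSampleError(ValueError):
    """Sample predictor correlation matrix is singular."""


class UndefinedRatioError(ZeroDivisionError):
    """Structure coefficient requested at zero multiple correlation."""


@dataclass(frozen=True)
class Sample:
    """An n x (k+1) numeric data matrix with one outcome column.

    ``outcome`` indexes the outcome column (default: last).  Requires
    n > k + 3, no missing values and nonzero variance in every column.
    """

    data: np.ndarray
    outcome: int = -1

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2 or data.shape[1] < 2:
            raise ParameterError("data must be 2-D with >= 2 columns")
        n, m = data.shape
        if n <= (m - 1) + 3:
            raise ParameterError(f"need n > k + 3, got n={n}, k={m - 1}")
        if not np.isfinite(data).all():
            raise ParameterError("data contains missing/non-finite values")
        if np.any(np.ptp(data, axis=0) == 0):
            raise ParameterError("every column must have nonzero variance")
        out = self.outcome % m
        object.__setattr__(self, "outcome", out)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def k(self) -> int:
        return self.data.shape[1] - 1


@dataclass(frozen=True)
class SampleEstimates:
    """Uncorrected coefficients for one sample.

    ``r2_structure`` is NaN (with ``structure_defined`` False) when the
    sample R^2 is numerically zero.
    """

    R2: float
    beta: np.ndarray = field(repr=False)
    r_xy: np.ndarray = field(repr=False)
    r2_xy: np.ndarray = field(repr=False)
    r2_structure: np.ndarray = field(repr=False)
    structure_defined: bool = True


def regression_estimates(sample: Sample) -> SampleEstimates:
    """Beta weights, R^2, validity and structure coefficients of a sample."""
    m = sample.data.shape[1]
    order = [j for j in range(m) if j != sample.outcome] + [sample.outcome]
    corr = np.corrcoef(sample.data[:, order], rowvar=False)
    k = m - 1
    r_xy = corr[:k, k]
    R_xx = corr[:k, :k]
    try:
        beta = np.linalg.solve(R_xx, r_xy)
    except np.linalg.LinAlgError as exc:
        raise DegenerateSampleError(
            "sample predictor correlation matrix is singular"
        ) from exc
    R2 = float(np.clip(r_xy @ beta, 0.0, 1.0))
    r2_xy = r_xy**2
    if R2 > R2_DEFINED_TOL:
        r2_structure = r2_xy / R2
        defined = True
    else:
        r2_structure = np.full(k, np.nan)
        defined = False
    return SampleEstimates(
        R2=R2,
        beta=beta,
        r_xy=r_xy,
        r2_xy=r2_xy,
        r2_structure=r2_structure,
        structure_defined=defined,
    )


def structure_from_validity(r_xy: float, R: float) -> float:
    """Structure coefficient as validity over multiple correlation."""
    if R == 0:
        raise UndefinedRatioError("structure coefficient undefined at R = 0")
    if R < 0 or abs(r_xy) > 1 + 1e-12:
        raise ParameterError("require R > 0 and |r_xy| <= 1")
    return r_xy / R


def batch_regression_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (R2, r2_xy) over a stack of samples.

    ``X`` has shape (reps, n, k+1) with the outcome in the last column.
    Returns ``R2`` of shape (reps,) clipped to [0, 1] and ``r2_xy`` of
    shape (reps, k).  This is the hot path of the simulation: one einsum
    for all cross-product matrices, one batched solve for all normal
    equations.
    """
    Xc = X - X.mean(axis=1, keepdims=True)
    C = np.einsum("rni,rnj->rij", Xc, Xc)
    d = np.sqrt(np.einsum("rii->ri", C))
    R = C / (d[:, :, None] * d[:, None, :])
    r_xy = R[:, :-1, -1]
    R_xx = R[:, :-1, :-1]
    beta = np.linalg.solve(R_xx, r_xy[..., None])[..., 0]
    R2 = np.clip(np.einsum("rk,rk->r", r_xy, beta), 0.0, 1.0)
    return R2, r_xy**2
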