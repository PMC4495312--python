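"""Pratt shrinkage correction for squared correlations.

Sample squared correlations overestimate their population counterparts;
Pratt's formula shrinks a squared multiple correlation R^2 given the
sample size N and the number of predictors p:

    adj = 1 - [(N - 3)(1 - R^2) / (N - p - 1)] * [1 + 2(1 - R^2) / (N - p - 2.3)]

The constant 2.3 is part of the formula.  Negative adjusted values are
clamped to zero.  A corrected squared structure coefficient is composed
from the clamped pieces: 0 when the adjusted R^2 is zero, 1 when the
adjusted squared validity exceeds a positive adjusted R^2, otherwise
their ratio.  Clamping happens on each component before the ratio, never
after.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimators import SampleEstimates
from .population import ParameterError

__all__ = [
    "CorrectedEstimates",
    "pratt_adjust",
    "corrected_structure",
    "corrected_estimates",
]


@dataclass(frozen=True)
class CorrectedEstimates:
    """Pratt-corrected coefficient set for one sample; all entries in [0, 1]."""

    R2_adj: float
    r2_xy_adj: np.ndarray = field(repr=False)
    r2_structure_adj: np.ndarray = field(repr=False)


def pratt_adjust(R2, N: int, p: int):
    """Pratt-corrected squared correlation, clamped at zero.

    Accepts a scalar or array ``R2``; requires ``0 <= R2 <= 1`` and
    ``N - p - 2.3 > 0``.
    """
    if N - p - 2.3 <= 0:
        raise ParameterError(
            f"need N - p - 2.3 > 0, got N={N}, p={p}"
        )
    R2 = np.asarray(R2, dtype=float)
    if np.any((R2 < 0) | (R2 > 1)):
        raise ParameterError("R2 must lie in [0, 1]")
    u = 1.0 - R2
    raw = 1.0 - (N - 3) * u / (N - p - 1) * (1.0 + 2.0 * u / (N - p - 2.3))
    adj = np.maximum(raw, 0.0)
    return adj if adj.ndim else float(adj)


def corrected_structure(r2_xy_adj, R2_adj):
    """Compose corrected squared structure coefficients from clamped parts.

    Elementwise over broadcastable arrays.  Three exhaustive, mutually
    exclusive branches:

    * adjusted R^2 == 0 -> 0 (the zero-denominator guard comes first, so
      a zero adjusted regression effect yields a zero structure
      coefficient even if the adjusted validity survived clamping);
    * adjusted validity > adjusted R^2 > 0 -> 1 (ratio capped);
    * otherwise the plain ratio, which then lies in [0, 1].
    """
    r2, R2 = np.broadcast_arrays(
        np.asarray(r2_xy_adj, dtype=float), np.asarray(R2_adj, dtype=float)
    )
    zero_R2 = R2 == 0
    exceeds = r2 > R2
    # safe denominator: ratio branch only applies where R2 > 0
    ratio = r2 / np.where(zero_R2, 1.0, R2)
    out = np.where(zero_R2, 0.0, np.where(exceeds, 1.0, ratio))
    return out if out.ndim else float(out)


def corrected_estimates(
    est: SampleEstimates, N: int, k: int
) -> CorrectedEstimates:
    """Pratt-correct a full sample estimate set.

    The R^2 correction uses p = k (the fitted model); each squared
    validity is corrected as a one-predictor model, p = 1.
    """
    R2_adj = pratt_adjust(est.R2, N, p=k)
    r2_xy_adj = pratt_adjust(est.r2_xy, N, p=1)
    r2_structure_adj = corrected_structure(r2_xy_adj, R2_adj)
    return CorrectedEstimates(
        R2_adj=R2_adj,
        r2_xy_adj=np.atleast_1d(r2_xy_adj),
        r2_structure_adj=np.atleast_1d(r2_structure_adj),
    )
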