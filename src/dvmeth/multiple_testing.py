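"""Q-value (FDR) estimation from P-value vectors.

Implements the standard q-value construction: estimate the proportion of
true nulls pi0 from the flat right tail of the P-value histogram, then
apply the step-up transform q_(i) = min_{j>=i} pi0 * n * p_(j) / j on the
P-sorted order.  With pi0 = 1 this reduces exactly to Benjamini-Hochberg
adjusted P-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["QValueResult", "estimate_pi0", "qvalues", "DEFAULT_LAMBDA_GRID"]

logger = logging.getLogger(__name__)

#: Default tuning grid for the pi0 estimator.
DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)

#: Below this many P-values the tail estimate of pi0 is too noisy; fall back
#: to pi0 = 1 (plain Benjamini-Hochberg).
MIN_PVALUES_FOR_PI0 = 100


@dataclass
class QValueResult:
    """Q-values aligned to the input P-values plus the estimated pi0."""

    q_values: np.ndarray
    pi0: float


def estimate_pi0(p, lambda_grid=None) -> float:
    """Estimate the null proportion pi0 from a vector of P-values.

    Computes ``pi0(lambda) = #{p > lambda} / (n (1 - lambda))`` on the grid,
    smooths with a cubic polynomial in lambda, and evaluates the smoother at
    the largest lambda.  The result is clamped to ``[1/n, 1]`` (the floor
    avoids a q-value collapse to 0 under dense signal).

    Fewer than 100 P-values -> returns 1 (Benjamini-Hochberg fallback).
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    n = p.size
    if n < MIN_PVALUES_FOR_PI0:
        logger.debug("only %d P-values; using pi0 = 1 (BH fallback)", n)
        return 1.0
    grid = DEFAULT_LAMBDA_GRID if lambda_grid is None else np.asarray(lambda_grid, float)
    if grid.ndim != 1 or grid.size < 4 or np.any(np.diff(grid) <= 0):
        raise ValueError("lambda_grid must be strictly increasing with >= 4 points")
    if grid.min() <= 0 or grid.max() >= 1:
        raise ValueError("lambda_grid values must lie in (0, 1)")
    pi0_lambda = np.array([(p > lam).sum() / (n * (1.0 - lam)) for lam in grid])
    coeffs = np.polyfit(grid, pi0_lambda, deg=3)
    pi0 = float(np.polyval(coeffs, grid.max()))
    return float(np.clip(pi0, 1.0 / n, 1.0))


def qvalues(p, pi0: float | str = "auto", lambda_grid=None) -> QValueResult:
    """Convert P-values to q-values (estimated FDR at each P threshold).

    ``pi0`` may be a number in (0, 1] or ``"auto"`` to estimate it via
    :func:`estimate_pi0`.  Empty input yields empty output.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return QValueResult(q_values=np.array([]), pi0=1.0)
    if np.any(np.isnan(p)):
        raise ValueError("P-values must be finite; mask missing results upstream")
    if pi0 == "auto":
        pi0 = estimate_pi0(p, lambda_grid)
    pi0 = float(pi0)
    if not 0.0 < pi0 <= 1.0:
        raise ValueError("pi0 must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return QValueResult(q_values=q, pi0=pi0)
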