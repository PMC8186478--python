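"""Self-contained statistical kernels shared by every analysis stage.

Four small kernels are used throughout the toolkit: an upper-tail
hypergeometric enrichment test (the workhorse for every gene-set /
cell-set overlap), Benjamini-Hochberg step-up FDR adjustment, a pooled
two-proportion z-test, and the per-class F1 score used to compare
classifier back-ends.  They are implemented here directly -- each is a
handful of lines and its exact conventions (log-space tail summation,
no continuity correction, F1 := 0 for empty classes) are contracts the
rest of the toolkit relies on -- and cross-checked in the test suite
against independent library routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm

from .errors import ParameterError

__all__ = [
    "EnrichmentResult",
    "hypergeometric_tail",
    "bh_adjust",
    "two_proportion_test",
    "f1_score",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """Outcome of a hypergeometric overlap test.

    Attributes
    ----------
    universe_size : int
        N, the number of items that could have been drawn.
    category_size : int
        K, the number of "successes" in the universe.
    draw_size : int
        n, the number of items drawn.
    overlap : int
        k, the observed number of successes among the draws.
    p_value : float
        Upper-tail probability P(X >= k) (lower tail if requested).
    representation_factor : float
        RF = k*N / (K*n), the observed/expected overlap ratio
        (NaN when K or n is zero).
    p_adjusted : float | None
        Slot for a multiplicity-adjusted p-value when tests are batched.
    """

    universe_size: int
    category_size: int
    draw_size: int
    overlap: int
    p_value: float
    representation_factor: float
    p_adjusted: float | None = None


def _log_hypergeom_pmf(j: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log P(X = j) for X ~ Hypergeometric(N, K, n), via log-gammas."""
    j = np.asarray(j, dtype=float)

    def _logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return _logC(K, j) + _logC(N - K, n - j) - _logC(N, n)


def hypergeometric_tail(
    N: int, K: int, n: int, k: int, *, lower: bool = False
) -> EnrichmentResult:
    """Tail probability of the hypergeometric distribution.

    Computes ``P(X >= k)`` (or ``P(X <= k)`` with ``lower=True``) for the
    number of successes X when drawing ``n`` items without replacement
    from a universe of ``N`` items of which ``K`` are successes.  The tail
    is summed in log space so that extreme enrichments do not underflow.

    Parameters
    ----------
    N, K, n, k :
        Universe size, category size, draw size, observed overlap.
    lower :
        Report the lower (depletion) tail instead of the default upper
        (over-enrichment) tail.
    """
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ParameterError(f"{name} must be a nonnegative integer, got {v!r}")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N:
        raise ParameterError(f"K={K} and n={n} must not exceed N={N}")
    if k > min(K, n):
        raise ParameterError(f"overlap k={k} exceeds min(K, n)={min(K, n)}")
    if k < max(0, n - (N - K)):
        raise ParameterError(
            f"overlap k={k} below the feasible minimum {max(0, n - (N - K))}"
        )

    lo = max(0, n - (N - K))
    hi = min(K, n)
    if lower:
        support = np.arange(lo, k + 1)
    else:
        support = np.arange(k, hi + 1)
    p = float(np.exp(logsumexp(_log_hypergeom_pmf(support, N, K, n))))
    p = min(p, 1.0)

    rf = k * N / (K * n) if K > 0 and n > 0 else float("nan")
    return EnrichmentResult(
        universe_size=N,
        category_size=K,
        draw_size=n,
        overlap=k,
        p_value=p,
        representation_factor=rf,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment.

    Returns adjusted p-values in the original input order, with the
    usual monotonicity enforcement (cumulative minimum from the largest
    p downward) and capping at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m, dtype=float)
    out[order] = adjusted
    return out


def two_proportion_test(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled two-proportion z-test (no continuity correction).

    Tests H0: p1 = p2 for counts ``x1/n1`` vs ``x2/n2`` using the pooled
    estimate of the common proportion.  Returns ``(z, p)`` with a
    two-sided normal p-value.  The squared statistic equals the Pearson
    chi-square of the 2x2 table without Yates correction; note that R's
    ``prop.test`` applies the continuity correction by default and will
    differ slightly.
    """
    for name, x, n in (("group 1", x1, n1), ("group 2", x2, n2)):
        if n < 1:
            raise ParameterError(f"{name}: sample size must be >= 1, got {n}")
        if not 0 <= x <= n:
            raise ParameterError(f"{name}: count {x} outside [0, {n}]")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var == 0:
        warnings.warn(
            "pooled variance is zero (all successes or all failures); p = 1",
            stacklevel=2,
        )
        return 0.0, 1.0
    z = (p1 - p2) / np.sqrt(var)
    p = 2 * norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def f1_score(y_true, y_pred, cls) -> float:
    """F1 score for one class: harmonic mean of precision and recall.

    Defined as 0 when precision + recall = 0 (including the degenerate
    case of a class absent from both truth and prediction), so that
    cross-validation summaries remain total.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ParameterError(
            f"label vectors differ in length: {y_true.shape} vs {y_pred.shape}"
        )
    tp = int(np.sum((y_true == cls) & (y_pred == cls)))
    fp = int(np.sum((y_true != cls) & (y_pred == cls)))
    fn = int(np.sum((y_true == cls) & (y_pred != cls)))
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 0.0
    return 2 * tp / denom
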