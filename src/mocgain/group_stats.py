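"""Group-level statistics for fitted cochlear parameters.

Implements the exhaustive nonparametric bootstrap of the sample mean: for
``N`` subjects, every one of the ``C(2N-1, N)`` distinct resamples (size-N
multisets of the N values) is enumerated and weighted by its multinomial
multiplicity, so that the weighted distribution of resample means is the
*exact* iid-bootstrap distribution (total weight ``N**N``).  Gaussian and
Nakagami probability densities are fitted to that weighted distribution,
along with percentile summaries, Spearman rank correlations, and
ordinary-least-squares regression slopes with exhaustive-bootstrap
confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln, psi
from scipy.stats import spearmanr

__all__ = [
    "BootstrapSummary",
    "ColumnSummary",
    "column_summary",
    "enumerate_bootstrap",
    "monte_carlo_bootstrap",
    "fit_gaussian",
    "fit_nakagami",
    "nakagami_mean",
    "spearman",
    "regression_bootstrap_ci",
    "ctilde_consistency",
]

#: Largest N for which the exhaustive enumeration is attempted
#: (C(2*14-1, 14) ~ 20 million multisets).
ENUMERATION_MAX_N = 14

_comp_memo: dict[tuple[int, int], np.ndarray] = {}


def _compositions(n: int, k: int) -> np.ndarray:
    """All weak compositions of ``n`` into ``k`` parts, one row each."""
    key = (n, k)
    if key in _comp_memo:
        return _comp_memo[key]
    if k == 1:
        out = np.array([[n]], dtype=np.int16)
    else:
        blocks = []
        for first in range(n + 1):
            rest = _compositions(n - first, k - 1)
            col = np.full((rest.shape[0], 1), first, dtype=np.int16)
            blocks.append(np.hstack([col, rest]))
        out = np.vstack(blocks)
    # cache only small subproblems and the final table to bound memory
    if out.nbytes < 64 << 20:
        _comp_memo[key] = out
    return out


def _multinomial_weights(counts: np.ndarray) -> np.ndarray:
    """Exact multinomial multiplicity N!/prod(c_i!) per counts row.

    All factorial products involved are below 2**53, so the float64
    arithmetic is exact.
    """
    n = int(counts[0].sum())
    fact = np.array([math.factorial(i) for i in range(n + 1)], dtype=float)
    return fact[n] / np.prod(fact[counts], axis=1)


@dataclass
class BootstrapSummary:
    """Weighted distribution of bootstrap resample means.

    ``resample_means[i]`` occurs with multiplicity ``weights[i]``; the
    weights sum to ``N**N`` for the exhaustive enumeration (or to the number
    of draws for the Monte-Carlo fallback).  Fitted densities are attached
    by :func:`fit_gaussian` / :func:`fit_nakagami`.
    """

    resample_means: np.ndarray
    weights: np.ndarray
    n: int
    exhaustive: bool = True
    gaussian_fit: Optional[tuple[float, float]] = None
    nakagami_fit: Optional[tuple[float, float]] = None
    nakagami_excluded_mass: float = field(default=0.0)

    @property
    def n_resamples(self) -> int:
        return len(self.resample_means)

    def weighted_mean(self) -> float:
        return float(np.average(self.resample_means, weights=self.weights))

    def weighted_sd(self) -> float:
        mu = self.weighted_mean()
        return float(
            math.sqrt(
                np.average((self.resample_means - mu) ** 2, weights=self.weights)
            )
        )


class ColumnSummary(NamedTuple):
    """Five-number summary of one parameter column."""

    median: float
    p25: float
    p75: float
    min: float
    max: float


def column_summary(values: Sequence[float]) -> ColumnSummary:
    """Median, quartiles and range; linear interpolation between order stats."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("column_summary requires a non-empty input")
    return ColumnSummary(
        median=float(np.median(v)),
        p25=float(np.percentile(v, 25)),
        p75=float(np.percentile(v, 75)),
        min=float(v.min()),
        max=float(v.max()),
    )


def enumerate_bootstrap(values: Sequence[float]) -> BootstrapSummary:
    """Exhaustive weighted bootstrap distribution of the sample mean.

    Enumerates all ``C(2N-1, N)`` multisets of size N drawn from the N
    ``values``; each contributes its mean with multinomial weight.  The
    weighted mean of resample means equals the plain sample mean exactly,
    and the weighted sd equals population-sd/sqrt(N).
    """
    v = np.asarray(values, dtype=float)
    n = v.size
    if not (2 <= n <= ENUMERATION_MAX_N):
        raise ValueError(
            f"exhaustive enumeration supports 2 <= N <= {ENUMERATION_MAX_N} "
            f"(got N={n}); use monte_carlo_bootstrap instead"
        )
    counts = _compositions(n, n)
    weights = _multinomial_weights(counts)
    means = counts @ v / n
    return BootstrapSummary(
        resample_means=means, weights=weights, n=n, exhaustive=True
    )


def monte_carlo_bootstrap(
    values: Sequence[float], n_draws: int, rng: np.random.Generator
) -> BootstrapSummary:
    """Seeded Monte-Carlo bootstrap of the mean (fallback for large N)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least two values")
    idx = rng.integers(0, v.size, size=(n_draws, v.size))
    means = v[idx].mean(axis=1)
    return BootstrapSummary(
        resample_means=means,
        weights=np.ones(n_draws),
        n=v.size,
        exhaustive=False,
    )


def fit_gaussian(summary: BootstrapSummary) -> tuple[float, float]:
    """Gaussian density fitted to the weighted resample means by moments.

    Closed form: the mean equals the sample mean of the inputs and the sd
    equals the population sd divided by sqrt(N).
    """
    fit = (summary.weighted_mean(), summary.weighted_sd())
    summary.gaussian_fit = fit
    return fit


def fit_nakagami(summary: BootstrapSummary) -> tuple[float, float]:
    """Weighted maximum-likelihood Nakagami fit to positive resample means.

    The Nakagami density
    ``f(x) = 2 m^m x^(2m-1) exp(-m x^2 / O) / (Gamma(m) O^m)`` has positive
    support; resample means <= 0 are excluded and the excluded probability
    mass recorded on the summary.  ML estimation uses the gamma-distribution
    equivalence of X^2: the spread is the weighted mean square,
    ``O = E[x^2]``, and the shape solves ``log m - psi(m) = log O -
    E[log x^2]``.

    Returns ``(m, omega)``.
    """
    x = summary.resample_means
    w = summary.weights
    pos = x > 0
    summary.nakagami_excluded_mass = float(1.0 - w[pos].sum() / w.sum())
    x, w = x[pos], w[pos]
    if np.unique(x).size < 2:
        raise ValueError("Nakagami fit needs >= 2 distinct positive means")
    omega = float(np.average(x**2, weights=w))
    s = math.log(omega) - float(np.average(np.log(x**2), weights=w))
    m = float(brentq(lambda mm: math.log(mm) - psi(mm) - s, 1e-6, 1e6))
    summary.nakagami_fit = (m, omega)
    return m, omega


def nakagami_mean(m: float, omega: float) -> float:
    """Expected value of a Nakagami(m, omega) variable.

    ``Gamma(m + 1/2) / Gamma(m) * sqrt(omega / m)``.
    """
    if m <= 0 or omega <= 0:
        raise ValueError("m and omega must be positive")
    return math.exp(gammaln(m + 0.5) - gammaln(m)) * math.sqrt(omega / m)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be aligned")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise ValueError("rank correlation undefined for constant input")
    return float(spearmanr(x, y).statistic)


class RegressionResult(NamedTuple):
    slope: float
    intercept: float
    slope_ci: tuple[float, float]
    excluded_mass: float


def _weighted_quantile(x: np.ndarray, w: np.ndarray, q: float) -> float:
    """Quantile of a weighted sample (inclusive linear interpolation)."""
    order = np.argsort(x)
    x, w = x[order], w[order]
    cum = np.cumsum(w) - 0.5 * w
    cum /= w.sum()
    return float(np.interp(q, cum, x))


def regression_bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float],
    level: float = 0.95,
) -> RegressionResult:
    """OLS line with an exhaustive paired-bootstrap CI on the slope.

    Cases (x_i, y_i) are resampled as multisets with multinomial weights;
    resamples with fewer than two distinct x (slope undefined) are excluded
    and their probability mass reported.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must be aligned")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 cases")
    if np.unique(x).size < 2:
        raise ValueError("regression undefined: x is constant")

    slope, intercept = np.polyfit(x, y, 1)

    counts = _compositions(n, n).astype(float)
    weights = _multinomial_weights(counts.astype(int))
    sx = counts @ x
    sy = counts @ y
    sxx = counts @ (x * x)
    sxy = counts @ (x * y)
    denom = n * sxx - sx * sx
    ok = denom > 1e-9 * max(1.0, float(np.abs(x).max()) ** 2)
    excluded = float(1.0 - weights[ok].sum() / weights.sum())
    slopes = (n * sxy[ok] - sx[ok] * sy[ok]) / denom[ok]
    alpha = 0.5 * (1.0 - level)
    ci = (
        _weighted_quantile(slopes, weights[ok], alpha),
        _weighted_quantile(slopes, weights[ok], 1.0 - alpha),
    )
    return RegressionResult(float(slope), float(intercept), ci, excluded)


def ctilde_consistency(row) -> float:
    """Recompute the with-elicitor compression exponent from a record.

    ``row`` is any mapping with keys ``G_max``, ``c`` and ``dG``.  Under
    fixed break points, ``c_tilde = 1 - (1 - c)(G_max - dG)/G_max``, clamped
    to <= 1 (effective gain floored at zero).
    """
    g_max, c, dg = float(row["G_max"]), float(row["c"]), float(row["dG"])
    if g_max <= 0:
        raise ValueError("G_max must be positive")
    return min(1.0 - (1.0 - c) * (g_max - dg) / g_max, 1.0)
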