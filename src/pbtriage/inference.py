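"""Statistical layer: 2x2 odds ratios, logistic regression, group tests.

Implements the analyses used to relate the Clinical Benefit Score and
Medicare insurance to receipt of proton beam therapy:

* reconstruction of a 2x2 exposure-outcome table from printed margins
  (row n and percent with the event, rounded half-up);
* the cross-product odds ratio with the Woolf (Wald-on-log-scale)
  confidence interval, with the Haldane-Anscombe +0.5 correction when a
  cell is zero;
* binary logistic regression fitted by Newton-Raphson (equivalently
  IRLS), with Wald standard errors from the inverse observed
  information -- used for the crude (CBS-only, Medicare-only) and
  adjusted (CBS + Medicare) receipt models;
* Welch's two-sample t test and one-way ANOVA for comparing mean scores
  across strata.

All routines are implemented directly from the formulas; scipy supplies
only distribution quantiles/tails and linear algebra.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import norm, t as t_dist, f as f_dist

__all__ = [
    "TwoByTwoTable",
    "ORResult",
    "LogisticFit",
    "ModelReport",
    "table_from_margins",
    "odds_ratio",
    "fit_logistic",
    "crude_and_adjusted",
    "group_mean_tests",
    "round_half_up",
]

Z_975 = float(norm.ppf(0.975))  # 1.959964...


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the table-printing convention)."""
    x = float(x)
    if not math.isfinite(x) or abs(x) >= 1e15:  # beyond printing precision
        return x
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts (a, b, c, d) = (exposed-event, exposed-nonevent,
    unexposed-event, unexposed-nonevent)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")


@dataclass(frozen=True)
class ORResult:
    or_: float
    ci_low: float
    ci_high: float
    alpha: float
    zero_cell_corrected: bool

    def __str__(self):
        return (f"{round_half_up(self.or_, 2):.2f} "
                f"({round_half_up(self.ci_low, 2):.2f}-"
                f"{round_half_up(self.ci_high, 2):.2f})")


def table_from_margins(n_exposed: int, pct_event_exposed: float,
                       n_unexposed: int, pct_event_unexposed: float
                       ) -> TwoByTwoTable:
    """Rebuild a 2x2 table from per-row n and percent-with-event.

    Event counts are round-half-up(n * pct / 100); complements fill the
    rows, so the rows sum to their printed n exactly.
    """
    if n_exposed <= 0 or n_unexposed <= 0:
        raise ValueError("row totals must be positive")
    for pct in (pct_event_exposed, pct_event_unexposed):
        if not 0 <= pct <= 100:
            raise ValueError(f"percent {pct} outside [0, 100]")
    a = int(round_half_up(n_exposed * pct_event_exposed / 100))
    c = int(round_half_up(n_unexposed * pct_event_unexposed / 100))
    return TwoByTwoTable(a, n_exposed - a, c, n_unexposed - c)


def odds_ratio(table: TwoByTwoTable, alpha: float = 0.05) -> ORResult:
    """Cross-product OR with the Woolf log-scale Wald CI.

    OR = ad/bc; CI = exp(ln OR +/- z_{1-alpha/2} * sqrt(1/a+1/b+1/c+1/d)).
    Any zero cell triggers the Haldane-Anscombe +0.5 correction to every
    cell, flagged in the result.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    corrected = 0 in (a, b, c, d)
    if corrected:
        if a == b == c == d == 0:  # unreachable via TwoByTwoTable, guard anyway
            raise ValueError("all-zero table")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = float(norm.ppf(1 - alpha / 2))
    log_or = math.log(or_)
    return ORResult(
        or_=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        alpha=alpha,
        zero_cell_corrected=corrected,
    )


# ---------------------------------------------------------------------------
# logistic regression

@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    log_likelihood: float
    converged: bool
    iterations: int
    alpha: float = 0.05

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.coef)

    @property
    def ci_low(self) -> np.ndarray:
        z = float(norm.ppf(1 - self.alpha / 2))
        with np.errstate(over="ignore"):  # separated fits: CI endpoint -> inf
            return np.exp(self.coef - z * self.se)

    @property
    def ci_high(self) -> np.ndarray:
        z = float(norm.ppf(1 - self.alpha / 2))
        with np.errstate(over="ignore"):
            return np.exp(self.coef + z * self.se)

    @property
    def p_values(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            z = self.coef / self.se
        return 2 * norm.sf(np.abs(z))


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(p)*y + log(1-p)*(1-y) in a numerically stable form
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic(X: np.ndarray, y: np.ndarray,
                 tol: float = 1e-10, max_iter: int = 100,
                 separation_bound: float = 15.0) -> LogisticFit:
    """Maximum-likelihood logistic regression via Newton-Raphson / IRLS.

    ``X`` is the n x p design matrix (include an intercept column
    explicitly); ``y`` is binary.  Convergence is declared when the
    relative change in log-likelihood drops below ``tol``.  If any
    coefficient exceeds ``separation_bound`` in absolute value during
    iteration, the data are treated as (quasi-)separated and a
    non-converged fit is returned rather than raising.  A rank-deficient
    design raises ``ValueError``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need n > p, got n={n}, p={p}")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcomes must be binary (0/1)")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank-deficient")

    beta = np.zeros(p)
    ll = _log_likelihood(X, y, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(X @ beta)
        w = mu * (1 - mu)
        info = X.T @ (X * w[:, None])          # observed information
        grad = X.T @ (y - mu)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(beta)) > separation_bound:
            # perfect / quasi-perfect separation: likelihood is monotone in
            # some direction and the MLE does not exist
            break
        new_ll = _log_likelihood(X, y, beta)
        if abs(new_ll - ll) < tol * (abs(ll) + tol):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    info = X.T @ (X * w[:, None])
    try:
        cov = np.linalg.inv(info)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(p, np.nan)
    return LogisticFit(coef=beta, se=se,
                       log_likelihood=_log_likelihood(X, y, beta),
                       converged=converged, iterations=it)


@dataclass
class ModelReport:
    """Crude and Medicare-adjusted receipt models, table-style."""

    crude_cbs: LogisticFit
    crude_medicare: LogisticFit
    adjusted: LogisticFit
    rows: list[dict] = field(default_factory=list)


def _fmt(fit: LogisticFit, idx: int) -> dict:
    return {
        "or": round_half_up(float(fit.odds_ratios[idx]), 2),
        "ci_low": round_half_up(float(fit.ci_low[idx]), 2),
        "ci_high": round_half_up(float(fit.ci_high[idx]), 2),
        "p": float(fit.p_values[idx]),
        "converged": fit.converged,
    }


def crude_and_adjusted(cbs: Sequence[float], medicare: Sequence[int],
                       received: Sequence[int]) -> ModelReport:
    """Fit received ~ CBS, received ~ Medicare and received ~ CBS + Medicare.

    Reports per-coefficient odds ratios with 95% Wald CIs rounded
    half-up to two decimals, matching the published table style.
    """
    cbs = np.asarray(cbs, dtype=float)
    med = np.asarray(medicare, dtype=float)
    y = np.asarray(received, dtype=float)
    if len(np.unique(cbs)) < 2:
        raise ValueError("need at least two distinct CBS values")
    if len(np.unique(med)) < 2:
        raise ValueError("both insurance levels must be present")
    ones = np.ones_like(y)
    crude_cbs = fit_logistic(np.column_stack([ones, cbs]), y)
    crude_med = fit_logistic(np.column_stack([ones, med]), y)
    adjusted = fit_logistic(np.column_stack([ones, cbs, med]), y)
    rows = [
        {"model": "crude", "term": "cbs", **_fmt(crude_cbs, 1)},
        {"model": "crude", "term": "medicare", **_fmt(crude_med, 1)},
        {"model": "adjusted", "term": "cbs", **_fmt(adjusted, 1)},
        {"model": "adjusted", "term": "medicare", **_fmt(adjusted, 2)},
    ]
    return ModelReport(crude_cbs=crude_cbs, crude_medicare=crude_med,
                       adjusted=adjusted, rows=rows)


# ---------------------------------------------------------------------------
# group-mean tests

def group_mean_tests(groups: Sequence[Sequence[float]]
                     ) -> tuple[float, float, str]:
    """Compare stratum means: Welch t for two strata, one-way ANOVA for more.

    Returns (statistic, p_value, test_name).  Each stratum needs at least
    two observations.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValueError("need at least two strata")
    for g in arrays:
        if len(g) < 2:
            raise ValueError("every stratum needs at least two observations")
    if len(arrays) == 2:
        x, ystrat = arrays
        n1, n2 = len(x), len(ystrat)
        v1, v2 = x.var(ddof=1), ystrat.var(ddof=1)
        denom = math.sqrt(v1 / n1 + v2 / n2)
        if denom == 0:
            return 0.0, 1.0, "welch_t"
        stat = (x.mean() - ystrat.mean()) / denom
        df = (v1 / n1 + v2 / n2) ** 2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2 * float(t_dist.sf(abs(stat), df))
        return float(stat), p, "welch_t"
    all_x = np.concatenate(arrays)
    grand = all_x.mean()
    k = len(arrays)
    n = len(all_x)
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in arrays)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in arrays)
    if ss_within == 0:
        if ss_between == 0:
            return 0.0, 1.0, "anova_f"
        return float("inf"), 0.0, "anova_f"
    stat = (ss_between / (k - 1)) / (ss_within / (n - k))
    p = float(f_dist.sf(stat, k - 1, n - k))
    return float(stat), p, "anova_f"
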