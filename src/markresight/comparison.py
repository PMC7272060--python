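"""Between-method comparisons: conversion factors, trend test, totals test.

A conversion factor (CF) places estimates from two survey platforms on a
common scale.  For periods surveyed by both platforms the per-period
quotient is ``n_hat(to_method) / n_hat(from_method)``, and the CF is the
arithmetic mean of the per-period quotients with its sample SD.  Applied to
a historical surface-observer series, the CF converts it onto the scale of
the newer platform.

Note on direction: the CF is defined here as to/from so that e.g. the
surface-observer-to-UAV factor is the UAV estimate divided by the (smaller,
bias-deflated) surface-observer estimate and comes out above 1, matching
how such factors are quoted for this survey programme.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .data import ComparisonError, Dataset
from .lincoln_petersen import LPEstimate, lp_point


@dataclass(frozen=True)
class ConversionFactor:
    from_method: str
    to_method: str
    per_period: tuple[tuple[str, float], ...]
    mean_cf: float
    sd_cf: float

    @property
    def n_periods(self) -> int:
        return len(self.per_period)


def conversion_factor(
    estimates: Sequence[LPEstimate],
    from_method: str,
    to_method: str,
    periods: Optional[Sequence[str]] = None,
) -> ConversionFactor:
    """CF between two methods from a list of period-level estimates.

    By default every period holding estimates for *both* methods is used;
    pass ``periods`` to restrict (e.g. to the periods where all three
    platforms operated).  The sample SD is NaN with a single period.
    """
    by_key = {(e.period_id, e.method): e.n_hat for e in estimates}
    order: list[str] = []
    for e in estimates:
        if e.period_id not in order:
            order.append(e.period_id)
    common = [
        p
        for p in order
        if (p, from_method) in by_key and (p, to_method) in by_key
    ]
    if periods is not None:
        common = [p for p in common if p in set(periods)]
    if not common:
        raise ComparisonError(
            f"no period has estimates for both {from_method!r} and {to_method!r}"
        )
    quotients = [(p, by_key[(p, to_method)] / by_key[(p, from_method)]) for p in common]
    vals = np.array([q for _, q in quotients])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return ConversionFactor(
        from_method, to_method, tuple(quotients), float(vals.mean()), sd
    )


def conversion_factor_by_survey(
    data: Dataset, from_method: str, to_method: str
) -> ConversionFactor:
    """CF paired at the individual-survey level (period, day, diel) instead
    of on period means; available as an alternative aggregation."""
    pairs = {}
    for s in data.surveys:
        pairs.setdefault((s.period_id, s.day, s.diel), {})[s.method] = s
    quotients = []
    for (pid, day, diel), by_m in pairs.items():
        if from_method in by_m and to_method in by_m:
            a, b = by_m[from_method], by_m[to_method]
            if a.marked_seen and b.marked_seen:
                M = data.marked_population(pid)
                quotients.append(
                    (
                        f"{pid}|d{day}|{diel}",
                        lp_point(M, b.total_seen, b.marked_seen)
                        / lp_point(M, a.total_seen, a.marked_seen),
                    )
                )
    if not quotients:
        raise ComparisonError(
            f"no survey is paired across {from_method!r} and {to_method!r}"
        )
    vals = np.array([q for _, q in quotients])
    sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else float("nan")
    return ConversionFactor(
        from_method, to_method, tuple(quotients), float(vals.mean()), sd
    )


def apply_conversion(
    series: Sequence[tuple[object, Optional[float]]], cf: ConversionFactor
) -> list[tuple[object, Optional[float]]]:
    """Multiply a historical (year, estimate) series by ``cf.mean_cf``.

    Missing values (None or NaN) propagate unchanged.
    """
    if not cf.mean_cf > 0:
        raise ValueError("conversion factor must be positive")
    out = []
    for year, value in series:
        if value is None or (isinstance(value, float) and math.isnan(value)):
            out.append((year, value))
        else:
            out.append((year, value * cf.mean_cf))
    return out


@dataclass(frozen=True)
class TrendTest:
    """Spearman rank correlation of CF against abundance, plus an OLS line."""

    rho: float
    p_value: float
    slope: float
    intercept: float
    n: int
    exact: bool


def _spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


def cf_trend_test(
    cfs: Sequence[float],
    abundances: Sequence[float],
    *,
    exact_max_n: int = 8,
) -> TrendTest:
    """Does the conversion factor trend with abundance?

    Spearman rho is computed from average ranks.  The two-sided p-value is
    an exact full-enumeration permutation p for n <= ``exact_max_n``
    (720 orderings at n = 6 — small-sample exact, as appropriate for a
    six-period series), otherwise the large-sample approximation.  A
    least-squares line of CF on abundance is returned alongside.
    """
    x = np.asarray(abundances, dtype=float)
    y = np.asarray(cfs, dtype=float)
    if len(x) != len(y):
        raise ValueError("cfs and abundances must have equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant input vector")
    rho = _spearman_rho(x, y)
    n = len(x)
    if n <= exact_max_n:
        ry = stats.rankdata(y)
        rx = stats.rankdata(x)
        count = 0
        total = 0
        tol = 1e-12
        for perm in itertools.permutations(range(n)):
            r = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
            if abs(r) >= abs(rho) - tol:
                count += 1
            total += 1
        p = count / total
        exact = True
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        exact = False
    slope, intercept = np.polyfit(x, y, 1)
    return TrendTest(rho, float(p), float(slope), float(intercept), n, exact)


def method_mean_totals(estimates: Sequence[LPEstimate]) -> dict[str, float]:
    """Mean turtles counted per method, averaging period-level mean totals."""
    by_method: dict[str, list[float]] = {}
    for e in estimates:
        by_method.setdefault(e.method, []).append(e.mean_total)
    return {m: float(np.mean(v)) for m, v in by_method.items()}


@dataclass(frozen=True)
class TotalsComparison:
    """Per-method mean totals/densities and the Gaussian LR method test."""

    method_means: dict[str, float]
    densities: Optional[dict[str, float]]
    deviance: float
    df: int
    p_value: float
    deviance_density: Optional[float] = None
    p_value_density: Optional[float] = None
    excluded: tuple[str, ...] = ()


def _gaussian_lr(y: np.ndarray, groups: np.ndarray) -> tuple[float, int, float]:
    """LR chi-square test of a group effect in a Gaussian model (MLE variance)."""
    n = len(y)
    rss_null = float(np.sum((y - y.mean()) ** 2))
    rss_full = 0.0
    labels = np.unique(groups)
    for g in labels:
        yg = y[groups == g]
        rss_full += float(np.sum((yg - yg.mean()) ** 2))
    if rss_full <= 0:
        D = math.inf if rss_null > 0 else 0.0
    else:
        D = n * math.log(rss_null / rss_full)
    df = len(labels) - 1
    p = float(stats.chi2.sf(D, df)) if df > 0 else float("nan")
    return float(D), df, p


def compare_totals(
    data: Dataset,
    areas: Optional[dict[str, float]] = None,
) -> TotalsComparison:
    """Mean turtles counted per method, and a test of the method effect.

    Per (period, method) the mean of per-survey totals is taken; the
    method-level mean of those period means is reported, together with a
    likelihood-ratio chi-square (n_methods - 1 df) for the method effect in
    a Gaussian model on log_e period totals.  Densities (turtles/km^2) are
    reported when per-method survey areas are supplied, with the analogous
    LR test on log densities.  Zero period totals are excluded from the
    log-scale fits.
    """
    methods = data.methods
    if len(methods) < 2:
        raise ComparisonError("need surveys from at least two methods")
    period_means: list[tuple[str, str, float]] = []
    for method in methods:
        per_period = {}
        for s in data.surveys_for(method=method):
            per_period.setdefault(s.period_id, []).append(s.total_seen)
        if len(per_period) < 2:
            raise ComparisonError(
                f"method {method!r} has period means for fewer than 2 periods"
            )
        for pid, totals in per_period.items():
            period_means.append((pid, method, float(np.mean(totals))))

    method_means = {
        m: float(np.mean([t for _, mm, t in period_means if mm == m]))
        for m in methods
    }
    excluded = tuple(
        f"{pid}/{m}" for pid, m, t in period_means if t <= 0
    )
    kept = [(pid, m, t) for pid, m, t in period_means if t > 0]
    y = np.log([t for _, _, t in kept])
    g = np.array([m for _, m, _ in kept])
    D, df, p = _gaussian_lr(y, g)

    densities = None
    D_d = p_d = None
    if areas is not None:
        densities = {m: method_means[m] / areas[m] for m in methods}
        y_d = np.array(
            [math.log(t / areas[m]) for _, m, t in kept]
        )
        D_d, _, p_d = _gaussian_lr(y_d, g)
    return TotalsComparison(
        method_means=method_means,
        densities=densities,
        deviance=D,
        df=df,
        p_value=p,
        deviance_density=D_d,
        p_value_density=p_d,
        excluded=excluded,
    )
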