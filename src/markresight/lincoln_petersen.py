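"""Lincoln-Petersen abundance estimation from repeated resight surveys.

The Lincoln-Petersen (LP) estimator for a closed population is

    N_hat = M * C / R

where M turtles are marked, C turtles are sighted in a resight survey and R
of those carry the mark.  With repeated surveys of one period the package
reports the mean of per-survey estimates with its standard error of the
mean, and a cumulative-pooling analysis in which the estimate after k
surveys is M * mean(C_1..C_k) / mean(R_1..R_k) with a leave-one-out
jackknife confidence interval — the precision-versus-effort analysis of the
repeated-sampling design.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .data import DIEL_PERIODS, Dataset, EstimationError, SurveyRecord

Z_95 = 1.959963984540054  # standard normal 97.5% quantile


def lp_point(M: int, C: int, R: int) -> float:
    """Classical Lincoln-Petersen point estimate ``M*C/R``.

    Raises :class:`EstimationError` when ``R == 0`` (no marked resights;
    callers may fall back to :func:`chapman_point`), and ``ValueError`` for
    structurally impossible inputs (``C < R`` or ``M < R``).
    """
    if R == 0:
        raise EstimationError("no marked resights (R = 0)")
    if R < 0 or C < R or M < R:
        raise ValueError(f"require 0 <= R <= min(M, C); got M={M}, C={C}, R={R}")
    return M * C / R


def chapman_point(M: int, C: int, R: int) -> float:
    """Chapman's small-sample variant ``(M+1)(C+1)/(R+1) - 1`` (defined at R=0)."""
    if R < 0 or C < R or M < R:
        raise ValueError(f"require 0 <= R <= min(M, C); got M={M}, C={C}, R={R}")
    return (M + 1) * (C + 1) / (R + 1) - 1


def lp_se(M: int, C: int, R: int) -> float:
    """Large-sample standard error ``sqrt(M^2 * C * (C-R) / R^3)``.

    Algebraically identical to the delta-method form
    ``sqrt(N_hat^2 * C * p * (1-p) / R^2)`` with ``p = R/C``.
    """
    if R == 0:
        raise EstimationError("no marked resights (R = 0)")
    if R < 0 or C < R or M < R:
        raise ValueError(f"require 0 <= R <= min(M, C); got M={M}, C={C}, R={R}")
    return float(np.sqrt(M * M * C * (C - R) / R**3))


@dataclass(frozen=True)
class LPEstimate:
    """Abundance estimate for one (period, method) with its provenance."""

    period_id: str
    method: str
    n_hat: float
    se: float
    n_surveys: int
    mean_total: float
    source: str  # "single" | "period_mean" | "cumulative"

    def __post_init__(self) -> None:
        if not self.n_hat > 0:
            raise ValueError("n_hat must be positive")
        if self.se < 0:
            raise ValueError("se must be >= 0")
        if self.source == "single" and self.n_surveys != 1:
            raise ValueError("source='single' requires n_surveys == 1")


@dataclass(frozen=True)
class CumulativeEstimate:
    """LP estimate from the first k pooled surveys, with a 95% interval."""

    k: int
    n_hat: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if not self.ci_low <= self.n_hat <= self.ci_high:
            raise ValueError("require ci_low <= n_hat <= ci_high")

    @property
    def width(self) -> float:
        return self.ci_high - self.ci_low


def _survey_order(s: SurveyRecord):
    return (s.day, DIEL_PERIODS.index(s.diel))


def period_estimate(
    data: Dataset,
    period_id: str,
    method: str,
    *,
    chapman: bool = False,
) -> LPEstimate:
    """Period-level abundance for one method: mean of per-survey LP estimates.

    ``se`` is the standard error of the mean of the per-survey estimates
    (sample SD / sqrt(n)); with a single survey it falls back to the
    analytic :func:`lp_se`.  Surveys with no marked resights are excluded
    with a warning (unless ``chapman=True``, in which case the Chapman
    variant keeps them).
    """
    surveys = data.surveys_for(period_id, method)
    if not surveys:
        raise EstimationError(f"no surveys for ({period_id!r}, {method!r})")
    M = data.marked_population(period_id)
    point = chapman_point if chapman else lp_point
    ests, totals = [], []
    for s in surveys:
        if s.marked_seen == 0 and not chapman:
            _warnings.warn(
                f"survey ({period_id}, day {s.day}, {s.diel}, {method}) has no "
                "marked resights; excluded from the period estimate",
                stacklevel=2,
            )
            continue
        ests.append(point(M, s.total_seen, s.marked_seen))
        totals.append(s.total_seen)
    if not ests:
        raise EstimationError(
            f"all surveys for ({period_id!r}, {method!r}) had zero marked resights"
        )
    n = len(ests)
    if n == 1:
        s = surveys[[sv.marked_seen > 0 or chapman for sv in surveys].index(True)]
        se = (
            lp_se(M, s.total_seen, s.marked_seen)
            if s.marked_seen > 0
            else float("nan")
        )
        source = "single"
    else:
        se = float(np.std(ests, ddof=1) / np.sqrt(n))
        source = "period_mean"
    return LPEstimate(
        period_id=period_id,
        method=method,
        n_hat=float(np.mean(ests)),
        se=se,
        n_surveys=n,
        mean_total=float(np.mean(totals)),
        source=source,
    )


def estimate_all(
    data: Dataset,
    *,
    methods: Optional[Sequence[str]] = None,
    chapman: bool = False,
) -> list[LPEstimate]:
    """Period estimates for every (period, method) pair with surveys."""
    out = []
    for period in data.periods:
        for method in methods or data.methods:
            if data.surveys_for(period, method):
                out.append(period_estimate(data, period, method, chapman=chapman))
    return out


def cumulative_estimates(
    data: Dataset,
    period_id: str,
    method: str,
    *,
    z: float = Z_95,
) -> list[CumulativeEstimate]:
    """Cumulative-pooling LP estimates for k = 1..n surveys of one period.

    Surveys are ordered chronologically (day, then AM before PM).  The k-th
    estimate pools counts as ``M * mean(C_1..C_k) / mean(R_1..R_k)``.  For
    k >= 2 the 95% interval is normal-theory with the leave-one-out
    jackknife variance over the k surveys; for k = 1 it uses the analytic
    per-survey standard error.
    """
    surveys = sorted(data.surveys_for(period_id, method), key=_survey_order)
    if not surveys:
        raise EstimationError(f"no surveys for ({period_id!r}, {method!r})")
    M = data.marked_population(period_id)
    C = np.array([s.total_seen for s in surveys], dtype=float)
    R = np.array([s.marked_seen for s in surveys], dtype=float)
    out: list[CumulativeEstimate] = []
    for k in range(1, len(surveys) + 1):
        if R[:k].mean() == 0:
            raise EstimationError(
                f"mean marked resights is zero over the first {k} surveys of "
                f"({period_id!r}, {method!r})"
            )
        n_hat = float(M * C[:k].mean() / R[:k].mean())
        if k == 1:
            half = z * lp_se(M, int(C[0]), int(R[0]))
        else:
            loo = []
            for i in range(k):
                mask = np.arange(k) != i
                r_mean = R[:k][mask].mean()
                if r_mean == 0:
                    raise EstimationError(
                        "leave-one-out resample has zero mean marked resights"
                    )
                loo.append(M * C[:k][mask].mean() / r_mean)
            loo = np.asarray(loo)
            var_jack = (k - 1) / k * np.sum((loo - loo.mean()) ** 2)
            half = z * float(np.sqrt(var_jack))
        out.append(CumulativeEstimate(k, n_hat, n_hat - half, n_hat + half))
    return out
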