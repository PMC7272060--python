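"""Synthetic survey generators.

Two generators are provided:

``simulate_dataset``
    An individual-based simulator of the whole resight study: a closed
    population of ``n_true`` inter-nesting females of which ``n_marked``
    carry the paint mark, surveyed repeatedly by up to three platforms.
    Detection of each present individual is an independent Bernoulli draw
    whose probability sits on the logit scale under nested Gaussian random
    intercepts (period / day-within-period / diel-within-day), and marked
    individuals receive an additional log-odds term ``log(mark_bias)`` —
    the marked-detection bias that violates the Lincoln-Petersen
    equal-detectability assumption.  An optional per-day departure
    probability breaks demographic closure.

``simulate_marked_counts``
    A direct generator from the binomial mixed model of marked-detection
    probability (the model fitted by :mod:`markresight.glmm`):
    ``marked_seen ~ Binomial(total_seen, logit^-1(alpha + beta_method +
    b_period + b_day + b_diel + eps))``.  This is the generator of choice
    for sampler-calibration and parameter-recovery checks, because the
    individual-based simulator's detection-scale random intercepts act on
    marked and unmarked turtles alike and therefore cancel (to first order
    at low detection probability) out of the marked fraction.

The default :class:`SimulationConfig` encodes the study conditions of the
Raine Island programme: six survey periods, up to 2000 turtles painted per
period, a true inter-nesting population of order 20 000, three survey days
with AM and PM surveys, and a surface-observer marked-detection odds ratio
of about 1.6 (the UAV and underwater-video platforms are unbiased).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data import (
    DIEL_PERIODS,
    METHODS,
    Dataset,
    DetectabilityTrial,
    Finding,
    MarkingRecord,
    SurveyRecord,
)

#: Default study-period labels (marking-night anchored field trips).
DEFAULT_PERIODS = (
    "Dec 2013",
    "Dec 2014",
    "Feb 2016",
    "Nov 2016",
    "Dec 2016",
    "Dec 2017",
)

_P_FLOOR = 1e-9
_P_CEIL = 1.0 - 1e-9


def _as_method_map(value, methods, name) -> dict[str, float]:
    if isinstance(value, Mapping):
        out = {m: float(value[m]) for m in methods}
    else:
        out = {m: float(value) for m in methods}
    return out


@dataclass
class SimulationConfig:
    """Parameters of the individual-based resight-study simulator.

    Attributes
    ----------
    n_true : int
        True female population in the inter-nesting habitat.
    n_marked : int
        Number painted per period (M); must not exceed ``n_true``.
    periods : sequence of str
        Survey-period labels.
    days, diel_per_day : int
        Days surveyed per period (default 3) and surveys per day (AM/PM).
    methods : sequence of str
        Platforms surveying simultaneously.
    base_detect : float or mapping
        Per-method probability that a present individual is counted in one
        survey (logit-scale intercept of the detection process).
    mark_bias : float or mapping
        Multiplicative odds increase for detecting a *marked* individual
        (kappa >= 1; 1 means the equal-detectability assumption holds).
    sigma_period, sigma_day, sigma_diel : float
        SDs of the nested Gaussian random intercepts on the logit
        detection scale.
    departure_prob : float
        Per-day probability that an individual permanently leaves the
        survey area (closure violation; 0 = closed population).
    seed : int
        Base seed; sub-streams are derived per period/day/survey so that
        adding a method does not perturb the other draws.
    """

    n_true: int = 20_000
    n_marked: int = 2_000
    periods: Sequence[str] = DEFAULT_PERIODS
    days: int = 3
    diel_per_day: int = 2
    methods: Sequence[str] = ("SO", "UWV", "UAV")
    base_detect: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"SO": 0.05, "UWV": 0.06, "UAV": 0.12}
    )
    mark_bias: Union[float, Mapping[str, float]] = field(
        default_factory=lambda: {"SO": 1.6, "UWV": 1.0, "UAV": 1.0}
    )
    sigma_period: float = 0.5
    sigma_day: float = 0.1
    sigma_diel: float = 0.05
    departure_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.methods = tuple(self.methods)
        self.periods = tuple(str(p) for p in self.periods)
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValueError(f"unknown method(s) {unknown}; allowed: {METHODS}")
        if not 1 <= self.n_marked <= self.n_true:
            raise ValueError("require 1 <= n_marked <= n_true")
        if self.diel_per_day not in (1, 2):
            raise ValueError("diel_per_day must be 1 (AM) or 2 (AM+PM)")
        if self.days < 1:
            raise ValueError("days must be >= 1")
        self.base_detect = _as_method_map(self.base_detect, self.methods, "base_detect")
        self.mark_bias = _as_method_map(self.mark_bias, self.methods, "mark_bias")
        for m in self.methods:
            if not 0.0 < self.base_detect[m] <= 1.0:
                raise ValueError(f"base_detect[{m}] must be in (0, 1]")
            if self.mark_bias[m] < 1.0:
                raise ValueError(f"mark_bias[{m}] must be >= 1")
        for name in ("sigma_period", "sigma_day", "sigma_diel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.departure_prob < 1.0:
            raise ValueError("departure_prob must be in [0, 1)")


@dataclass
class SimulationTruth:
    """Latent state of one simulated study, for parameter-recovery tests."""

    config: SimulationConfig
    #: columns period_id, day, marked_present, unmarked_present, n_present
    presence: pd.DataFrame
    #: columns period_id, day, diel, b_period, b_day, b_diel
    effects: pd.DataFrame
    #: clamping warnings emitted while forming detection probabilities
    warnings: list[Finding] = field(default_factory=list)


@dataclass
class SimulationResult:
    dataset: Dataset
    truth: SimulationTruth


def _clamp_p(p: float, where: str, warnings: list[Finding]) -> float:
    if p < _P_FLOOR or p > _P_CEIL:
        warnings.append(
            Finding(
                "probability_clamped",
                f"{where}: detection probability {p!r} clamped to "
                f"[{_P_FLOOR}, {_P_CEIL}]",
            )
        )
        return float(min(max(p, _P_FLOOR), _P_CEIL))
    return float(p)


def simulate_dataset(config: SimulationConfig) -> SimulationResult:
    """Simulate a full resight study; returns the Dataset plus latent truth.

    Deterministic given ``config.seed``: independent sub-streams are derived
    per (period), (period, presence) and (period, day, diel, method), so the
    same seed always yields a byte-identical dataset and removing/adding a
    method leaves the other methods' counts unchanged.
    """
    cfg = config
    warnings: list[Finding] = []
    surveys: list[SurveyRecord] = []
    presence_rows = []
    effect_rows = []
    for pi, period in enumerate(cfg.periods):
        eff_rng = np.random.default_rng([cfg.seed, 1, pi])
        b_i = eff_rng.normal(0.0, cfg.sigma_period)
        b_ij = eff_rng.normal(0.0, cfg.sigma_day, size=cfg.days)
        b_ijk = eff_rng.normal(0.0, cfg.sigma_diel, size=(cfg.days, cfg.diel_per_day))
        pres_rng = np.random.default_rng([cfg.seed, 2, pi])
        marked_present = cfg.n_marked
        unmarked_present = cfg.n_true - cfg.n_marked
        for day in range(1, cfg.days + 1):
            if day > 1 and cfg.departure_prob > 0:
                stay = 1.0 - cfg.departure_prob
                marked_present = int(pres_rng.binomial(marked_present, stay))
                unmarked_present = int(pres_rng.binomial(unmarked_present, stay))
            presence_rows.append(
                {
                    "period_id": period,
                    "day": day,
                    "marked_present": marked_present,
                    "unmarked_present": unmarked_present,
                    "n_present": marked_present + unmarked_present,
                }
            )
            for di in range(cfg.diel_per_day):
                diel = DIEL_PERIODS[di]
                effect_rows.append(
                    {
                        "period_id": period,
                        "day": day,
                        "diel": diel,
                        "b_period": b_i,
                        "b_day": b_ij[day - 1],
                        "b_diel": b_ijk[day - 1, di],
                    }
                )
                for method in cfg.methods:
                    mi = METHODS.index(method)
                    rng = np.random.default_rng([cfg.seed, 3, pi, day, di, mi])
                    base = cfg.base_detect[method]
                    eta = logit(base) + b_i + b_ij[day - 1] + b_ijk[day - 1, di]
                    where = f"{period} day {day} {diel} {method}"
                    p_u = _clamp_p(float(expit(eta)), where, warnings)
                    p_m = _clamp_p(
                        float(expit(eta + math.log(cfg.mark_bias[method]))),
                        where,
                        warnings,
                    )
                    marked_seen = int(rng.binomial(marked_present, p_m))
                    unmarked_seen = int(rng.binomial(unmarked_present, p_u))
                    surveys.append(
                        SurveyRecord(period, day, diel, method, marked_seen, unmarked_seen)
                    )
    dataset = Dataset(
        surveys, [MarkingRecord(p, cfg.n_marked) for p in cfg.periods]
    )
    truth = SimulationTruth(
        cfg, pd.DataFrame(presence_rows), pd.DataFrame(effect_rows), warnings
    )
    return SimulationResult(dataset, truth)


def simulate_detectability_trials(
    plain_mu: float,
    mark_gain: float,
    noise_sd: float,
    n_sites: int,
    seed: int = 0,
) -> list[DetectabilityTrial]:
    """Simulate the paired model-turtle depth-detectability experiment.

    Per site, the plain model disappears at ``plain_mu`` metres and the
    marked model at ``plain_mu + mark_gain`` metres, each multiplied by
    independent log-normal noise with log-scale SD ``noise_sd``.
    """
    if plain_mu <= 0:
        raise ValueError("plain_mu must be positive")
    if mark_gain < 0:
        raise ValueError("mark_gain must be >= 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if n_sites < 2:
        raise ValueError("n_sites must be >= 2 (downstream test needs >= 2)")
    rng = np.random.default_rng(seed)
    trials: list[DetectabilityTrial] = []
    for site in range(1, n_sites + 1):
        plain = plain_mu * rng.lognormal(0.0, noise_sd)
        marked = (plain_mu + mark_gain) * rng.lognormal(0.0, noise_sd)
        trials.append(DetectabilityTrial(site, "PLAIN", float(plain)))
        trials.append(DetectabilityTrial(site, "MARKED", float(marked)))
    return trials


def simulate_marked_counts(
    alpha: float,
    beta: Optional[Mapping[str, float]] = None,
    *,
    sigma_period: float = 1.0,
    sigma_day: float = 0.05,
    sigma_diel: float = 0.05,
    sigma_resid: float = 0.1,
    n_periods: int = 6,
    days: int = 3,
    diel_per_day: int = 2,
    methods: Sequence[str] = ("SO", "UWV", "UAV"),
    mean_total: float = 800.0,
    n_marked: int = 2_000,
    seed: int = 0,
) -> tuple[Dataset, pd.DataFrame]:
    """Generate survey counts directly from the binomial mixed model.

    ``logit(P) = alpha + beta[method] + b_period + b_day + b_diel + eps``,
    with ``marked_seen ~ Binomial(total_seen, P)`` and
    ``total_seen ~ 1 + Poisson(mean_total - 1)``.  ``beta`` maps non-reference
    methods to fixed-effect contrasts (missing methods, including the
    reference, get 0).  Returns the Dataset and a DataFrame of the realised
    random effects per survey row.
    """
    beta = dict(beta or {})
    methods = tuple(methods)
    rng = np.random.default_rng(seed)
    surveys: list[SurveyRecord] = []
    rows = []
    for pi in range(n_periods):
        period = f"P{pi + 1}"
        b_i = rng.normal(0.0, sigma_period)
        for day in range(1, days + 1):
            b_ij = rng.normal(0.0, sigma_day)
            for di in range(diel_per_day):
                diel = DIEL_PERIODS[di]
                b_ijk = rng.normal(0.0, sigma_diel)
                for method in methods:
                    eps = rng.normal(0.0, sigma_resid)
                    eta = alpha + beta.get(method, 0.0) + b_i + b_ij + b_ijk + eps
                    total = 1 + int(rng.poisson(max(mean_total - 1.0, 0.0)))
                    marked = int(rng.binomial(total, float(expit(eta))))
                    marked = min(marked, n_marked)
                    surveys.append(
                        SurveyRecord(period, day, diel, method, marked, total - marked)
                    )
                    rows.append(
                        {
                            "period_id": period,
                            "day": day,
                            "diel": diel,
                            "method": method,
                            "b_period": b_i,
                            "b_day": b_ij,
                            "b_diel": b_ijk,
                            "eps": eps,
                            "eta": eta,
                        }
                    )
    markings = [MarkingRecord(f"P{pi + 1}", n_marked) for pi in range(n_periods)]
    return Dataset(surveys, markings), pd.DataFrame(rows)


def truth_frame(truth: SimulationTruth) -> pd.DataFrame:
    """Wide per-period presence table (``n_present_day1..N``) for sidecar CSVs."""
    wide = truth.presence.pivot(index="period_id", columns="day", values="n_present")
    wide = wide.rename(columns=lambda d: f"n_present_day{d}")
    wide = wide.reindex(list(truth.config.periods))
    return wide.reset_index()
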