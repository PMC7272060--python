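"""Core data containers for mark-resight survey data.

A *survey period* is a multi-day field trip anchored on one night of mass
carapace painting (e.g. ``"Dec 2016"``).  During the following days the
waters around the rookery are surveyed twice daily (AM/PM) by one or more
platforms — surface observer (SO), underwater video (UWV) or UAV — and each
survey records how many of the sighted turtles carried the paint mark.

Every downstream stage of the package (Lincoln-Petersen estimation, the
detection GLMM, method comparison) consumes the :class:`Dataset` container
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

#: Canonical survey-platform labels, in reporting order.
METHODS = ("SO", "UWV", "UAV")

#: Diel (time-of-day) survey slots.
DIEL_PERIODS = ("AM", "PM")

#: Treatments in the model-turtle depth-detectability experiment.
TREATMENTS = ("PLAIN", "MARKED")


class SchemaError(ValueError):
    """A delimited input file does not have the expected columns."""


class ValidationError(ValueError):
    """A record violates a structural invariant of the data model."""


class EstimationError(RuntimeError):
    """An estimator cannot be computed from the data given to it."""


class ComparisonError(RuntimeError):
    """A between-method comparison has no usable overlap."""


@dataclass(frozen=True)
class Finding:
    """One validation finding: the violated rule plus a human-readable message."""

    rule: str
    message: str
    record: Optional[object] = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.rule}] {self.message}"


@dataclass(frozen=True)
class SurveyRecord:
    """Marked/unmarked counts from a single resight survey.

    Parameters
    ----------
    period_id : str
        Survey-period label, e.g. ``"Dec 2016"``.
    day : int
        Day since marking (1-3 in the standard design).
    diel : str
        ``"AM"`` or ``"PM"``.
    method : str
        ``"SO"``, ``"UWV"`` or ``"UAV"``.
    marked_seen : int
        Number of painted turtles resighted (the recapture count R).
    unmarked_seen : int
        Number of unpainted turtles sighted.
    """

    period_id: str
    day: int
    diel: str
    method: str
    marked_seen: int
    unmarked_seen: int

    def __post_init__(self) -> None:
        if self.diel not in DIEL_PERIODS:
            raise ValidationError(
                f"unknown diel label {self.diel!r}; allowed: {DIEL_PERIODS}"
            )
        if self.method not in METHODS:
            raise ValidationError(
                f"unknown method label {self.method!r}; allowed: {METHODS}"
            )
        for name in ("marked_seen", "unmarked_seen"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if int(self.day) != self.day or self.day < 1:
            raise ValidationError(f"day must be a positive integer, got {self.day!r}")

    @property
    def total_seen(self) -> int:
        """Total turtles sighted (C).  Always recomputed, never read from file."""
        return self.marked_seen + self.unmarked_seen


@dataclass(frozen=True)
class MarkingRecord:
    """Number of turtles painted at the start of one survey period (M)."""

    period_id: str
    n_marked: int
    marking_note: str = ""

    def __post_init__(self) -> None:
        if int(self.n_marked) != self.n_marked or self.n_marked <= 0:
            raise ValidationError(
                f"n_marked must be a positive integer, got {self.n_marked!r}"
            )


@dataclass(frozen=True)
class DetectabilityTrial:
    """One lowering of the model turtle: depth (m) at which it became indiscernible."""

    site: int
    treatment: str
    loss_depth_m: float

    def __post_init__(self) -> None:
        if self.treatment not in TREATMENTS:
            raise ValidationError(
                f"unknown treatment {self.treatment!r}; allowed: {TREATMENTS}"
            )
        if not self.loss_depth_m > 0:
            raise ValidationError(
                f"loss_depth_m must be positive, got {self.loss_depth_m!r}"
            )


def _sort_key(rec: SurveyRecord):
    return (
        rec.period_id,
        rec.day,
        DIEL_PERIODS.index(rec.diel),
        METHODS.index(rec.method),
    )


@dataclass
class Dataset:
    """A collection of resight surveys plus the per-period marking record."""

    surveys: list[SurveyRecord] = field(default_factory=list)
    markings: list[MarkingRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[SurveyRecord]:
        return iter(self.surveys)

    def __len__(self) -> int:
        return len(self.surveys)

    @property
    def periods(self) -> list[str]:
        """Period labels, in marking-record order."""
        return [m.period_id for m in self.markings]

    @property
    def methods(self) -> list[str]:
        """Methods present in the surveys, in canonical order."""
        present = {s.method for s in self.surveys}
        return [m for m in METHODS if m in present]

    def marked_population(self, period_id: str) -> int:
        """M for one period; raises ``KeyError`` if the period has no marking record."""
        for m in self.markings:
            if m.period_id == period_id:
                return m.n_marked
        raise KeyError(f"no marking record for period {period_id!r}")

    def surveys_for(
        self, period_id: Optional[str] = None, method: Optional[str] = None
    ) -> list[SurveyRecord]:
        out = self.surveys
        if period_id is not None:
            out = [s for s in out if s.period_id == period_id]
        if method is not None:
            out = [s for s in out if s.method == method]
        return list(out)

    def sorted(self) -> "Dataset":
        """Copy with surveys ordered by (period, day, diel, method)."""
        return Dataset(sorted(self.surveys, key=_sort_key), list(self.markings))

    def to_frame(self) -> pd.DataFrame:
        """Surveys as a DataFrame (with the recomputed ``total_seen`` column)."""
        return pd.DataFrame(
            {
                "period_id": [s.period_id for s in self.surveys],
                "day": [s.day for s in self.surveys],
                "diel": [s.diel for s in self.surveys],
                "method": [s.method for s in self.surveys],
                "marked_seen": [s.marked_seen for s in self.surveys],
                "unmarked_seen": [s.unmarked_seen for s in self.surveys],
                "total_seen": [s.total_seen for s in self.surveys],
            }
        )

    def markings_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "period_id": [m.period_id for m in self.markings],
                "n_marked": [m.n_marked for m in self.markings],
            }
        )

    def validate(self, allow_extended_days: bool = False) -> list[Finding]:
        """Check cross-record invariants; returns findings instead of raising.

        Rules checked:

        * exactly one marking record per period;
        * every survey's period has a marking record;
        * ``marked_seen`` never exceeds the marked population M;
        * ``day`` within the standard 1-3 design unless ``allow_extended_days``;
        * periods with fewer than two surveys are flagged (not dropped) as sparse.
        """
        findings: list[Finding] = []
        seen_periods: set[str] = set()
        marked: dict[str, int] = {}
        for m in self.markings:
            if m.period_id in seen_periods:
                findings.append(
                    Finding(
                        "duplicate_marking",
                        f"period {m.period_id!r} has more than one marking record",
                        m,
                    )
                )
            seen_periods.add(m.period_id)
            marked.setdefault(m.period_id, m.n_marked)
        counts: dict[str, int] = {}
        for i, s in enumerate(self.surveys):
            counts[s.period_id] = counts.get(s.period_id, 0) + 1
            if s.period_id not in marked:
                findings.append(
                    Finding(
                        "missing_marking",
                        f"survey row {i} period {s.period_id!r} has no marking record",
                        s,
                    )
                )
            elif s.marked_seen > marked[s.period_id]:
                findings.append(
                    Finding(
                        "marked_exceeds_population",
                        f"survey row {i} ({s.period_id}, day {s.day}, {s.diel}, "
                        f"{s.method}): marked exceeds marked population "
                        f"({s.marked_seen} > {marked[s.period_id]})",
                        s,
                    )
                )
            if not allow_extended_days and s.day not in (1, 2, 3):
                findings.append(
                    Finding(
                        "day_out_of_design",
                        f"survey row {i}: day {s.day} outside the standard 1-3 design",
                        s,
                    )
                )
        for pid, n in counts.items():
            if n < 2:
                findings.append(
                    Finding("sparse_period", f"period {pid!r} has only {n} survey(s)")
                )
        return findings
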