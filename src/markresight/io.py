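"""Delimited-text readers and writers.

Two flat CSV files describe a resight study:

* surveys:  ``period_id,day,diel,method,marked_seen,unmarked_seen``
* markings: ``period_id,n_marked``

Lines starting with ``#`` are provenance comments and are skipped on read.
Detectability trials use ``site,treatment,loss_depth_m``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .data import (
    DIEL_PERIODS,
    METHODS,
    TREATMENTS,
    Dataset,
    DetectabilityTrial,
    MarkingRecord,
    SchemaError,
    SurveyRecord,
    ValidationError,
)

PathLike = Union[str, Path]

SURVEY_COLUMNS = ("period_id", "day", "diel", "method", "marked_seen", "unmarked_seen")
MARKING_COLUMNS = ("period_id", "n_marked")
TRIAL_COLUMNS = ("site", "treatment", "loss_depth_m")


def _read_table(path: PathLike, required: Sequence[str], delimiter: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter, comment="#", skip_blank_lines=True)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def read_surveys(
    surveys_path: PathLike,
    markings_path: PathLike,
    *,
    delimiter: str = ",",
    allow_extended_days: bool = False,
) -> Dataset:
    """Read a survey file and its marking file into a validated :class:`Dataset`.

    Row order is preserved; counts are parsed as integers and ``total_seen``
    is always recomputed from the marked/unmarked columns.  Raises
    :class:`SchemaError` for a missing column and :class:`ValidationError`
    for an unknown method label or a marked count that exceeds the marked
    population of its period.
    """
    sdf = _read_table(surveys_path, SURVEY_COLUMNS, delimiter)
    mdf = _read_table(markings_path, MARKING_COLUMNS, delimiter)

    markings = [
        MarkingRecord(str(r.period_id), int(r.n_marked)) for r in mdf.itertuples()
    ]
    marked = {m.period_id: m.n_marked for m in markings}

    surveys: list[SurveyRecord] = []
    for i, r in enumerate(sdf.itertuples()):
        if str(r.method) not in METHODS:
            raise ValidationError(
                f"{surveys_path} row {i}: unknown method label {r.method!r}; "
                f"allowed labels: {', '.join(METHODS)}"
            )
        rec = SurveyRecord(
            period_id=str(r.period_id),
            day=int(r.day),
            diel=str(r.diel),
            method=str(r.method),
            marked_seen=int(r.marked_seen),
            unmarked_seen=int(r.unmarked_seen),
        )
        if not allow_extended_days and rec.day not in (1, 2, 3):
            raise ValidationError(
                f"{surveys_path} row {i}: day {rec.day} outside the standard 1-3 "
                "design (pass allow_extended_days=True to accept)"
            )
        if rec.period_id in marked and rec.marked_seen > marked[rec.period_id]:
            raise ValidationError(
                f"{surveys_path} row {i}: marked_seen {rec.marked_seen} exceeds the "
                f"marked population {marked[rec.period_id]} of period {rec.period_id!r}"
            )
        surveys.append(rec)
    return Dataset(surveys, markings)


def _provenance_lines(provenance: Optional[Mapping[str, object]]) -> str:
    from . import __version__

    lines = [f"# markresight {__version__}"]
    for k, v in (provenance or {}).items():
        lines.append(f"# {k}={v}")
    return "\n".join(lines) + "\n"


def _write_frame(df: pd.DataFrame, path: PathLike, provenance) -> None:
    buf = _io.StringIO()
    buf.write(_provenance_lines(provenance))
    df.to_csv(buf, index=False)
    Path(path).write_text(buf.getvalue())


def write_surveys(
    data: Dataset,
    surveys_path: PathLike,
    markings_path: PathLike,
    *,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    """Write a Dataset to the two-file CSV schema.

    Surveys are written sorted by (period, day, diel AM<PM, method SO<UWV<UAV),
    so ``read_surveys`` after ``write_surveys`` reproduces the sorted dataset
    field-for-field.
    """
    d = data.sorted()
    _write_frame(
        d.to_frame()[list(SURVEY_COLUMNS)], surveys_path, provenance
    )
    _write_frame(d.markings_frame(), markings_path, provenance)


def read_trials(path: PathLike, *, delimiter: str = ",") -> list[DetectabilityTrial]:
    df = _read_table(path, TRIAL_COLUMNS, delimiter)
    trials = []
    for i, r in enumerate(df.itertuples()):
        if str(r.treatment) not in TREATMENTS:
            raise ValidationError(
                f"{path} row {i}: unknown treatment {r.treatment!r}; "
                f"allowed: {', '.join(TREATMENTS)}"
            )
        trials.append(
            DetectabilityTrial(int(r.site), str(r.treatment), float(r.loss_depth_m))
        )
    return trials


def write_trials(
    trials: Iterable[DetectabilityTrial],
    path: PathLike,
    *,
    provenance: Optional[Mapping[str, object]] = None,
) -> None:
    trials = list(trials)
    df = pd.DataFrame(
        {
            "site": [t.site for t in trials],
            "treatment": [t.treatment for t in trials],
            "loss_depth_m": [t.loss_depth_m for t in trials],
        }
    )
    _write_frame(df, path, provenance)
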