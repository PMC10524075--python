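"""Readers, writers and report serialisation.

Cohort files are delimited text (comma by default, tab for ``.tsv``/
``.tab``), one row per screening episode, header required::

    subject_id, wave_index,
    major_cancer_history, major_polyp_history, major_family_crc,
    minor_constipation, minor_diarrhea, minor_mucus_bloody_stool,
    minor_life_event, minor_appendix, minor_gallbladder,
    fit1, fit2, days_to_diagnosis

Booleans accept 0/1 and true/false (any case); a blank
``days_to_diagnosis`` means no diagnosis within follow-up (never zero).
Study tables carry study_id, tp, fp, fn, tn plus any number of extra
columns, each preserved as a categorical covariate.

Report writers are deterministic: sorted JSON keys, fixed column order,
half-up rounding to the printed precision of the accuracy report (two
decimals) applied only at serialisation.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping, Sequence, Union

import pandas as pd

from .accuracy import AccuracyResult, round_half_up
from .cohort import ScreeningEpisode, Strategy
from .meta import StudyRecord
from .simulate import RA_ITEM_COLUMNS, episodes_from_frame

__all__ = [
    "COHORT_COLUMNS",
    "STUDY_COLUMNS",
    "read_cohort",
    "write_cohort",
    "read_studies",
    "write_studies",
    "accuracy_report_rows",
    "write_report",
]

COHORT_COLUMNS = (
    ("subject_id", "wave_index")
    + RA_ITEM_COLUMNS
    + ("fit1", "fit2", "days_to_diagnosis")
)

STUDY_COLUMNS = ("study_id", "tp", "fp", "fn", "tn")

_TRUE = {"1", "true", "t", "yes"}
_FALSE = {"0", "false", "f", "no"}


def _sep_for(path: Union[str, Path]) -> str:
    return "\t" if str(path).lower().endswith((".tsv", ".tab")) else ","


def _parse_bool(token: str, column: str, line: int) -> bool:
    t = token.strip().lower()
    if t in _TRUE:
        return True
    if t in _FALSE:
        return False
    raise ValueError(f"line {line}: column {column!r}: not a boolean: {token!r}")


def read_cohort(path: Union[str, Path]) -> list[ScreeningEpisode]:
    """Read a cohort file into typed episodes.

    The RA decision rule is applied to the nine item columns to produce
    each episode's ``ra_positive``.  Malformed rows raise with the
    offending 1-based line number and column name.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort file {path} missing column(s): {', '.join(missing)}")

    bool_cols = RA_ITEM_COLUMNS + ("fit1", "fit2")
    parsed = {"subject_id": frame["subject_id"].astype(str)}
    for col in ("wave_index",):
        vals = []
        for i, token in enumerate(frame[col]):
            try:
                vals.append(int(token))
            except ValueError:
                raise ValueError(
                    f"line {i + 2}: column {col!r}: not an integer: {token!r}"
                ) from None
        parsed[col] = vals
    for col in bool_cols:
        parsed[col] = [
            _parse_bool(token, col, i + 2) for i, token in enumerate(frame[col])
        ]
    days = []
    for i, token in enumerate(frame["days_to_diagnosis"]):
        t = token.strip()
        if t == "" or t.lower() in ("na", "nan"):
            days.append(math.nan)
        else:
            try:
                value = float(t)
            except ValueError:
                raise ValueError(
                    f"line {i + 2}: column 'days_to_diagnosis': not a number: {token!r}"
                ) from None
            if value < 0:
                raise ValueError(
                    f"line {i + 2}: column 'days_to_diagnosis': negative lag {token!r}"
                )
            days.append(value)
    typed = pd.DataFrame(parsed)
    typed["days_to_diagnosis"] = days
    for col in bool_cols:
        typed[col] = typed[col].astype(bool)
    return episodes_from_frame(typed)


def write_cohort(frame: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a cohort frame (schema of ``simulate_cohort_frame``) to disk."""
    path = Path(path)
    out = frame.copy()
    out["days_to_diagnosis"] = out["days_to_diagnosis"].map(
        lambda v: "" if (isinstance(v, float) and math.isnan(v)) else int(v)
    )
    out.to_csv(path, sep=_sep_for(path), index=False)


def read_studies(path: Union[str, Path]) -> list[StudyRecord]:
    """Read a study table; extra columns become covariates, verbatim."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), dtype=str, keep_default_na=False)
    missing = [c for c in STUDY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"study table {path} missing column(s): {', '.join(missing)}")
    extra = [c for c in frame.columns if c not in STUDY_COLUMNS]
    records: list[StudyRecord] = []
    seen: set[str] = set()
    for i, row in frame.iterrows():
        sid = str(row["study_id"])
        if sid in seen:
            raise ValueError(f"line {i + 2}: duplicate study_id {sid!r}")
        seen.add(sid)
        cells = {}
        for col in ("tp", "fp", "fn", "tn"):
            try:
                cells[col] = int(row[col])
            except ValueError:
                raise ValueError(
                    f"line {i + 2}: column {col!r}: not an integer: {row[col]!r}"
                ) from None
            if cells[col] < 0:
                raise ValueError(f"line {i + 2}: column {col!r}: negative count")
        records.append(
            StudyRecord(
                study_id=sid,
                covariates={c: str(row[c]) for c in extra},
                **cells,
            )
        )
    return records


def write_studies(records: Sequence[StudyRecord], path: Union[str, Path]) -> None:
    path = Path(path)
    extra = sorted({k for r in records for k in r.covariates})
    rows = []
    for r in records:
        row = {"study_id": r.study_id, "tp": r.tp, "fp": r.fp, "fn": r.fn, "tn": r.tn}
        for c in extra:
            row[c] = r.covariates.get(c, "")
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False)


_REPORT_COLUMNS = (
    "strategy",
    "positives",
    "sensitivity",
    "specificity",
    "lr_pos",
    "lr_neg",
    "detection_rate",
    "ppv",
)


def accuracy_report_rows(
    results: Mapping[Strategy, tuple[int, AccuracyResult]],
) -> list[dict]:
    """Rows mirroring the programme's accuracy-table layout.

    ``results`` maps strategy -> (number of positives, AccuracyResult).
    Proportions, LRs and rates are rounded half-up to 2 decimals; PPV is
    reported as a percentage.
    """
    rows = []
    for strategy in Strategy:
        if strategy not in results:
            continue
        positives, res = results[strategy]
        rows.append(
            {
                "strategy": strategy.value,
                "positives": positives,
                "sensitivity": round_half_up(res.sensitivity, 2),
                "specificity": round_half_up(res.specificity, 2),
                "lr_pos": round_half_up(res.lr_pos, 2),
                "lr_neg": round_half_up(res.lr_neg, 2),
                "detection_rate": round_half_up(res.detection_rate, 2),
                "ppv": round_half_up(100.0 * res.ppv, 2),
            }
        )
    return rows


def write_report(rows, path: Union[str, Path], format: str = "json") -> None:
    """Serialise report rows deterministically as JSON or TSV."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(rows, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        if rows and set(rows[0]) == set(_REPORT_COLUMNS):
            frame = pd.DataFrame(rows, columns=list(_REPORT_COLUMNS))
        else:
            frame = pd.DataFrame(rows)
        frame.to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
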