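"""Reading, writing and validating behavioural trial tables.

A trial table holds one row per trial of a masked-Gabor orientation
discrimination session.  Each trial carries the prospective decision made
before the stimulus (belief of success, or decision to engage attention),
the stimulus and orientation response, correctness, and the two
retrospective ratings: visual awareness and response confidence.  All
ratings are binary.

The canonical CSV schema (exact header order) is::

    subject,experiment,block,trial,prospective,stimulus,response,correct,awareness,confidence

Binary columns accept ``0/1`` as well as the string dialects ``low/high``
(prospective, confidence) and ``unaware/aware`` (awareness); stimulus and
response are ``left``/``right``.  Anything else is rejected rather than
guessed at.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .exceptions import TrialParseError

SCHEMA = [
    "subject",
    "experiment",
    "block",
    "trial",
    "prospective",
    "stimulus",
    "response",
    "correct",
    "awareness",
    "confidence",
]

EXPERIMENTS = ("belief", "attention")

_BINARY_COLUMNS = ("prospective", "correct", "awareness", "confidence")

# accepted string dialects for binary columns, lower-cased
_BINARY_DIALECT = {
    "0": 0,
    "1": 1,
    "low": 0,
    "high": 1,
    "unaware": 0,
    "aware": 1,
}

_SIDE_DIALECT = {"left": "left", "right": "right", "l": "left", "r": "right"}


def _coerce_binary(series: pd.Series, column: str) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().map(_BINARY_DIALECT)
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise TrialParseError(
            f"column '{column}', row {row}: value {series.loc[row]!r} is not "
            f"binary (accepted: 0/1, low/high, unaware/aware)"
        )
    return out.astype(np.int64)


def _coerce_side(series: pd.Series, column: str) -> pd.Series:
    out = series.astype(str).str.strip().str.lower().map(_SIDE_DIALECT)
    if out.isna().any():
        row = int(out.index[out.isna()][0])
        raise TrialParseError(
            f"column '{column}', row {row}: value {series.loc[row]!r} is not "
            f"'left' or 'right'"
        )
    return out


class TrialTable:
    """An ordered, validated multi-subject table of behavioural trials.

    Parameters
    ----------
    data
        DataFrame with the canonical schema columns.  Rows are sorted by
        (subject, block, trial) on construction and every invariant is
        checked: binary coding, a single experiment label, unique and
        contiguous (block, trial) pairs per subject, and consistency of
        ``correct`` with ``response == stimulus``.
    """

    def __init__(self, data: pd.DataFrame):
        self.data = self._validate(data)

    # -- construction -----------------------------------------------------

    @staticmethod
    def _validate(df: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in SCHEMA if c not in df.columns]
        if missing:
            raise TrialParseError(f"missing column(s): {', '.join(missing)}")
        df = df.loc[:, SCHEMA].copy().reset_index(drop=True)

        for col in _BINARY_COLUMNS:
            df[col] = _coerce_binary(df[col], col)
        for col in ("stimulus", "response"):
            df[col] = _coerce_side(df[col], col)
        df["subject"] = df["subject"].astype(str)
        df["experiment"] = df["experiment"].astype(str)
        for col in ("block", "trial"):
            try:
                df[col] = df[col].astype(np.int64)
            except (TypeError, ValueError) as err:
                raise TrialParseError(f"column '{col}' is not integer: {err}") from None

        labels = df["experiment"].unique()
        if len(labels) > 1:
            raise TrialParseError(
                f"a table must carry a single experiment label, found {sorted(labels)}"
            )
        if len(labels) == 1 and labels[0] not in EXPERIMENTS:
            raise TrialParseError(
                f"unknown experiment label {labels[0]!r}; expected one of {EXPERIMENTS}"
            )

        bad = df.index[df["correct"] != (df["response"] == df["stimulus"]).astype(int)]
        if len(bad):
            raise TrialParseError(
                f"row {int(bad[0])}: 'correct' contradicts response == stimulus"
            )

        df = df.sort_values(["subject", "block", "trial"], kind="stable").reset_index(
            drop=True
        )
        dup = df.duplicated(["subject", "block", "trial"])
        if dup.any():
            raise TrialParseError(
                f"duplicate (subject, block, trial) at row {int(df.index[dup][0])}"
            )
        # contiguity within subject: trials 1..n within each block, blocks ascending
        for subject, g in df.groupby("subject", sort=False):
            for block, gb in g.groupby("block", sort=False):
                trials = gb["trial"].to_numpy()
                if not np.array_equal(trials, np.arange(1, len(trials) + 1)):
                    raise TrialParseError(
                        f"subject {subject}, block {block}: trial indices are not "
                        f"contiguous from 1"
                    )
        return df

    # -- basic protocol ---------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, TrialTable):
            return NotImplemented
        return self.data.equals(other.data)

    def __repr__(self) -> str:
        return (
            f"TrialTable({len(self)} trials, {len(self.subjects)} subjects, "
            f"experiment={self.experiment!r})"
        )

    # -- accessors --------------------------------------------------------

    @property
    def experiment(self) -> str | None:
        labels = self.data["experiment"].unique()
        return str(labels[0]) if len(labels) else None

    @property
    def subjects(self) -> list[str]:
        return list(dict.fromkeys(self.data["subject"]))

    def subject(self, subject_id: str) -> pd.DataFrame:
        """Rows for one subject, in session order."""
        out = self.data[self.data["subject"] == str(subject_id)]
        if out.empty:
            raise KeyError(f"no such subject: {subject_id}")
        return out.reset_index(drop=True)

    def select_subjects(self, subject_ids: Iterable[str]) -> "TrialTable":
        keep = set(map(str, subject_ids))
        return TrialTable(self.data[self.data["subject"].isin(keep)])


def read_trials(path: str | Path) -> TrialTable:
    """Read and validate a trial CSV (see module docstring for the schema)."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except FileNotFoundError:
        raise
    except Exception as err:  # malformed CSV
        raise TrialParseError(f"{path}: {err}") from err
    return TrialTable(df)


def write_trials(table: TrialTable, path: str | Path) -> None:
    """Write a trial table as canonical CSV; round-trips through read_trials."""
    table.data.to_csv(path, index=False, columns=SCHEMA)


@dataclass
class SubjectReport:
    """Exclusion screening outcome for a single subject."""

    subject: str
    empty_cells: int
    p_aware: float
    retained: bool


@dataclass
class ExclusionReport:
    """Participant-screening report for a whole table."""

    subjects: dict[str, SubjectReport] = field(default_factory=dict)

    @property
    def retained(self) -> list[str]:
        return [s for s, r in self.subjects.items() if r.retained]

    @property
    def excluded(self) -> list[str]:
        return [s for s, r in self.subjects.items() if not r.retained]

    def to_dict(self) -> dict:
        return {
            s: {
                "empty_cells": r.empty_cells,
                "p_aware": r.p_aware,
                "retained": r.retained,
            }
            for s, r in self.subjects.items()
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def validate_subjects(
    table: TrialTable,
    p_aware_floor: float = 0.05,
    max_empty_cells: int = 0,
) -> tuple[TrialTable, ExclusionReport]:
    """Apply participant-level exclusion screening.

    A subject is flagged when (a) any cell of the awareness x confidence
    2x2 grid is empty over the whole session (participants who never use
    part of the rating scale cannot be analysed in the full design), or
    (b) the proportion of aware trials falls below ``p_aware_floor``
    (default 0.05, below which the aware cells are too sparse to estimate
    anything).

    Returns the retained-subject table together with a machine-readable
    report covering every subject.  Screening is idempotent: validating a
    retained table flags nobody.
    """
    report = ExclusionReport()
    for subject in table.subjects:
        g = table.subject(subject)
        cells = (
            g.groupby(["awareness", "confidence"]).size()
            .reindex(pd.MultiIndex.from_product([[0, 1], [0, 1]]), fill_value=0)
        )
        empty = int((cells == 0).sum())
        p_aware = float(g["awareness"].mean())
        retained = empty <= max_empty_cells and p_aware >= p_aware_floor
        report.subjects[subject] = SubjectReport(subject, empty, p_aware, retained)
    kept = table.select_subjects(report.retained)
    return kept, report
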