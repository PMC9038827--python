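"""Trial-level data model, file I/O and filtering rules.

A picture-word-interference (PWI) experiment yields one row per naming
trial: a participant names a pictured object while ignoring a distractor
word that is either semantically *related* or *unrelated* to the picture.
The canonical delimited-text format has a header row with columns
``study,participant,item,condition,rt,correct``; ``condition`` takes the
literal values ``related``/``unrelated`` and ``rt`` is the naming latency
in milliseconds.

Filtering follows the standard pipeline for this task: keep correct
responses only, then drop any participant (or item) with too few correct
trials in either condition to form quintiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from pwimeta.errors import FormatError, ParseError

logger = logging.getLogger(__name__)

CONDITIONS = ("related", "unrelated")

#: canonical column names of the trial-table text format
CANONICAL_COLUMNS = ("study", "participant", "item", "condition", "rt", "correct")

_TRUE_STRINGS = {"1", "true", "t", "yes", "y"}
_FALSE_STRINGS = {"0", "false", "f", "no", "n"}


@dataclass(frozen=True)
class TrialTable:
    """An ordered collection of naming trials plus provenance metadata.

    The backing store is a :class:`pandas.DataFrame` with the canonical
    columns; ``correct`` may be absent if the source file carried no
    correctness flag.
    """

    data: pd.DataFrame
    source: str | None = None
    filters: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.data)

    @property
    def has_correct(self) -> bool:
        return "correct" in self.data.columns

    def with_filter(self, data: pd.DataFrame, label: str) -> "TrialTable":
        return replace(self, data=data, filters=self.filters + (label,))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, source: str | None = None) -> "TrialTable":
        missing = [c for c in ("study", "participant", "item", "condition", "rt") if c not in frame.columns]
        if missing:
            raise FormatError(f"trial frame is missing required column(s): {', '.join(missing)}")
        bad = set(frame["condition"].unique()) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition label(s): {sorted(bad)}")
        if (frame["rt"] <= 0).any():
            raise ValueError("reaction times must be positive")
        return cls(data=frame.reset_index(drop=True), source=source)


@dataclass(frozen=True)
class ExclusionReport:
    """Units removed for having too few correct trials in a condition.

    One row per excluded unit: ``(unit_id, unit_kind, n_related,
    n_unrelated, reason)``.
    """

    rows: tuple[tuple[str, str, int, int, str], ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.rows),
            columns=["unit_id", "unit_kind", "n_related", "n_unrelated", "reason"],
        )

    def write(self, path: str | Path, sep: str = ",") -> None:
        frame = self.to_frame()[["unit_kind", "unit_id", "n_related", "n_unrelated", "reason"]]
        frame.to_csv(path, sep=sep, index=False)


def read_trials(
    path: str | Path,
    sep: str = ",",
    columns: Mapping[str, str] | None = None,
) -> TrialTable:
    """Read a delimited trial table.

    Parameters
    ----------
    path
        Delimited text file with a header row.
    sep
        Field delimiter (comma by default).
    columns
        Optional mapping from canonical names (``study``, ``participant``,
        ``item``, ``condition``, ``rt``, ``correct``) to the column names
        used in the file.

    Raises
    ------
    FormatError
        A required column is absent (``correct`` is optional).
    ParseError
        A reaction time cannot be parsed as a number; the message cites
        the 1-based data row.
    ValueError
        A condition label is not ``related``/``unrelated``.
    """
    path = Path(path)
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    rename = {v: k for k, v in (columns or {}).items()}
    raw = raw.rename(columns=rename)

    required = ("study", "participant", "item", "condition", "rt")
    missing = [c for c in required if c not in raw.columns]
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(missing)}"
        )

    rt = pd.to_numeric(raw["rt"], errors="coerce")
    if rt.isna().any():
        row = int(np.flatnonzero(rt.isna().to_numpy())[0]) + 1
        raise ParseError(
            f"{path.name}: non-numeric rt {raw['rt'].iloc[row - 1]!r} on data row {row}"
        )

    condition = raw["condition"].str.strip().str.lower()
    bad = set(condition.unique()) - set(CONDITIONS)
    if bad:
        raise ValueError(f"{path.name}: unknown condition label(s): {sorted(bad)}")

    frame = pd.DataFrame(
        {
            "study": raw["study"],
            "participant": raw["participant"],
            "item": raw["item"],
            "condition": condition,
            "rt": rt.astype(float),
        }
    )
    if (frame["rt"] <= 0).any():
        row = int(np.flatnonzero((frame["rt"] <= 0).to_numpy())[0]) + 1
        raise ValueError(f"{path.name}: non-positive rt on data row {row}")

    if "correct" in raw.columns:
        flags = raw["correct"].str.strip().str.lower()
        unknown = set(flags.unique()) - _TRUE_STRINGS - _FALSE_STRINGS
        if unknown:
            raise ValueError(f"{path.name}: unparseable correct flag(s): {sorted(unknown)}")
        frame["correct"] = flags.isin(_TRUE_STRINGS)

    return TrialTable(data=frame, source=str(path))


def write_trials(table: TrialTable, path: str | Path, sep: str = ",") -> None:
    """Write a trial table in the canonical text format (round-trips with
    :func:`read_trials`)."""
    frame = table.data.copy()
    if "correct" in frame.columns:
        frame["correct"] = frame["correct"].map({True: "1", False: "0"})
    frame.to_csv(path, sep=sep, index=False)


def filter_correct(table: TrialTable) -> TrialTable:
    """Keep correct responses only.

    Raises :class:`~pwimeta.errors.FormatError` if the table has no
    correctness flag — correctness is never assumed. An all-incorrect
    table yields an empty result with a logged warning, not an error.
    """
    if not table.has_correct:
        raise FormatError("trial table has no 'correct' column; cannot filter")
    kept = table.data[table.data["correct"]].reset_index(drop=True)
    if len(kept) == 0 and len(table) > 0:
        logger.warning("filter_correct: no correct responses remain")
    return table.with_filter(kept, "correct_only")


def trim_rt(table: TrialTable, lo: float, hi: float) -> TrialTable:
    """Keep trials with ``lo <= rt <= hi`` (an optional analysis window;
    no trimming is applied unless requested)."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    kept = table.data[table.data["rt"].between(lo, hi)].reset_index(drop=True)
    return table.with_filter(kept, f"rt_window[{lo:g},{hi:g}]")


def _unit_column(unit_kind: str) -> str:
    if unit_kind not in ("participant", "item"):
        raise ValueError(f"unit_kind must be 'participant' or 'item', got {unit_kind!r}")
    return unit_kind


def condition_counts(table: TrialTable, unit_kind: str) -> pd.DataFrame:
    """Per-unit trial counts in each condition (columns ``related``,
    ``unrelated``), with absent cells as 0."""
    col = _unit_column(unit_kind)
    counts = (
        table.data.groupby([col, "condition"], sort=False, observed=True)
        .size()
        .unstack("condition", fill_value=0)
    )
    for cond in CONDITIONS:
        if cond not in counts.columns:
            counts[cond] = 0
    return counts[list(CONDITIONS)]


def exclude_sparse_units(
    table: TrialTable,
    unit_kind: str = "participant",
    min_per_condition: int = 5,
) -> tuple[TrialTable, ExclusionReport]:
    """Remove units with fewer than ``min_per_condition`` trials in either
    condition (the minimum needed to form quintiles is one trial per bin).

    Expects a table already restricted to correct responses. Returns the
    reduced table and a report listing every removed unit with its
    per-condition counts.
    """
    if min_per_condition < 1:
        raise ValueError("min_per_condition must be >= 1")
    col = _unit_column(unit_kind)
    counts = condition_counts(table, unit_kind)
    sparse = counts[(counts["related"] < min_per_condition) | (counts["unrelated"] < min_per_condition)]

    rows = []
    for unit_id, row in sparse.iterrows():
        lacking = [c for c in CONDITIONS if row[c] < min_per_condition]
        reason = f"fewer than {min_per_condition} correct trials in: {', '.join(lacking)}"
        rows.append((str(unit_id), unit_kind, int(row["related"]), int(row["unrelated"]), reason))

    if not rows:
        return table, ExclusionReport()

    kept = table.data[~table.data[col].isin(sparse.index)].reset_index(drop=True)
    out = table.with_filter(kept, f"min_{min_per_condition}_per_condition_{unit_kind}")
    return out, ExclusionReport(rows=tuple(rows))


def split_by_study(table: TrialTable) -> dict[str, TrialTable]:
    """Split a multi-study table into per-study tables, preserving order."""
    out: dict[str, TrialTable] = {}
    for study_id, group in table.data.groupby("study", sort=False):
        out[str(study_id)] = replace(table, data=group.reset_index(drop=True))
    return out


def make_trial_frame(
    study: Sequence[str] | str,
    participant: Iterable[str],
    item: Iterable[str],
    condition: Iterable[str],
    rt: Iterable[float],
    correct: Iterable[bool] | None = None,
) -> pd.DataFrame:
    """Convenience constructor for a canonical trial frame."""
    frame = pd.DataFrame(
        {
            "participant": list(participant),
            "item": list(item),
            "condition": list(condition),
            "rt": np.asarray(list(rt), dtype=float),
        }
    )
    frame.insert(0, "study", study if isinstance(study, str) else list(study))
    if correct is not None:
        frame["correct"] = list(correct)
    return frame
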