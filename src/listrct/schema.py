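"""Participant-level trial data model and the CSV interchange format.

The pipeline's single interchange format is a flat CSV, one row per
participant, carrying arm assignment, list-group assignment, the 18
true/false knowledge item responses, the five list-experiment counts,
demographics, and a completion flag:

    participant_id, arm, list_group, k01..k18, lc1..lc5,
    age_band, gender, country, education, first_language, completed

Knowledge items are coded ``1`` (correct), ``0`` (incorrect) and ``9``
(timed out after the 30-second answer window).  The timeout code is kept
distinct in the schema — recoding it to "incorrect" is an explicit scoring
step in :mod:`listrct.knowledge`, not something done at read time.

Internally a :class:`TrialDataset` wraps a :class:`pandas.DataFrame` in
exactly this column layout, so large simulated trials never materialise
per-row Python objects; :class:`ParticipantRecord` is the validated
single-row view.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("listrct")

# ---------------------------------------------------------------------------
# Enumerations (trial arms, list groups, demographics)
# ---------------------------------------------------------------------------

#: Trial arms: do-nothing control, attention placebo control video,
#: intervention video.  Order fixed; used everywhere as the canonical order.
ARMS = ("do_nothing", "apc", "covideo")
LIST_GROUPS = ("control", "treatment")

AGE_BANDS = ("18-24", "25-34", "35-44", "45-54", "55-59")
GENDERS = ("female", "male", "other")
COUNTRIES = ("DE", "MX", "ES", "UK", "US")
EDUCATION_LEVELS = ("primary", "high_school", "bachelor_some_college", "masters_phd")
LANGUAGES = ("German", "English", "Spanish_MX", "Spanish")

#: Knowledge response codes: correct / incorrect / timed-out.
CORRECT, INCORRECT, TIMEOUT = 1, 0, 9
KNOWLEDGE_CODES = (CORRECT, INCORRECT, TIMEOUT)

N_KNOWLEDGE_ITEMS = 18
N_LIST_EXPERIMENTS = 5
CONTROL_LIST_LEN = 5   # control list: 5 neutral items
TREATMENT_LIST_LEN = 6  # treatment list: 5 neutral items + 1 sensitive item

KNOWLEDGE_COLUMNS = tuple(f"k{j:02d}" for j in range(1, N_KNOWLEDGE_ITEMS + 1))
LIST_COLUMNS = tuple(f"lc{i}" for i in range(1, N_LIST_EXPERIMENTS + 1))
DEMOGRAPHIC_COLUMNS = ("age_band", "gender", "country", "education", "first_language")

CSV_COLUMNS = (
    ("participant_id", "arm", "list_group")
    + KNOWLEDGE_COLUMNS
    + LIST_COLUMNS
    + DEMOGRAPHIC_COLUMNS
    + ("completed",)
)

_DEMOGRAPHIC_LEVELS = {
    "age_band": AGE_BANDS,
    "gender": GENDERS,
    "country": COUNTRIES,
    "education": EDUCATION_LEVELS,
    "first_language": LANGUAGES,
}


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class TrialSchemaError(ValueError):
    """The file-level column contract is violated (missing/extra columns)."""


class RecordValidationError(ValueError):
    """A row carries an out-of-range value or unknown enumeration code."""


class ContractError(ValueError):
    """An analysis operation's precondition is violated (e.g. empty cell)."""


# ---------------------------------------------------------------------------
# Records and datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParticipantRecord:
    """One trial subject.

    ``knowledge_responses`` are the 18 coded item responses (1/0/9) and
    ``list_counts`` the five item-count responses; a participant keeps one
    ``list_group`` across all five list experiments, so control-group counts
    lie in [0, 5] and treatment-group counts in [0, 6].
    """

    participant_id: str
    arm: str
    list_group: str
    knowledge_responses: tuple[int, ...]
    list_counts: tuple[int, ...]
    age_band: str
    gender: str
    country: str
    education: str
    first_language: str
    completed: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "knowledge_responses", tuple(int(v) for v in self.knowledge_responses))
        object.__setattr__(self, "list_counts", tuple(int(v) for v in self.list_counts))
        _validate_record(self)

    def as_row(self) -> dict:
        row = {"participant_id": self.participant_id, "arm": self.arm,
               "list_group": self.list_group}
        row.update(zip(KNOWLEDGE_COLUMNS, self.knowledge_responses))
        row.update(zip(LIST_COLUMNS, self.list_counts))
        for col in DEMOGRAPHIC_COLUMNS:
            row[col] = getattr(self, col)
        row["completed"] = self.completed
        return row


def _validate_record(rec: ParticipantRecord) -> None:
    if rec.arm not in ARMS:
        raise RecordValidationError(f"unknown arm {rec.arm!r}")
    if rec.list_group not in LIST_GROUPS:
        raise RecordValidationError(f"unknown list_group {rec.list_group!r}")
    if len(rec.knowledge_responses) != N_KNOWLEDGE_ITEMS:
        raise RecordValidationError(
            f"expected {N_KNOWLEDGE_ITEMS} knowledge responses, got {len(rec.knowledge_responses)}")
    if any(v not in KNOWLEDGE_CODES for v in rec.knowledge_responses):
        raise RecordValidationError("knowledge responses must be coded 1/0/9")
    if len(rec.list_counts) != N_LIST_EXPERIMENTS:
        raise RecordValidationError(
            f"expected {N_LIST_EXPERIMENTS} list counts, got {len(rec.list_counts)}")
    max_count = CONTROL_LIST_LEN if rec.list_group == "control" else TREATMENT_LIST_LEN
    for i, c in enumerate(rec.list_counts, start=1):
        if not 0 <= c <= max_count:
            raise RecordValidationError(
                f"list count lc{i}={c} outside [0, {max_count}] for "
                f"{rec.list_group} list")
    for colname, levels in _DEMOGRAPHIC_LEVELS.items():
        if getattr(rec, colname) not in levels:
            raise RecordValidationError(
                f"unknown {colname} code {getattr(rec, colname)!r}")
    if not isinstance(rec.completed, (bool, np.bool_)):
        raise RecordValidationError("completed must be boolean")


@dataclass
class TrialDataset:
    """A collection of participant records, stored as a validated DataFrame.

    ``provenance`` is a free-text label (e.g. generator seed) carried through
    reads and writes for reproducibility bookkeeping.
    """

    frame: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        self.frame = self.frame.reset_index(drop=True)
        _validate_frame(self.frame)

    # -- construction -------------------------------------------------------
    @classmethod
    def from_records(cls, records: Sequence[ParticipantRecord],
                     provenance: str = "") -> "TrialDataset":
        if len(records) == 0:
            frame = pd.DataFrame(columns=list(CSV_COLUMNS))
            frame = frame.astype({c: int for c in KNOWLEDGE_COLUMNS + LIST_COLUMNS})
            frame = frame.astype({"completed": bool})
            return cls(frame, provenance)
        return cls(pd.DataFrame([r.as_row() for r in records]), provenance)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.frame)

    def records(self) -> Iterator[ParticipantRecord]:
        """Yield validated per-row views (slow path; analyses use .frame)."""
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            yield ParticipantRecord(
                participant_id=d["participant_id"], arm=d["arm"],
                list_group=d["list_group"],
                knowledge_responses=tuple(d[c] for c in KNOWLEDGE_COLUMNS),
                list_counts=tuple(d[c] for c in LIST_COLUMNS),
                age_band=d["age_band"], gender=d["gender"], country=d["country"],
                education=d["education"], first_language=d["first_language"],
                completed=bool(d["completed"]))

    def cell_sizes(self) -> pd.Series:
        """Participant count per arm × list-group cell."""
        return self.frame.groupby(["arm", "list_group"], observed=True).size()

    def require_full_design(self) -> None:
        """Raise ContractError unless every arm × list cell is populated."""
        sizes = self.cell_sizes()
        for arm in ARMS:
            for lg in LIST_GROUPS:
                if (arm, lg) not in sizes.index or sizes[(arm, lg)] == 0:
                    raise ContractError(f"empty design cell: arm={arm}, list_group={lg}")


def _validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if missing:
        raise TrialSchemaError(f"missing column(s): {', '.join(missing)}")
    if extra:
        raise TrialSchemaError(f"unexpected column(s): {', '.join(extra)}")
    if len(frame) == 0:
        return
    if frame["participant_id"].duplicated().any():
        dup = frame["participant_id"][frame["participant_id"].duplicated()].iloc[0]
        raise RecordValidationError(f"duplicate participant_id {dup!r}")

    def _bad_rows(mask: pd.Series, msg: str) -> None:
        if mask.any():
            row = int(np.flatnonzero(mask.to_numpy())[0])
            raise RecordValidationError(f"row {row}: {msg} "
                                        f"(participant_id={frame['participant_id'].iloc[row]!r})")

    _bad_rows(~frame["arm"].isin(ARMS), "unknown arm code")
    _bad_rows(~frame["list_group"].isin(LIST_GROUPS), "unknown list_group code")
    for col in KNOWLEDGE_COLUMNS:
        _bad_rows(~frame[col].isin(KNOWLEDGE_CODES), f"{col} not coded 1/0/9")
    max_count = frame["list_group"].map(
        {"control": CONTROL_LIST_LEN, "treatment": TREATMENT_LIST_LEN})
    for col in LIST_COLUMNS:
        _bad_rows((frame[col] < 0) | (frame[col] > max_count),
                  f"{col} outside the valid range for the assigned list")
    for col, levels in _DEMOGRAPHIC_LEVELS.items():
        _bad_rows(~frame[col].isin(levels), f"unknown {col} code")
    if frame["completed"].dtype != bool:
        raise RecordValidationError("completed must be boolean")


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

_TRUE_CODES = {"true", "True", "TRUE", "1"}
_FALSE_CODES = {"false", "False", "FALSE", "0"}


def read_trial_csv(path: str | Path) -> TrialDataset:
    """Read a participant-level trial CSV into a validated dataset.

    Rows with ``completed=false`` are retained (analysis operations filter
    them via :func:`filter_complete`).  Schema violations raise
    :class:`TrialSchemaError`; value violations raise
    :class:`RecordValidationError` naming the offending row.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    extra = [c for c in frame.columns if c not in CSV_COLUMNS]
    if missing:
        raise TrialSchemaError(f"{path.name}: missing column(s): {', '.join(missing)}")
    if extra:
        raise TrialSchemaError(f"{path.name}: unexpected column(s): {', '.join(extra)}")
    for col in KNOWLEDGE_COLUMNS + LIST_COLUMNS:
        try:
            frame[col] = pd.to_numeric(frame[col], errors="raise").astype(int)
        except (ValueError, TypeError) as exc:
            raise RecordValidationError(f"column {col}: non-integer value ({exc})") from None
    comp = frame["completed"]
    bad = ~(comp.isin(_TRUE_CODES) | comp.isin(_FALSE_CODES))
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise RecordValidationError(f"row {row}: completed must be true/false")
    frame["completed"] = comp.isin(_TRUE_CODES)
    return TrialDataset(frame[list(CSV_COLUMNS)], provenance=f"read:{path.name}")


def write_trial_csv(dataset: TrialDataset, path: str | Path) -> Path:
    """Write a dataset to CSV with deterministic column and row order.

    Rows are sorted by ``participant_id`` so that write → read → write is
    byte-identical.
    """
    path = Path(path)
    frame = dataset.frame.sort_values("participant_id", kind="mergesort")
    frame = frame[list(CSV_COLUMNS)].copy()
    frame["completed"] = np.where(frame["completed"], "true", "false")
    frame.to_csv(path, index=False, lineterminator="\n")
    return path


def filter_complete(dataset: TrialDataset) -> TrialDataset:
    """Complete-case filter: keep only participants who finished the survey.

    The number of dropped records is reported through the package logger,
    mirroring a trial flow diagram's attrition accounting.
    """
    keep = dataset.frame["completed"]
    n_dropped = int((~keep).sum())
    logger.info("filter_complete: %d enrolled, %d lost, %d analysed",
                len(dataset), n_dropped, int(keep.sum()))
    return TrialDataset(dataset.frame.loc[keep].reset_index(drop=True),
                        provenance=dataset.provenance)
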