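"""Domain model of the Berg Balance Scale (BBS) battery.

The BBS is a validated clinical balance battery of 14 motor tasks, each
scored on a five-level ordinal scale from 0 (unable) to 4 (independent).
The total score (0-56) maps to a three-band fall-risk category:

* 0-20   high fall risk
* 21-40  medium fall risk
* 41-56  low fall risk

This module provides the task registry, per-subject score vectors (with a
first-class missing-score marker, since real cohorts have per-task
missingness), subset restriction, and the risk-band mapping that every
downstream component shares.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RiskCategory",
    "TaskDefinition",
    "Battery",
    "ScoreVector",
    "TaskSubset",
    "Cohort",
    "MissingScoreError",
    "STANDARD_TASK_NAMES",
    "MAX_TASK_SCORE",
    "standard_battery",
    "sfbbs_battery",
    "total_score",
    "classify_risk",
    "restrict",
]

MAX_TASK_SCORE = 4

#: Standard names of the 14 BBS tasks, indexed by the standard 1-based numbering.
STANDARD_TASK_NAMES: dict[int, str] = {
    1: "Sitting to Standing",
    2: "Standing Unsupported",
    3: "Sitting with Back Unsupported",
    4: "Standing to Sitting",
    5: "Transfers",
    6: "Standing Unsupported, Eyes Closed",
    7: "Standing Unsupported, Feet Together",
    8: "Reaching Forward",
    9: "Pick up Object from the Floor",
    10: "Look Behind Shoulders",
    11: "Turn 360°",
    12: "Alternate Feet on Step",
    13: "Standing Unsupported, One Foot in Front",
    14: "Standing on One Leg",
}

#: A task subset is simply a frozenset of standard task ids.
TaskSubset = frozenset


class MissingScoreError(KeyError):
    """Raised when an operation requires scores that a vector lacks."""

    def __init__(self, subject_id: str, missing: Iterable[int]):
        self.subject_id = subject_id
        self.missing = tuple(sorted(missing))
        super().__init__(
            f"subject {subject_id!r} is missing scores for tasks {list(self.missing)}"
        )


class RiskCategory(enum.IntEnum):
    """Three-band fall-risk category, ordinal-coded by decreasing risk."""

    HIGH = 0
    MEDIUM = 1
    LOW = 2

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "RiskCategory":
        try:
            return cls[label.strip().upper()]
        except KeyError:
            raise ValueError(
                f"unknown risk label {label!r}; expected one of high/medium/low"
            ) from None


@dataclass(frozen=True)
class TaskDefinition:
    task_id: int
    name: str
    max_score: int = MAX_TASK_SCORE

    def __post_init__(self):
        if not 1 <= self.task_id <= 14:
            raise ValueError(f"task_id must be in 1..14, got {self.task_id}")


@dataclass(frozen=True)
class Battery:
    """An ordered collection of BBS tasks (the full scale or a reduction)."""

    tasks: tuple[TaskDefinition, ...]

    def __post_init__(self):
        ids = [t.task_id for t in self.tasks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate task ids in battery: {ids}")

    @property
    def task_ids(self) -> tuple[int, ...]:
        return tuple(t.task_id for t in self.tasks)

    @property
    def id_set(self) -> TaskSubset:
        return frozenset(self.task_ids)

    def __len__(self) -> int:
        return len(self.tasks)

    @property
    def max_total(self) -> int:
        return sum(t.max_score for t in self.tasks)


def standard_battery() -> Battery:
    """The full 14-task BBS battery in standard numbering order."""
    return Battery(
        tuple(
            TaskDefinition(i, STANDARD_TASK_NAMES[i]) for i in sorted(STANDARD_TASK_NAMES)
        )
    )


def sfbbs_battery(member_ids: Iterable[int]) -> Battery:
    """Short-form comparator battery: exactly seven of the fourteen tasks.

    The short-form membership is configuration (published reductions exist
    but the choice is the caller's); only the cardinality is enforced here.
    """
    ids = sorted(set(member_ids))
    if len(ids) != 7:
        raise ValueError(f"short-form battery requires exactly 7 distinct tasks, got {len(ids)}")
    unknown = [i for i in ids if i not in STANDARD_TASK_NAMES]
    if unknown:
        raise ValueError(f"unknown BBS task ids: {unknown}")
    return Battery(tuple(TaskDefinition(i, STANDARD_TASK_NAMES[i]) for i in ids))


@dataclass(frozen=True)
class ScoreVector:
    """Per-subject BBS scores; tasks absent from ``scores`` are missing.

    Missingness is first-class: unperformed or unrecorded tasks simply do
    not appear in the mapping, and operations that need them raise
    :class:`MissingScoreError` naming the offending task ids.
    """

    subject_id: str
    scores: Mapping[int, int]

    def __post_init__(self):
        clean = {}
        for tid, s in self.scores.items():
            tid = int(tid)
            if not 1 <= tid <= 14:
                raise ValueError(f"task id {tid} outside 1..14")
            if isinstance(s, float):
                if math.isnan(s):
                    continue  # NaN doubles as the missing marker
                if not float(s).is_integer():
                    raise ValueError(f"task {tid}: score {s!r} is not an integer")
                s = int(s)
            if not isinstance(s, (int, np.integer)):
                raise ValueError(f"task {tid}: score {s!r} is not an integer")
            if not 0 <= s <= MAX_TASK_SCORE:
                raise ValueError(f"task {tid}: score {s} outside 0..{MAX_TASK_SCORE}")
            clean[tid] = int(s)
        object.__setattr__(self, "scores", clean)

    def present(self) -> TaskSubset:
        return frozenset(self.scores)

    def is_missing(self, task_id: int) -> bool:
        return task_id not in self.scores

    def values_for(self, subset: Iterable[int]) -> np.ndarray:
        """Scores for ``subset`` in ascending task-id order (feature order)."""
        ids = sorted(subset)
        missing = [t for t in ids if t not in self.scores]
        if missing:
            raise MissingScoreError(self.subject_id, missing)
        return np.array([self.scores[t] for t in ids], dtype=float)


def total_score(v: ScoreVector, battery: Battery | None = None) -> int:
    """Sum of all task scores in the battery; errors if any is missing."""
    battery = battery or standard_battery()
    missing = [t for t in battery.task_ids if v.is_missing(t)]
    if missing:
        raise MissingScoreError(v.subject_id, missing)
    return sum(v.scores[t] for t in battery.task_ids)


def classify_risk(total: int) -> RiskCategory:
    """Map a BBS total (0-56) to its fall-risk band."""
    if isinstance(total, float):
        if not total.is_integer():
            raise ValueError(f"total score must be an integer, got {total}")
        total = int(total)
    if not 0 <= total <= 56:
        raise ValueError(f"total score {total} outside 0..56")
    if total <= 20:
        return RiskCategory.HIGH
    if total <= 40:
        return RiskCategory.MEDIUM
    return RiskCategory.LOW


def restrict(v: ScoreVector, subset: Iterable[int]) -> ScoreVector:
    """Project a score vector onto a task subset (values unchanged)."""
    ids = sorted(subset)
    missing = [t for t in ids if t not in v.scores]
    if missing:
        raise MissingScoreError(v.subject_id, missing)
    return ScoreVector(v.subject_id, {t: v.scores[t] for t in ids})


@dataclass
class Cohort:
    """Tabular cohort of score vectors with (optional) risk labels.

    ``scores`` is a DataFrame whose columns are the battery task ids and
    whose values are float scores with NaN as the missing marker; ``labels``
    holds ordinal risk codes (high=0, medium=1, low=2) aligned with the rows,
    or None when the cohort is unlabeled.
    """

    scores: pd.DataFrame
    labels: np.ndarray | None = None
    battery: Battery = field(default_factory=standard_battery)

    def __post_init__(self):
        want = list(self.battery.task_ids)
        got = [int(c) for c in self.scores.columns]
        if got != want:
            raise ValueError(f"score columns {got} do not match battery tasks {want}")
        self.scores = self.scores.astype(float)
        self.scores.columns = want
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.scores):
                raise ValueError("labels length does not match number of subjects")

    def __len__(self) -> int:
        return len(self.scores)

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.scores.index]

    def vector(self, i: int) -> ScoreVector:
        row = self.scores.iloc[i]
        return ScoreVector(str(self.scores.index[i]), {t: row[t] for t in self.scores.columns if not math.isnan(row[t])})

    def vectors(self) -> list[ScoreVector]:
        return [self.vector(i) for i in range(len(self))]

    def complete_mask(self, subset: Iterable[int] | None = None) -> np.ndarray:
        """Boolean mask of subjects with no missing score on ``subset``."""
        cols = sorted(subset) if subset is not None else list(self.scores.columns)
        if not cols:
            return np.ones(len(self), dtype=bool)
        return ~self.scores[cols].isna().any(axis=1).to_numpy()

    def subset_matrix(self, subset: Iterable[int]) -> tuple[np.ndarray, np.ndarray]:
        """(mask, X) where X holds scores on ``subset`` for complete subjects."""
        cols = sorted(subset)
        mask = self.complete_mask(cols)
        X = self.scores.loc[mask, cols].to_numpy(dtype=float)
        return mask, X

    def select(self, index: np.ndarray) -> "Cohort":
        """Row-subset cohort (boolean mask or integer positions)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return Cohort(
            self.scores.iloc[index].copy(),
            None if self.labels is None else self.labels[index].copy(),
            self.battery,
        )

    def fingerprint(self) -> str:
        """Stable digest of scores+labels, used to assert fold hygiene."""
        import hashlib

        h = hashlib.sha256()
        h.update(self.scores.fillna(-1.0).to_numpy().tobytes())
        if self.labels is not None:
            h.update(self.labels.tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_vectors(
        cls,
        vectors: Iterable[ScoreVector],
        labels: Iterable[RiskCategory | int] | None = None,
        battery: Battery | None = None,
    ) -> "Cohort":
        battery = battery or standard_battery()
        vectors = list(vectors)
        data = {
            t: [v.scores.get(t, np.nan) for v in vectors] for t in battery.task_ids
        }
        df = pd.DataFrame(data, index=[v.subject_id for v in vectors], dtype=float)
        lab = None if labels is None else np.array([int(l) for l in labels])
        return cls(df, lab, battery)
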