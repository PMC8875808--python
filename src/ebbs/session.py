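"""Adaptive administration of a shortened BBS session.

A session starts from a small initial subset of tasks, predicts the risk
category with its vote-share confidence after every administered task, and
stops as soon as the confidence reaches the threshold (or the battery is
exhausted).  Subjects' scores are read strictly on demand — the engine
never consults a score for a task it has not "administered", preserving
the clinical semantics of a simulated test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

from .battery import (
    Battery,
    MissingScoreError,
    RiskCategory,
    ScoreVector,
    TaskSubset,
)
from .bank import PredictorBank
from .selectors import SelectorConfig, select_next_task

__all__ = [
    "SessionConfig",
    "SessionStep",
    "SessionTrace",
    "TaskUnavailableError",
    "run_session",
    "fixed_order_session",
]


@dataclass(frozen=True)
class SessionConfig:
    initial_subset: TaskSubset
    selector: SelectorConfig = field(default_factory=SelectorConfig)
    max_tasks: int | None = None  # None -> battery size
    stop_rule: Literal["geq", "gt"] = "geq"

    def __post_init__(self):
        object.__setattr__(self, "initial_subset", frozenset(self.initial_subset))
        if not self.initial_subset:
            raise ValueError("initial_subset must be non-empty")
        if self.stop_rule not in ("geq", "gt"):
            raise ValueError(f"unknown stop_rule {self.stop_rule!r}")


@dataclass(frozen=True)
class SessionStep:
    """One prediction point: the task just added (None for the initial
    subset), the cumulative subset, and the prediction with confidence."""

    added_task: int | None
    subset: TaskSubset
    prediction: RiskCategory
    confidence: float


@dataclass
class SessionTrace:
    subject_id: str
    initial_subset: TaskSubset
    steps: list[SessionStep]
    stop_reason: Literal["confidence_reached", "tasks_exhausted"]

    @property
    def final_prediction(self) -> RiskCategory:
        return self.steps[-1].prediction

    @property
    def final_confidence(self) -> float:
        return self.steps[-1].confidence

    @property
    def n_tasks_used(self) -> int:
        return len(self.steps[-1].subset)

    @property
    def task_sequence(self) -> list[int]:
        """Administered tasks in order; initial tasks in ascending id order."""
        seq = sorted(self.initial_subset)
        seq += [s.added_task for s in self.steps if s.added_task is not None]
        return seq


class TaskUnavailableError(MissingScoreError):
    """The session requested a task the subject has no score for; carries
    the partial trace accumulated so far."""

    def __init__(self, subject_id: str, missing: Iterable[int], partial: SessionTrace | None):
        super().__init__(subject_id, missing)
        self.partial_trace = partial


def _stop(conf: float, ct: float, rule: str) -> bool:
    return conf >= ct if rule == "geq" else conf > ct


def _administer(subject: ScoreVector, subset: TaskSubset, trace: SessionTrace | None):
    missing = [t for t in sorted(subset) if subject.is_missing(t)]
    if missing:
        raise TaskUnavailableError(subject.subject_id, missing, trace)


def run_session(
    subject: ScoreVector,
    bank: PredictorBank,
    cfg: SessionConfig,
) -> SessionTrace:
    """Run one adaptive session for a subject against a trained bank."""
    battery: Battery = bank.battery
    max_tasks = cfg.max_tasks or len(battery)
    if max_tasks > len(battery):
        raise ValueError("max_tasks exceeds battery size")
    if not cfg.initial_subset <= battery.id_set:
        raise ValueError("initial subset contains tasks outside the battery")
    ct = cfg.selector.confidence_threshold

    css = frozenset(cfg.initial_subset)
    _administer(subject, css, None)
    pred, conf = bank.predict(css, subject)
    steps = [SessionStep(None, css, pred, conf)]
    trace = SessionTrace(subject.subject_id, frozenset(cfg.initial_subset), steps, "tasks_exhausted")

    while not _stop(conf, ct, cfg.stop_rule):
        ut = battery.id_set - css
        if not ut or len(css) >= max_tasks:
            trace.stop_reason = "tasks_exhausted"
            return trace
        nt = select_next_task(cfg.selector, css, ut, bank, patient=subject)
        _administer(subject, frozenset({nt}), trace)
        css = css | {nt}
        pred, conf = bank.predict(css, subject)
        steps.append(SessionStep(nt, css, pred, conf))

    trace.stop_reason = "confidence_reached"
    return trace


def fixed_order_session(
    subject: ScoreVector,
    bank: PredictorBank,
    order: Sequence[int],
    ct: float,
    stop_rule: Literal["geq", "gt"] = "geq",
) -> SessionTrace:
    """Administer tasks in a constant order with the same stopping rule.

    Used for the standard battery order and for replaying the constant
    orders that the patient-independent selector methods produce.
    """
    battery = bank.battery
    if sorted(order) != sorted(battery.task_ids):
        raise ValueError("order must be a permutation of the battery tasks")
    first = frozenset({order[0]})
    _administer(subject, first, None)
    css = first
    pred, conf = bank.predict(css, subject)
    steps = [SessionStep(None, css, pred, conf)]
    trace = SessionTrace(subject.subject_id, first, steps, "tasks_exhausted")
    for nt in order[1:]:
        if _stop(conf, ct, stop_rule):
            trace.stop_reason = "confidence_reached"
            return trace
        _administer(subject, frozenset({nt}), trace)
        css = css | {nt}
        pred, conf = bank.predict(css, subject)
        steps.append(SessionStep(nt, css, pred, conf))
    if _stop(conf, ct, stop_rule):
        trace.stop_reason = "confidence_reached"
    return trace
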