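"""Greedy next-task selection for adaptive BBS administration.

Four selector methods choose which task to administer next, given the
current administered subset CSS, the unused tasks UT, a trained predictor
bank, and (for the adaptive methods) the patient's scores so far.  All four
maximise a weighted count of correct training-set predictions for the
augmented subset CSS + {T}:

* Method 1: plain count — I(Pred(CSS+{T}, x_i) = y_i).
* Method 2: restricted to undecided training subjects, i.e. those whose
  CSS-predictor confidence is still below the threshold CT (strict <).
* Method 3: additionally weights subject i by its similarity to the
  patient's scores on CSS, d(x_i, x_p) = exp(-||x_i - x_p||^2 / sigma^2).
* Method 4: additionally keeps only subjects the all-tasks predictor
  classifies correctly (y_i = yhat_i).

Methods 1-2 are patient-independent and induce one constant task order for
all subjects; Methods 3-4 adapt the order to the patient being tested.
Ties are broken toward the lowest standard task number.  If the weights
annihilate every candidate's objective, the selector falls back to the
Method-1 objective and logs the event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .battery import ScoreVector, TaskSubset
from .bank import PredictorBank

logger = logging.getLogger(__name__)

__all__ = ["SelectorConfig", "similarity", "auto_sigma2", "select_next_task"]

SIGMA2_FLOOR = 1e-6


@dataclass(frozen=True)
class SelectorConfig:
    method: int = 3
    confidence_threshold: float = 0.96
    sigma2: float | str = "auto"

    def __post_init__(self):
        if self.method not in (1, 2, 3, 4):
            raise ValueError(f"selector method must be 1..4, got {self.method}")
        if not 0 < self.confidence_threshold <= 1:
            raise ValueError("confidence_threshold must be in (0, 1]")
        if self.sigma2 != "auto" and not (
            isinstance(self.sigma2, (int, float)) and self.sigma2 > 0
        ):
            raise ValueError("sigma2 must be positive or 'auto'")


def similarity(
    vi: ScoreVector, vp: ScoreVector, css: Iterable[int], sigma2: float
) -> float:
    """Gaussian similarity of two score vectors restricted to ``css``."""
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    a = vi.values_for(css)
    b = vp.values_for(css)
    return float(np.exp(-np.sum((a - b) ** 2) / sigma2))


def auto_sigma2(X: np.ndarray) -> float:
    """Median pairwise squared distance of training restrictions (floored).

    A scale-free bandwidth choice: with the median heuristic roughly half
    the training set sits at weight >= exp(-1) from any typical point.
    """
    n = len(X)
    if n < 2:
        return 1.0
    sq = np.sum((X[:, None, :] - X[None, :, :]) ** 2, axis=-1)
    vals = sq[np.triu_indices(n, k=1)]
    return max(float(np.median(vals)), SIGMA2_FLOOR)


def _patient_weights(
    bank: PredictorBank, css: TaskSubset, patient: ScoreVector, sigma2: float | str
) -> np.ndarray:
    """Similarity weight of every training subject to the patient on css."""
    mask, X = bank.cohort.subset_matrix(css)
    if sigma2 == "auto":
        sigma2 = auto_sigma2(X)
    xp = patient.values_for(css)
    w = np.zeros(len(bank.cohort))
    w[mask] = np.exp(-np.sum((X - xp[None, :]) ** 2, axis=1) / sigma2)
    return w


def _objectives(
    method: int,
    css: TaskSubset,
    candidates: list[int],
    bank: PredictorBank,
    ct: float,
    patient: ScoreVector | None,
    sigma2: float | str,
) -> np.ndarray:
    labels = bank.cohort.labels
    base = np.zeros(len(bank.cohort))

    weights = np.ones(len(bank.cohort))
    if method >= 2:
        _, _, confs = bank.training_predictions(css)
        below = np.zeros(len(confs))
        ok = ~np.isnan(confs)
        below[ok] = (confs[ok] < ct).astype(float)
        weights *= below
    if method >= 3:
        weights *= _patient_weights(bank, css, patient, sigma2)
    if method == 4:
        mask_at, preds_at, _ = bank.training_predictions(bank.all_tasks)
        weights *= ((preds_at == labels) & mask_at).astype(float)

    out = np.empty(len(candidates))
    for j, t in enumerate(candidates):
        ss = css | {t}
        mask, preds, _ = bank.training_predictions(ss)
        correct = ((preds == labels) & mask).astype(float)
        out[j] = float(np.sum(correct * weights))
    return out


def select_next_task(
    cfg: SelectorConfig,
    css: TaskSubset,
    ut: TaskSubset,
    bank: PredictorBank,
    patient: ScoreVector | None = None,
) -> int:
    """Return the next task id from ``ut`` under the configured method.

    ``patient`` is required for the adaptive methods (3 and 4).  The
    returned task maximises the method's weighted correct-prediction sum
    over the training cohort; ties go to the lowest task number.
    """
    css = frozenset(css)
    ut = frozenset(ut)
    if not ut:
        raise ValueError("no candidate tasks: UT is empty")
    if css & ut:
        raise ValueError(f"UT and CSS overlap: {sorted(css & ut)}")
    if cfg.method >= 3 and patient is None:
        raise ValueError(f"method {cfg.method} requires the patient's scores")
    if cfg.method >= 2 and not css:
        raise ValueError(f"method {cfg.method} requires a non-empty current subset")

    candidates = sorted(ut)
    if len(candidates) == 1:
        return candidates[0]

    obj = _objectives(
        cfg.method, css, candidates, bank, cfg.confidence_threshold, patient, cfg.sigma2
    )
    if cfg.method != 1 and not np.any(obj > 0):
        logger.warning(
            "method %d objective vanished for all candidates at css=%s; "
            "falling back to the method-1 objective",
            cfg.method,
            sorted(css),
        )
        obj = _objectives(1, css, candidates, bank, cfg.confidence_threshold, None, cfg.sigma2)

    logger.debug(
        "css=%s objectives=%s", sorted(css), dict(zip(candidates, obj.round(4)))
    )
    best = int(np.argmax(obj))  # first max -> lowest task id on ties
    return candidates[best]
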