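"""Independent brute-force oracles used by the unit and acceptance tests.

These recompute the selector objectives and ensemble confidences from their
definitions — per-subject predict calls and explicit arithmetic — without
touching the vectorised paths they are checked against.
"""

import math

import numpy as np

from ebbs.battery import Cohort, ScoreVector
from ebbs.bank import PredictorBank


def brute_force_objective(
    method: int,
    css: frozenset,
    candidate: int,
    bank: PredictorBank,
    ct: float,
    patient: ScoreVector | None,
    sigma2: float,
) -> float:
    """Direct evaluation of the method's weighted correct-prediction sum."""
    cohort: Cohort = bank.cohort
    total = 0.0
    aug = css | {candidate}
    for i in range(len(cohort)):
        v = cohort.vector(i)
        if not aug <= v.present():
            continue  # subject incomplete on the augmented subset
        y = int(cohort.labels[i])
        pred, _ = bank.predict(aug, v)
        term = 1.0 if int(pred) == y else 0.0
        if method >= 2:
            _, conf_css = bank.predict(css, v)
            term *= 1.0 if conf_css < ct else 0.0
        if method >= 3:
            a = v.values_for(css)
            b = patient.values_for(css)
            term *= math.exp(-float(np.sum((a - b) ** 2)) / sigma2)
        if method == 4:
            if not bank.all_tasks <= v.present():
                term = 0.0
            else:
                yhat, _ = bank.predict(bank.all_tasks, v)
                term *= 1.0 if int(yhat) == y else 0.0
        total += term
    return total


def brute_force_next_task(
    method: int,
    css: frozenset,
    ut: frozenset,
    bank: PredictorBank,
    ct: float,
    patient: ScoreVector | None,
    sigma2: float,
) -> int:
    """Argmax of the brute-force objective; ties to the lowest task id."""
    best_t, best_val = None, -1.0
    for t in sorted(ut):
        val = brute_force_objective(method, css, t, bank, ct, patient, sigma2)
        if val > best_val:
            best_t, best_val = t, val
    return best_t


def per_tree_confidence(model, x: np.ndarray) -> tuple[int, float]:
    """Ensemble confidence recomputed tree by tree.

    Averages each tree's leaf class fractions for a single sample and takes
    the maximal class, ties toward the higher-risk (lower) code.
    """
    acc = np.zeros(3)
    for tree in model.estimators_:
        proba = tree.predict_proba(x[None, :])[0]
        for j, c in enumerate(model.classes_.astype(int)):
            acc[c] += proba[j]
    acc /= len(model.estimators_)
    pred = int(np.argmax(acc))
    return pred, float(acc[pred])
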