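"""Evaluation surface for adaptive BBS shortening.

Provides leakage-free cross-validated accuracy-vs-mean-tasks curves for
adaptive sessions, occurrence matrices summarising where each task lands in
the administered sequences, ordinal confusion/MSE and weighted P/R/F1
metrics, false-negative threshold adjustment for the full-battery
classifier, and ICC(3,1) inter-rater reliability of total scores.

Cross-validation retrains every component (predictor bank, initial-subset
choice, selector statistics) on the training split of each fold; held-out
subjects only ever meet trained artifacts.  Accuracy is pooled over the
held-out predictions of all folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .battery import Battery, Cohort, RiskCategory, TaskSubset
from .bank import (
    BankConfig,
    PredictorBank,
    optimal_initial_subset,
    train_subset_predictor,
)
from .selectors import SelectorConfig
from .session import SessionConfig, SessionTrace, run_session

__all__ = [
    "CurvePoint",
    "CrossvalResult",
    "crossval_curve",
    "subset_cv_predictions",
    "occurrence_matrix",
    "confusion_and_mse",
    "weighted_prf",
    "adjust_thresholds",
    "icc_3_1",
    "rater_table",
    "plot_curve",
]

N_CLASSES = 3


@dataclass(frozen=True)
class CurvePoint:
    confidence_threshold: float
    accuracy: float
    mean_tasks: float


@dataclass
class CrossvalResult:
    points: list[CurvePoint]
    truth: dict[float, np.ndarray]
    predicted: dict[float, np.ndarray]
    n_tasks: dict[float, np.ndarray]
    traces: dict[float, list[SessionTrace]]
    fold_fingerprints: list[tuple[str, str]]  # (train fingerprint, full fingerprint)


def _stratified_folds(labels: np.ndarray, n_folds: int, seed: int):
    counts = np.bincount(labels, minlength=N_CLASSES)
    present = counts[counts > 0]
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if (present < n_folds).any():
        raise ValueError(
            f"stratification impossible: a class has fewer members ({present.min()}) "
            f"than folds ({n_folds})"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return skf.split(np.zeros(len(labels)), labels)


def crossval_curve(
    cohort: Cohort,
    selector: SelectorConfig,
    thresholds: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
    initial_subset_size: int = 1,
    initial_subset: TaskSubset | None = None,
    bank_cfg: BankConfig | None = None,
    keep_traces: bool = True,
) -> CrossvalResult:
    """Accuracy and mean administered tasks per confidence threshold.

    Per fold, a predictor bank is trained on the training split only; the
    initial subset is either fixed or re-optimised per fold at the given
    size.  Sessions run on held-out subjects that are complete on the whole
    battery (at administration time any task can be performed; missingness
    is a training-data artifact).
    """
    if cohort.labels is None:
        raise ValueError("cohort must be labeled for cross-validation")
    bank_cfg = bank_cfg or BankConfig()
    full_fp = cohort.fingerprint()
    res = CrossvalResult([], {}, {}, {}, {}, [])
    for ct in thresholds:
        res.truth[ct] = []
        res.predicted[ct] = []
        res.n_tasks[ct] = []
        res.traces[ct] = []

    for train_idx, test_idx in _stratified_folds(cohort.labels, n_folds, seed):
        train = cohort.select(train_idx)
        res.fold_fingerprints.append((train.fingerprint(), full_fp))
        bank = PredictorBank(train, bank_cfg)
        init = initial_subset or optimal_initial_subset(bank, initial_subset_size)
        complete = cohort.complete_mask()
        for ct in thresholds:
            sel = SelectorConfig(
                method=selector.method, confidence_threshold=ct, sigma2=selector.sigma2
            )
            scfg = SessionConfig(initial_subset=init, selector=sel)
            for i in test_idx:
                if not complete[i]:
                    continue
                trace = run_session(cohort.vector(i), bank, scfg)
                res.truth[ct].append(int(cohort.labels[i]))
                res.predicted[ct].append(int(trace.final_prediction))
                res.n_tasks[ct].append(trace.n_tasks_used)
                if keep_traces:
                    res.traces[ct].append(trace)

    for ct in thresholds:
        t = np.array(res.truth[ct], dtype=int)
        p = np.array(res.predicted[ct], dtype=int)
        n = np.array(res.n_tasks[ct], dtype=float)
        res.truth[ct], res.predicted[ct], res.n_tasks[ct] = t, p, n
        res.points.append(
            CurvePoint(ct, float(np.mean(t == p)), float(np.mean(n)))
        )
    return res


def subset_cv_predictions(
    cohort: Cohort,
    subset: TaskSubset,
    n_folds: int = 5,
    seed: int = 0,
    bank_cfg: BankConfig | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated (truth, predicted) for one fixed task subset.

    This is how the short-form comparator point is computed: the subset's
    predictor is retrained per fold and evaluated on held-out subjects
    complete on the subset.
    """
    bank_cfg = bank_cfg or BankConfig()
    subset = frozenset(subset)
    mask = cohort.complete_mask(subset)
    sub = cohort.select(mask)
    truth, pred = [], []
    for train_idx, test_idx in _stratified_folds(sub.labels, n_folds, seed):
        train = sub.select(train_idx)
        sp = train_subset_predictor(train, subset, bank_cfg)
        for i in test_idx:
            cat, _ = sp.predict(sub.vector(i))
            truth.append(int(sub.labels[i]))
            pred.append(int(cat))
    return np.array(truth), np.array(pred)


def occurrence_matrix(traces: Iterable[SessionTrace], battery: Battery) -> np.ndarray:
    """Task-by-position proportion matrix over a set of session traces.

    Entry (i, j) is the fraction of traces in which battery task i was
    administered at sequence position j (0-based on both axes; rows follow
    the battery's task order).
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces given")
    ids = list(battery.task_ids)
    row = {t: r for r, t in enumerate(ids)}
    k = len(ids)
    counts = np.zeros((k, k))
    for tr in traces:
        seq = tr.task_sequence
        if not set(seq) <= set(ids):
            raise ValueError(
                f"trace for {tr.subject_id} uses tasks outside the battery: {sorted(set(seq) - set(ids))}"
            )
        for j, t in enumerate(seq):
            counts[row[t], j] += 1
    return counts / len(traces)


def confusion_and_mse(
    truth: Sequence[int], predicted: Sequence[int]
) -> tuple[np.ndarray, float]:
    """3x3 confusion matrix (rows = truth) and ordinal MSE.

    MSE is the mean squared difference of the ordinal risk codes
    (high=0, medium=1, low=2), so an adjacent-band error contributes 1 and
    a high<->low error contributes 4.
    """
    t = np.asarray([int(x) for x in truth])
    p = np.asarray([int(x) for x in predicted])
    if len(t) != len(p):
        raise ValueError("truth and predicted differ in length")
    if len(t) == 0:
        raise ValueError("empty class sequences")
    cm = _sk_confusion(t, p, labels=[0, 1, 2])
    mse = float(np.mean((t - p) ** 2))
    return cm, mse


def weighted_prf(
    truth: Sequence[int], predicted: Sequence[int]
) -> tuple[float, float, float]:
    """Support-weighted precision, recall and F1 over the three classes."""
    t = np.asarray([int(x) for x in truth])
    p = np.asarray([int(x) for x in predicted])
    if len(t) != len(p):
        raise ValueError("truth and predicted differ in length")
    prec, rec, f1, _ = precision_recall_fscore_support(
        t, p, labels=[0, 1, 2], average="weighted", zero_division=0
    )
    return float(prec), float(rec), float(f1)


def adjust_thresholds(scores: np.ndarray, tau: float) -> np.ndarray:
    """Conservative re-thresholding of per-class scores.

    Each row holds non-negative scores for (high, medium, low); rows are
    normalised to sum one.  A subject is assigned the highest-risk class
    whose normalised score reaches ``tau``; if none does, the modal class.
    Lowering ``tau`` therefore never decreases the number of high-risk
    calls, which is how false negatives are traded against false alarms.
    """
    S = np.asarray(scores, dtype=float)
    if S.ndim != 2 or S.shape[1] != N_CLASSES:
        raise ValueError(f"scores must be (n, {N_CLASSES}), got {S.shape}")
    if (S < 0).any() or not np.isfinite(S).all():
        raise ValueError("scores must be finite and non-negative")
    if not 0 <= tau <= 1:
        raise ValueError("tau must be in [0, 1]")
    sums = S.sum(axis=1)
    if (sums <= 0).any():
        raise ValueError("every score row must have positive mass")
    P = S / sums[:, None]
    out = np.argmax(P, axis=1)  # modal; ties -> higher risk
    for c in range(N_CLASSES - 1, -1, -1):  # scan low -> high so high wins
        out = np.where(P[:, c] >= tau, c, out)
    return out.astype(int)


def rater_table(
    a: Sequence[float],
    d: Sequence[float],
    ml: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Total-score table for reliability analysis.

    Columns: rater A, rater D, their per-subject minimum MIN(A,D) (the
    conservative consensus), and optionally the machine prediction.
    """
    a = np.asarray(a, dtype=float)
    d = np.asarray(d, dtype=float)
    if a.shape != d.shape:
        raise ValueError("rater columns differ in length")
    for name, col in (("A", a), ("D", d)):
        if ((col < 0) | (col > 56)).any():
            raise ValueError(f"rater {name} totals outside 0..56")
    data = {"A": a, "D": d, "MIN(A,D)": np.minimum(a, d)}
    if ml is not None:
        ml = np.asarray(ml, dtype=float)
        if ml.shape != a.shape:
            raise ValueError("ml column differs in length")
        data["ML"] = ml
    return pd.DataFrame(data)


def icc_3_1(table: pd.DataFrame | np.ndarray, pair: tuple | None = None) -> float:
    """ICC(3,1): two-way mixed model, single measure, consistency form.

    Computed from the two-way ANOVA mean squares of an n-subjects x 2-raters
    table: (MSR - MSE) / (MSR + (k-1) MSE) with k = 2.  Consistency-type:
    adding a constant offset to one rater leaves it unchanged.
    """
    if isinstance(table, pd.DataFrame):
        Y = table[list(pair)].to_numpy(dtype=float) if pair else table.to_numpy(dtype=float)
    else:
        Y = np.asarray(table, dtype=float)
        if pair is not None:
            Y = Y[:, list(pair)]
    if Y.ndim != 2 or Y.shape[1] != 2:
        raise ValueError("ICC(3,1) here compares exactly two rater columns")
    n, k = Y.shape
    if n < 2:
        raise ValueError("need at least two subjects")
    grand = Y.mean()
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((Y - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse
    if denom <= 0 or math.isclose(denom, 0.0, abs_tol=1e-12):
        raise ValueError("undefined ICC: no between-subject variance")
    return float((msr - mse) / denom)


def plot_curve(points: Sequence[CurvePoint], path, label: str = "adaptive"):
    """Accuracy vs. mean administered tasks, one marker per threshold."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    xs = [p.mean_tasks for p in points]
    ys = [p.accuracy for p in points]
    ax.plot(xs, ys, "o-", label=label)
    for p in points:
        ax.annotate(f"{p.confidence_threshold:.2f}", (p.mean_tasks, p.accuracy), fontsize=8)
    ax.set_xlabel("mean number of administered tasks")
    ax.set_ylabel("risk-category accuracy")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
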