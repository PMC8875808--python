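"""Bank of fall-risk classifiers over BBS task subsets.

For a task subset SS, the bank trains a random-forest classifier that
predicts the three-band fall-risk category from only the scores of the
tasks in SS.  Each prediction carries a confidence: the ensemble-averaged
class probability of the predicted class (the mean over trees of each
tree's leaf class fraction).  This is the statistic the adaptive
early-stopping rule thresholds.  Unlike a hard modal vote share — which
saturates at 1 whenever the bootstrapped trees happen to agree, however
ambiguous the score pattern — the averaged posterior retains the
class-mixing information of the leaves, so the threshold remains an
operative stopping dial.

Subjects with a missing score on SS are dropped from that subset's training
set rather than imputed, so per-subset training sizes vary exactly as
per-task sample sizes do in real cohorts.  Ties in the vote count are broken
toward the higher-risk category, the conservative clinical choice.

The bank also hosts the full-battery reference classifier: an RBF-kernel
SVM on all 14 scores with gamma = 1/n_features and C = 3, evaluated by
cross-validation (leave-one-out by default).
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, cross_val_predict
from sklearn.svm import SVC

from .battery import (
    Battery,
    Cohort,
    MissingScoreError,
    RiskCategory,
    ScoreVector,
    TaskSubset,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BankConfig",
    "FullBatteryConfig",
    "SubsetPredictor",
    "PredictorBank",
    "DegenerateTrainingError",
    "train_subset_predictor",
    "rank_predictors",
    "optimal_initial_subset",
    "FullBatteryClassifier",
    "train_full_battery_classifier",
    "full_battery_cv_predictions",
    "subset_seed",
]

N_CLASSES = 3


class DegenerateTrainingError(ValueError):
    """Training set restricted to a subset contains fewer than two classes."""


@dataclass(frozen=True)
class BankConfig:
    ensemble_size: int = 100
    max_depth: int = 10
    enumeration_mode: Literal["all_subsets", "lazy_on_demand"] = "lazy_on_demand"
    seed: int = 0

    def __post_init__(self):
        if self.ensemble_size < 1:
            raise ValueError("ensemble_size must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.enumeration_mode not in ("all_subsets", "lazy_on_demand"):
            raise ValueError(f"unknown enumeration_mode {self.enumeration_mode!r}")


@dataclass(frozen=True)
class FullBatteryConfig:
    """RBF-SVM configuration for the all-tasks risk classifier."""

    regularization_C: float = 3.0
    cv_scheme: Literal["loo", "stratified_kfold"] = "loo"
    n_folds: int = 5
    seed: int = 0

    @staticmethod
    def kernel_gamma(n_features: int) -> float:
        return 1.0 / n_features


def subset_seed(master: int, subset: TaskSubset) -> int:
    """Deterministic per-subset seed so lazy and eager training agree."""
    key = f"{master}:{sorted(subset)}".encode()
    return zlib.crc32(key) % (2**31 - 1)


class _ConstantModel:
    """Degenerate-training fallback: always predicts one class, confidence 1."""

    def __init__(self, code: int):
        self.code = int(code)

    def class_shares(self, X: np.ndarray) -> np.ndarray:
        out = np.zeros((len(X), N_CLASSES))
        out[:, self.code] = 1.0
        return out


def _forest_class_shares(model: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Ensemble-averaged class probabilities in risk-code order, shape (n, 3).

    Equals the mean over trees of each tree's leaf class fractions; columns
    are ordinal risk codes 0..2 (absent classes get probability 0).
    """
    proba = model.predict_proba(X)
    out = np.zeros((len(X), N_CLASSES))
    for j, c in enumerate(model.classes_.astype(int)):
        out[:, c] = proba[:, j]
    return out


def _decide(shares: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Modal class and vote share; ties broken toward higher risk (code 0)."""
    pred = np.argmax(shares, axis=1)  # argmax returns first max: highest risk
    conf = shares[np.arange(len(shares)), pred]
    return pred, conf


@dataclass
class SubsetPredictor:
    subset: TaskSubset
    model: RandomForestClassifier | _ConstantModel
    train_accuracy: float
    mean_confidence: float
    n_train: int
    is_constant: bool = False

    def class_shares(self, X: np.ndarray) -> np.ndarray:
        if isinstance(self.model, _ConstantModel):
            return self.model.class_shares(X)
        return _forest_class_shares(self.model, X)

    def predict(self, v: ScoreVector) -> tuple[RiskCategory, float]:
        X = v.values_for(self.subset)[None, :]
        pred, conf = _decide(self.class_shares(X))
        return RiskCategory(int(pred[0])), float(conf[0])


def train_subset_predictor(
    cohort: Cohort, subset: TaskSubset, cfg: BankConfig
) -> SubsetPredictor:
    """Fit the random-forest risk predictor for one task subset.

    Only subjects with no missing score in ``subset`` contribute; their
    labels must span at least two classes, else the training is degenerate
    and the caller may substitute a constant predictor.
    """
    if cohort.labels is None:
        raise ValueError("cohort must be labeled to train predictors")
    subset = frozenset(subset)
    if not subset:
        raise ValueError("cannot train a predictor on an empty subset")
    mask, X = cohort.subset_matrix(subset)
    y = cohort.labels[mask]
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError(
            f"subset {sorted(subset)}: training subjects span a single class"
        )
    model = RandomForestClassifier(
        n_estimators=cfg.ensemble_size,
        max_depth=cfg.max_depth,
        random_state=subset_seed(cfg.seed, subset),
    )
    model.fit(X, y)
    shares = _forest_class_shares(model, X)
    pred, conf = _decide(shares)
    return SubsetPredictor(
        subset=subset,
        model=model,
        train_accuracy=float(np.mean(pred == y)),
        mean_confidence=float(np.mean(conf)),
        n_train=int(len(y)),
    )


class PredictorBank:
    """Trained subset -> classifier map over one training cohort.

    In ``lazy_on_demand`` mode, predictors are trained and cached on first
    use (a greedy session only ever touches O(k^2) subsets per path); in
    ``all_subsets`` mode all 2^k - 1 predictors are trained eagerly and a
    query for anything else fails.
    """

    def __init__(self, cohort: Cohort, cfg: BankConfig | None = None):
        if cohort.labels is None:
            raise ValueError("predictor bank requires a labeled cohort")
        self.cohort = cohort
        self.battery = cohort.battery
        self.cfg = cfg or BankConfig()
        self.training_cohort_fingerprint = cohort.fingerprint()
        self._predictors: dict[TaskSubset, SubsetPredictor] = {}
        self._train_stats: dict[TaskSubset, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if self.cfg.enumeration_mode == "all_subsets":
            self.train_all()

    def __len__(self) -> int:
        return len(self._predictors)

    @property
    def predictors(self) -> dict[TaskSubset, SubsetPredictor]:
        return dict(self._predictors)

    @property
    def all_tasks(self) -> TaskSubset:
        return self.battery.id_set

    def train_all(self) -> None:
        ids = sorted(self.battery.task_ids)
        for r in range(1, len(ids) + 1):
            for combo in itertools.combinations(ids, r):
                self.get(frozenset(combo), _force_train=True)

    def get(self, subset: TaskSubset, _force_train: bool = False) -> SubsetPredictor:
        subset = frozenset(subset)
        if subset in self._predictors:
            return self._predictors[subset]
        if self.cfg.enumeration_mode == "all_subsets" and not _force_train:
            raise KeyError(
                f"subset {sorted(subset)} not in the eagerly-enumerated bank"
            )
        if not subset <= self.all_tasks:
            raise ValueError(
                f"subset {sorted(subset)} not contained in battery tasks"
            )
        try:
            sp = train_subset_predictor(self.cohort, subset, self.cfg)
        except DegenerateTrainingError:
            mask, _ = self.cohort.subset_matrix(subset)
            y = self.cohort.labels[mask]
            code = int(y[0]) if len(y) else int(RiskCategory.HIGH)
            logger.warning(
                "subset %s: degenerate training (single class); using constant "
                "predictor for class %d with confidence 1",
                sorted(subset),
                code,
            )
            sp = SubsetPredictor(
                subset=subset,
                model=_ConstantModel(code),
                train_accuracy=float(np.mean(y == code)) if len(y) else 0.0,
                mean_confidence=1.0,
                n_train=int(len(y)),
                is_constant=True,
            )
        self._predictors[subset] = sp
        return sp

    def predict(self, subset: TaskSubset, v: ScoreVector) -> tuple[RiskCategory, float]:
        """Risk category (modal ensemble vote) and its vote-share confidence."""
        return self.get(subset).predict(v)

    def training_predictions(
        self, subset: TaskSubset
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Cached (complete_mask, predictions, confidences) on the training cohort.

        Arrays are aligned with the cohort rows; incomplete subjects carry
        prediction -1 and confidence NaN.
        """
        subset = frozenset(subset)
        if subset not in self._train_stats:
            sp = self.get(subset)
            mask, X = self.cohort.subset_matrix(subset)
            preds = np.full(len(self.cohort), -1, dtype=int)
            confs = np.full(len(self.cohort), np.nan)
            if mask.any():
                p, c = _decide(sp.class_shares(X))
                preds[mask] = p
                confs[mask] = c
            self._train_stats[subset] = (mask, preds, confs)
        return self._train_stats[subset]


def rank_predictors(
    bank: PredictorBank,
) -> list[tuple[TaskSubset, float, float]]:
    """Rank trained predictors: accuracy desc, then mean confidence desc,
    then smaller subset, then lexicographic task ids."""
    if not bank.predictors:
        raise ValueError("bank holds no trained predictors to rank")
    rows = [
        (ss, sp.train_accuracy, sp.mean_confidence) for ss, sp in bank.predictors.items()
    ]
    rows.sort(key=lambda r: (-r[1], -r[2], len(r[0]), sorted(r[0])))
    return rows


def optimal_initial_subset(bank: PredictorBank, size: int) -> TaskSubset:
    """Best-accuracy subset of exactly the given cardinality.

    In lazy mode this enumerates (and trains) all subsets of that size; the
    ranking tie-breaks match :func:`rank_predictors`.
    """
    k = len(bank.battery)
    if not 1 <= size <= k:
        raise ValueError(f"initial subset size {size} outside 1..{k}")
    ids = sorted(bank.battery.task_ids)
    candidates = []
    for combo in itertools.combinations(ids, size):
        ss = frozenset(combo)
        sp = bank.get(ss)
        candidates.append((ss, sp.train_accuracy, sp.mean_confidence))
    candidates.sort(key=lambda r: (-r[1], -r[2], sorted(r[0])))
    return candidates[0][0]


class FullBatteryClassifier:
    """RBF-SVM risk classifier on the complete battery of scores."""

    def __init__(self, model: SVC, battery: Battery, cfg: FullBatteryConfig):
        self.model = model
        self.battery = battery
        self.cfg = cfg

    @property
    def gamma(self) -> float:
        return FullBatteryConfig.kernel_gamma(len(self.battery))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.model.predict(np.asarray(X, dtype=float)).astype(int)

    def predict_vector(self, v: ScoreVector) -> RiskCategory:
        X = v.values_for(self.battery.id_set)[None, :]
        return RiskCategory(int(self.predict(X)[0]))

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        """Per-class scores (probabilities) in class-code order 0,1,2."""
        proba = self.model.predict_proba(np.asarray(X, dtype=float))
        out = np.zeros((len(proba), N_CLASSES))
        for j, c in enumerate(self.model.classes_.astype(int)):
            out[:, c] = proba[:, j]
        return out


def _svc(n_features: int, cfg: FullBatteryConfig) -> SVC:
    return SVC(
        kernel="rbf",
        gamma=FullBatteryConfig.kernel_gamma(n_features),
        C=cfg.regularization_C,
        probability=True,
        random_state=cfg.seed,
    )


def train_full_battery_classifier(
    cohort: Cohort, cfg: FullBatteryConfig | None = None
) -> FullBatteryClassifier:
    """Fit the all-tasks SVM on subjects complete on the whole battery."""
    cfg = cfg or FullBatteryConfig()
    if cohort.labels is None:
        raise ValueError("cohort must be labeled")
    mask, X = cohort.subset_matrix(cohort.battery.id_set)
    y = cohort.labels[mask]
    if len(np.unique(y)) < 2:
        raise DegenerateTrainingError("full-battery cohort spans a single class")
    model = _svc(X.shape[1], cfg)
    model.fit(X, y)
    return FullBatteryClassifier(model, cohort.battery, cfg)


def full_battery_cv_predictions(
    cohort: Cohort, cfg: FullBatteryConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Cross-validated (truth, predicted) for the all-tasks SVM.

    Uses leave-one-out or seeded stratified k-fold per ``cfg.cv_scheme``,
    restricted to subjects complete on the whole battery.
    """
    cfg = cfg or FullBatteryConfig()
    mask, X = cohort.subset_matrix(cohort.battery.id_set)
    y = cohort.labels[mask]
    if cfg.cv_scheme == "loo":
        splitter = LeaveOneOut()
    else:
        splitter = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)
    pred = cross_val_predict(_svc(X.shape[1], cfg), X, y, cv=splitter)
    return y, pred.astype(int)
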