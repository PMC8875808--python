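"""Shared fixtures: a 4-task toy battery with a handcrafted 12-subject
cohort (including one contradictory score pattern so ensemble confidences
stay below 1), a cleanly separable cohort, and trained banks over them."""

import numpy as np
import pytest

from ebbs.battery import Battery, Cohort, ScoreVector, TaskDefinition
from ebbs.bank import BankConfig, PredictorBank

TOY_TASK_IDS = (1, 2, 3, 4)


def make_toy_battery() -> Battery:
    return Battery(tuple(TaskDefinition(i, f"toy task {i}") for i in TOY_TASK_IDS))


# 12 subjects, three risk classes; the pattern (2,2,2,2) appears with all
# three labels so that no classifier can be certain there.
TOY_ROWS = [
    ((0, 0, 1, 0), 0),
    ((1, 0, 0, 1), 0),
    ((0, 1, 0, 0), 0),
    ((2, 2, 2, 2), 0),
    ((2, 2, 2, 2), 1),
    ((2, 3, 2, 1), 1),
    ((3, 2, 2, 2), 1),
    ((2, 2, 2, 2), 2),
    ((4, 4, 3, 4), 2),
    ((3, 4, 4, 4), 2),
    ((4, 3, 4, 4), 2),
    ((4, 4, 4, 3), 2),
]


def make_toy_cohort() -> Cohort:
    vecs = [
        ScoreVector(f"T{i:02d}", dict(zip(TOY_TASK_IDS, row)))
        for i, (row, _) in enumerate(TOY_ROWS)
    ]
    return Cohort.from_vectors(
        vecs, labels=[lab for _, lab in TOY_ROWS], battery=make_toy_battery()
    )


def make_separable_cohort(n_per_class: int = 10, seed: int = 5) -> Cohort:
    """Classes fully determined by score band: every task of a high-risk
    subject is 0-1, medium 2, low 3-4, so any feature separates."""
    rng = np.random.default_rng(seed)
    vecs, labels = [], []
    bands = {0: (0, 1), 1: (2, 2), 2: (3, 4)}
    for cls, (lo, hi) in bands.items():
        for i in range(n_per_class):
            row = rng.integers(lo, hi + 1, size=len(TOY_TASK_IDS))
            vecs.append(
                ScoreVector(f"C{cls}_{i:02d}", dict(zip(TOY_TASK_IDS, row.tolist())))
            )
            labels.append(cls)
    return Cohort.from_vectors(vecs, labels=labels, battery=make_toy_battery())


@pytest.fixture(scope="session")
def toy_battery():
    return make_toy_battery()


@pytest.fixture(scope="session")
def toy_cohort():
    return make_toy_cohort()


@pytest.fixture(scope="session")
def toy_bank(toy_cohort):
    """Fully enumerated bank (all 15 subsets) over the toy cohort."""
    return PredictorBank(
        toy_cohort,
        BankConfig(ensemble_size=25, max_depth=3, enumeration_mode="all_subsets", seed=11),
    )


@pytest.fixture(scope="session")
def shallow_toy_bank(toy_cohort):
    """Depth-1 stumps keep every leaf impure: confidences strictly below 1."""
    return PredictorBank(
        toy_cohort,
        BankConfig(ensemble_size=30, max_depth=1, enumeration_mode="lazy_on_demand", seed=3),
    )


@pytest.fixture(scope="session")
def separable_cohort():
    return make_separable_cohort()
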