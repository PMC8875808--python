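"""Synthetic BBS score cohorts.

No clinical cohort is publicly deposited, so testable inputs are simulated
with the statistical structure the adaptive-shortening analysis assumes:

* a latent balance ability theta per subject, drawn from a three-stratum
  Gaussian mixture so that all three risk bands are populated, with the
  low-risk stratum heaviest (community controls outnumber high-risk
  in-patients in screening settings);
* ordinal task scores generated by a binomial-logistic item model: the
  score of task t at ability theta is Binomial(4, logistic(a_t*(theta-b_t))),
  where b_t is the task's difficulty and a_t > 0 its discrimination.  The
  binomial form gives the closed-form mean 4*logistic(a_t*(theta-b_t)) used
  by the generator's own tests;
* per-task missingness applied after the ground-truth label is computed,
  so stored labels always remain consistent with the unmasked total score.

All randomness flows through a single ``numpy.random.Generator`` seeded from
the config; equal seeds give bitwise-equal cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .battery import (
    Battery,
    Cohort,
    RiskCategory,
    classify_risk,
    standard_battery,
)

__all__ = [
    "AbilityStratum",
    "GeneratorConfig",
    "SyntheticCohort",
    "generate_cohort",
    "default_bbs_profile",
    "expected_task_score",
]


@dataclass(frozen=True)
class AbilityStratum:
    """One mixture component of the latent-ability distribution."""

    weight: float
    mean: float
    sd: float

    def __post_init__(self):
        if self.weight < 0:
            raise ValueError("stratum weight must be non-negative")
        if self.sd <= 0:
            raise ValueError("stratum sd must be positive")


@dataclass(frozen=True)
class GeneratorConfig:
    n_subjects: int
    ability_mixture: tuple[AbilityStratum, ...]
    task_difficulty: tuple[float, ...]
    task_discrimination: tuple[float, ...]
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if not self.ability_mixture:
            raise ValueError("ability_mixture must be non-empty")
        w = sum(s.weight for s in self.ability_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if len(self.task_difficulty) != len(self.task_discrimination):
            raise ValueError("difficulty and discrimination vectors differ in length")
        if any(a <= 0 for a in self.task_discrimination):
            raise ValueError("task discriminations must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")

    @property
    def n_tasks(self) -> int:
        return len(self.task_difficulty)


@dataclass
class SyntheticCohort(Cohort):
    """A generated cohort carrying the latent abilities alongside scores."""

    theta: np.ndarray = field(default_factory=lambda: np.empty(0))
    config: GeneratorConfig | None = None


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_cohort(cfg: GeneratorConfig, battery: Battery | None = None) -> SyntheticCohort:
    """Draw a cohort of ordinal score vectors with sum-consistent labels.

    Labels are computed from the completed (pre-masking) totals; missingness
    is then applied independently per task at ``cfg.missing_rate``.
    """
    battery = battery or standard_battery()
    if cfg.n_tasks != len(battery):
        raise ValueError(
            f"config specifies {cfg.n_tasks} tasks but battery has {len(battery)}"
        )
    rng = np.random.default_rng(cfg.seed)

    weights = np.array([s.weight for s in cfg.ability_mixture])
    comp = rng.choice(len(weights), size=cfg.n_subjects, p=weights)
    means = np.array([s.mean for s in cfg.ability_mixture])
    sds = np.array([s.sd for s in cfg.ability_mixture])
    theta = rng.normal(means[comp], sds[comp])

    a = np.asarray(cfg.task_discrimination, dtype=float)
    b = np.asarray(cfg.task_difficulty, dtype=float)
    p = _logistic(a[None, :] * (theta[:, None] - b[None, :]))  # (n, k)
    scores = rng.binomial(4, p).astype(float)

    totals = scores.sum(axis=1)
    # labels from the complete totals, rescaled for toy batteries < 14 tasks
    scale = 56 / battery.max_total
    labels = np.array([int(classify_risk(int(round(t * scale)))) for t in totals])

    if cfg.missing_rate > 0:
        mask = rng.random(scores.shape) < cfg.missing_rate
        scores[mask] = np.nan

    df = pd.DataFrame(
        scores,
        index=[f"S{i:04d}" for i in range(cfg.n_subjects)],
        columns=list(battery.task_ids),
    )
    return SyntheticCohort(df, labels, battery, theta=theta, config=cfg)


def default_bbs_profile(n_subjects: int = 300, seed: int = 0, missing_rate: float = 0.05) -> GeneratorConfig:
    """Default 14-task generator profile.

    Calibrated qualitatively to the known structure of clinical BBS data:
    Task 3 (sitting with back unsupported) is by far the easiest and is
    almost always top-scored, Tasks 12-14 (stepping / tandem / one-leg
    stance) are the hardest with heavy low-score tails, and the cohort mixes
    all three risk bands with low-risk subjects the most frequent.  A small
    per-task missing rate mirrors the per-task sample-size variation seen in
    real recordings.
    """
    difficulty = (
        -1.2,  # 1  sitting to standing
        -1.0,  # 2  standing unsupported
        -4.0,  # 3  sitting with back unsupported (easiest)
        -1.1,  # 4  standing to sitting
        -0.6,  # 5  transfers
        -0.8,  # 6  standing eyes closed
        -0.4,  # 7  feet together
        -0.2,  # 8  reaching forward
        -0.3,  # 9  pick up object
        0.0,   # 10 look behind
        0.3,   # 11 turn 360
        1.0,   # 12 alternate feet on step
        1.2,   # 13 one foot in front
        1.5,   # 14 standing on one leg
    )
    discrimination = (
        1.2, 1.2, 1.0, 1.2, 1.4, 1.3, 1.4, 1.6, 1.6, 1.3, 1.6, 1.5, 1.4, 1.3,
    )
    # Stratum means are placed so the expected total score sits mid-band
    # (roughly 11, 30 and 49 of 56): distinct clinical strata whose members
    # rarely straddle a band boundary, with the binomial score noise still
    # leaving a few ambiguous subjects near the cuts.
    mixture = (
        AbilityStratum(weight=0.15, mean=-1.8, sd=0.30),  # high risk
        AbilityStratum(weight=0.35, mean=-0.1, sd=0.22),  # medium risk
        AbilityStratum(weight=0.50, mean=1.6, sd=0.35),   # low risk
    )
    return GeneratorConfig(
        n_subjects=n_subjects,
        ability_mixture=mixture,
        task_difficulty=difficulty,
        task_discrimination=discrimination,
        missing_rate=missing_rate,
        seed=seed,
    )


def expected_task_score(cfg: GeneratorConfig, task_index: int, theta: float) -> float:
    """Closed-form mean score of a task at fixed ability (binomial mean)."""
    a = cfg.task_discrimination[task_index]
    b = cfg.task_difficulty[task_index]
    return 4.0 * float(_logistic(np.array(a * (theta - b))))
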