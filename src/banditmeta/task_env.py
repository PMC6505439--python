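"""Generative model of the two-armed bandit task and trial-log I/O.

The task is a block-structured two-armed bandit. Within each block the two
arms pay out points drawn from scaled beta distributions; the subject either
observes an outcome and rates one arm (rating trials) or freely chooses an
arm and reports decision confidence (choice trials). Two designs are
supported: ``exp1`` (75% rating trials, rating trials reveal an outcome,
one arm rated) and ``exp2`` (25% rating trials, no outcome on rating trials,
both arms rated).

Trial logs are plain CSV with one row per trial and empty cells for fields
that do not apply to a trial type.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ArmSpec",
    "BlockSpec",
    "ExperimentConfig",
    "TrialRecord",
    "STANDARD_ARM_PARAMS",
    "TRIAL_LOG_COLUMNS",
    "sample_reward",
    "build_experiment",
    "write_trial_log",
    "read_trial_log",
    "records_to_frame",
    "frame_to_records",
]

#: The five (alpha, beta) shape pairs used to generate arm payouts. Their
#: means span 25..75 points with different skews, all unimodal on [0, 100].
STANDARD_ARM_PARAMS: tuple[tuple[float, float], ...] = (
    (1.0, 3.0),
    (2.0, 3.0),
    (3.0, 3.0),
    (3.0, 2.0),
    (3.0, 1.0),
)

TRIAL_LOG_COLUMNS = [
    "subject",
    "block",
    "trial",
    "trial_type",
    "arm",
    "outcome",
    "value_rating",
    "belief_conf",
    "value_rating_other",
    "belief_conf_other",
    "decision_conf",
    "rt_ms",
]

_FLOAT_COLUMNS = [
    "outcome",
    "value_rating",
    "belief_conf",
    "value_rating_other",
    "belief_conf_other",
    "decision_conf",
    "rt_ms",
]


@dataclass(frozen=True)
class ArmSpec:
    """Beta-distributed reward generator for one bandit arm.

    Rewards are ``scale * Beta(alpha, beta_)`` draws, so the expected payout
    is ``scale * alpha / (alpha + beta_)`` points.
    """

    alpha: float
    beta_: float
    scale: float = 100.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta_ > 0):
            raise ValueError(
                f"beta shape parameters must be positive, got "
                f"alpha={self.alpha}, beta={self.beta_}"
            )

    @property
    def mean(self) -> float:
        return self.scale * self.alpha / (self.alpha + self.beta_)

    @property
    def sd(self) -> float:
        a, b = self.alpha, self.beta_
        return self.scale * np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


@dataclass(frozen=True)
class BlockSpec:
    """One block of the experiment: its two arms and its trial schedule."""

    block_id: int
    length: int
    arms: tuple[ArmSpec, ArmSpec]
    trial_types: tuple[str, ...]  # 'rating' | 'choice', one per trial
    rating_arm_sequence: tuple[int, ...]  # arm shown on each rating trial

    def __post_init__(self) -> None:
        if not (20 <= self.length <= 60):
            raise ValueError(f"block length {self.length} outside [20, 60]")
        if len(self.trial_types) != self.length:
            raise ValueError("trial_types length must equal block length")
        n_rating = sum(t == "rating" for t in self.trial_types)
        if len(self.rating_arm_sequence) != n_rating:
            raise ValueError("one rating arm needed per rating trial")


@dataclass(frozen=True)
class ExperimentConfig:
    """Design parameters for one experiment run.

    ``exp1``: 75% rating trials, rating trials show an outcome for one arm.
    ``exp2``: 25% rating trials, no outcome shown, both arms rated.
    """

    design: str = "exp1"
    total_trials: int = 600
    p_rating: float | None = None
    rating_shows_outcome: bool | None = None
    rating_rates_both_arms: bool | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("exp1", "exp2"):
            raise ValueError(f"unknown design {self.design!r}")
        defaults = {
            "exp1": (0.75, True, False),
            "exp2": (0.25, False, True),
        }[self.design]
        for name, value in zip(
            ("p_rating", "rating_shows_outcome", "rating_rates_both_arms"), defaults
        ):
            if getattr(self, name) is None:
                object.__setattr__(self, name, value)
        if not (0.0 <= self.p_rating <= 1.0):
            raise ValueError("p_rating must lie in [0, 1]")
        if self.total_trials < 20:
            raise ValueError(
                "total_trials cannot be partitioned into blocks of 20-60 trials"
            )


@dataclass
class TrialRecord:
    """One experimental or simulated trial.

    Rating rows carry ``value_rating`` and ``belief_conf`` (plus the
    ``*_other`` pair when both arms are rated) and never decision
    confidence; choice rows carry ``decision_conf`` and ``rt_ms`` and never
    a value rating. Absent fields are ``None``.
    """

    subject: str
    block: int
    trial: int  # 1-based within block
    trial_type: str  # 'rating' | 'choice'
    arm: int  # shown arm on rating trials, chosen arm on choice trials
    outcome: float | None = None
    value_rating: float | None = None
    belief_conf: float | None = None
    value_rating_other: float | None = None
    belief_conf_other: float | None = None
    decision_conf: float | None = None
    rt_ms: float | None = None


def sample_reward(arm: ArmSpec, rng: np.random.Generator, size=None):
    """Draw rewards in points from an arm's scaled beta distribution."""
    return arm.scale * rng.beta(arm.alpha, arm.beta_, size=size)


def _draw_block_lengths(total: int, rng: np.random.Generator) -> list[int]:
    # Uniform draws on {20..60}; the tail is constrained so the final block
    # also lands in [20, 60] and the lengths sum exactly to `total`.
    lengths: list[int] = []
    remaining = total
    while remaining > 60:
        hi = min(60, remaining - 20)
        lengths.append(int(rng.integers(20, hi + 1)))
        remaining -= lengths[-1]
    lengths.append(remaining)
    return lengths


def build_experiment(
    config: ExperimentConfig, rng: np.random.Generator | None = None
) -> list[BlockSpec]:
    """Build the block schedule for one experiment.

    Block lengths are drawn uniformly on {20..60} and partition
    ``total_trials`` exactly. Each block's two arms are a uniformly drawn
    unordered pair of the five standard beta parameterizations. Trial types
    are i.i.d. Bernoulli(``p_rating``); the rated arm on each rating trial
    is uniform. The schedule is deterministic given ``rng_seed``, so every
    simulated subject of a cohort can face the same blocks.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed)
    lengths = _draw_block_lengths(config.total_trials, rng)
    blocks = []
    for block_id, length in enumerate(lengths, start=1):
        i, j = rng.choice(len(STANDARD_ARM_PARAMS), size=2, replace=False)
        arms = (
            ArmSpec(*STANDARD_ARM_PARAMS[i]),
            ArmSpec(*STANDARD_ARM_PARAMS[j]),
        )
        types = tuple(
            "rating" if u < config.p_rating else "choice"
            for u in rng.random(length)
        )
        n_rating = sum(t == "rating" for t in types)
        rating_arms = tuple(int(a) for a in rng.integers(0, 2, size=n_rating))
        blocks.append(
            BlockSpec(
                block_id=block_id,
                length=length,
                arms=arms,
                trial_types=types,
                rating_arm_sequence=rating_arms,
            )
        )
    return blocks


# ---------------------------------------------------------------------------
# Trial-log I/O


def records_to_frame(records: Iterable[TrialRecord]) -> pd.DataFrame:
    rows = [
        {col: getattr(r, col) for col in TRIAL_LOG_COLUMNS} for r in records
    ]
    frame = pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)
    for col in _FLOAT_COLUMNS:
        frame[col] = frame[col].astype(float)
    return frame


def frame_to_records(frame: pd.DataFrame) -> list[TrialRecord]:
    records = []
    for row in frame.itertuples(index=False):
        kwargs = {col: getattr(row, col) for col in TRIAL_LOG_COLUMNS}
        for col in _FLOAT_COLUMNS:
            if pd.isna(kwargs[col]):
                kwargs[col] = None
        kwargs["block"] = int(kwargs["block"])
        kwargs["trial"] = int(kwargs["trial"])
        kwargs["arm"] = int(kwargs["arm"])
        kwargs["subject"] = str(kwargs["subject"])
        records.append(TrialRecord(**kwargs))
    return records


class TrialLogError(ValueError):
    """Raised when a trial-log file violates the format contract."""


_RANGES = {
    "outcome": (0.0, 100.0),
    "value_rating": (0.0, 100.0),
    "value_rating_other": (0.0, 100.0),
    "belief_conf": (0.0, 1.0),
    "belief_conf_other": (0.0, 1.0),
    "decision_conf": (0.0, 1.0),
}


def validate_trial_log(frame: pd.DataFrame) -> None:
    """Check the row-level invariants; raise TrialLogError naming the row.

    Line numbers refer to the CSV file (header = line 1).
    """
    missing = [c for c in TRIAL_LOG_COLUMNS if c not in frame.columns]
    if missing:
        raise TrialLogError(f"missing mandatory columns: {missing}")
    for idx, row in enumerate(frame.itertuples(index=False)):
        line = idx + 2
        if row.trial_type not in ("rating", "choice"):
            raise TrialLogError(
                f"line {line}: trial_type {row.trial_type!r} not rating/choice"
            )
        if row.arm not in (0, 1):
            raise TrialLogError(f"line {line}: arm must be 0 or 1")
        for col, (lo, hi) in _RANGES.items():
            v = getattr(row, col)
            if pd.notna(v) and not (lo <= v <= hi):
                raise TrialLogError(
                    f"line {line}: {col}={v} outside [{lo}, {hi}]"
                )
        if pd.notna(row.rt_ms) and row.rt_ms <= 0:
            raise TrialLogError(f"line {line}: rt_ms must be positive")
        if row.trial_type == "rating":
            if pd.isna(row.value_rating) or pd.isna(row.belief_conf):
                raise TrialLogError(
                    f"line {line}: rating row lacks value_rating/belief_conf"
                )
            if pd.notna(row.decision_conf):
                raise TrialLogError(
                    f"line {line}: rating row carries decision_conf"
                )
        else:
            if pd.isna(row.decision_conf):
                raise TrialLogError(
                    f"line {line}: choice row lacks decision_conf"
                )
            if pd.notna(row.value_rating):
                raise TrialLogError(
                    f"line {line}: choice row carries value_rating"
                )


def write_trial_log(log: pd.DataFrame | Sequence[TrialRecord], path) -> None:
    """Write a trial log as UTF-8 CSV with the canonical column order."""
    if not isinstance(log, pd.DataFrame):
        log = records_to_frame(log)
    validate_trial_log(log)
    log = log[TRIAL_LOG_COLUMNS]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    # %.17g guarantees exact float64 round-trips
    log.to_csv(path, index=False, encoding="utf-8", float_format="%.17g")


def read_trial_log(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read and validate a trial log.

    ``column_map`` maps foreign column names onto the canonical ones, so a
    differently-labelled deposit can be ingested without code changes
    (e.g. ``{"ppt": "subject"}``).
    """
    frame = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    if column_map:
        frame = frame.rename(columns=column_map)
    for col in _FLOAT_COLUMNS:
        if col in frame.columns:
            frame[col] = pd.to_numeric(frame[col], errors="coerce")
    frame["subject"] = frame["subject"].astype(str)
    validate_trial_log(frame)
    return frame.reset_index(drop=True)
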