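"""Cohorts of simulated subjects with known, heterogeneous parameters.

Each subject draws their agent parameters from cohort-level distributions
(Gaussian on a log scale for positive parameters and a logit scale for
unit-interval ones, so hard bounds are respected), simulates a full
session on the shared block schedule, and is recorded in a ground-truth
table so downstream recovery analyses can compare estimates to truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .agents import MODEL_TAGS, AgentParams, simulate_subject
from .task_env import ExperimentConfig, build_experiment

__all__ = ["CohortSpec", "CohortData", "generate_cohort", "DEFAULT_PARAM_DISTS"]

#: Default cohort-level (mean, sd) per heterogeneous parameter, natural scale.
DEFAULT_PARAM_DISTS: dict[str, tuple[float, float]] = {
    "learning_rate": (0.3, 0.1),
    "confidence_gain": (2.0, 0.3),
    "uncertainty_bonus": (0.5, 0.15),
    "inverse_temperature": (8.0, 1.5),
    "rating_noise_sd": (14.0, 3.5),
    "confidence_noise_sd": (0.08, 0.02),
}

# how each parameter is transformed before the Gaussian subject-level draw
_LOG_SCALE = {
    "confidence_gain",
    "inverse_temperature",
    "rating_noise_sd",
    "confidence_noise_sd",
}
_LOGIT_SCALE = {"learning_rate"}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a simulated cohort."""

    n_subjects: int = 21
    design: str = "exp1"
    param_dists: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_DISTS)
    )
    model_mix: dict[str, float] = field(default_factory=lambda: {"ideal": 1.0})
    master_seed: int = 0
    total_trials: int = 600

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for tag in self.model_mix:
            if tag not in MODEL_TAGS:
                raise ValueError(f"unknown model tag {tag!r} in model_mix")
        if abs(sum(self.model_mix.values()) - 1.0) > 1e-9:
            raise ValueError("model_mix proportions must sum to 1")
        for name, (_, sd) in self.param_dists.items():
            if sd < 0:
                raise ValueError(f"negative sd for parameter {name!r}")


@dataclass
class CohortData:
    """Simulated cohort: combined trial log, truth table, latent sidecar."""

    trials: pd.DataFrame  # all subjects' trial logs, stacked
    truth: pd.DataFrame  # one row per subject: model_tag, params, seed
    latents: pd.DataFrame  # per-trial latent states, stacked

    def subject_log(self, subject: str) -> pd.DataFrame:
        return self.trials[self.trials["subject"] == subject].reset_index(drop=True)


def _draw_param(
    name: str, mean: float, sd: float, rng: np.random.Generator
) -> float:
    """Subject-level draw: Gaussian on the transformed scale (delta method)."""
    if sd == 0.0:
        return mean
    if name in _LOG_SCALE:
        t, slope = math.log(mean), 1.0 / mean
        return float(np.exp(rng.normal(t, sd * slope)))
    if name in _LOGIT_SCALE:
        t = logit(mean)
        slope = 1.0 / (mean * (1.0 - mean))
        return float(np.clip(expit(rng.normal(t, sd * slope)), 1e-3, 1.0))
    return float(rng.normal(mean, sd))


def generate_cohort(spec: CohortSpec) -> CohortData:
    """Simulate a cohort of subjects on a shared block schedule.

    Per-subject seeds are derived deterministically from ``master_seed``;
    the same spec always yields the same cohort. Every subject faces the
    same blocks, as in the task design.
    """
    master = np.random.default_rng(spec.master_seed)
    schedule_seed = int(master.integers(0, 2**31 - 1))
    config = ExperimentConfig(
        design=spec.design, total_trials=spec.total_trials, rng_seed=schedule_seed
    )
    blocks = build_experiment(config)

    tags = list(spec.model_mix)
    probs = np.array([spec.model_mix[t] for t in tags])
    n_digits = len(str(spec.n_subjects))
    logs, truths, latents = [], [], []
    for i in range(spec.n_subjects):
        subject = f"s{i + 1:0{n_digits}d}"
        seed = int(master.integers(0, 2**31 - 1))
        tag = tags[int(master.choice(len(tags), p=probs))]
        kwargs = {
            name: _draw_param(name, mean, sd, master)
            for name, (mean, sd) in spec.param_dists.items()
        }
        params = AgentParams(model_tag=tag, rng_seed=seed, **kwargs)
        log, latent = simulate_subject(
            config, params, subject_id=subject, blocks=blocks
        )
        logs.append(log)
        latents.append(latent)
        truths.append({"subject": subject, "model_tag": tag, "seed": seed, **kwargs})
    return CohortData(
        trials=pd.concat(logs, ignore_index=True),
        truth=pd.DataFrame(truths),
        latents=pd.concat(latents, ignore_index=True),
    )
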