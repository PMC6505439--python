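"""Simulated participants for the bandit task.

Three agent families are implemented, each maintaining a per-arm value
belief (a point estimate) and a per-arm dispersion that is read out as
belief confidence:

``ideal``
    An ideal-observer tracker: the value belief is the running mean of all
    outcomes observed for an arm and the dispersion is the running sample
    standard deviation. This is the normative benchmark against which
    human belief-confidence reports are compared.

``rl``
    A delta-rule learner: ``V <- V + eta * (r - V)`` with a dispersion that
    tracks an exponentially weighted recent absolute prediction error, so a
    surprising outcome transiently *lowers* reported confidence — the
    non-Bayesian signature seen in human reports.

``particle``
    A sequential Monte-Carlo (particle filter) posterior over the arm's
    mean payout, with a beta observation model. Dispersion is the posterior
    standard deviation, which contracts monotonically with evidence.

On top of the learner sits a fixed report/choice layer: noisy clipped
readouts of value and confidence, a logistic choice policy with an
uncertainty bonus that promotes exploration of the lower-valued arm when
confidence in the higher-valued arm is low, and a linear decision-confidence
readout in which value and belief confidence of both options enter with
the signed pattern (+V_chosen, -V_unchosen, +C_chosen, +C_unchosen).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_env import (
    BlockSpec,
    ExperimentConfig,
    TrialRecord,
    build_experiment,
    records_to_frame,
    sample_reward,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AgentParams",
    "BeliefState",
    "update_ideal",
    "update_rl",
    "update_particle",
    "update_belief",
    "readout_rating",
    "report_dispersion",
    "rating_report_noise",
    "belief_confidence_noiseless",
    "choose",
    "explore_probability",
    "step_conf_drift",
    "readout_decision_confidence",
    "simulate_subject",
]

MODEL_TAGS = ("ideal", "rl", "particle")

_PRIOR_VALUE = 50.0  # midpoint of the 0-100 payout scale
_UNIFORM_SD = 100.0 / math.sqrt(12.0)  # SD of a flat prior over payouts


@dataclass
class AgentParams:
    """Free parameters of one simulated participant.

    Units: values and dispersions are in points (0-100), confidences in
    [0, 1]. ``inverse_temperature`` acts on the value difference divided by
    100; ``uncertainty_bonus`` (phi) weighs ``1 - C_high`` in the choice
    policy, so positive phi yields uncertainty-driven exploration.
    """

    model_tag: str = "ideal"
    learning_rate: float = 0.3  # delta-rule eta, (0, 1]
    confidence_gain: float = 2.0  # dispersion (points/100) -> confidence drop
    uncertainty_bonus: float = 0.5  # phi
    inverse_temperature: float = 8.0
    rating_noise_sd: float = 14.0  # points, at prior-level uncertainty
    confidence_noise_sd: float = 0.08  # confidence units
    n_particles: int = 200
    obs_concentration: float = 10.0  # alpha+beta of the particle obs model
    rl_init_sd: float = 25.0  # delta-rule dispersion before any outcome
    # decision-confidence readout (linear in centred inputs, then clipped)
    dc_baseline: float = 0.6
    dc_w_value_chosen: float = 0.6
    dc_w_value_unchosen: float = 0.35
    dc_w_conf_chosen: float = 0.5
    dc_w_conf_unchosen: float = 0.25
    # slow AR(1) wander of subjective confidence, shared by reports and
    # choices (stationary SD in confidence units; rho per trial)
    conf_drift_sd: float = 0.25
    conf_drift_rho: float = 0.85
    # reaction-time generator (log-normal, faster when more confident)
    rt_median_ms: float = 800.0
    rt_conf_slope: float = 0.8  # log-ms decrease per unit decision confidence
    rt_log_sd: float = 0.25
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.model_tag not in MODEL_TAGS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        if not (0.0 < self.learning_rate <= 1.0):
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.confidence_gain <= 0:
            raise ValueError("confidence_gain must be positive")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be non-negative")
        for name in ("rating_noise_sd", "confidence_noise_sd", "rt_log_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_particles < 2:
            raise ValueError("n_particles must be at least 2")


@dataclass
class BeliefState:
    """Per-arm value estimate, dispersion and evidence count for one block."""

    est_value: np.ndarray  # (2,) points
    est_sd: np.ndarray  # (2,) points
    n_obs: np.ndarray  # (2,) int
    # current value of the slow subjective-confidence wander, per arm
    conf_drift: np.ndarray = field(default_factory=lambda: np.zeros(2))
    # ideal-observer running-moment accumulators (Welford)
    _m2: np.ndarray | None = None
    # particle filter state
    particle_means: np.ndarray | None = None  # (2, N) candidate means
    particle_weights: np.ndarray | None = None  # (2, N), rows sum to 1
    _jitter_rng: np.random.Generator | None = None
    # cached beta observation-model terms, recomputed when means change
    _pf_am1: np.ndarray | None = None  # (2, N) alpha - 1
    _pf_bm1: np.ndarray | None = None  # (2, N) beta - 1
    _pf_logbeta: np.ndarray | None = None  # (2, N) log B(alpha, beta)

    @classmethod
    def initial(cls, params: AgentParams) -> "BeliefState":
        est_value = np.full(2, _PRIOR_VALUE)
        n_obs = np.zeros(2, dtype=int)
        if params.model_tag == "ideal":
            return cls(est_value, np.zeros(2), n_obs, _m2=np.zeros(2))
        if params.model_tag == "rl":
            return cls(est_value, np.full(2, params.rl_init_sd), n_obs)
        # particle: uniform candidate means over (0, 100)
        n = params.n_particles
        means = np.tile(np.linspace(0.5, 99.5, n), (2, 1))
        weights = np.full((2, n), 1.0 / n)
        state = cls(
            est_value.copy(),
            np.full(2, _UNIFORM_SD),
            n_obs,
            particle_means=means,
            particle_weights=weights,
            _jitter_rng=np.random.default_rng(params.rng_seed),
        )
        state._refresh_particle_moments(0)
        state._refresh_particle_moments(1)
        state._refresh_obs_model(0, params)
        state._refresh_obs_model(1, params)
        return state

    def _refresh_obs_model(self, arm: int, params: AgentParams) -> None:
        from scipy.special import betaln

        if self._pf_am1 is None:
            n = self.particle_means.shape[1]
            self._pf_am1 = np.empty((2, n))
            self._pf_bm1 = np.empty((2, n))
            self._pf_logbeta = np.empty((2, n))
        nu = params.obs_concentration
        mu = np.clip(self.particle_means[arm] / 100.0, 1e-4, 1.0 - 1e-4)
        a, b = nu * mu, nu * (1.0 - mu)
        self._pf_am1[arm] = a - 1.0
        self._pf_bm1[arm] = b - 1.0
        self._pf_logbeta[arm] = betaln(a, b)

    def _refresh_particle_moments(self, arm: int) -> None:
        w = self.particle_weights[arm]
        m = self.particle_means[arm]
        mu = float(np.dot(w, m))
        var = float(np.dot(w, (m - mu) ** 2))
        self.est_value[arm] = mu
        self.est_sd[arm] = math.sqrt(max(var, 0.0))


def _check_outcome(outcome: float) -> None:
    if not (0.0 <= outcome <= 100.0):
        raise ValueError(f"outcome {outcome} outside [0, 100]")


def update_ideal(state: BeliefState, arm: int, outcome: float) -> BeliefState:
    """Running mean / running sample SD update (Welford recursion).

    The dispersion is 0 until two outcomes have been seen.
    """
    _check_outcome(outcome)
    n = int(state.n_obs[arm]) + 1
    if n == 1:
        mean, m2 = float(outcome), 0.0
    else:
        mean = float(state.est_value[arm])
        delta = outcome - mean
        mean += delta / n
        m2 = float(state._m2[arm]) + delta * (outcome - mean)
    state.n_obs[arm] = n
    state.est_value[arm] = mean
    state._m2[arm] = m2
    state.est_sd[arm] = math.sqrt(m2 / (n - 1)) if n >= 2 else 0.0
    return state


def update_rl(
    state: BeliefState, arm: int, outcome: float, params: AgentParams
) -> BeliefState:
    """Delta-rule value update plus prediction-error-tracking dispersion."""
    _check_outcome(outcome)
    eta = params.learning_rate
    v_before = float(state.est_value[arm])
    pe = outcome - v_before
    state.est_value[arm] = v_before + eta * pe
    state.est_sd[arm] = (1.0 - eta) * float(state.est_sd[arm]) + eta * abs(pe)
    state.n_obs[arm] += 1
    return state


def update_particle(
    state: BeliefState, arm: int, outcome: float, params: AgentParams
) -> BeliefState:
    """Sequential importance resampling over candidate arm means.

    The observation model is a beta density with mean equal to the
    particle's candidate mean and fixed concentration
    ``obs_concentration``; systematic resampling (with a small jitter on
    the candidate means to prevent impoverishment) is triggered when the
    effective sample size drops below half the particle count.
    """
    _check_outcome(outcome)
    x = min(max(outcome / 100.0, 1e-4), 1.0 - 1e-4)
    log_x, log_1mx = math.log(x), math.log1p(-x)
    logw = (
        state._pf_am1[arm] * log_x
        + state._pf_bm1[arm] * log_1mx
        - state._pf_logbeta[arm]
    )
    w = state.particle_weights[arm] * np.exp(logw - logw.max())
    total = w.sum()
    if not np.isfinite(total) or total <= 0.0:
        logger.warning("particle weights underflowed; re-initializing arm %d", arm)
        n = w.size
        state.particle_means[arm] = np.linspace(0.5, 99.5, n)
        state._refresh_obs_model(arm, params)
        w = np.full(n, 1.0 / n)
        total = 1.0
    w = w / total
    ess = 1.0 / np.sum(w**2)
    if ess < w.size / 2.0:
        # systematic resampling with deterministic offset, then roughening
        positions = (np.arange(w.size) + 0.5) / w.size
        idx = np.searchsorted(np.cumsum(w), positions)
        means = state.particle_means[arm][np.minimum(idx, w.size - 1)]
        if state._jitter_rng is not None:
            means = means + state._jitter_rng.normal(0.0, 1.0, size=means.size)
        state.particle_means[arm] = np.clip(means, 0.0, 100.0)
        state._refresh_obs_model(arm, params)
        w = np.full(w.size, 1.0 / w.size)
    state.particle_weights[arm] = w
    state.n_obs[arm] += 1
    state._refresh_particle_moments(arm)
    return state


def update_belief(
    state: BeliefState, arm: int, outcome: float, params: AgentParams
) -> BeliefState:
    """Dispatch to the update rule named by ``params.model_tag``."""
    if params.model_tag == "ideal":
        return update_ideal(state, arm, outcome)
    if params.model_tag == "rl":
        return update_rl(state, arm, outcome, params)
    return update_particle(state, arm, outcome, params)


# ---------------------------------------------------------------------------
# Report and choice layer


def report_dispersion(state: BeliefState, arm: int, params: AgentParams) -> float:
    """Effective dispersion entering confidence reports and choice, in points.

    The particle filter's ``est_sd`` is already a posterior dispersion, so
    it is used as is. The ideal and delta-rule trackers report the
    prior-regularized outcome dispersion

        d_eff = sqrt((n * s^2 + n0 * sigma_prior^2) / (n + n0)),  n0 = 2,

    i.e. the agent's current estimate of the arm's outcome variability,
    shrunk toward a flat-prior SD while evidence is scarce. Confidence
    derived from it rises early in a block (the prior washes out), drops
    after surprising outcomes (which inflate ``s`` for the delta-rule
    tracker), and otherwise tracks the realized outcome SD — with no
    strong dependence on the raw observation count, matching the weak
    trial-number loads in human confidence reports.
    """
    if params.model_tag == "particle":
        return float(state.est_sd[arm])
    n = float(state.n_obs[arm])
    s2 = float(state.est_sd[arm]) ** 2
    n0 = 2.0
    return math.sqrt((n * s2 + n0 * _UNIFORM_SD**2) / (n + n0))


def rating_report_noise(state: BeliefState, arm: int, params: AgentParams) -> float:
    """Value-rating noise SD in points: sharpens with the evidence count.

    ``params.rating_noise_sd`` is the noise SD before any outcome;
    precision grows as (n+1)^(1/4), a slow power-law sharpening. The
    schedule depends on the observation count only — not on the arm's
    estimated dispersion — so report precision and reported confidence
    carry separate pieces of the latent state.
    """
    n = float(state.n_obs[arm])
    return params.rating_noise_sd / (n + 1.0) ** 0.25


def belief_confidence_noiseless(
    state: BeliefState, arm: int, params: AgentParams
) -> float:
    """Monotone-decreasing map from effective dispersion to confidence.

    Includes the state's slow subjective-confidence wander (zero in a
    freshly initialized state, so likelihood evaluation is deterministic).
    """
    d = report_dispersion(state, arm, params)
    c = 1.0 - params.confidence_gain * d / 100.0 + float(state.conf_drift[arm])
    return min(max(c, 0.0), 1.0)


def step_conf_drift(
    state: BeliefState, params: AgentParams, rng: np.random.Generator
) -> None:
    """Advance the AR(1) subjective-confidence wander by one trial.

    The wander is stationary with SD ``conf_drift_sd``; because it moves
    slowly (``conf_drift_rho`` per trial) it is shared between a rating
    and the choices that follow it, so it carries genuine signal from
    reported confidence to exploration behaviour rather than acting as
    pure measurement noise.
    """
    rho, sd = params.conf_drift_rho, params.conf_drift_sd
    innov = sd * math.sqrt(max(1.0 - rho**2, 0.0))
    state.conf_drift = rho * state.conf_drift + rng.normal(0.0, innov, size=2)


def readout_rating(
    state: BeliefState, arm: int, params: AgentParams, rng: np.random.Generator
) -> tuple[float, float]:
    """Noisy clipped (value rating, belief confidence) report for one arm.

    Value-rating noise sharpens with the arm's evidence count (see
    ``rating_report_noise``); confidence noise is constant.
    """
    noise_sd = rating_report_noise(state, arm, params)
    value = float(
        np.clip(
            state.est_value[arm] + rng.normal(0.0, noise_sd),
            0.0,
            100.0,
        )
    )
    conf = float(
        np.clip(
            belief_confidence_noiseless(state, arm, params)
            + rng.normal(0.0, params.confidence_noise_sd),
            0.0,
            1.0,
        )
    )
    return value, conf


def explore_probability(state: BeliefState, params: AgentParams) -> float:
    """P(choose the lower-valued arm) under the uncertainty-bonus policy.

    ``logistic(-beta * |dV|/100 + phi * (1 - C_high))`` where C_high is the
    (noiseless) belief confidence of the currently higher-valued arm.
    """
    v0, v1 = float(state.est_value[0]), float(state.est_value[1])
    dv = abs(v0 - v1)
    high = 0 if v0 >= v1 else 1
    c_high = belief_confidence_noiseless(state, high, params)
    x = (
        -params.inverse_temperature * dv / 100.0
        + params.uncertainty_bonus * (1.0 - c_high)
    )
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    ex = math.exp(x)
    return ex / (1.0 + ex)


def choose(
    state: BeliefState, params: AgentParams, rng: np.random.Generator
) -> int:
    """Sample an arm; value ties are broken uniformly."""
    v0, v1 = float(state.est_value[0]), float(state.est_value[1])
    if v0 == v1:
        return int(rng.integers(0, 2))
    high = 0 if v0 > v1 else 1
    p_explore = explore_probability(state, params)
    return 1 - high if rng.random() < p_explore else high


def decision_confidence_noiseless(
    state: BeliefState, chosen_arm: int, params: AgentParams
) -> float:
    other = 1 - chosen_arm
    v_c = float(state.est_value[chosen_arm])
    v_u = float(state.est_value[other])
    c_c = belief_confidence_noiseless(state, chosen_arm, params)
    c_u = belief_confidence_noiseless(state, other, params)
    g = (
        params.dc_baseline
        + params.dc_w_value_chosen * (v_c - 50.0) / 100.0
        - params.dc_w_value_unchosen * (v_u - 50.0) / 100.0
        + params.dc_w_conf_chosen * (c_c - 0.5)
        + params.dc_w_conf_unchosen * (c_u - 0.5)
    )
    return float(np.clip(g, 0.0, 1.0))


def readout_decision_confidence(
    state: BeliefState,
    chosen_arm: int,
    params: AgentParams,
    rng: np.random.Generator,
) -> float:
    g = decision_confidence_noiseless(state, chosen_arm, params)
    return float(np.clip(g + rng.normal(0.0, params.confidence_noise_sd), 0.0, 1.0))


def _sample_rt(dc: float, params: AgentParams, rng: np.random.Generator) -> float:
    # log-normal RT, median decreasing in decision confidence
    log_rt = (
        math.log(params.rt_median_ms)
        - params.rt_conf_slope * (dc - 0.5)
        + rng.normal(0.0, params.rt_log_sd)
    )
    return float(np.exp(log_rt))


# ---------------------------------------------------------------------------
# Full-session simulation


def simulate_subject(
    config: ExperimentConfig,
    params: AgentParams,
    rng: np.random.Generator | None = None,
    subject_id: str = "sim",
    blocks: list[BlockSpec] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate one subject's full session.

    Beliefs reset at block boundaries (the arm distributions change per
    block). On rating trials the agent observes an outcome, updates, then
    rates the shown arm (``exp1``) or rates both arms with no outcome and
    no update (``exp2``). On choice trials the agent chooses, reports
    decision confidence before seeing the outcome, then updates on the
    revealed outcome.

    Returns ``(trial_log, latent_sidecar)``; the sidecar holds the agent's
    post-trial latent value and dispersion per arm for every trial.
    """
    if rng is None:
        rng = np.random.default_rng(params.rng_seed)
    if blocks is None:
        blocks = build_experiment(config)
    records: list[TrialRecord] = []
    latents: list[dict] = []
    for block in blocks:
        state = BeliefState.initial(params)
        state.conf_drift = rng.normal(0.0, params.conf_drift_sd, size=2)
        rating_idx = 0
        for t, trial_type in enumerate(block.trial_types, start=1):
            step_conf_drift(state, params, rng)
            rec = TrialRecord(
                subject=subject_id, block=block.block_id, trial=t,
                trial_type=trial_type, arm=0,
            )
            if trial_type == "rating":
                shown = block.rating_arm_sequence[rating_idx]
                rating_idx += 1
                rec.arm = shown
                if config.rating_shows_outcome:
                    outcome = float(sample_reward(block.arms[shown], rng))
                    update_belief(state, shown, outcome, params)
                    rec.outcome = outcome
                rec.value_rating, rec.belief_conf = readout_rating(
                    state, shown, params, rng
                )
                if config.rating_rates_both_arms:
                    other = 1 - shown
                    rec.value_rating_other, rec.belief_conf_other = readout_rating(
                        state, other, params, rng
                    )
            else:
                chosen = choose(state, params, rng)
                rec.arm = chosen
                rec.decision_conf = readout_decision_confidence(
                    state, chosen, params, rng
                )
                rec.rt_ms = _sample_rt(rec.decision_conf, params, rng)
                outcome = float(sample_reward(block.arms[chosen], rng))
                rec.outcome = outcome
                update_belief(state, chosen, outcome, params)
            records.append(rec)
            latents.append(
                {
                    "subject": subject_id,
                    "block": block.block_id,
                    "trial": t,
                    "est_value_0": float(state.est_value[0]),
                    "est_value_1": float(state.est_value[1]),
                    "est_sd_0": float(state.est_sd[0]),
                    "est_sd_1": float(state.est_sd[1]),
                }
            )
    return records_to_frame(records), pd.DataFrame(latents)
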