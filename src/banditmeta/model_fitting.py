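"""Likelihood-based fitting of the agent models to trial logs.

The likelihood walks a trial log in time order, maintaining the latent
belief state with exactly the update rules of the agents module. Rating
rows contribute Gaussian observation densities of the value rating and
belief confidence around the model's noiseless readouts (after updating
on the revealed outcome, where the design shows one); choice rows
contribute the choice policy's log-probability of the chosen arm, with
the belief update on the revealed outcome applied afterwards. Rows of a
design that hides rating outcomes simply carry no update.

Model comparison uses BIC = k ln(n) + 2 NLL with n the number of
contributing trials; fitting is bounded multi-start Nelder-Mead.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import optimize

from .agents import (
    AgentParams,
    BeliefState,
    belief_confidence_noiseless,
    explore_probability,
    rating_report_noise,
    update_belief,
)

__all__ = ["FitResult", "FREE_PARAMS", "PARAM_BOUNDS", "nll", "fit", "compare"]

_LOG_2PI = math.log(2.0 * math.pi)
_PENALTY = 1e10

#: free parameters per model family, in optimization order
FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "ideal": (
        "confidence_gain", "uncertainty_bonus", "inverse_temperature",
        "rating_noise_sd", "confidence_noise_sd",
    ),
    "rl": (
        "learning_rate", "confidence_gain", "uncertainty_bonus",
        "inverse_temperature", "rating_noise_sd", "confidence_noise_sd",
    ),
    "particle": (
        "confidence_gain", "uncertainty_bonus", "inverse_temperature",
        "rating_noise_sd", "confidence_noise_sd",
    ),
}

PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "learning_rate": (0.02, 1.0),
    "confidence_gain": (0.2, 6.0),
    "uncertainty_bonus": (-2.0, 3.0),
    "inverse_temperature": (0.0, 30.0),
    "rating_noise_sd": (1.0, 40.0),
    "confidence_noise_sd": (0.01, 0.5),
}


@dataclass
class FitResult:
    """Best fit of one model family to one subject's log."""

    model_tag: str
    params: dict[str, float]
    nll: float
    bic: float
    n_obs: int
    converged: bool
    n_restarts: int

    def to_row(self) -> dict:
        return {
            "model": self.model_tag, **self.params, "nll": self.nll,
            "bic": self.bic, "n_obs": self.n_obs, "converged": self.converged,
        }


def _norm_logpdf(x: float, mu: float, sd: float) -> float:
    z = (x - mu) / sd
    return -0.5 * (z * z + _LOG_2PI) - math.log(sd)


def _log_rows(log: pd.DataFrame) -> list[tuple]:
    """Flatten a (single-subject) trial log into plain-python row tuples."""
    log = log.sort_values(["block", "trial"], kind="stable")
    rows = []
    for r in log.itertuples(index=False):
        rows.append(
            (
                int(r.block),
                r.trial_type == "rating",
                int(r.arm),
                None if pd.isna(r.outcome) else float(r.outcome),
                None if pd.isna(r.value_rating) else float(r.value_rating),
                None if pd.isna(r.belief_conf) else float(r.belief_conf),
                None if pd.isna(r.value_rating_other) else float(r.value_rating_other),
                None if pd.isna(r.belief_conf_other) else float(r.belief_conf_other),
            )
        )
    return rows


def _rating_loglik(
    state: BeliefState, arm: int, value: float | None, conf: float | None,
    params: AgentParams,
) -> float:
    ll = 0.0
    if value is not None:
        noise_sd = rating_report_noise(state, arm, params)
        ll += _norm_logpdf(value, float(state.est_value[arm]), max(noise_sd, 0.5))
    if conf is not None:
        mu = belief_confidence_noiseless(state, arm, params)
        ll += _norm_logpdf(conf, mu, params.confidence_noise_sd)
    return ll


def nll(
    log: pd.DataFrame,
    model_tag: str,
    params: AgentParams | dict,
    _rows: list | None = None,
) -> float:
    """Negative log-likelihood of one subject's log under one model.

    ``params`` may be an ``AgentParams`` or a dict of the model's free
    parameters. Out-of-bounds parameters return a large penalty value.
    """
    if isinstance(params, dict):
        try:
            params = AgentParams(model_tag=model_tag, **params)
        except ValueError:
            return _PENALTY
    elif params.model_tag != model_tag:
        params = dc_replace(params, model_tag=model_tag)
    for name in FREE_PARAMS[model_tag]:
        lo, hi = PARAM_BOUNDS[name]
        if not (lo <= getattr(params, name) <= hi):
            return _PENALTY
    rows = _rows if _rows is not None else _log_rows(log)
    total = 0.0
    state = None
    current_block = None
    for block, is_rating, arm, outcome, value, conf, value_o, conf_o in rows:
        if block != current_block:
            state = BeliefState.initial(params)
            current_block = block
        if is_rating:
            if outcome is not None:
                update_belief(state, arm, outcome, params)
            total += _rating_loglik(state, arm, value, conf, params)
            if value_o is not None or conf_o is not None:
                total += _rating_loglik(state, 1 - arm, value_o, conf_o, params)
        else:
            v0, v1 = float(state.est_value[0]), float(state.est_value[1])
            if v0 == v1:
                p_arm = 0.5
            else:
                p_explore = explore_probability(state, params)
                low = 0 if v0 < v1 else 1
                p_arm = p_explore if arm == low else 1.0 - p_explore
            total += math.log(max(p_arm, 1e-12))
            if outcome is not None:
                update_belief(state, arm, outcome, params)
    if not math.isfinite(total):
        return _PENALTY
    return -total


def _default_start(model_tag: str) -> dict[str, float]:
    base = AgentParams(model_tag=model_tag)
    return {name: getattr(base, name) for name in FREE_PARAMS[model_tag]}


def fit(
    log: pd.DataFrame,
    model_tag: str,
    n_restarts: int = 10,
    seed: int = 0,
    n_particles: int = 100,
    maxiter: int = 400,
) -> FitResult:
    """Bounded multi-start ML fit of one model family to one subject.

    The first start is the family's default parameter vector; the rest
    are drawn uniformly inside the bounds from a seeded generator.
    """
    rows = _log_rows(log)
    if len(rows) < 50:
        raise ValueError(f"need >= 50 trials to fit, got {len(rows)}")
    names = FREE_PARAMS[model_tag]
    bounds = [PARAM_BOUNDS[n] for n in names]
    rng = np.random.default_rng(seed)

    fixed = {"n_particles": n_particles, "rng_seed": int(seed)}

    def objective(x: np.ndarray) -> float:
        kwargs = {n: float(v) for n, v in zip(names, x)}
        try:
            p = AgentParams(model_tag=model_tag, **kwargs, **fixed)
        except ValueError:
            return _PENALTY
        return nll(log, model_tag, p, _rows=rows)

    starts = [np.array([_default_start(model_tag)[n] for n in names])]
    for _ in range(max(0, n_restarts - 1)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best = None
    n_ok = 0
    for x0 in starts:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                objective, x0, method="Nelder-Mead",
                options={"maxiter": maxiter, "xatol": 1e-3, "fatol": 1e-3},
            )
        if not math.isfinite(res.fun) or res.fun >= _PENALTY:
            continue
        n_ok += 1
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError(f"all {len(starts)} restarts failed for {model_tag}")
    k = len(names)
    n_obs = len(rows)
    value = float(best.fun)
    return FitResult(
        model_tag=model_tag,
        params={n: float(np.clip(v, *PARAM_BOUNDS[n]))
                for n, v in zip(names, best.x)},
        nll=value,
        bic=k * math.log(n_obs) + 2.0 * value,
        n_obs=n_obs,
        converged=bool(best.success),
        n_restarts=n_ok,
    )


def compare(
    log: pd.DataFrame,
    model_tags: tuple[str, ...] = ("ideal", "rl", "particle"),
    subject_col: str = "subject",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fit several model families per subject; rank them by summed BIC.

    Returns the tidy per-subject fit table with columns ``subject``,
    ``model``, the fitted parameters, ``nll``, ``bic``; the summed-BIC
    ranking and per-subject best-model counts are in ``.attrs['summed_bic']``
    and ``.attrs['best_counts']``.
    """
    if len(model_tags) < 2:
        raise ValueError("need at least 2 models to compare")
    rows = []
    for subject, grp in log.groupby(subject_col, sort=False):
        for tag in model_tags:
            result = fit(grp, tag, **fit_kwargs)
            rows.append({"subject": subject, **result.to_row()})
    table = pd.DataFrame(rows)
    summed = table.groupby("model")["bic"].sum().sort_values()
    best = (
        table.loc[table.groupby("subject")["bic"].idxmin(), "model"]
        .value_counts()
    )
    table.attrs["summed_bic"] = summed.to_dict()
    table.attrs["best_counts"] = best.to_dict()
    table.attrs["winner"] = summed.index[0]
    return table
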